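"""Run- and library-level sequencing QC.

Run metrics (ISP loading, usable reads) are advisory: a poor run is flagged
but never blocks processing, because individual libraries are judged on
their own merits.  Library metrics gate reporting: a library needs at least
800x mean target coverage, 80% of mapped reads on target and 100,000 mapped
reads.  All thresholds are inclusive ("at least X" passes at exactly X).

Also provides the FF-vs-FFPE comparison statistics: Welch t-tests on QC
metrics, amplicon-length coverage binning (FFPE coverage decays with
amplicon length because formalin fragments the template), and the
substitution-spectrum chi-squared test that exposes the FFPE C:G>T:A
deamination excess.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .panel import Panel
from .variants import VariantCall

log = logging.getLogger(__name__)

MATERIALS = ("FF", "FFPE")

#: the 12 single-nucleotide substitution classes, lexicographic
SUBSTITUTION_CLASSES = tuple(
    f"{r}>{a}" for r in "ACGT" for a in "ACGT" if r != a
)
#: classes attributable to formalin-induced cytosine deamination
DEAMINATION_CLASSES = ("C>T", "G>A")


@dataclass
class RunQC:
    """Per-run quality metrics from the sequencer's run report."""

    run_id: str
    isp_density_pct: float
    usable_reads_pct: float
    polyclonal_pct: float = 0.0
    low_quality_pct: float = 0.0
    run_date: str | None = None
    material: str = "mixed"

    def __post_init__(self) -> None:
        for name in ("isp_density_pct", "usable_reads_pct", "polyclonal_pct",
                     "low_quality_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{self.run_id}: {name}={v} outside [0, 100]")


@dataclass
class LibraryQC:
    """Per-library quality metrics from coverage analysis."""

    sample_id: str
    material: str
    mean_coverage: float
    mapped_reads: int
    on_target_pct: float
    tumour_pct: float | None = None

    def __post_init__(self) -> None:
        if self.material not in MATERIALS:
            raise ValueError(f"{self.sample_id}: material must be FF or FFPE")
        if self.mean_coverage < 0:
            raise ValueError(f"{self.sample_id}: negative mean_coverage")
        if not 0 <= self.on_target_pct <= 100:
            raise ValueError(f"{self.sample_id}: on_target_pct outside [0, 100]")


@dataclass
class QCThresholds:
    run_min_isp_pct: float = 30.0
    run_min_usable_pct: float = 30.0
    lib_min_mean_coverage: float = 800.0
    lib_min_on_target_pct: float = 80.0
    lib_min_mapped_reads: int = 100_000
    amplicon_min_mean_coverage: float = 100.0

    def __post_init__(self) -> None:
        for name, v in vars(self).items():
            if v < 0:
                raise ValueError(f"{name} must be non-negative")


def evaluate_run(run: RunQC, t: QCThresholds | None = None) -> tuple[str, list[str]]:
    """Advisory run evaluation: ``("good"|"poor", reasons)``.

    A poor run is never rejected outright; its libraries are still
    evaluated individually.
    """
    t = t or QCThresholds()
    reasons = []
    if run.isp_density_pct < t.run_min_isp_pct:
        reasons.append("isp_density")
    if run.usable_reads_pct < t.run_min_usable_pct:
        reasons.append("usable_reads")
    return ("poor" if reasons else "good", reasons)


def evaluate_library(lib: LibraryQC, t: QCThresholds | None = None) -> tuple[str, list[str]]:
    """Gating library evaluation: ``("pass"|"fail", reasons)``.

    Failing libraries are excluded from variant reporting.
    """
    t = t or QCThresholds()
    reasons = []
    if lib.mean_coverage < t.lib_min_mean_coverage:
        reasons.append("mean_coverage")
    if lib.on_target_pct < t.lib_min_on_target_pct:
        reasons.append("on_target")
    if lib.mapped_reads < t.lib_min_mapped_reads:
        reasons.append("mapped_reads")
    return ("fail" if reasons else "pass", reasons)


def exclusion_summary(
    libs: Sequence[LibraryQC], t: QCThresholds | None = None
) -> dict[str, float | None]:
    """Cohort exclusion statistics under the mean-coverage rule.

    Exclusion is keyed on mean coverage alone (< lib_min_mean_coverage);
    among excluded libraries the share with low on-target and the share of
    FFPE material are reported.  Percentages are rounded to 1 decimal; the
    conditional shares are None when nothing is excluded.
    """
    if not libs:
        raise ValueError("exclusion_summary requires >= 1 library")
    t = t or QCThresholds()
    excluded = [l for l in libs if l.mean_coverage < t.lib_min_mean_coverage]
    out: dict[str, float | None] = {
        "pct_excluded": round(100.0 * len(excluded) / len(libs), 1)
    }
    if not excluded:
        out["pct_excluded_with_low_on_target"] = None
        out["pct_excluded_ffpe"] = None
    else:
        low_ot = sum(1 for l in excluded if l.on_target_pct < t.lib_min_on_target_pct)
        ffpe = sum(1 for l in excluded if l.material == "FFPE")
        out["pct_excluded_with_low_on_target"] = round(100.0 * low_ot / len(excluded), 1)
        out["pct_excluded_ffpe"] = round(100.0 * ffpe / len(excluded), 1)
    return out


def compare_groups(
    ff: Sequence[float], ffpe: Sequence[float], welch: bool = True
) -> dict[str, float]:
    """Two-sided independent t-test between FF and FFPE metric values.

    Welch (unequal-variance) by default; ``welch=False`` pools variances.
    Degenerate case: identical group means with zero variance report p=1;
    differing means with zero variance report p=0 with a warning.
    """
    ff = np.asarray(ff, dtype=float)
    ffpe = np.asarray(ffpe, dtype=float)
    if len(ff) < 2 or len(ffpe) < 2:
        raise ValueError("each group needs >= 2 values")
    mean_ff, mean_ffpe = float(np.mean(ff)), float(np.mean(ffpe))
    diff = mean_ff - mean_ffpe
    if np.var(ff) == 0 and np.var(ffpe) == 0:
        if diff == 0:
            t_stat, p = 0.0, 1.0
        else:
            warnings.warn("zero variance in both groups; reporting p=0", stacklevel=2)
            t_stat, p = math.inf if diff > 0 else -math.inf, 0.0
    else:
        t_stat, p = stats.ttest_ind(ff, ffpe, equal_var=not welch)
    return {
        "mean_ff": mean_ff,
        "mean_ffpe": mean_ffpe,
        "difference": diff,
        "t_statistic": float(t_stat),
        "p_value": float(p),
    }


def coverage_by_length_bin(
    panel: Panel,
    coverage_tables: Mapping[str, Sequence[pd.DataFrame]],
    bin_width: int = 20,
) -> pd.DataFrame:
    """Average per-amplicon coverage by amplicon-length bin and material.

    ``coverage_tables`` maps material -> list of per-sample tables with
    columns ``amplicon_id`` and ``coverage``.  Bins are [k*w, (k+1)*w);
    averaging is over amplicons within a sample first, then over samples.
    Empty bins are omitted.
    """
    lengths = {a.id: a.length for a in panel}
    rows = []
    for material, tables in coverage_tables.items():
        per_sample_bins = []
        for tbl in tables:
            df = tbl.copy()
            missing = set(lengths) - set(df["amplicon_id"])
            if missing:
                raise ValueError(f"coverage table missing amplicons: {sorted(missing)[:5]}")
            df["length"] = df["amplicon_id"].map(lengths)
            df["bin_start"] = (df["length"] // bin_width) * bin_width
            per_sample_bins.append(df.groupby("bin_start")["coverage"].mean())
        combined = pd.concat(per_sample_bins, axis=1).mean(axis=1)
        for bin_start, cov in combined.items():
            rows.append(
                {
                    "bin_start": int(bin_start),
                    "bin_end": int(bin_start) + bin_width,
                    "material": material,
                    "mean_coverage": float(cov),
                }
            )
    return (
        pd.DataFrame(rows, columns=["bin_start", "bin_end", "material", "mean_coverage"])
        .sort_values(["material", "bin_start"])
        .reset_index(drop=True)
    )


def substitution_spectrum(variants: Iterable[VariantCall]) -> dict[str, int]:
    """Counts of SNVs over the 12 substitution classes.

    Indels are ignored (their count is logged).  The returned dict also
    carries the 2-class collapse under keys ``"C:G>T:A"`` (C>T plus G>A,
    the FFPE deamination signature) and ``"other"``.
    """
    counts = {c: 0 for c in SUBSTITUTION_CLASSES}
    n_indels = 0
    for v in variants:
        if v.is_snv:
            key = f"{v.ref.upper()}>{v.alt.upper()}"
            if key in counts:
                counts[key] += 1
        else:
            n_indels += 1
    if n_indels:
        log.info("substitution_spectrum: ignored %d non-SNV records", n_indels)
    deam = sum(counts[c] for c in DEAMINATION_CLASSES)
    counts["C:G>T:A"] = deam
    counts["other"] = sum(counts[c] for c in SUBSTITUTION_CLASSES) - deam
    return counts


def spectrum_test(
    ff_counts: Mapping[str, int], ffpe_counts: Mapping[str, int]
) -> dict[str, float]:
    """Chi-squared homogeneity test of two substitution spectra.

    Operates on the 12 substitution classes (collapse keys are ignored);
    classes empty in both groups are dropped.  Uses the uncorrected
    chi-squared statistic.
    """
    classes = [
        c
        for c in SUBSTITUTION_CLASSES
        if ff_counts.get(c, 0) + ffpe_counts.get(c, 0) > 0
    ]
    if not classes:
        raise ValueError("all substitution classes empty in both groups")
    table = np.array(
        [[ff_counts.get(c, 0) for c in classes],
         [ffpe_counts.get(c, 0) for c in classes]]
    )
    # a group with zero total has no distribution to compare
    if table.sum(axis=1).min() == 0:
        raise ValueError("one group has zero SNVs")
    if len(classes) == 1:
        return {"statistic": 0.0, "p_value": 1.0, "df": 0}
    chi2, p, dof, _ = stats.chi2_contingency(table, correction=False)
    return {"statistic": float(chi2), "p_value": float(p), "df": int(dof)}


# ---------------------------------------------------------------------------
# TSV I/O


def read_library_qc_tsv(path: str | Path) -> list[LibraryQC]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        tumour = getattr(row, "tumour_pct", None)
        out.append(
            LibraryQC(
                sample_id=str(row.sample_id),
                material=str(row.material),
                mean_coverage=float(row.mean_coverage),
                mapped_reads=int(row.mapped_reads),
                on_target_pct=float(row.on_target_pct),
                tumour_pct=None if tumour is None or pd.isna(tumour) else float(tumour),
            )
        )
    return out


def write_library_qc_tsv(libs: Sequence[LibraryQC], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": l.sample_id,
                "material": l.material,
                "mean_coverage": l.mean_coverage,
                "mapped_reads": l.mapped_reads,
                "on_target_pct": l.on_target_pct,
                "tumour_pct": l.tumour_pct,
            }
            for l in libs
        ]
    ).to_csv(path, sep="\t", index=False)


def read_run_qc_tsv(path: str | Path) -> list[RunQC]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            RunQC(
                run_id=str(row.run_id),
                isp_density_pct=float(row.isp_density_pct),
                usable_reads_pct=float(row.usable_reads_pct),
                polyclonal_pct=float(getattr(row, "polyclonal_pct", 0.0)),
                low_quality_pct=float(getattr(row, "low_quality_pct", 0.0)),
                run_date=str(getattr(row, "run_date", "")) or None,
                material=str(getattr(row, "material", "mixed")),
            )
        )
    return out


def metric_trend(runs: Sequence[RunQC], metric: str) -> dict[str, float]:
    """Least-squares slope of a run metric over run order (temporal drift)."""
    values = np.array([getattr(r, metric) for r in runs], dtype=float)
    if len(values) < 2:
        raise ValueError("need >= 2 runs for a trend")
    x = np.arange(len(values), dtype=float)
    res = stats.linregress(x, values)
    return {"slope": float(res.slope), "intercept": float(res.intercept)}
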