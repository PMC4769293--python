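"""Detection-power model for somatic variants in impure tumour samples.

A heterozygous somatic mutation in a diploid tumour of purity ``f`` is
expected at VAF ``f/2``.  Calling it requires at least ``n_min`` mutant
reads, so the coverage needed scales as ``n_min / (f/2)``; the model adds a
configurable safety factor (default 2) so that the expected mutant-read
count at the recommended coverage is twice the calling threshold, which
keeps the binomial detection probability near 1 rather than near 1/2.
With the defaults (n_min=20, safety 2) a 10%-purity sample needs 800x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class DetectionParams:
    """Parameters of the coverage-requirement model.

    n_min
        Minimum mutant reads for a confident call (assay operating point: 20).
    ploidy, mutant_copies
        Tumour-cell genotype assumption; 2 and 1 give the heterozygous
        diploid expectation VAF = f/2.
    safety_factor
        Multiplier on the naive coverage requirement so the expected
        mutant-read count exceeds n_min with margin.
    vaf_floor, min_tumour_fraction
        The assay's reporting floor (5% VAF) and minimum accepted tumour
        cell content (10%); recorded here for downstream consumers.
    """

    n_min: int = 20
    ploidy: int = 2
    mutant_copies: int = 1
    safety_factor: float = 2.0
    vaf_floor: float = 0.05
    min_tumour_fraction: float = 0.10

    def __post_init__(self) -> None:
        if self.n_min < 1:
            raise ValueError("n_min must be >= 1")
        if not 1 <= self.mutant_copies <= self.ploidy:
            raise ValueError("mutant_copies must be in [1, ploidy]")
        if self.safety_factor < 1:
            raise ValueError("safety_factor must be >= 1")


def expected_vaf(
    tumour_fraction: float, ploidy: int = 2, mutant_copies: int = 1
) -> float:
    """Expected VAF of a clonal mutation at the given tumour cell fraction.

    For a mutation on ``mutant_copies`` of ``ploidy`` chromosomes in every
    tumour cell, diluted by normal cells: ``f * mutant_copies / ploidy``.
    10% tumour cells, heterozygous diploid -> 5% VAF.
    """
    if not 0 <= tumour_fraction <= 1:
        raise ValueError(f"tumour_fraction {tumour_fraction} outside [0, 1]")
    return tumour_fraction * mutant_copies / ploidy


def required_coverage(p: DetectionParams, tumour_fraction: float) -> int:
    """Coverage needed to expect ``safety_factor * n_min`` mutant reads."""
    vaf = expected_vaf(tumour_fraction, p.ploidy, p.mutant_copies)
    if vaf == 0:
        raise ValueError("expected VAF is 0; tumour_fraction must be > 0")
    # tolerance guards ceil against float error on exactly-representable points
    return math.ceil(p.safety_factor * p.n_min / vaf - 1e-9)


def detection_probability(coverage: int, vaf: float, n_min: int) -> float:
    """P(at least n_min mutant reads) with alt reads ~ Binomial(coverage, vaf)."""
    if coverage < 0:
        raise ValueError("coverage must be >= 0")
    if not 0 <= vaf <= 1:
        raise ValueError("vaf must be in [0, 1]")
    if n_min <= 0:
        return 1.0
    if n_min > coverage:
        return 0.0
    return float(stats.binom.sf(n_min - 1, coverage, vaf))


def min_detectable_tumour_fraction(coverage: float, p: DetectionParams) -> float:
    """Smallest tumour fraction whose required coverage fits in ``coverage``.

    Closed form: safety * n_min * ploidy / (mutant_copies * coverage),
    clipped to [0, 1].
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    f = p.safety_factor * p.n_min * p.ploidy / (p.mutant_copies * coverage)
    return min(max(f, 0.0), 1.0)


def power_curve(
    p: DetectionParams,
    tumour_fractions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Tabulate required coverage and detection power over tumour fractions."""
    if tumour_fractions is None:
        tumour_fractions = np.arange(0.05, 1.0001, 0.05)
    rows = []
    for f in np.asarray(tumour_fractions, dtype=float):
        vaf = expected_vaf(f, p.ploidy, p.mutant_copies)
        cov = required_coverage(p, f)
        rows.append(
            {
                "tumour_fraction": round(float(f), 4),
                "expected_vaf": vaf,
                "required_coverage": cov,
                "detection_probability": detection_probability(cov, vaf, p.n_min),
            }
        )
    return pd.DataFrame(rows)


def dilution_regression(points) -> dict[str, float]:
    """OLS of observed on expected VAF for a dilution series.

    ``points`` is an iterable of (expected_vaf, observed_vaf).  Returns
    slope, intercept and r_squared; a perfectly linear series gives
    slope 1 (or the dilution bias) and r_squared 1.
    """
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("need >= 3 dilution points")
    x = np.array([p[0] for p in pts], dtype=float)
    y = np.array([p[1] for p in pts], dtype=float)
    if np.allclose(x, x[0]):
        raise ValueError("expected VAFs are all equal; regression degenerate")
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
    }


def purity_vaf_analysis(pairs) -> dict[str, object]:
    """Relationship between pathologist tumour percentage and observed VAF.

    ``pairs`` is an iterable of (tumour_pct, vaf) with tumour_pct in percent.
    Returns the Pearson correlation, the forced least-squares line of VAF on
    tumour %, and a table adding the theoretical heterozygous expectation
    ``vaf = tumour_pct / 200`` for comparison.  A flat VAF profile (zero
    variance) is reported as correlation 0.
    """
    pts = list(pairs)
    if len(pts) < 3:
        raise ValueError("need >= 3 (tumour_pct, vaf) pairs")
    pct = np.array([p[0] for p in pts], dtype=float)
    vaf = np.array([p[1] for p in pts], dtype=float)
    if np.allclose(vaf, vaf[0]) or np.allclose(pct, pct[0]):
        corr = 0.0
        slope, intercept = 0.0, float(np.mean(vaf))
    else:
        corr = float(stats.pearsonr(pct, vaf)[0])
        res = stats.linregress(pct, vaf)
        slope, intercept = float(res.slope), float(res.intercept)
    table = pd.DataFrame(
        {
            "tumour_pct": pct,
            "vaf": vaf,
            "theoretical_het_vaf": pct / 200.0,
        }
    )
    return {
        "correlation": corr,
        "slope": slope,
        "intercept": intercept,
        "table": table,
    }
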