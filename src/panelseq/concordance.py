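"""Validation of panel NGS calls against orthogonal assays.

Each comparison of one variant (or one tested region) between NGS and a
conventional method (Sanger, high-resolution melting, allele-specific PCR)
becomes a :class:`ConcordanceRecord` with a category.  Overall concordance
counts both mutant and wildtype agreement; sensitivity is
concordant / (concordant + false negatives), the reading consistent with a
printed pair like 98.5% / 99.1% on 328 comparisons with 3 false negatives.
A discordance where NGS found a real low-VAF variant the reference assay
could not see (``ngs_only_sensitive``) counts against concordance but not
as a false positive of the NGS assay.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .panel import Panel
from .variants import VariantCall, normalize_variant

CATEGORIES = (
    "concordant_mutant",
    "concordant_wildtype",
    "false_negative",
    "false_positive",
    "ngs_only_sensitive",
    "uncovered",
)

#: substrings of the resolution note that mark superior NGS sensitivity
_SENSITIVITY_MARKERS = ("more sensitive", "low tumour", "low-tumour", "sensitivity")


@dataclass
class ConcordanceRecord:
    sample_id: str
    gene: str
    exon: str = "NA"
    variant_label: str = "NA"
    ngs_detected: bool = False
    reference_detected: bool = False
    panel_covered: bool = True
    category: str = "concordant_wildtype"
    note: str = ""

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if (self.category == "uncovered") != (not self.panel_covered):
            raise ValueError("category 'uncovered' iff panel_covered is False")
        if self.panel_covered:
            expected = classify_pair(
                self.ngs_detected, self.reference_detected, True, self.note
            )
            if expected != self.category:
                raise ValueError(
                    f"category {self.category!r} inconsistent with detection "
                    f"flags (expected {expected!r})"
                )


def classify_pair(
    ngs_detected: bool,
    reference_detected: bool,
    panel_covered: bool = True,
    resolution_note: str = "",
) -> str:
    """Category for one NGS-vs-reference comparison.

    An NGS-positive/reference-negative pair is a false positive unless the
    resolution note marks it as superior NGS sensitivity (the reference
    assay missed a real variant in low-tumour-content input).
    """
    if not panel_covered:
        return "uncovered"
    if ngs_detected and reference_detected:
        return "concordant_mutant"
    if not ngs_detected and not reference_detected:
        return "concordant_wildtype"
    if reference_detected:
        return "false_negative"
    note = resolution_note.lower()
    if any(m in note for m in _SENSITIVITY_MARKERS):
        return "ngs_only_sensitive"
    return "false_positive"


@dataclass
class ValidationStats:
    n_total: int
    n_concordant: int
    n_discordant: int
    n_false_negative: int
    n_false_positive: int
    n_ngs_only_sensitive: int
    n_uncovered: int
    concordance_pct: float
    sensitivity_pct: float
    per_gene: pd.DataFrame


def concordance_stats(records: Sequence[ConcordanceRecord]) -> ValidationStats:
    """Overall validation statistics; uncovered records are excluded first.

    concordance = 100 * (concordant_mutant + concordant_wildtype) / n_total
    sensitivity = 100 * concordant / (concordant + false_negatives)

    Percentages are rounded to 1 decimal.
    """
    covered = [r for r in records if r.panel_covered]
    if not covered:
        raise ValueError("no covered records to evaluate")
    n = {c: sum(1 for r in covered if r.category == c) for c in CATEGORIES}
    n_conc = n["concordant_mutant"] + n["concordant_wildtype"]
    n_disc = n["false_negative"] + n["false_positive"] + n["ngs_only_sensitive"]
    sens_denom = n_conc + n["false_negative"]
    return ValidationStats(
        n_total=len(covered),
        n_concordant=n_conc,
        n_discordant=n_disc,
        n_false_negative=n["false_negative"],
        n_false_positive=n["false_positive"],
        n_ngs_only_sensitive=n["ngs_only_sensitive"],
        n_uncovered=sum(1 for r in records if not r.panel_covered),
        concordance_pct=round(100.0 * n_conc / len(covered), 1),
        sensitivity_pct=round(100.0 * n_conc / sens_denom, 1) if sens_denom else 0.0,
        per_gene=per_gene_summary(records),
    )


def per_gene_summary(records: Sequence[ConcordanceRecord]) -> pd.DataFrame:
    """Per-gene validation table, ordered by number of comparisons."""
    covered = [r for r in records if r.panel_covered]
    if not covered:
        return pd.DataFrame(
            columns=["gene", "n_tested", "n_concordant_mutant",
                     "n_concordant_wildtype", "n_discordant", "pct_mutant"]
        )
    rows = []
    for gene in sorted({r.gene for r in covered}):
        rs = [r for r in covered if r.gene == gene]
        cm = sum(1 for r in rs if r.category == "concordant_mutant")
        cw = sum(1 for r in rs if r.category == "concordant_wildtype")
        disc = len(rs) - cm - cw
        rows.append(
            {
                "gene": gene,
                "n_tested": len(rs),
                "n_concordant_mutant": cm,
                "n_concordant_wildtype": cw,
                "n_discordant": disc,
                "pct_mutant": round(100.0 * cm / len(rs), 1),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values(["n_tested", "gene"], ascending=[False, True])
        .reset_index(drop=True)
    )


def match_variants(
    ngs_calls: Sequence[VariantCall],
    reference_results: pd.DataFrame,
    panel: Panel,
    reference_seq: Mapping[str, str] | None = None,
) -> list[ConcordanceRecord]:
    """Pair NGS calls with orthogonal assay results.

    ``reference_results`` rows describe one assay result each: sample_id,
    gene, exon, chrom, start, end (tested region, 0-based half-open),
    detected (yes/no), optional pos/ref/alt of the reference-found variant,
    optional note.  Matching uses normalized (trimmed, left-aligned when a
    reference sequence is available) variant keys inside the tested region.
    NGS calls inside a tested region with no reference counterpart become
    false-positive candidates; reference variants in regions the panel does
    not cover are ``uncovered``.
    """
    required = {"sample_id", "gene", "exon", "chrom", "start", "end", "detected"}
    missing = required - set(reference_results.columns)
    if missing:
        raise ValueError(f"reference results missing columns: {sorted(missing)}")
    if reference_results[["chrom", "start", "end"]].isna().any().any():
        raise ValueError("reference result row without tested-region coordinates")
    records: list[ConcordanceRecord] = []
    consumed: set[int] = set()  # indices of NGS calls already matched
    calls = list(ngs_calls)
    keys = [c.normalized_key(reference_seq) for c in calls]
    for row in reference_results.itertuples(index=False):
        chrom, start, end = str(row.chrom), int(row.start), int(row.end)
        sample = str(row.sample_id)
        detected = str(row.detected).lower() in ("yes", "true", "1")
        note = str(getattr(row, "note", "") or "")
        covered = panel.covers_interval(chrom, start, end)
        in_region = [
            i
            for i, c in enumerate(calls)
            if c.sample_id == sample and c.chrom == chrom and start < c.pos <= end
        ]
        if detected and not pd.isna(getattr(row, "pos", float("nan"))):
            ref_key = "{}:{}:{}>{}".format(
                *normalize_variant(chrom, int(row.pos), str(row.ref),
                                   str(row.alt), reference_seq)
            )
            matches = [i for i in in_region if keys[i] == ref_key]
        else:
            matches = in_region if detected else []
        ngs_detected = bool(matches) if detected else bool(in_region)
        consumed.update(matches if detected else in_region)
        category = classify_pair(ngs_detected, detected, covered, note)
        records.append(
            ConcordanceRecord(
                sample_id=sample,
                gene=str(row.gene),
                exon=str(row.exon),
                variant_label=str(getattr(row, "variant", "NA") or "NA"),
                ngs_detected=ngs_detected if covered else False,
                reference_detected=detected,
                panel_covered=covered,
                category=category,
                note=note,
            )
        )
    # NGS calls inside tested regions that matched nothing
    tested = [
        (str(r.chrom), int(r.start), int(r.end), str(r.sample_id))
        for r in reference_results.itertuples(index=False)
    ]
    for i, c in enumerate(calls):
        if i in consumed:
            continue
        hit = any(
            c.sample_id == s and c.chrom == chrom and start < c.pos <= end
            for chrom, start, end, s in tested
        )
        if hit:
            records.append(
                ConcordanceRecord(
                    sample_id=c.sample_id,
                    gene=c.gene,
                    exon="NA",
                    variant_label=c.key(),
                    ngs_detected=True,
                    reference_detected=False,
                    panel_covered=True,
                    category="false_positive",
                    note="no orthogonal counterpart",
                )
            )
    return records


def write_records_tsv(records: Sequence[ConcordanceRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "sample_id": r.sample_id, "gene": r.gene, "exon": r.exon,
                "variant": r.variant_label,
                "ngs_detected": "yes" if r.ngs_detected else "no",
                "reference_detected": "yes" if r.reference_detected else "no",
                "panel_covered": "yes" if r.panel_covered else "no",
                "category": r.category, "note": r.note,
            }
            for r in records
        ]
    ).to_csv(path, sep="\t", index=False)
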