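"""Cohort-level mutation landscape summaries.

Tables behind the three standard cohort views for a hotspot panel: per-codon
mutation counts (the data behind lollipop plots), a gene x tumour-type
matrix of relative mutation counts (mutations per sample in the group), and
sample-level co-occurrence / mutual-exclusivity counts between genes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Sequence

import pandas as pd

from .triage import TriageDecision
from .variants import VariantCall

_AA_CHANGE = re.compile(r"^[A-Z*]([0-9]+)[A-Z*]$|^[A-Z*]?([0-9]+)")


@dataclass
class SampleMeta:
    sample_id: str
    patient_id: str
    material: str
    tumour_type: str
    tumour_pct: float | None = None

    def __post_init__(self) -> None:
        if self.tumour_pct is not None and not 0 <= self.tumour_pct <= 100:
            raise ValueError(f"{self.sample_id}: tumour_pct outside [0, 100]")


@dataclass(frozen=True)
class CodonCount:
    gene: str
    codon: int
    aa_changes: tuple[str, ...]
    count: int

    def __post_init__(self) -> None:
        if self.count < 1 or self.codon < 1:
            raise ValueError("count and codon must be >= 1")


def read_meta_tsv(path: str | Path) -> list[SampleMeta]:
    df = pd.read_csv(path, sep="\t")
    metas = []
    for row in df.itertuples(index=False):
        pct = getattr(row, "tumour_pct", None)
        metas.append(
            SampleMeta(
                sample_id=str(row.sample_id),
                patient_id=str(getattr(row, "patient_id", row.sample_id)),
                material=str(getattr(row, "material", "FFPE")),
                tumour_type=str(row.tumour_type),
                tumour_pct=None if pct is None or pd.isna(pct) else float(pct),
            )
        )
    ids = [m.sample_id for m in metas]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate sample_id in metadata")
    return metas


def _reported_variants(decisions: Sequence[TriageDecision]) -> list[VariantCall]:
    return [d.variant for d in decisions if d.status == "reported"]


def _codon_of(v: VariantCall) -> int | None:
    if not v.aa_change:
        return None
    m = _AA_CHANGE.match(v.aa_change)
    if not m:
        return None
    return int(m.group(1) or m.group(2))


def codon_counts(
    variants: Sequence[VariantCall],
) -> tuple[list[CodonCount], list[VariantCall]]:
    """Aggregate reported variants per (gene, codon).

    Returns ``(counts, unmapped)``; variants whose codon cannot be derived
    from the amino-acid change land in ``unmapped`` rather than being
    dropped silently.
    """
    buckets: dict[tuple[str, int], list[str]] = {}
    unmapped: list[VariantCall] = []
    for v in variants:
        codon = _codon_of(v)
        if codon is None:
            unmapped.append(v)
            continue
        buckets.setdefault((v.gene, codon), []).append(v.aa_change)
    counts = [
        CodonCount(gene=g, codon=c, aa_changes=tuple(sorted(set(labels))),
                   count=len(labels))
        for (g, c), labels in sorted(buckets.items())
    ]
    return counts, unmapped


def gene_by_tumour_matrix(
    variants: Sequence[VariantCall],
    meta: Sequence[SampleMeta],
    binarize: bool = False,
) -> pd.DataFrame:
    """Relative mutation counts: rows tumour types, columns genes.

    cell(t, g) = mutations in gene g among samples of type t, divided by
    the number of samples of type t.  With ``binarize`` a sample counts at
    most once per gene.
    """
    by_sample = {m.sample_id: m for m in meta}
    orphans = sorted({v.sample_id for v in variants} - set(by_sample))
    if orphans:
        raise ValueError(f"variants from samples without metadata: {orphans}")
    group_sizes: dict[str, int] = {}
    for m in meta:
        group_sizes[m.tumour_type] = group_sizes.get(m.tumour_type, 0) + 1
    genes = sorted({v.gene for v in variants})
    counts = pd.DataFrame(
        0.0, index=sorted(group_sizes), columns=genes
    )
    if binarize:
        seen = {(v.sample_id, v.gene) for v in variants}
        for sample_id, gene in seen:
            counts.loc[by_sample[sample_id].tumour_type, gene] += 1
    else:
        for v in variants:
            counts.loc[by_sample[v.sample_id].tumour_type, v.gene] += 1
    for t, size in group_sizes.items():
        counts.loc[t] /= size
    counts.index.name = "tumour_type"
    return counts


def cooccurrence_counts(
    variants: Sequence[VariantCall],
    meta: Sequence[SampleMeta],
    tumour_type: str | None = None,
    include_zero_pairs: bool = False,
) -> dict[str, pd.DataFrame]:
    """Sample-level gene co-occurrence counts and mutual-exclusivity report.

    Presence/absence of a mutated gene per sample; unordered gene pairs.
    The mutual-exclusivity list contains pairs never observed together
    whose marginals would expect >= 1 co-occurrence under independence.
    """
    by_sample_meta = {m.sample_id: m for m in meta}
    keep = {
        m.sample_id
        for m in meta
        if tumour_type is None or m.tumour_type == tumour_type
    }
    genes_per_sample: dict[str, set[str]] = {}
    for v in variants:
        if v.sample_id not in by_sample_meta:
            raise ValueError(f"variant from sample without metadata: {v.sample_id}")
        if v.sample_id in keep:
            genes_per_sample.setdefault(v.sample_id, set()).add(v.gene)
    n_samples = len(keep)
    marginals: dict[str, int] = {}
    for gs in genes_per_sample.values():
        for g in gs:
            marginals[g] = marginals.get(g, 0) + 1
    pair_counts: dict[tuple[str, str], int] = {}
    for gs in genes_per_sample.values():
        for a, b in combinations(sorted(gs), 2):
            pair_counts[(a, b)] = pair_counts.get((a, b), 0) + 1
    all_pairs = (
        list(combinations(sorted(marginals), 2)) if include_zero_pairs
        else sorted(pair_counts)
    )
    pairs = pd.DataFrame(
        [
            {"gene_a": a, "gene_b": b, "n_samples_both": pair_counts.get((a, b), 0)}
            for a, b in all_pairs
        ],
        columns=["gene_a", "gene_b", "n_samples_both"],
    )
    totals = pd.DataFrame(
        [{"gene": g, "n_samples": n} for g, n in sorted(marginals.items())],
        columns=["gene", "n_samples"],
    )
    exclusive_rows = []
    if n_samples:
        for a, b in combinations(sorted(marginals), 2):
            expected = marginals[a] * marginals[b] / n_samples
            if expected >= 1 and pair_counts.get((a, b), 0) == 0:
                exclusive_rows.append(
                    {"gene_a": a, "gene_b": b, "expected_cooccurrence": expected}
                )
    exclusive = pd.DataFrame(
        exclusive_rows, columns=["gene_a", "gene_b", "expected_cooccurrence"]
    )
    return {"pairs": pairs, "totals": totals, "mutually_exclusive": exclusive}


def per_patient_collapse(
    variants: Sequence[VariantCall], meta: Sequence[SampleMeta]
) -> tuple[list[VariantCall], list[SampleMeta]]:
    """Collapse multiple samples of one patient to a single pseudo-sample.

    Keeps one representative sample per patient (the first in metadata
    order) and re-labels that patient's variants to it, deduplicating
    identical variant keys.
    """
    rep: dict[str, SampleMeta] = {}
    sample_to_patient = {m.sample_id: m.patient_id for m in meta}
    for m in meta:
        rep.setdefault(m.patient_id, m)
    seen: set[tuple[str, str]] = set()
    collapsed: list[VariantCall] = []
    for v in variants:
        patient = sample_to_patient.get(v.sample_id)
        if patient is None:
            raise ValueError(f"variant from sample without metadata: {v.sample_id}")
        key = (patient, v.normalized_key())
        if key in seen:
            continue
        seen.add(key)
        from dataclasses import replace

        collapsed.append(replace(v, sample_id=rep[patient].sample_id))
    return collapsed, list(rep.values())


def write_codon_counts_tsv(counts: Sequence[CodonCount], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"gene": c.gene, "codon": c.codon,
             "aa_changes": ",".join(c.aa_changes), "count": c.count}
            for c in counts
        ],
        columns=["gene", "codon", "aa_changes", "count"],
    ).to_csv(path, sep="\t", index=False)
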