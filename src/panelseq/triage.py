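"""Somatic variant triage: annotate, filter, flag for review.

The cascade turns raw caller output into a reportable set with auditable
reasons, mirroring diagnostic practice for hotspot-panel sequencing:

1. annotation (consequence, amino-acid change, population allele frequency)
2. hard filters, in fixed order — non-impactful consequence (synonymous,
   UTR, intronic), coverage < 100x, VAF < 5%, probable germline (population
   AF at or above threshold), artifact blacklist
3. review flags on surviving variants — total depth <= 500, alt reads <= 30,
   homopolymer context, mandatory-inspection region.  Flags never reject on
   their own: they reproduce the criteria a technician applies during manual
   inspection of the alignments.

Probable germline variants are kept in a separate report section rather
than silently dropped, so they can be escalated for genetic counselling.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .panel import Panel
from .variants import VariantCall

log = logging.getLogger(__name__)

FILTER_ORDER = ("consequence", "low_coverage", "low_vaf", "germline", "blacklist")
REVIEW_FLAGS = ("low_total_depth", "low_alt_reads", "homopolymer_context",
                "mandatory_region")

#: consequences excluded from reporting
EXCLUDED_CONSEQUENCES = frozenset({"synonymous", "utr5", "utr3", "intronic"})

#: regions always inspected manually because large deletions can escape the
#: caller: all TP53 amplicons, KIT exons 9/11, PDGFRA exons 12/18,
#: EGFR exons 19/20
MANDATORY_REVIEW_REGIONS: tuple[tuple[str, str], ...] = (
    ("TP53", "*"),
    ("KIT", "9"),
    ("KIT", "11"),
    ("PDGFRA", "12"),
    ("PDGFRA", "18"),
    ("EGFR", "19"),
    ("EGFR", "20"),
)


@dataclass
class TriageParams:
    min_depth: int = 100
    min_vaf: float = 0.05
    germline_af_threshold: float = 0.01
    germline_mode: str = "threshold"  # "presence": any population entry filters
    excluded_consequences: frozenset[str] = EXCLUDED_CONSEQUENCES
    review_min_depth: int = 500
    review_min_alt_reads: int = 30
    homopolymer_min_run: int = 4
    blacklist: frozenset[str] = frozenset()
    mandatory_review_regions: tuple[tuple[str, str], ...] = MANDATORY_REVIEW_REGIONS

    def __post_init__(self) -> None:
        if not 0 < self.min_vaf < 1:
            raise ValueError("min_vaf must be in (0, 1)")
        if self.min_depth <= 0:
            raise ValueError("min_depth must be > 0")


@dataclass
class TriageDecision:
    variant: VariantCall
    status: str  # "reported" | "filtered"
    filter_reasons: list[str] = field(default_factory=list)
    review_flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.status == "filtered") != bool(self.filter_reasons):
            raise ValueError("status 'filtered' iff filter_reasons non-empty")
        if self.status == "filtered" and self.review_flags:
            raise ValueError("review flags only apply to reported variants")

    @property
    def primary_reason(self) -> str | None:
        return self.filter_reasons[0] if self.filter_reasons else None

    @property
    def is_probable_germline(self) -> bool:
        return "germline" in self.filter_reasons


# ---------------------------------------------------------------------------
# annotation


def read_transcript_table(path: str | Path) -> pd.DataFrame:
    """Transcript regions: chrom, start, end (0-based half-open), gene,
    exon, region_class in {coding, intronic, utr5, utr3, splice}, frame
    (codon phase at region start), optional codon_start (aa number of the
    first complete codon)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "exon": str})
    required = {"chrom", "start", "end", "gene", "exon", "region_class", "frame"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"transcript table missing columns: {sorted(missing)}")
    if "codon_start" not in df.columns:
        df["codon_start"] = 1
    return df


def read_population_table(path: str | Path) -> dict[str, dict[str, float]]:
    """Population AFs keyed on normalized variant key; columns key, source, af."""
    df = pd.read_csv(path, sep="\t")
    table: dict[str, dict[str, float]] = {}
    for row in df.itertuples(index=False):
        table.setdefault(str(row.key), {})[str(row.source)] = float(row.af)
    return table


def read_blacklist(path: str | Path) -> frozenset[str]:
    """Artifact blacklist: one normalized variant key per line (column 'key')."""
    df = pd.read_csv(path, sep="\t")
    return frozenset(str(k) for k in df["key"])


def _codon_consequence(
    v: VariantCall, region, reference: Mapping[str, str]
) -> tuple[str, str | None]:
    """Consequence and aa_change of a coding SNV by codon comparison."""
    seq = reference.get(v.chrom)
    if seq is None:
        return "missense", None
    start, frame = int(region.start), int(region.frame)
    offset = (v.pos - 1) - start
    if offset < frame:
        return "missense", None  # partial codon at region edge
    codon_idx = (offset - frame) // 3
    codon_start0 = start + frame + 3 * codon_idx
    if codon_start0 + 3 > len(seq):
        return "missense", None
    ref_codon = seq[codon_start0 : codon_start0 + 3].upper()
    within = (v.pos - 1) - codon_start0
    if ref_codon[within] != v.ref.upper():
        log.warning("%s: reference base mismatch at %s:%d", v.sample_id, v.chrom, v.pos)
    alt_codon = ref_codon[:within] + v.alt.upper() + ref_codon[within + 1 :]
    ref_aa = str(Seq(ref_codon).translate())
    alt_aa = str(Seq(alt_codon).translate())
    aa_number = int(getattr(region, "codon_start", 1)) + codon_idx
    aa_change = f"{ref_aa}{aa_number}{alt_aa}"
    if alt_aa == ref_aa:
        return "synonymous", aa_change
    if alt_aa == "*":
        return "nonsense", aa_change
    return "missense", aa_change


def annotate(
    v: VariantCall,
    transcripts: pd.DataFrame,
    population: Mapping[str, Mapping[str, float]] | None = None,
    reference: Mapping[str, str] | None = None,
) -> VariantCall:
    """Annotate a call with consequence, gene, aa change and population AFs.

    The transcript table plays the role of a local annotation source; the
    population table maps normalized variant keys to per-source allele
    frequencies.  A variant outside every transcript region keeps
    consequence ``unknown``.
    """
    hit = transcripts[
        (transcripts["chrom"] == v.chrom)
        & (transcripts["start"] < v.pos)
        & (v.pos <= transcripts["end"])
    ]
    consequence, gene, aa_change = "unknown", v.gene, v.aa_change
    if hit.empty:
        log.warning("variant %s outside all transcript regions", v.key())
    else:
        region = next(hit.itertuples(index=False))
        gene = str(region.gene)
        cls = str(region.region_class)
        if cls in ("intronic", "utr5", "utr3", "splice"):
            consequence = "intronic" if cls == "intronic" else cls
        elif cls == "coding":
            if v.is_indel:
                delta = abs(len(v.ref) - len(v.alt))
                consequence = "frameshift" if delta % 3 else "inframe_indel"
            elif reference is not None:
                consequence, aa_change = _codon_consequence(v, region, reference)
            else:
                consequence = "missense"  # no reference to compare codons
        else:
            consequence = "unknown"
    pop_af = dict(v.population_af)
    if population is not None:
        key = v.normalized_key(reference)
        pop_af.update(population.get(key, {}))
    return replace(
        v,
        consequence=consequence,
        gene=gene,
        aa_change=aa_change,
        population_af=pop_af,
    )


# ---------------------------------------------------------------------------
# homopolymer detection


def _runs(seq: str) -> list[tuple[int, int, str]]:
    """Maximal homopolymer runs as (start, end) offsets, 0-based half-open."""
    runs = []
    i = 0
    while i < len(seq):
        j = i
        while j < len(seq) and seq[j] == seq[i]:
            j += 1
        runs.append((i, j, seq[i]))
        i = j
    return runs


def affected_interval(v: VariantCall) -> tuple[int, int]:
    """Reference interval touched by the variant, 0-based half-open.

    SNV/MNP: the substituted bases.  Deletion (anchored): the deleted bases.
    Insertion: the zero-length point between anchor and next base.
    """
    p0 = v.pos - 1
    if len(v.ref) == len(v.alt):
        return p0, p0 + len(v.ref)
    if len(v.ref) > len(v.alt):  # deletion with anchor base
        return p0 + len(v.alt), p0 + len(v.ref)
    return p0 + len(v.ref), p0 + len(v.ref)  # insertion point


def detect_homopolymer(
    window: str,
    window_start: int,
    v: VariantCall,
    min_run: int = 4,
) -> bool:
    """Is the variant inside or immediately adjacent to a homopolymer run?

    ``window`` is reference sequence starting at 1-based ``window_start``;
    it must span the variant's affected interval plus ``min_run`` bases of
    context on each side.  True iff a run of >= min_run identical bases
    overlaps or directly abuts the affected interval.
    """
    a_start, a_end = affected_interval(v)
    w0 = window_start - 1  # 0-based offset of window in the chromosome
    need_lo = a_start - min_run
    need_hi = a_end + min_run
    if w0 > max(need_lo, 0) or w0 + len(window) < need_hi:
        raise ValueError(
            "window too small: need "
            f"[{need_lo}, {need_hi}) covered, got [{w0}, {w0 + len(window)})"
        )
    rel_start, rel_end = a_start - w0, a_end - w0
    for r_start, r_end, _base in _runs(window.upper()):
        if r_end - r_start < min_run:
            continue
        # overlap or adjacency with [rel_start, rel_end)
        if r_start <= rel_end and rel_start <= r_end:
            return True
    return False


# ---------------------------------------------------------------------------
# filter cascade


def apply_filters(
    v: VariantCall,
    p: TriageParams | None = None,
    reference: Mapping[str, str] | None = None,
) -> TriageDecision:
    """Run the ordered filter cascade on an annotated call.

    All failing reasons are recorded (the first is primary).  Boundary
    semantics: depth 100 and VAF 0.05 pass ("below 100x"/"below 5%" filter);
    review thresholds flag at exactly 500 reads / 30 alt reads ("more than"
    is required to escape the flag).
    """
    p = p or TriageParams()
    if v.total_depth is None or v.alt_depth is None or v.vaf is None:
        raise ValueError(f"{v.key()}: depth unknown; cannot be triaged")
    reasons = []
    if v.consequence in p.excluded_consequences:
        reasons.append("consequence")
    if v.total_depth < p.min_depth:
        reasons.append("low_coverage")
    if v.vaf < p.min_vaf:
        reasons.append("low_vaf")
    if v.population_af:
        if p.germline_mode == "presence" or any(
            af >= p.germline_af_threshold for af in v.population_af.values()
        ):
            reasons.append("germline")
    if v.normalized_key(reference) in p.blacklist:
        reasons.append("blacklist")
    if reasons:
        return TriageDecision(variant=v, status="filtered", filter_reasons=reasons)
    flags = []
    if v.total_depth <= p.review_min_depth:
        flags.append("low_total_depth")
    if v.alt_depth <= p.review_min_alt_reads:
        flags.append("low_alt_reads")
    if reference is not None and v.chrom in reference:
        seq = reference[v.chrom]
        a_start, a_end = affected_interval(v)
        lo = max(0, a_start - p.homopolymer_min_run - len(v.ref) - len(v.alt))
        hi = min(len(seq), a_end + p.homopolymer_min_run + len(v.ref) + len(v.alt))
        window = seq[lo:hi]
        try:
            if detect_homopolymer(window, lo + 1, v, p.homopolymer_min_run):
                flags.append("homopolymer_context")
        except ValueError:
            log.warning("homopolymer window truncated at contig edge for %s", v.key())
    if _in_mandatory_region(v, p.mandatory_review_regions):
        flags.append("mandatory_region")
    return TriageDecision(variant=v, status="reported", review_flags=flags)


def _in_mandatory_region(
    v: VariantCall, regions: Sequence[tuple[str, str]]
) -> bool:
    # exon-resolved matching needs exon annotation the call does not carry;
    # gene-level matching is the conservative (over-flagging) choice
    return any(v.gene == gene for gene, _exon in regions)


# ---------------------------------------------------------------------------
# per-sample triage


@dataclass
class SampleReport:
    sample_id: str
    reported: list[TriageDecision]
    filtered: list[TriageDecision]
    germline: list[TriageDecision]  # subset of filtered, for counselling
    mandatory_regions: pd.DataFrame  # gene, exon, amplicon_id, mean_coverage

    @property
    def decisions(self) -> list[TriageDecision]:
        return self.reported + self.filtered


def mandatory_region_table(
    panel: Panel,
    coverage: Mapping[str, float] | None,
    requested_genes: Sequence[str] = (),
    fixed_regions: Sequence[tuple[str, str]] = MANDATORY_REVIEW_REGIONS,
) -> pd.DataFrame:
    """Inspection list: requested genes plus the fixed high-risk regions,
    one row per panel amplicon with its mean coverage (NaN if unknown)."""
    wanted: list[tuple[str, str]] = [(g, "*") for g in requested_genes]
    wanted += [r for r in fixed_regions if r not in wanted]
    rows = []
    for gene, exon in wanted:
        for a in panel.amplicons_for_gene(gene):
            cov = coverage.get(a.id) if coverage else None
            rows.append(
                {
                    "gene": gene,
                    "exon": exon,
                    "amplicon_id": a.id,
                    "mean_coverage": float("nan") if cov is None else float(cov),
                }
            )
        if not panel.amplicons_for_gene(gene):
            rows.append(
                {"gene": gene, "exon": exon, "amplicon_id": "absent_from_panel",
                 "mean_coverage": float("nan")}
            )
    return pd.DataFrame(rows, columns=["gene", "exon", "amplicon_id", "mean_coverage"])


def triage_sample(
    variants: Sequence[VariantCall],
    panel: Panel,
    coverage: Mapping[str, float] | None = None,
    params: TriageParams | None = None,
    requested_genes: Sequence[str] = (),
    transcripts: pd.DataFrame | None = None,
    population: Mapping[str, Mapping[str, float]] | None = None,
    reference: Mapping[str, str] | None = None,
) -> SampleReport:
    """Full per-sample triage: annotate (optional), filter, flag, report."""
    params = params or TriageParams()
    sample_id = variants[0].sample_id if variants else "NA"
    decisions = []
    for v in variants:
        if transcripts is not None:
            v = annotate(v, transcripts, population, reference)
        elif population is not None:
            key = v.normalized_key(reference)
            pop = dict(v.population_af)
            pop.update(population.get(key, {}))
            v = replace(v, population_af=pop)
        decisions.append(apply_filters(v, params, reference))
    reported = [d for d in decisions if d.status == "reported"]
    filtered = [d for d in decisions if d.status == "filtered"]
    germline = [d for d in filtered if d.is_probable_germline]
    return SampleReport(
        sample_id=sample_id,
        reported=reported,
        filtered=filtered,
        germline=germline,
        mandatory_regions=mandatory_region_table(panel, coverage, requested_genes,
                                                 params.mandatory_review_regions),
    )


# ---------------------------------------------------------------------------
# report I/O

REPORT_COLUMNS = [
    "sample_id", "chrom", "pos", "ref", "alt", "gene", "consequence",
    "aa_change", "total_depth", "alt_depth", "vaf", "status",
    "filter_reasons", "review_flags", "population_af",
]


def write_triage_report(decisions: Sequence[TriageDecision], path: str | Path) -> None:
    """TSV report, one row per variant, deterministic column order.

    ``filter_reasons`` keeps cascade order (first = primary reason);
    round-trips through :func:`read_triage_report`.
    """
    rows = []
    for d in decisions:
        v = d.variant
        rows.append(
            {
                "sample_id": v.sample_id,
                "chrom": v.chrom,
                "pos": v.pos,
                "ref": v.ref,
                "alt": v.alt,
                "gene": v.gene,
                "consequence": v.consequence,
                "aa_change": v.aa_change or "",
                "total_depth": v.total_depth,
                "alt_depth": v.alt_depth,
                "vaf": f"{v.vaf:.6f}" if v.vaf is not None else "",
                "status": d.status,
                "filter_reasons": ",".join(d.filter_reasons),
                "review_flags": ",".join(d.review_flags),
                "population_af": json.dumps(v.population_af, sort_keys=True),
            }
        )
    pd.DataFrame(rows, columns=REPORT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_triage_report(path: str | Path) -> list[TriageDecision]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        v = VariantCall(
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref=str(row.ref),
            alt=str(row.alt),
            total_depth=int(row.total_depth),
            alt_depth=int(row.alt_depth),
            sample_id=str(row.sample_id),
            consequence=str(row.consequence),
            gene=str(row.gene),
            aa_change=str(row.aa_change) or None,
            population_af=json.loads(row.population_af) if row.population_af else {},
        )
        out.append(
            TriageDecision(
                variant=v,
                status=str(row.status),
                filter_reasons=[r for r in str(row.filter_reasons).split(",") if r],
                review_flags=[r for r in str(row.review_flags).split(",") if r],
            )
        )
    return out
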