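"""Variant records, allele normalization and VCF I/O.

A :class:`VariantCall` is the unit flowing through the triage cascade: one
alternate allele at one position in one sample, with the depth and alt-read
counts the filters need.  VCF positions are 1-based and stay 1-based.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import pysam

log = logging.getLogger(__name__)

CONSEQUENCES = (
    "missense",
    "nonsense",
    "frameshift",
    "inframe_indel",
    "splice",
    "synonymous",
    "utr5",
    "utr3",
    "intronic",
    "unknown",
)


@dataclass
class VariantCall:
    """One called variant (single alternate allele) in one sample.

    ``total_depth`` may be None when the source VCF carried no depth
    information; such records cannot be triaged and fail that precondition
    downstream.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    total_depth: int | None = None
    alt_depth: int | None = None
    vaf: float | None = None
    sample_id: str = "NA"
    consequence: str = "unknown"
    gene: str = "NA"
    aa_change: str | None = None
    population_af: dict[str, float] = field(default_factory=dict)
    cosmic_id: str | None = None

    def __post_init__(self) -> None:
        if self.consequence not in CONSEQUENCES:
            raise ValueError(f"unknown consequence {self.consequence!r}")
        if self.total_depth is not None and self.alt_depth is not None:
            if not 0 <= self.alt_depth <= self.total_depth:
                raise ValueError(
                    f"{self.key()}: alt_depth {self.alt_depth} outside "
                    f"[0, {self.total_depth}]"
                )
            if self.total_depth > 0:
                computed = self.alt_depth / self.total_depth
                if self.vaf is None:
                    self.vaf = computed
                elif abs(self.vaf - computed) > 1e-6:
                    raise ValueError(
                        f"{self.key()}: vaf {self.vaf} inconsistent with "
                        f"{self.alt_depth}/{self.total_depth}"
                    )

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != len(self.alt)

    def key(self) -> str:
        """Raw (un-normalized) variant key."""
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"

    def normalized_key(self, reference: Mapping[str, str] | None = None) -> str:
        chrom, pos, ref, alt = normalize_variant(
            self.chrom, self.pos, self.ref, self.alt, reference
        )
        return f"{chrom}:{pos}:{ref}>{alt}"


def normalize_variant(
    chrom: str,
    pos: int,
    ref: str,
    alt: str,
    reference: Mapping[str, str] | None = None,
) -> tuple[str, int, str, str]:
    """Normalize an allele pair: trim shared suffix/prefix, then left-align.

    Without normalization the same indel written left- and right-aligned
    fails blacklist and concordance matching.  Left-alignment shifts an
    indel through a repeat tract as long as the flanking reference base
    matches; it needs the reference sequence (``chrom -> sequence``,
    0-based strings) and is skipped when none is given.
    """
    ref, alt = ref.upper(), alt.upper()
    seq = reference.get(chrom) if reference is not None else None
    if seq is None:
        while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
        while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
        return chrom, pos, ref, alt
    # left-align against the reference: repeatedly strip a shared terminal
    # base and, when an allele empties, pull in the preceding reference base
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
        if not ref or not alt:
            if pos <= 1:
                break
            prev = seq[pos - 2].upper()
            ref, alt = prev + ref, prev + alt
            pos -= 1
            continue
        if not (ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1)):
            break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def _first_int(value) -> int | None:
    if value is None:
        return None
    if isinstance(value, (tuple, list)):
        value = value[0] if value else None
    try:
        return int(value)
    except (TypeError, ValueError):
        return None


def _alt_depth_from_record(rec, alt_index: int) -> int | None:
    """Alt-read count for one alternate allele, trying FORMAT then INFO.

    Prefers the first sample's FORMAT fields: AD (ref + one count per alt)
    or AO (one count per alt); falls back to INFO AO/AD.
    """
    if rec.samples:
        sample = rec.samples[0]
        ad = sample.get("AD")
        if ad is not None and len(ad) > alt_index + 1 and ad[alt_index + 1] is not None:
            return int(ad[alt_index + 1])
        ao = sample.get("AO")
        if ao is not None:
            if isinstance(ao, (tuple, list)):
                if len(ao) > alt_index and ao[alt_index] is not None:
                    return int(ao[alt_index])
            else:
                return int(ao)
    for tag in ("AO", "AD"):
        try:
            val = rec.info.get(tag)
        except (KeyError, ValueError):  # tag not declared in this header
            continue
        if val is None:
            continue
        if isinstance(val, (tuple, list)):
            if len(val) > alt_index and val[alt_index] is not None:
                return int(val[alt_index])
        else:
            return int(val)
    return None


def _total_depth_from_record(rec) -> int | None:
    if rec.samples:
        dp = _first_int(rec.samples[0].get("DP"))
        if dp is not None:
            return dp
    return _first_int(rec.info.get("DP"))


def read_variants_vcf(path: str | Path, sample_id: str | None = None) -> list[VariantCall]:
    """Read a VCF into :class:`VariantCall` records.

    Multi-allelic records are split into one record per alternate allele.
    Depth is taken from the first sample's FORMAT DP with AD/AO alt counts,
    falling back to INFO DP/AO; records without depth get ``total_depth=None``
    and a warning.  VAF is recomputed as alt/total whenever both are known.
    """
    path = Path(path)
    calls: list[VariantCall] = []
    with pysam.VariantFile(str(path)) as vcf:
        default_sample = sample_id or (
            list(vcf.header.samples)[0] if vcf.header.samples else path.stem
        )
        for rec in vcf:
            total = _total_depth_from_record(rec)
            for i, alt in enumerate(rec.alts or ()):
                alt_depth = _alt_depth_from_record(rec, i)
                if total is None or alt_depth is None:
                    warnings.warn(
                        f"{path.name}: {rec.chrom}:{rec.pos} missing depth "
                        "fields; record cannot be triaged",
                        stacklevel=2,
                    )
                    total_i, alt_i = None, None
                else:
                    total_i, alt_i = total, min(alt_depth, total)
                calls.append(
                    VariantCall(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=str(alt),
                        total_depth=total_i,
                        alt_depth=alt_i,
                        sample_id=default_sample,
                    )
                )
    return calls


VCF_HEADER_LINES = [
    '##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">',
    '##INFO=<ID=AO,Number=A,Type=Integer,Description="Alternate allele read count">',
    '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
    '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
]


def write_variants_vcf(
    calls: Sequence[VariantCall],
    path: str | Path,
    contigs: Sequence[str] | None = None,
) -> None:
    """Write calls as an uncompressed single-sample VCF (deterministic)."""
    if contigs is None:
        seen: dict[str, None] = {}
        for c in calls:
            seen.setdefault(c.chrom)
        contigs = list(seen)
    sample = calls[0].sample_id if calls else "SAMPLE"
    header = pysam.VariantHeader()
    for line in VCF_HEADER_LINES:
        header.add_line(line)
    for chrom in contigs:
        header.add_line(f"##contig=<ID={chrom}>")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for c in calls:
            rec = out.new_record(
                contig=c.chrom,
                start=c.pos - 1,
                stop=c.pos - 1 + len(c.ref),
                alleles=(c.ref, c.alt),
            )
            if c.total_depth is not None:
                rec.info["DP"] = c.total_depth
                rec.samples[sample]["DP"] = c.total_depth
            if c.alt_depth is not None:
                rec.info["AO"] = (c.alt_depth,)
                ref_depth = (
                    c.total_depth - c.alt_depth if c.total_depth is not None else 0
                )
                rec.samples[sample]["AD"] = (ref_depth, c.alt_depth)
            rec.samples[sample]["GT"] = (0, 1)
            out.write(rec)


def annotated_copy(call: VariantCall, **changes) -> VariantCall:
    """Return a copy of ``call`` with the given fields replaced."""
    return replace(call, **changes)
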