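"""Synthetic amplicon-panel data with the statistical structure of the assay.

Everything downstream is testable without patient data because this module
generates panels, reference sequence, coverage profiles and call sets with
the features the analyses assume:

* FF coverage is Poisson around the library depth; FFPE coverage decays
  multiplicatively with amplicon length beyond ~100 bp (formalin fragments
  the template), floored at 20% of the FF mean.
* somatic variants sit at VAF = tumour_fraction / 2 (heterozygous, diploid)
  with binomially sampled alt reads;
* germline SNPs sit at ~50% VAF and carry population allele frequencies in
  the emitted population table (somatic variants never do);
* FFPE deamination artifacts are exclusively C>T / G>A substitutions with
  Beta-distributed low VAFs;
* homopolymer artifacts are 1-bp indels inside planted runs of >= 4
  identical bases;
* dilution series scale a base VAF by known factors with binomial
  resampling at fixed depth.

Truth labels are returned for every simulated call so parameter-recovery
tests can check each class end to end.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .panel import Amplicon, Panel, write_panel_bed
from .qc import LibraryQC
from .variants import VariantCall, write_variants_vcf

TRUTH_CLASSES = ("somatic", "germline", "ffpe_artifact", "homopolymer_artifact")

#: gene symbols used for synthetic panels (hotspot-panel style)
PANEL_GENES = (
    "TP53", "KRAS", "EGFR", "BRAF", "NRAS", "KIT", "PDGFRA", "PIK3CA", "APC",
    "PTEN", "CTNNB1", "IDH1", "IDH2", "ERBB2", "ERBB4", "FGFR1", "FGFR2",
    "FGFR3", "MET", "ALK", "RET", "NOTCH1", "SMAD4", "STK11", "VHL", "RB1",
    "CDKN2A", "ATM", "CDH1", "MLH1", "SMO", "PTPN11", "JAK2", "JAK3", "ABL1",
    "AKT1", "CSF1R", "EZH2", "FLT3", "GNA11", "GNAQ", "GNAS", "HNF1A", "HRAS",
    "KDR", "MPL", "NPM1", "SRC", "FBXW7", "SMARCB1",
)

TUMOUR_TYPES = ("colorectal", "lung", "melanoma", "GIST", "other")

BASES = np.array(list("ACGT"))

#: concentration of the Beta distribution for artifact VAFs; mean is the
#: tunable parameter, the concentration keeps the mass well below the 5%
#: reporting floor as observed for deamination noise
ARTIFACT_BETA_CONCENTRATION = 200.0


@dataclass
class SimulationParams:
    """Study conditions for the synthetic cohort.

    Defaults follow the assay's design point: ~1000x mean library depth,
    heterozygous somatic variants at VAF = tumour_fraction/2, low-frequency
    (mean 2% VAF) FFPE deamination artifacts, and FFPE coverage decaying 1%
    per bp beyond 100 bp of amplicon length, floored at 0.2.
    """

    n_samples: int = 20
    material_mix: float = 0.5  # fraction FFPE
    tumour_fraction: float = 0.40
    depth_mean: float = 1000.0
    n_somatic: int = 2
    germline_rate: int = 10  # germline SNPs per panel
    ffpe_artifact_rate: int = 10  # per panel; 0 for FF libraries
    artifact_vaf_mean: float = 0.02
    homopolymer_artifact_rate: int = 2
    length_decay_start: float = 100.0
    length_decay_per_bp: float = 0.01
    length_decay_floor: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_somatic", "germline_rate",
                     "ffpe_artifact_rate", "homopolymer_artifact_rate",
                     "length_decay_per_bp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("material_mix", "tumour_fraction", "artifact_vaf_mean",
                     "length_decay_floor"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")


@dataclass(frozen=True)
class TruthRecord:
    """Ground-truth label for one simulated call."""

    chrom: str
    pos: int
    ref: str
    alt: str
    truth_class: str
    true_vaf: float
    sample_id: str = "NA"

    def __post_init__(self) -> None:
        if self.truth_class not in TRUTH_CLASSES:
            raise ValueError(f"unknown truth class {self.truth_class!r}")
        if not 0 < self.true_vaf <= 1:
            raise ValueError("true_vaf must be in (0, 1]")

    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


# ---------------------------------------------------------------------------
# panel + reference


def generate_panel(
    n_genes: int,
    n_amplicons: int,
    length_range: tuple[int, int] = (80, 160),
    seed: int = 0,
) -> tuple[Panel, dict[str, str]]:
    """Deterministic synthetic panel plus per-contig reference sequence.

    Amplicons are laid out non-overlapping with 30 bp gaps, one contig per
    gene; each amplicon gets a planted homopolymer run of 5-8 identical
    bases so homopolymer-context checks have real targets.  Returns
    ``(panel, reference)`` with ``reference`` mapping contig -> sequence.
    """
    if not 1 <= n_genes <= n_amplicons:
        raise ValueError("need n_amplicons >= n_genes >= 1")
    lo, hi = length_range
    if lo < 50 or hi < lo:
        raise ValueError("amplicon lengths must be >= 50 with min <= max")
    if n_genes > len(PANEL_GENES):
        raise ValueError(f"at most {len(PANEL_GENES)} genes supported")
    rng = np.random.default_rng(seed)
    genes = list(PANEL_GENES[:n_genes])
    # distribute amplicons round-robin so every gene gets at least one
    assignment = [genes[i % n_genes] for i in range(n_amplicons)]
    amplicons: list[Amplicon] = []
    reference: dict[str, str] = {}
    cursors: dict[str, int] = {}
    seqs: dict[str, list[str]] = {}
    counter: dict[str, int] = {}
    for gene in assignment:
        contig = f"chr_{gene}"
        if contig not in cursors:
            cursors[contig] = 30  # left flank
            seqs[contig] = list(rng.choice(BASES, size=30))
        counter[gene] = counter.get(gene, 0) + 1
        length = int(rng.integers(lo, hi + 1))
        start = cursors[contig]
        seq = list(rng.choice(BASES, size=length))
        # plant one homopolymer run of 5-8 bases away from the edges
        run_len = int(rng.integers(5, 9))
        run_base = str(rng.choice(BASES))
        run_at = int(rng.integers(10, length - run_len - 10))
        seq[run_at : run_at + run_len] = [run_base] * run_len
        # break accidental extension of the planted run
        if run_at > 0 and seq[run_at - 1] == run_base:
            seq[run_at - 1] = str(BASES[(list(BASES).index(run_base) + 1) % 4])
        after = run_at + run_len
        if after < length and seq[after] == run_base:
            seq[after] = str(BASES[(list(BASES).index(run_base) + 1) % 4])
        seqs[contig].extend(seq)
        seqs[contig].extend(rng.choice(BASES, size=30))  # gap / right flank
        amplicons.append(
            Amplicon(
                id=f"{gene}_amp{counter[gene]}",
                chrom=contig,
                start=start,
                end=start + length,
                gene=gene,
            )
        )
        cursors[contig] = start + length + 30
    reference = {c: "".join(s) for c, s in seqs.items()}
    return Panel(amplicons=amplicons, name=f"synthetic_{n_amplicons}"), reference


def planted_homopolymer_runs(
    reference: Mapping[str, str], min_run: int = 4
) -> list[tuple[str, int, int, str]]:
    """All runs of >= min_run identical bases as (contig, start0, end0, base)."""
    out = []
    for contig, seq in reference.items():
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            if j - i >= min_run:
                out.append((contig, i, j, seq[i]))
            i = j
    return out


# ---------------------------------------------------------------------------
# coverage / library simulation


def ffpe_length_multiplier(
    length: float,
    decay_start: float = 100.0,
    decay_per_bp: float = 0.01,
    floor: float = 0.2,
) -> float:
    """Coverage multiplier for an FFPE amplicon of the given length.

    Stable up to ``decay_start`` bp, then losing ``decay_per_bp`` of the
    mean per extra bp, floored."""
    return max(floor, 1.0 - decay_per_bp * max(0.0, length - decay_start))


def simulate_library(
    panel: Panel,
    material: str,
    params: SimulationParams | None = None,
    rng: np.random.Generator | None = None,
    sample_id: str = "S1",
) -> tuple[pd.DataFrame, LibraryQC]:
    """Per-amplicon coverage and library QC for one sample.

    FF coverage ~ Poisson(depth_mean) per amplicon; FFPE means are shrunk
    by the length-decay multiplier first.  The QC row is derived
    consistently: mean_coverage is the mean of per-amplicon coverages,
    on-target reads are the summed coverages, and mapped reads back out of
    the sampled on-target percentage.
    """
    params = params or SimulationParams()
    rng = rng if rng is not None else np.random.default_rng(params.seed)
    if material not in ("FF", "FFPE"):
        raise ValueError("material must be FF or FFPE")
    rows = []
    for a in panel:
        mean = params.depth_mean
        if material == "FFPE":
            mean *= ffpe_length_multiplier(
                a.length,
                params.length_decay_start,
                params.length_decay_per_bp,
                params.length_decay_floor,
            )
        rows.append(
            {
                "amplicon_id": a.id,
                "length": a.length,
                "coverage": int(rng.poisson(mean)),
            }
        )
    cov = pd.DataFrame(rows, columns=["amplicon_id", "length", "coverage"])
    # FF libraries run slightly cleaner than FFPE (higher on-target share)
    if material == "FF":
        on_target_pct = float(np.clip(rng.normal(95.0, 1.5), 50, 99.9))
    else:
        on_target_pct = float(np.clip(rng.normal(91.0, 3.0), 50, 99.9))
    on_target_reads = int(cov["coverage"].sum())
    lib = LibraryQC(
        sample_id=sample_id,
        material=material,
        mean_coverage=float(cov["coverage"].mean()),
        mapped_reads=int(round(on_target_reads / (on_target_pct / 100.0))),
        on_target_pct=round(on_target_pct, 1),
    )
    return cov, lib


# ---------------------------------------------------------------------------
# variant simulation


def _random_position(
    rng: np.random.Generator,
    amplicon: Amplicon,
    reference: Mapping[str, str],
    want_bases: str | None = None,
    margin: int = 5,
) -> tuple[int, str] | None:
    """Random 1-based position inside the amplicon (with edge margin),
    optionally restricted to reference bases in ``want_bases``."""
    seq = reference[amplicon.chrom]
    lo, hi = amplicon.start + margin, amplicon.end - margin
    if hi <= lo:
        return None
    candidates = np.arange(lo, hi)
    if want_bases is not None:
        mask = np.array([seq[i] in want_bases for i in candidates])
        candidates = candidates[mask]
        if len(candidates) == 0:
            return None
    idx = int(rng.choice(candidates))
    return idx + 1, seq[idx]  # 1-based


def _alt_for(rng: np.random.Generator, ref_base: str) -> str:
    choices = [b for b in "ACGT" if b != ref_base]
    return str(rng.choice(choices))


def simulate_variants(
    panel: Panel,
    tumour_fraction: float,
    depth_table: pd.DataFrame,
    params: SimulationParams | None = None,
    seed: int | np.random.Generator = 0,
    reference: Mapping[str, str] | None = None,
    material: str = "FFPE",
    sample_id: str = "S1",
    used_positions: set[tuple[str, int]] | None = None,
) -> tuple[list[VariantCall], list[TruthRecord], dict[str, dict[str, float]]]:
    """Simulate one sample's call set with truth labels.

    Returns ``(calls, truths, population_table)``; the population table
    carries allele frequencies only for germline truth variants, so the
    germline filter is exercisable and somatic variants can never match it.

    * somatic: alt reads ~ Binomial(depth, tumour_fraction/2)
    * germline: alt reads ~ Binomial(depth, 0.5), population AF ~ U(0.01, 0.5)
    * ffpe_artifact (FFPE only): C>T or G>A only, VAF ~ Beta with mean
      ``artifact_vaf_mean`` truncated to (0, 0.2]
    * homopolymer_artifact: 1-bp indel inside a planted run of >= 4 bases
    """
    params = params or SimulationParams()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if reference is None:
        raise ValueError("simulate_variants requires the synthetic reference")
    if tumour_fraction == 0 and params.n_somatic > 0:
        raise ValueError("cannot place somatic variants at tumour_fraction 0")
    depth_by_amp = dict(zip(depth_table["amplicon_id"], depth_table["coverage"]))
    missing = [a.id for a in panel if a.id not in depth_by_amp]
    if missing:
        raise ValueError(f"depth table missing amplicons: {missing[:5]}")
    calls: list[VariantCall] = []
    truths: list[TruthRecord] = []
    population: dict[str, dict[str, float]] = {}
    amplicons = list(panel)
    # one event per site (within the sample, and across the cohort when a
    # shared set is passed in): a somatic variant must never share a site
    # with a germline SNP or it would inherit that SNP's population AF
    used = used_positions if used_positions is not None else set()

    def emit_snv(truth_class: str, true_vaf: float, want_bases: str | None,
                 forced_alt: Mapping[str, str] | None = None) -> None:
        for _attempt in range(100):
            amp = amplicons[int(rng.integers(len(amplicons)))]
            found = _random_position(rng, amp, reference, want_bases)
            if found is None:
                continue
            pos, ref_base = found
            if (amp.chrom, pos) in used:
                continue
            depth = int(depth_by_amp[amp.id])
            if depth == 0:
                continue
            alt = forced_alt[ref_base] if forced_alt else _alt_for(rng, ref_base)
            alt_depth = int(rng.binomial(depth, true_vaf))
            if truth_class != "somatic":
                alt_depth = max(1, alt_depth)  # a caller never emits 0 alt reads
            elif alt_depth == 0:
                alt_depth = 1  # clamp: the call exists by construction
            call = VariantCall(
                chrom=amp.chrom, pos=pos, ref=ref_base, alt=alt,
                total_depth=depth, alt_depth=alt_depth,
                sample_id=sample_id, gene=amp.gene, consequence="missense",
            )
            truth = TruthRecord(
                chrom=amp.chrom, pos=pos, ref=ref_base, alt=alt,
                truth_class=truth_class, true_vaf=true_vaf, sample_id=sample_id,
            )
            calls.append(call)
            truths.append(truth)
            used.add((amp.chrom, pos))
            if truth_class == "germline":
                af = float(rng.uniform(0.01, 0.5))
                population[call.normalized_key()] = {"1000G": af}
            return
        raise RuntimeError("could not place variant after 100 attempts")

    for _ in range(params.n_somatic):
        emit_snv("somatic", tumour_fraction / 2.0, None)
    for _ in range(params.germline_rate):
        emit_snv("germline", 0.5, None)
    if material == "FFPE":
        a = params.artifact_vaf_mean * ARTIFACT_BETA_CONCENTRATION
        b = (1 - params.artifact_vaf_mean) * ARTIFACT_BETA_CONCENTRATION
        for _ in range(params.ffpe_artifact_rate):
            vaf = float(np.clip(rng.beta(a, b), 1e-4, 0.2))
            emit_snv("ffpe_artifact", vaf, "CG", forced_alt={"C": "T", "G": "A"})
        runs = planted_homopolymer_runs(reference)
        for _ in range(params.homopolymer_artifact_rate):
            vaf = float(np.clip(rng.beta(a, b), 1e-4, 0.2))
            contig, r_start, r_end, base = runs[int(rng.integers(len(runs)))]
            amp = next(
                (x for x in panel if x.chrom == contig and x.start <= r_start < x.end),
                None,
            )
            if amp is None:
                continue
            depth = int(depth_by_amp[amp.id])
            anchor_pos = r_start  # 1-based position of base before the run
            if anchor_pos < 1 or (contig, anchor_pos) in used:
                continue
            anchor = reference[contig][anchor_pos - 1]
            if rng.random() < 0.5:  # insertion of one run base
                ref_a, alt_a = anchor, anchor + base
            else:  # deletion of one run base
                ref_a, alt_a = anchor + base, anchor
            used.add((contig, anchor_pos))
            alt_depth = max(1, int(rng.binomial(depth, vaf)))
            calls.append(
                VariantCall(
                    chrom=contig, pos=anchor_pos, ref=ref_a, alt=alt_a,
                    total_depth=depth, alt_depth=min(alt_depth, depth),
                    sample_id=sample_id, gene=amp.gene, consequence="missense",
                )
            )
            truths.append(
                TruthRecord(
                    chrom=contig, pos=anchor_pos, ref=ref_a, alt=alt_a,
                    truth_class="homopolymer_artifact", true_vaf=vaf,
                    sample_id=sample_id,
                )
            )
    return calls, truths, population


def simulate_dilution_series(
    base_vaf: float,
    dilution_factors: Sequence[float],
    depth: int,
    seed: int | np.random.Generator = 0,
) -> list[tuple[float, float]]:
    """(expected, observed) VAF pairs for a dilution series.

    expected = base_vaf * factor; observed = Binomial(depth, expected)/depth.
    """
    if base_vaf * max(dilution_factors) > 1:
        raise ValueError("base_vaf * max(factor) must be <= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for f in dilution_factors:
        expected = base_vaf * f
        observed = rng.binomial(depth, expected) / depth if expected > 0 else 0.0
        out.append((float(expected), float(observed)))
    return out


# ---------------------------------------------------------------------------
# cohort simulation


@dataclass
class SimulatedSample:
    sample_id: str
    patient_id: str
    material: str
    tumour_type: str
    tumour_fraction: float
    coverage: pd.DataFrame
    library_qc: LibraryQC
    calls: list[VariantCall]
    truths: list[TruthRecord]


@dataclass
class SimulatedCohort:
    panel: Panel
    reference: dict[str, str]
    samples: list[SimulatedSample]
    population: dict[str, dict[str, float]]

    @property
    def meta(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "patient_id": s.patient_id,
                    "material": s.material,
                    "tumour_type": s.tumour_type,
                    "tumour_pct": round(100 * s.tumour_fraction, 1),
                }
                for s in self.samples
            ]
        )


def simulate_cohort(
    params: SimulationParams | None = None,
    n_genes: int = 50,
    n_amplicons: int = 207,
) -> SimulatedCohort:
    """Simulate a full cohort: panel, libraries, call sets, truth, metadata."""
    params = params or SimulationParams()
    rng = np.random.default_rng(params.seed)
    panel, reference = generate_panel(n_genes, n_amplicons, seed=params.seed)
    n_ffpe = int(round(params.n_samples * params.material_mix))
    samples = []
    population: dict[str, dict[str, float]] = {}
    used_positions: set[tuple[str, int]] = set()
    for i in range(params.n_samples):
        material = "FFPE" if i < n_ffpe else "FF"
        sid = f"S{i + 1:03d}"
        tumour_fraction = float(np.clip(rng.normal(params.tumour_fraction, 0.15),
                                        0.10, 0.95))
        cov, lib = simulate_library(panel, material, params, rng, sample_id=sid)
        lib.tumour_pct = round(100 * tumour_fraction, 1)
        calls, truths, pop = simulate_variants(
            panel, tumour_fraction, cov, params, rng,
            reference=reference, material=material, sample_id=sid,
            used_positions=used_positions,
        )
        population.update(pop)
        samples.append(
            SimulatedSample(
                sample_id=sid,
                patient_id=f"P{i + 1:03d}",
                material=material,
                tumour_type=str(rng.choice(TUMOUR_TYPES)),
                tumour_fraction=tumour_fraction,
                coverage=cov,
                library_qc=lib,
                calls=calls,
                truths=truths,
            )
        )
    return SimulatedCohort(panel=panel, reference=reference, samples=samples,
                           population=population)


# ---------------------------------------------------------------------------
# on-disk output


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> None:
    """Write a cohort as plain-text files: BED, FASTA, VCFs and TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_panel_bed(cohort.panel, outdir / "panel.bed")
    with open(outdir / "reference.fa", "w") as fh:
        for contig, seq in cohort.reference.items():
            fh.write(f">{contig}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")
    pop_rows = [
        {"key": key, "source": src, "af": af}
        for key, srcs in sorted(cohort.population.items())
        for src, af in sorted(srcs.items())
    ]
    pd.DataFrame(pop_rows, columns=["key", "source", "af"]).to_csv(
        outdir / "population_af.tsv", sep="\t", index=False
    )
    cohort.meta.to_csv(outdir / "meta.tsv", sep="\t", index=False)
    lib_rows, truth_rows, cov_rows = [], [], []
    for s in cohort.samples:
        write_variants_vcf(s.calls, outdir / f"{s.sample_id}.vcf",
                           contigs=sorted(cohort.reference))
        lib_rows.append(
            {
                "sample_id": s.sample_id,
                "material": s.material,
                "mean_coverage": s.library_qc.mean_coverage,
                "mapped_reads": s.library_qc.mapped_reads,
                "on_target_pct": s.library_qc.on_target_pct,
                "tumour_pct": s.library_qc.tumour_pct,
            }
        )
        for t in s.truths:
            truth_rows.append(
                {
                    "sample_id": t.sample_id, "chrom": t.chrom, "pos": t.pos,
                    "ref": t.ref, "alt": t.alt, "truth_class": t.truth_class,
                    "true_vaf": t.true_vaf,
                }
            )
        cov = s.coverage.copy()
        cov.insert(0, "sample_id", s.sample_id)
        cov_rows.append(cov)
    pd.DataFrame(lib_rows).to_csv(outdir / "library_qc.tsv", sep="\t", index=False)
    pd.DataFrame(
        truth_rows,
        columns=["sample_id", "chrom", "pos", "ref", "alt", "truth_class", "true_vaf"],
    ).to_csv(outdir / "truth.tsv", sep="\t", index=False)
    pd.concat(cov_rows, ignore_index=True).to_csv(
        outdir / "coverage.tsv", sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# validation fixture (orthogonal-method comparison)


def make_validation_fixture():
    """The packaged orthogonal-validation comparison set: 328 records.

    323 concordant calls plus the five discordant ones: two unresolved
    TP53 exon 8 G266E false negatives, one TP53 exon 7 c.757insA false
    negative (missed by the caller, visible on manual inspection), one TP53
    exon 7 c.723delC false positive (called, not visible on inspection),
    and one EGFR exon 20 L858R found only by the higher-sensitivity assay
    in a low-tumour-content sample (VAF 7.3%).
    """
    from .concordance import ConcordanceRecord

    records = []
    # concordant backbone: typical gene distribution of a validation series
    concordant_genes = (
        ["TP53"] * 120 + ["KRAS"] * 90 + ["EGFR"] * 50 + ["BRAF"] * 40
        + ["NRAS"] * 13 + ["PIK3CA"] * 10
    )
    assert len(concordant_genes) == 323
    n_wildtype = 80  # a share of the comparisons confirm wildtype status
    for i, gene in enumerate(concordant_genes):
        mutant = i >= n_wildtype
        records.append(
            ConcordanceRecord(
                sample_id=f"V{i + 1:03d}",
                gene=gene,
                exon="NA",
                variant_label="NA",
                ngs_detected=mutant,
                reference_detected=mutant,
                panel_covered=True,
                category="concordant_mutant" if mutant else "concordant_wildtype",
            )
        )
    discordant = [
        ("TP53", "8", "G266E", False, True, "false_negative",
         "not resolved: detected by orthogonal sequencing only"),
        ("TP53", "8", "G266E", False, True, "false_negative",
         "not resolved: detected by orthogonal sequencing only"),
        ("TP53", "7", "c.757insA", False, True, "false_negative",
         "not called by the caller, visible on manual inspection"),
        ("TP53", "7", "c.723delC", True, False, "false_positive",
         "called, not visible on manual inspection"),
        ("EGFR", "20", "L858R", True, False, "ngs_only_sensitive",
         "NGS more sensitive: VAF 7.3%, tumour content 5-10% below assay range"),
    ]
    for j, (gene, exon, label, ngs, ref, category, note) in enumerate(discordant):
        records.append(
            ConcordanceRecord(
                sample_id=f"D{j + 1:03d}",
                gene=gene,
                exon=exon,
                variant_label=label,
                ngs_detected=ngs,
                reference_detected=ref,
                panel_covered=True,
                category=category,
                note=note,
            )
        )
    return records
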