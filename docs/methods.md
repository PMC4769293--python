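# Methods

`panelseq` implements the analysis layer of a diagnostic amplicon
hotspot-panel sequencing workflow: it consumes called variants (VCF), panel
definitions (BED) and per-library QC tables, and produces triaged variant
reports, power calculations, validation statistics and cohort summaries.
It does not align reads or call variants.

## QC model

Run-level metrics (ISP loading density, usable-read percentage) are
*advisory*: a poor run is flagged but its libraries are still evaluated,
because a bad run can contain salvageable libraries. Library-level metrics
*gate* reporting. The default operating points are the validated ones for a
~1000x amplicon assay: mean target coverage >= 800x, on-target fraction
>= 80%, mapped reads >= 100,000. All thresholds are inclusive ("at least
X" passes at exactly X), matching how such criteria are phrased in
laboratory SOPs.

Cohort exclusion statistics (`exclusion_summary`) key on mean coverage
alone; low on-target and low mapped-read counts are reported among the
excluded rather than driving exclusion themselves, since in practice low
on-target manifests as low coverage and coverage is the metric the
reporting decision uses. Percentages are reported to one decimal.

FF-vs-FFPE comparisons use Welch's two-sided t-test by default (group
variances are not credibly equal between materials); a pooled-variance
variant is available via `welch=False` / the `welch_ttest` config key. A
zero-variance degenerate input with unequal means reports p = 0 with a
warning instead of raising, so batch comparisons never abort on a constant
column. The substitution-spectrum comparison is an uncorrected chi-squared
homogeneity test over the 12 single-nucleotide substitution classes;
classes empty in both groups are dropped before testing. The 2-class
collapse (C>T plus G>A versus everything else) isolates the formalin
deamination signature.

## Triage cascade

Filters run in a fixed order — consequence class, coverage, VAF, probable
germline, blacklist — and *all* failing reasons are recorded, with the
first as the primary reason, so an audit trail never hides a second
defect. Boundary semantics follow the filter definitions "coverage below
100x" and "VAF below 5%": exactly 100x and exactly 5% pass. Review flags
reproduce the manual-inspection checklist — they require depth *above*
500x and alt reads *above* 30 to stay silent, so exactly 500/30 are
flagged. Flags never reject automatically; resolution is a human review
step, and the `strict_review` option merely demotes flagged variants to a
separate tier.

Probable germline status is decided from population allele frequencies
(any source AF >= 1% by default). Pure presence in a population database
would misclassify somatic hotspot variants that have database identifiers,
so presence-based filtering is available but not the default. Probable
germline variants are written to their own report section rather than
dropped, so they can be escalated for genetic counselling.

Consequence annotation uses a local transcript-region table (chrom, start,
end, gene, exon, region class, codon phase) plus the reference sequence:
coding SNVs are classified by codon comparison (synonymous / missense /
nonsense, plus-strand model), indels by length modulo 3 (frameshift vs
in-frame). Variants outside all regions are `unknown` and are *not*
filtered by consequence — an unannotatable variant should fail loudly in
review, not disappear.

Homopolymer context is positive when a run of >= 4 identical reference
bases overlaps or directly abuts the variant's affected interval (the
substituted bases for SNVs, the deleted bases for deletions, the insertion
point for insertions). Four is a conservative reading of "homopolymer
stretch" for flow-based sequencers and is configurable.

The mandatory-inspection list combines per-request genes with the fixed
high-risk set (all TP53 amplicons, KIT exons 9/11, PDGFRA exons 12/18,
EGFR exons 19/20, where large deletions can escape the caller). Because a
variant call does not carry an exon annotation, the mandatory-region
*review flag* matches at gene level — over-flagging is the safe direction
for a manual-review prompt; the inspection *table* lists the amplicons and
their coverage per region.

Indel representation is normalized (shared suffix/prefix trimming, then
left-alignment against the reference when sequence is available, following
the standard variant-normalization algorithm) before any blacklist or
concordance matching, so left- and right-aligned spellings of the same
indel always compare equal.

## Detection-power model

A clonal mutation on `m` of `p` chromosome copies in a tumour of cell
fraction `f` has expected VAF `f·m/p`; the default heterozygous-diploid
case gives VAF = f/2, so 10% tumour cells put a variant at 5% VAF — the
assay's reporting floor. Calling requires at least `n_min` mutant reads
(default 20). The naive coverage requirement `n_min/(f·m/p)` would leave
the expected alt-read count *equal* to the calling threshold, i.e. roughly
a coin-flip of detection; the model therefore applies a safety factor
(default 2) so the expected count is twice the threshold:

    required_coverage(f) = ceil( safety · n_min · p / (m · f) )

With defaults this reproduces the assay's design point, 800x at 10% tumour
content, and keeps the binomial detection probability
P(Binom(coverage, VAF) >= n_min) above 0.97 across the whole purity range
(verified numerically in the test suite). The safety-factor
parameterization is one consistent reading of that design point; it is
configurable and documented here precisely because the margin, not the
naive calculation, is what makes the arithmetic come out at 800x.
`detection_probability` uses the scipy binomial survival function and is
checked exhaustively against direct pmf summation for small coverages.

Dilution linearity is unweighted OLS of observed on expected VAF
(weighting is not obviously justified when all points come from the same
depth). The purity–VAF analysis reports the Pearson correlation and the
forced least-squares line of observed VAF on pathologist tumour
percentage, alongside the theoretical heterozygous line VAF = pct/200;
constant-VAF input is guarded to correlation 0. Tumour content is percent
at interfaces (pathologist convention) and fraction internally.

## Concordance statistics

Each orthogonal comparison is classified from two detection flags, panel
coverage and a free-text resolution note: concordant mutant/wildtype,
false negative, false positive, or "NGS-only sensitive" (the reference
assay missed a true low-VAF variant, marked explicitly via the note —
never inferred automatically). Regions the panel does not cover are
`uncovered` and excluded before any percentage. Overall concordance is
(concordant mutant + concordant wildtype)/total; sensitivity is
concordant/(concordant + false negatives). The packaged 328-record
validation fixture (323 concordant, 3 false negatives, 1 false positive,
1 NGS-only) reproduces 98.5% / 99.1% under exactly this reading, which is
the reconstruction consistent with those printed values; the denominator
choice is therefore documented rather than universal.

## Synthetic data

The generator produces the conditions the analyses assume, not realistic
genomes:

* **Panel/reference**: non-overlapping amplicons (80–160 bp by default) on
  one synthetic contig per gene, 50 hotspot-style gene symbols, with one
  planted homopolymer run of 5–8 bases per amplicon so context checks have
  true positives. Gene symbols are real oncogene names purely so that
  mandatory-region and co-occurrence logic is exercised naturally.
* **Coverage**: Poisson around the library mean (default 1000x); no
  overdispersion model is claimed. FFPE means decay 1% per bp of amplicon
  length beyond 100 bp, floored at 20% — the fragmentation signature of
  formalin-fixed input.
* **Variants**: somatic alt reads ~ Binomial(depth, f/2); germline ~
  Binomial(depth, 0.5) with a population AF ~ U(0.01, 0.5) emitted in the
  population table (somatic keys never appear there, so "0 somatic
  variants filtered as germline" is a meaningful recovery check); FFPE
  deamination artifacts are exclusively C>T/G>A with VAF ~ Beta(mean 2%,
  concentration 200) truncated to (0, 0.2], which keeps ~97% of the mass
  below the 5% reporting floor; homopolymer artifacts are 1-bp indels
  anchored at planted runs. One event per site is enforced cohort-wide so
  truth labels stay unambiguous.
* **Dilution series**: expected VAF = base VAF x factor, observed
  resampled binomially at fixed depth.

What this does *not* emulate: read-level errors, strand bias, mapping
artifacts, copy-number effects on VAF, subclonality, and inter-amplicon
PCR competition. Passing recovery tests therefore demonstrates the
*logic* of the cascade and the power model, not performance on real FFPE
libraries.

Default cohort conditions: 20 samples, half FFPE, tumour fraction ~
N(0.40, 0.15) clipped to [0.10, 0.95] (the assay accepts >= 10% tumour
cells), 2 somatic variants, 10 germline SNPs and (FFPE only) 10
deamination + 2 homopolymer artifacts per sample.

## Numerical choices and degenerate inputs

* `required_coverage` subtracts 1e-9 before `ceil` so exactly-representable
  operating points do not round up through float error.
* Chi-squared uses no continuity correction (the closed-form 2x2 value on
  disjoint counts is the uncorrected statistic); a single shared class
  returns statistic 0 rather than a 0-df error.
* Empty inputs raise (`exclusion_summary`, `concordance_stats` with no
  covered records, regressions with < 3 points or degenerate X) instead of
  returning NaN silently; the two conditional exclusion percentages are
  `None` exactly when nothing is excluded.
* All randomness flows through `numpy.random.default_rng` seeded from one
  integer; fixed seed implies byte-identical outputs, and all writers emit
  deterministic column orders.

## Problem sizes used in tests

Recovery tests run at 1,000 somatic / 1,000 germline / 1,000 artifact
variants on a 207-amplicon, 50-gene panel at ~800x — large enough for
3-standard-error assertions on binomial means while keeping the whole
suite in a few seconds. The binomial-tail oracle is exhaustive for all
coverage <= 50 and spot-checked at the 800x operating point and against a
normal approximation at 20,000x.

## Known limitations

* Annotation assumes plus-strand, single-transcript regions; no splice-
  distance modelling and no MNP codon handling across codon boundaries.
* The shipped blacklist is empty (recurrent aligner/caller artifacts are
  laboratory-specific); `examples/blacklist_example.tsv` documents the
  format.
* Concordance matching assumes one variant per reference-assay row;
  complex multi-variant regions need one row each.
* The dilution module models binomial sampling only — no PCR jackpotting,
  so real dilution series will scatter more than simulated ones.
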