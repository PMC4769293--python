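"""Annotation, homopolymer detection and the filter/review cascade."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_call
from panelseq.triage import (
    TriageDecision,
    TriageParams,
    affected_interval,
    annotate,
    apply_filters,
    detect_homopolymer,
    mandatory_region_table,
    read_triage_report,
    triage_sample,
    write_triage_report,
)
from panelseq.variants import VariantCall


# ---------------------------------------------------------------------------
# annotation

CODING_SEQ = {"c": "ATGCTGTGGTAACCGGTA"}  # M  L  W  *
TRANSCRIPTS = pd.DataFrame(
    {
        "chrom": ["c", "c"],
        "start": [0, 12],
        "end": [12, 18],
        "gene": ["G1", "G1"],
        "exon": ["1", "1"],
        "region_class": ["coding", "utr3"],
        "frame": [0, 0],
        "codon_start": [1, 1],
    }
)


class TestAnnotate:
    def annotate(self, v, population=None):
        return annotate(v, TRANSCRIPTS, population, CODING_SEQ)

    def test_synonymous_snv(self):
        # CTG -> CTA, both leucine
        v = self.annotate(VariantCall("c", 6, "G", "A", 1000, 100))
        assert v.consequence == "synonymous"
        assert v.aa_change == "L2L"

    def test_missense_snv(self):
        # CTG -> ATG: L2M
        v = self.annotate(VariantCall("c", 4, "C", "A", 1000, 100))
        assert v.consequence == "missense"
        assert v.aa_change == "L2M"
        assert v.gene == "G1"

    def test_nonsense_snv(self):
        # TGG -> TGA: W3*
        v = self.annotate(VariantCall("c", 9, "G", "A", 1000, 100))
        assert v.consequence == "nonsense"
        assert v.aa_change == "W3*"

    def test_one_bp_deletion_is_frameshift(self):
        v = self.annotate(VariantCall("c", 4, "CT", "C", 1000, 100))
        assert v.consequence == "frameshift"

    def test_three_bp_deletion_is_inframe(self):
        v = self.annotate(VariantCall("c", 4, "CTGT", "C", 1000, 100))
        assert v.consequence == "inframe_indel"

    def test_utr_region_class(self):
        v = self.annotate(VariantCall("c", 15, "G", "A", 1000, 100))
        assert v.consequence == "utr3"

    def test_outside_regions_is_unknown(self):
        v = self.annotate(VariantCall("c", 100, "G", "A", 1000, 100))
        assert v.consequence == "unknown"

    def test_population_af_lookup(self):
        pop = {"c:4:C>A": {"dbSNP": 0.12}}
        v = self.annotate(VariantCall("c", 4, "C", "A", 1000, 100), pop)
        assert v.population_af == {"dbSNP": 0.12}


# ---------------------------------------------------------------------------
# homopolymer detection


class TestDetectHomopolymer:
    def test_insertion_inside_run(self):
        # insert A inside the AAAA run of CAAAAG
        v = VariantCall("c", 1, "C", "CA", 100, 10)
        assert detect_homopolymer("CAAAAG", 1, v, min_run=4)

    def test_snv_without_run(self):
        v = VariantCall("c", 4, "T", "C", 100, 10)
        assert not detect_homopolymer("ACGTACGTACGT", 1, v, min_run=4)

    def test_deletion_adjacent_to_run(self):
        # delete the C that directly precedes TTTT
        v = VariantCall("c", 5, "GC", "G", 100, 10)
        assert detect_homopolymer("AAGCGCTTTTGCA", 1, v, min_run=4)

    def test_run_shorter_than_min_ignored(self):
        v = VariantCall("c", 5, "C", "T", 100, 10)
        assert not detect_homopolymer("ACGTCAAAGT", 1, v, min_run=4)

    def test_window_too_small_rejected(self):
        v = VariantCall("c", 50, "C", "T", 100, 10)
        with pytest.raises(ValueError, match="window too small"):
            detect_homopolymer("ACGT", 49, v, min_run=4)

    def test_agrees_with_brute_force_scan(self):
        """Oracle: enumerate every run in the window and test overlap/adjacency."""
        rng = np.random.default_rng(99)
        for _ in range(1000):
            window = "".join(rng.choice(list("ACGT"), size=40))
            kind = rng.choice(["snv", "ins", "del"])
            pos = int(rng.integers(10, 30))  # 1-based within window
            base = window[pos - 1]
            if kind == "snv":
                alt = rng.choice([b for b in "ACGT" if b != base])
                v = VariantCall("c", pos, base, str(alt), 100, 10)
            elif kind == "ins":
                v = VariantCall("c", pos, base, base + str(rng.choice(list("ACGT"))),
                                100, 10)
            else:
                v = VariantCall("c", pos, window[pos - 1 : pos + 1], base, 100, 10)
            a_start, a_end = affected_interval(v)
            # independent run scan
            expect = False
            i = 0
            while i < len(window):
                j = i
                while j < len(window) and window[j] == window[i]:
                    j += 1
                if j - i >= 4 and i <= a_end and a_start <= j:
                    expect = True
                i = j
            assert detect_homopolymer(window, 1, v, min_run=4) == expect, (
                window, v.key(),
            )


# ---------------------------------------------------------------------------
# filter cascade


class TestApplyFilters:
    def test_clean_missense_reported_without_flags(self):
        d = apply_filters(make_call(total_depth=1000, alt_depth=300))
        assert d.status == "reported" and d.review_flags == []
        assert d.filter_reasons == []

    @pytest.mark.parametrize(
        "depth,expected_status", [(99, "filtered"), (100, "reported")]
    )
    def test_coverage_boundary(self, depth, expected_status):
        d = apply_filters(make_call(total_depth=depth, alt_depth=31))
        assert d.status == expected_status
        if expected_status == "filtered":
            assert d.primary_reason == "low_coverage"

    @pytest.mark.parametrize(
        "alt,expected_status", [(49, "filtered"), (50, "reported")]
    )
    def test_vaf_boundary(self, alt, expected_status):
        d = apply_filters(make_call(total_depth=1000, alt_depth=alt))
        assert d.status == expected_status
        if expected_status == "filtered":
            assert d.primary_reason == "low_vaf"

    def test_excluded_consequence(self):
        d = apply_filters(make_call(consequence="synonymous"))
        assert d.primary_reason == "consequence"

    def test_germline_by_population_af(self):
        d = apply_filters(
            make_call(total_depth=1000, alt_depth=500,
                      population_af={"dbSNP": 0.25})
        )
        assert d.status == "filtered" and d.filter_reasons == ["germline"]

    def test_germline_threshold_spares_rare_entries(self):
        d = apply_filters(
            make_call(population_af={"dbSNP": 0.005})  # below 1% threshold
        )
        assert d.status == "reported"

    def test_germline_presence_mode(self):
        p = TriageParams(germline_mode="presence")
        d = apply_filters(make_call(population_af={"dbSNP": 0.005}), p)
        assert d.filter_reasons == ["germline"]

    def test_blacklist(self):
        p = TriageParams(blacklist=frozenset({"chr_KRAS:100:C>T"}))
        d = apply_filters(make_call(), p)
        assert d.filter_reasons == ["blacklist"]

    def test_all_failing_reasons_recorded_in_cascade_order(self):
        d = apply_filters(
            make_call(consequence="intronic", total_depth=90, alt_depth=4,
                      population_af={"GoNL": 0.3})
        )
        assert d.filter_reasons == ["consequence", "low_coverage", "low_vaf",
                                    "germline"]
        assert d.primary_reason == "consequence"

    @pytest.mark.parametrize(
        "depth,alt,flags",
        [
            (480, 28, ["low_total_depth", "low_alt_reads"]),
            (500, 100, ["low_total_depth"]),
            (501, 100, []),
            (600, 30, ["low_alt_reads"]),
            (600, 31, []),
        ],
    )
    def test_review_flag_boundaries(self, depth, alt, flags):
        d = apply_filters(make_call(total_depth=depth, alt_depth=alt))
        assert d.status == "reported"
        assert d.review_flags == flags

    def test_homopolymer_flag_with_reference(self):
        ref = {"chr_KRAS": "GCGCGT" + "AAAAA" + "GTGCGCGT" * 20}
        v = make_call(pos=7, ref="A", alt="T", total_depth=1000, alt_depth=300)
        d = apply_filters(v, reference=ref)
        assert "homopolymer_context" in d.review_flags

    def test_mandatory_region_flag_for_fixed_gene(self):
        d = apply_filters(make_call(gene="TP53", total_depth=1000, alt_depth=300))
        assert "mandatory_region" in d.review_flags
        d2 = apply_filters(make_call(gene="SRC"))
        assert "mandatory_region" not in d2.review_flags

    def test_unknown_depth_rejected(self):
        with pytest.raises(ValueError, match="depth unknown"):
            apply_filters(VariantCall("c", 1, "C", "T"))

    @given(
        depth=st.integers(50, 2000),
        alt=st.integers(0, 2000),
        vaf_cut=st.floats(0.01, 0.5),
    )
    @settings(max_examples=200, deadline=None)
    def test_raising_min_vaf_never_adds_reported_variants(self, depth, alt, vaf_cut):
        alt = min(alt, depth)
        v = make_call(total_depth=depth, alt_depth=alt)
        low = apply_filters(v, TriageParams(min_vaf=vaf_cut))
        high = apply_filters(v, TriageParams(min_vaf=min(vaf_cut * 2, 0.99)))
        if high.status == "reported":
            assert low.status == "reported"

    def test_partition_every_variant_classified_once(self):
        variants = [
            make_call(total_depth=d, alt_depth=a)
            for d, a in [(1000, 300), (90, 30), (1000, 10), (1000, 500)]
        ]
        decisions = [apply_filters(v) for v in variants]
        assert all(d.status in ("reported", "filtered") for d in decisions)
        assert sum(d.status == "reported" for d in decisions) + sum(
            d.status == "filtered" for d in decisions
        ) == len(variants)


class TestTriageDecisionInvariants:
    def test_status_reason_consistency_enforced(self):
        with pytest.raises(ValueError):
            TriageDecision(variant=make_call(), status="filtered")
        with pytest.raises(ValueError):
            TriageDecision(variant=make_call(), status="reported",
                           filter_reasons=["low_vaf"])

    def test_flags_only_on_reported(self):
        with pytest.raises(ValueError):
            TriageDecision(variant=make_call(), status="filtered",
                           filter_reasons=["low_vaf"], review_flags=["low_alt_reads"])


# ---------------------------------------------------------------------------
# per-sample triage + truth-label recovery


class TestTriageSample:
    def test_empty_input_still_lists_mandatory_regions(self, small_panel):
        panel, _ = small_panel
        report = triage_sample([], panel, requested_genes=["KRAS"])
        genes = set(report.mandatory_regions["gene"])
        assert "KRAS" in genes
        assert {"TP53", "KIT", "PDGFRA", "EGFR"} <= genes
        assert report.reported == [] and report.filtered == []

    def test_mandatory_table_carries_coverage(self, small_panel):
        panel, _ = small_panel
        cov = {a.id: 950.0 for a in panel}
        table = mandatory_region_table(panel, cov, requested_genes=["KRAS"])
        kras = table[table["gene"] == "KRAS"]
        assert (kras["mean_coverage"] == 950.0).all()

    def test_truth_recovery_on_simulated_sample(self):
        from panelseq.simulate import SimulationParams, simulate_cohort

        params = SimulationParams(n_samples=4, n_somatic=5, germline_rate=20,
                                  ffpe_artifact_rate=20, seed=17,
                                  tumour_fraction=0.4)
        cohort = simulate_cohort(params, n_genes=10, n_amplicons=40)
        for s in cohort.samples:
            report = triage_sample(
                s.calls, cohort.panel, population=cohort.population,
                reference=cohort.reference,
            )
            truth = {t.key(): t for t in s.truths}
            for d in report.reported:
                t = truth[d.variant.key()]
                # somatic variants at >=5% true VAF and adequate depth report
                if t.truth_class == "somatic":
                    assert t.true_vaf >= 0.05
            for d in report.filtered:
                t = truth[d.variant.key()]
                if t.truth_class == "somatic":
                    assert "germline" not in d.filter_reasons
            somatic_reported = [
                d for d in report.reported
                if truth[d.variant.key()].truth_class == "somatic"
            ]
            eligible = [
                t for t in s.truths
                if t.truth_class == "somatic" and t.true_vaf >= 0.05
            ]
            # every adequately-supported somatic truth variant is reported
            reported_keys = {d.variant.key() for d in report.reported}
            for t in eligible:
                v = next(c for c in s.calls if c.key() == t.key())
                if v.total_depth >= 100 and v.vaf >= 0.05:
                    assert t.key() in reported_keys

    def test_germline_section_populated(self):
        from panelseq.simulate import SimulationParams, simulate_cohort

        params = SimulationParams(n_samples=1, germline_rate=10, seed=23)
        cohort = simulate_cohort(params, n_genes=5, n_amplicons=15)
        s = cohort.samples[0]
        report = triage_sample(s.calls, cohort.panel, population=cohort.population,
                               reference=cohort.reference)
        assert all(d.is_probable_germline for d in report.germline)
        truth = {t.key(): t.truth_class for t in s.truths}
        assert {truth[d.variant.key()] for d in report.germline} == {"germline"}


# ---------------------------------------------------------------------------
# report I/O


class TestReportRoundTrip:
    def make_decisions(self):
        return [
            apply_filters(make_call(total_depth=1000, alt_depth=300)),
            apply_filters(make_call(pos=200, total_depth=90, alt_depth=30)),
            apply_filters(make_call(pos=300, population_af={"dbSNP": 0.3})),
        ]

    def test_round_trip(self, tmp_path):
        decisions = self.make_decisions()
        path = tmp_path / "triage.tsv"
        write_triage_report(decisions, path)
        again = read_triage_report(path)
        assert [(d.variant.key(), d.status, d.filter_reasons, d.review_flags)
                for d in again] == [
            (d.variant.key(), d.status, d.filter_reasons, d.review_flags)
            for d in decisions
        ]
        assert again[2].variant.population_af == {"dbSNP": 0.3}

    def test_empty_report_is_header_only(self, tmp_path):
        path = tmp_path / "empty.tsv"
        write_triage_report([], path)
        assert len(path.read_text().splitlines()) == 1
        assert read_triage_report(path) == []

    def test_filtered_row_carries_primary_reason_first(self, tmp_path):
        d = apply_filters(make_call(consequence="intronic", total_depth=90,
                                    alt_depth=30))
        path = tmp_path / "t.tsv"
        write_triage_report([d], path)
        row = pd.read_csv(path, sep="\t").iloc[0]
        assert row["status"] == "filtered"
        assert row["filter_reasons"].split(",")[0] == "consequence"

    def test_writer_deterministic(self, tmp_path):
        decisions = self.make_decisions()
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_triage_report(decisions, p1)
        write_triage_report(decisions, p2)
        assert p1.read_bytes() == p2.read_bytes()
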