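"""Variant re-intersection, amplicon-screen filters and diagnostic yield."""

import itertools

import numpy as np
import pytest

from conftest import make_set, make_tx
from exon_unmask.models import VariantRecord
from exon_unmask.simulate import simulate_variants
from exon_unmask.variants import (
    cohort_filter,
    diagnostic_yield,
    genomic_to_transcript_pos,
    made_exonic,
    mask_unsequenced,
)


def _variant(pos, chrom="chr1", vid="v", **kw):
    kw.setdefault("coverage", 30)
    kw.setdefault("caller_scores", {"gatk": 99.0, "samtools": 80.0})
    kw.setdefault("caller_set", frozenset({"gatk", "samtools"}))
    return VariantRecord(chrom, pos, "A", "T", variant_id=vid, **kw)


def _locus():
    """Old: 3-exon gene; new adds a cassette exon deep in intron 1 and a
    46-nt extension of exon 2's donor side."""
    old = make_set(make_tx([(100, 200), (1000, 1100), (2000, 2100)]), tag="old")
    new = make_set(
        make_tx([(100, 200), (1000, 1100), (2000, 2100)]),
        make_tx([(100, 200), (500, 700), (1000, 1100), (2000, 2100)],
                transcript_id="T2"),
        make_tx([(100, 200), (1000, 1146), (2000, 2100)], transcript_id="T3"),
        tag="new",
    )
    return old, new


class TestMadeExonic:
    def test_variant_deep_inside_new_exon_is_newly_exonic(self):
        old, new = _locus()
        calls = made_exonic([_variant(600)], old, new)
        assert calls[0].status == "newly_exonic"
        assert calls[0].old_consequence == "intronic"
        assert calls[0].new_consequence == "exonic"

    def test_variant_3bp_past_old_donor_is_splice_proximal(self):
        """Exonic in the new extension but 3 nt from the pre-existing
        splice site: demoted, not counted as newly exonic."""
        old, new = _locus()
        calls = made_exonic([_variant(1103)], old, new)
        assert calls[0].status == "splice_proximal"
        assert calls[0].distance_to_old_splice_site == 3

    def test_flank_boundary_is_eight(self):
        old, new = _locus()
        at_8 = made_exonic([_variant(1108)], old, new)[0]
        at_9 = made_exonic([_variant(1109)], old, new)[0]
        assert at_8.status == "splice_proximal"
        assert at_9.status == "newly_exonic"

    def test_old_exonic_and_deep_intronic_are_unchanged(self):
        old, new = _locus()
        calls = made_exonic([_variant(150), _variant(800)], old, new)
        assert [c.status for c in calls] == ["unchanged", "unchanged"]

    def test_identity_comparison_never_newly_exonic(self):
        old, _ = _locus()
        positions = range(90, 2110, 37)
        calls = made_exonic([_variant(p, vid=f"v{p}") for p in positions], old, old)
        assert all(c.status != "newly_exonic" for c in calls)

    def test_statuses_partition_the_input(self):
        old, new = _locus()
        vs = [_variant(p, vid=f"v{p}") for p in range(90, 2110, 13)]
        calls = made_exonic(vs, old, new)
        assert len(calls) == len(vs)
        counts = {}
        for c in calls:
            counts[c.status] = counts.get(c.status, 0) + 1
        assert sum(counts.values()) == len(vs)
        assert set(counts) <= {"newly_exonic", "splice_proximal", "unchanged"}

    def test_unknown_chromosome_warns_and_stays_unchanged(self):
        old, new = _locus()
        call = made_exonic([_variant(600, chrom="chrZ")], old, new)[0]
        assert call.status == "unchanged" and call.warning

    def test_old_only_splice_site_source(self):
        """With old-only boundaries, proximity to a *new* splice site does
        not demote a call."""
        old, new = _locus()
        # 502 is 2 nt inside the new cassette exon boundary (a new splice
        # site) but far from any old one
        both = made_exonic([_variant(502)], old, new)[0]
        old_only = made_exonic([_variant(502)], old, new,
                               splice_site_source="old")[0]
        assert both.status == "splice_proximal"
        assert old_only.status == "newly_exonic"


class TestMaskUnsequenced:
    def test_boundaries(self):
        masked = mask_unsequenced([_variant(1, coverage=4,
                                            caller_scores={"gatk": 99.0})])
        assert masked.n_masked == 1
        kept = mask_unsequenced([_variant(1, coverage=5,
                                          caller_scores={"gatk": 30.0})])
        assert kept.n_masked == 0 and len(kept.kept) == 1

    def test_toy_table_survivor_count(self):
        coverages = [4, 5, 6, 3, 10, 2, 7, 5, 1, 30]
        vs = [_variant(i + 1, vid=f"v{i}", coverage=c)
              for i, c in enumerate(coverages)]
        res = mask_unsequenced(vs)
        assert len(res.kept) == sum(1 for c in coverages if c >= 5)

    def test_missing_coverage_names_variant(self):
        with pytest.raises(ValueError, match="vX"):
            mask_unsequenced([_variant(1, vid="vX", coverage=None)])


class TestCohortFilter:
    def test_keep_rule_boundaries(self):
        keep = _variant(1, coverage=8, caller_scores={"gatk": 51.0, "samtools": 60.0})
        assert cohort_filter([keep]) == [keep]
        at_cov = _variant(1, coverage=7)
        at_q = _variant(1, caller_scores={"gatk": 50.0, "samtools": 60.0})
        assert cohort_filter([at_cov, at_q]) == []

    def test_homopolymer_boundary(self):
        ok = _variant(1, homopolymer_run=8)
        bad = _variant(2, homopolymer_run=9)
        assert cohort_filter([ok, bad]) == [ok]

    def test_fixture_matches_rule_by_rule_oracle(self):
        specs = [
            dict(),
            dict(coverage=7),
            dict(coverage=4),
            dict(caller_scores={"gatk": 50.0, "samtools": 99.0}),
            dict(caller_scores={"gatk": 49.0, "samtools": 99.0}),
            dict(caller_set=frozenset({"gatk"})),
            dict(caller_set=frozenset({"samtools"}),
                 caller_scores={"samtools": 99.0, "gatk": 60.0}),
            dict(in_database=True),
            dict(homopolymer_run=9),
            dict(homopolymer_run=12),
            dict(in_simple_repeat=True),
            dict(coverage=100),
        ]
        vs = [_variant(i + 1, vid=f"v{i}", **kw) for i, kw in enumerate(specs)]
        survivors = cohort_filter(vs)

        def oracle(v):
            return (v.coverage > 7
                    and v.caller_scores.get("gatk", -1) > 50
                    and {"gatk", "samtools"} <= v.caller_set
                    and not v.in_database
                    and v.homopolymer_run <= 8
                    and not v.in_simple_repeat)

        assert [v.variant_id for v in survivors] == \
            [v.variant_id for v in vs if oracle(v)]

    def test_rules_are_order_independent(self):
        """Disabling/forcing individual rules in any order gives the same
        survivors as the conjunction."""
        vs = [_variant(i + 1, vid=f"v{i}", **kw) for i, kw in enumerate([
            dict(), dict(coverage=7), dict(in_database=True),
            dict(homopolymer_run=9), dict(in_simple_repeat=True),
        ])]
        rules = [
            lambda v: v.coverage > 7,
            lambda v: v.caller_scores.get("gatk", -1) > 50,
            lambda v: {"gatk", "samtools"} <= v.caller_set,
            lambda v: not v.in_database,
            lambda v: v.homopolymer_run <= 8,
            lambda v: not v.in_simple_repeat,
        ]
        reference = {v.variant_id for v in cohort_filter(vs)}
        for perm in itertools.permutations(rules):
            survivors = list(vs)
            for rule in perm:
                survivors = [v for v in survivors if rule(v)]
            assert {v.variant_id for v in survivors} == reference


class TestGenomicToTranscriptPos:
    def test_first_base_of_second_exon(self):
        tx = make_tx([(1, 100), (201, 300)], cds=(1, 300))
        p = genomic_to_transcript_pos(tx, 201)
        assert p.spliced_offset == 101 and p.region == "cds"

    def test_intronic_signed_distance(self):
        tx = make_tx([(1, 100), (201, 300)], cds=(1, 300))
        near_donor = genomic_to_transcript_pos(tx, 103)
        assert near_donor.region == "intronic"
        assert near_donor.distance_to_junction == 3
        near_acceptor = genomic_to_transcript_pos(tx, 198)
        assert near_acceptor.distance_to_junction == -3

    def test_off_span_rejected(self):
        tx = make_tx([(10, 100)])
        with pytest.raises(ValueError):
            genomic_to_transcript_pos(tx, 5)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_exonic_positions_match_enumeration(self, strand):
        """100 random exonic positions agree with an exhaustively built
        spliced-coordinate table."""
        exons = [(10, 60), (100, 180), (300, 340)]
        tx = make_tx(exons, strand=strand, cds=(20, 330))
        genomic = [p for s, e in exons for p in range(s, e + 1)]
        ordered = genomic if strand == "+" else genomic[::-1]
        table = {g: i + 1 for i, g in enumerate(ordered)}
        rng = np.random.default_rng(0)
        for g in rng.choice(genomic, size=100):
            assert genomic_to_transcript_pos(tx, int(g)).spliced_offset == table[int(g)]


class TestDiagnosticYield:
    @pytest.mark.parametrize(
        "diagnosed,cohort,expected",
        [(2, 122, 1.6), (0, 50, 0.0), (122, 122, 100.0), (1, 3, 33.3), (1, 16, 6.3)],
    )
    def test_rounding_half_up_to_one_decimal(self, diagnosed, cohort, expected):
        assert diagnostic_yield(diagnosed, cohort) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            diagnostic_yield(1, 0)
        with pytest.raises(ValueError):
            diagnostic_yield(5, 3)


def test_planted_variant_statuses_recovered_exactly(sim_bundle):
    cfg, old, new, truth = sim_bundle
    variants = simulate_variants(truth, cfg, old, new)
    calls = made_exonic(variants, old, new)
    assert {c.variant_id: c.status for c in calls} == truth.variant_status


def test_planted_filter_fates_recovered_exactly(sim_bundle):
    cfg, old, new, truth = sim_bundle
    variants = simulate_variants(truth, cfg, old, new)
    res = mask_unsequenced(variants)
    masked_ids = {v.variant_id for v in res.masked}
    assert masked_ids == {k for k, f in truth.variant_filter_fate.items()
                          if f == "masked"}
    survivors = {v.variant_id for v in cohort_filter(res.kept)}
    assert survivors == {k for k, f in truth.variant_filter_fate.items()
                         if f == "pass"}
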