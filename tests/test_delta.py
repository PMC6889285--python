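"""Annotation-delta detection: definitions, exclusivity, truth recovery."""

import numpy as np
import pytest

from conftest import make_set, make_tx
from exon_unmask.delta import (
    detect_deltas,
    exclude_retained_introns,
    footprint_and_cds_gain,
    novel_exons,
    novel_introns,
    shifted_splice_junctions,
)


def _two_exon_old():
    return make_set(make_tx([(100, 200), (300, 400)]), tag="old")


class TestNovelExons:
    def test_disjoint_added_exon_is_novel(self):
        old = _two_exon_old()
        new = make_set(
            make_tx([(100, 200), (300, 400)]),
            make_tx([(100, 200), (300, 400), (500, 600)], transcript_id="T2"),
            tag="new",
        )
        deltas, _ = novel_exons(old, new)
        assert [(d.interval.start, d.interval.end) for d in deltas] == [(500, 600)]

    def test_overlapping_added_exon_is_not_novel(self):
        old = _two_exon_old()
        new = make_set(
            make_tx([(100, 200), (300, 400)]),
            make_tx([(150, 250), (300, 400)], transcript_id="T2"),
            tag="new",
        )
        deltas, _ = novel_exons(old, new)
        assert deltas == []

    def test_adjacent_exon_is_novel(self):
        """201-250 next to 100-200 shares no base (inclusive coordinates)."""
        old = make_set(make_tx([(100, 200), (400, 500)]), tag="old")
        new = make_set(
            make_tx([(100, 200), (400, 500)]),
            make_tx([(201, 250), (400, 500)], transcript_id="T2"),
            tag="new",
        )
        deltas, _ = novel_exons(old, new)
        # brute-force base-set check backs the adjacency claim
        old_bases = set(range(100, 201)) | set(range(400, 501))
        assert set(range(201, 251)) & old_bases == set()
        assert [(d.interval.start, d.interval.end) for d in deltas] == [(201, 250)]

    def test_gene_absent_from_old_goes_to_new_gene_bucket(self):
        old = _two_exon_old()
        new = make_set(
            make_tx([(100, 200), (300, 400)]),
            make_tx([(1000, 1100), (1200, 1300)], transcript_id="T9", gene_id="G9"),
            tag="new",
        )
        deltas, new_genes = novel_exons(old, new)
        assert deltas == [] and new_genes == ["G9"]


class TestNovelIntrons:
    def test_exact_match_not_novel_one_boundary_novel(self):
        old = make_set(make_tx([(100, 200), (300, 400)]), tag="old")  # intron 201-299
        same = make_set(
            make_tx([(100, 200), (300, 400)]),
            make_tx([(100, 200), (300, 400)], transcript_id="T2"),
            tag="new",
        )
        assert novel_introns(old, same) == []
        moved = make_set(
            make_tx([(100, 200), (300, 400)]),
            make_tx([(100, 200), (311, 400)], transcript_id="T2"),
            tag="new",
        )
        deltas = novel_introns(old, moved)
        assert [(d.interval.start, d.interval.end) for d in deltas] == [(201, 310)]

    def test_single_exon_transcripts_contribute_no_introns(self):
        old = make_set(make_tx([(100, 400)]), tag="old")
        new = make_set(
            make_tx([(100, 400)]),
            make_tx([(500, 900)], transcript_id="T2", gene_id="G1"),
            tag="new",
        )
        assert novel_introns(old, new) == []


class TestShiftedJunctions:
    def test_single_boundary_extension(self):
        old = make_set(make_tx([(1, 50), (100, 200), (300, 350)]), tag="old")
        new = make_set(
            make_tx([(1, 50), (100, 200), (300, 350)]),
            make_tx([(1, 50), (100, 246), (300, 350)], transcript_id="T2"),
            tag="new",
        )
        deltas = shifted_splice_junctions(old, new)
        assert len(deltas) == 1
        d = deltas[0]
        assert d.direction == "extension" and d.shift_nt == 46
        assert (d.interval.start, d.interval.end) == (201, 246)
        assert d.side == "donor"  # plus strand, end boundary

    def test_identical_exon_yields_no_delta(self):
        a = make_set(make_tx([(1, 50), (100, 200), (300, 350)]), tag="a")
        assert shifted_splice_junctions(a, a) == []

    def test_both_boundaries_moved_gives_two_reports(self):
        old = make_set(make_tx([(1, 50), (100, 200), (300, 350)]), tag="old")
        new = make_set(
            make_tx([(1, 50), (100, 200), (300, 350)]),
            make_tx([(1, 50), (150, 250), (300, 350)], transcript_id="T2"),
            tag="new",
        )
        deltas = shifted_splice_junctions(old, new)
        got = {(d.side, d.direction, d.shift_nt) for d in deltas}
        assert got == {("acceptor", "truncation", 50), ("donor", "extension", 50)}

    def test_terminal_end_changes_are_not_junction_shifts(self):
        old = make_set(make_tx([(100, 200), (300, 400)]), tag="old")
        new = make_set(
            make_tx([(100, 200), (300, 400)]),
            make_tx([(50, 200), (300, 450)], transcript_id="T2"),
            tag="new",
        )
        # only outer (transcript-end) boundaries moved: no splice site changed
        assert shifted_splice_junctions(old, new) == []


class TestFootprint:
    def test_added_exon_gain(self):
        old = make_set(make_tx([(100, 200)]), tag="old")
        new = make_set(
            make_tx([(100, 200)]),
            make_tx([(100, 200), (300, 400)], transcript_id="T2"),
            tag="new",
        )
        s = footprint_and_cds_gain(old, new)
        assert s.footprint_gain_bases == 101

    def test_no_change_no_gain(self):
        a = make_set(make_tx([(100, 200), (300, 400)]), tag="a")
        assert footprint_and_cds_gain(a, a).footprint_gain_bases == 0

    @pytest.mark.parametrize("seed", [0, 1])
    def test_random_sets_match_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)

        def random_exons(n):
            out = []
            pos = 100
            for _ in range(n):
                pos += int(rng.integers(1, 300))
                out.append((pos, pos + int(rng.integers(20, 200))))
                pos = out[-1][1]
            return out

        old_ex = random_exons(5)
        extra = random_exons(3)
        old = make_set(make_tx(old_ex), tag="old")
        new = make_set(
            make_tx(old_ex),
            make_tx(sorted(extra), transcript_id="T2"),
            tag="new",
        )
        s = footprint_and_cds_gain(old, new)
        old_bases = set().union(*(range(a, b + 1) for a, b in old_ex))
        new_bases = old_bases | set().union(*(range(a, b + 1) for a, b in extra))
        assert s.footprint_gain_bases == len(new_bases - old_bases)

    def test_gain_is_monotone_in_added_exons(self):
        old = make_set(make_tx([(100, 200)]), tag="old")
        gains = []
        added = []
        for extra in [(300, 350), (500, 520), (700, 790)]:
            added.append(extra)
            new = make_set(
                make_tx([(100, 200)]),
                make_tx(sorted([(100, 200)] + added), transcript_id="T2"),
                tag="new",
            )
            gains.append(footprint_and_cds_gain(old, new).footprint_gain_bases)
        assert gains == sorted(gains)


def test_retained_intron_exclusion():
    base = make_tx([(100, 200), (300, 400)])
    ri = make_tx([(100, 400)], transcript_id="T2", biotype="retained_intron")
    other = make_tx([(100, 200), (300, 400)], transcript_id="T3",
                    biotype="processed_transcript")
    s = make_set(base, ri, other, tag="v")
    out = exclude_retained_introns(s)
    assert set(out.transcripts) == {"T1", "T3"}
    assert set(exclude_retained_introns(make_set(base, tag="v")).transcripts) == {"T1"}


def test_self_comparison_yields_no_deltas(sim_bundle):
    _, old, new, _ = sim_bundle
    for ann in (old, new):
        res = detect_deltas(ann, ann)
        assert res.novel_exons == [] and res.novel_introns == []
        assert res.shifted_junctions == []
        assert res.summary.footprint_gain_bases == 0


def test_category_exclusivity_on_synthetic_pair(sim_bundle):
    """No new exon appears both as novel and as a junction shift."""
    _, old, new, _ = sim_bundle
    res = detect_deltas(old, new)
    novel = {(d.interval.chrom, d.interval.start, d.interval.end)
             for d in res.novel_exons}
    # a shift's changed bases extend/truncate an exon that overlaps an old
    # exon, so the full shifted exon can never be in the novel set
    for d in res.shifted_junctions:
        assert (d.interval.chrom, d.interval.start, d.interval.end) not in novel


def test_truth_recovery_exact_on_synthetic_pair(sim_bundle):
    _, old, new, truth = sim_bundle
    res = detect_deltas(old, new)
    got_ne = {(d.gene_id, d.interval.start, d.interval.end) for d in res.novel_exons}
    exp_ne = {(p.gene_id, p.interval.start, p.interval.end) for p in truth.novel_exons}
    assert got_ne == exp_ne
    got_ni = {(d.gene_id, d.interval.start, d.interval.end) for d in res.novel_introns}
    exp_ni = {
        (p.gene_id, p.interval.start, p.interval.end)
        for p in truth.novel_introns + truth.induced_novel_introns
    }
    assert got_ni == exp_ni
    got_sj = {(d.gene_id, d.interval.start, d.interval.end, d.side, d.direction,
               d.shift_nt) for d in res.shifted_junctions}
    exp_sj = {(s.gene_id, s.changed.start, s.changed.end, s.side, s.direction,
               s.shift_nt) for s in truth.shifted_junctions}
    assert got_sj == exp_sj
    assert res.summary.footprint_gain_bases == truth.expected_footprint_gain
    assert res.summary.cds_gain_bases == truth.expected_cds_gain
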