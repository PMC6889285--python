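"""Conservation permutation null and junction-expression metrics."""

import numpy as np
import pandas as pd
import pytest

from exon_unmask.evidence import (
    ConservedElementTrack,
    JunctionCountMatrix,
    enrichment_t_test,
    normalize_junctions,
    overlap_fraction,
    permutation_null,
    stage_enrichment,
    support_class,
)
from exon_unmask.intervals import GenomicInterval
from exon_unmask.simulate import (
    SimulationConfig,
    simulate_junction_counts,
    simulate_locus_pair,
    simulate_track_and_mutability,
)


def _matrix(counts_by_key, totals=None, samples_per_stage=1):
    """Small junction matrix; counts_by_key maps key -> per-sample counts."""
    from exon_unmask.evidence import LIFE_STAGES

    n_samples = 6 * samples_per_stage
    samples = [f"S{i}" for i in range(n_samples)]
    stages = {s: LIFE_STAGES[i // samples_per_stage] for i, s in enumerate(samples)}
    totals = totals or {s: 2_000_000 for s in samples}
    introns, rows, keys = [], [], []
    for key, values in counts_by_key.items():
        chrom, span = key.split(":")
        start, end = map(int, span.split("-"))
        introns.append(GenomicInterval(chrom, start, end, "."))
        keys.append(key)
        rows.append(values)
    counts = pd.DataFrame(rows, index=keys, columns=samples)
    return JunctionCountMatrix(introns, counts, stages, totals)


class TestOverlapFraction:
    def test_full_inside_and_disjoint(self):
        q = [GenomicInterval("chr1", 10, 20)]
        assert overlap_fraction(q, [GenomicInterval("chr1", 1, 100)]) == 1.0
        assert overlap_fraction(q, [GenomicInterval("chr1", 50, 60)]) == 0.0

    def test_half_overlap_matches_base_count(self):
        q = [GenomicInterval("chr1", 1, 100)]
        t = [GenomicInterval("chr1", 51, 150)]
        covered = len(set(range(1, 101)) & set(range(51, 151)))
        assert overlap_fraction(q, t) == covered / 100 == 0.5

    def test_invariant_to_splitting_query(self):
        track = [GenomicInterval("chr1", 30, 90)]
        whole = [GenomicInterval("chr1", 1, 100)]
        split = [GenomicInterval("chr1", 1, 40), GenomicInterval("chr1", 41, 100)]
        assert overlap_fraction(whole, track) == overlap_fraction(split, track)

    def test_empty_query_rejected(self):
        with pytest.raises(ValueError):
            overlap_fraction([], [GenomicInterval("chr1", 1, 10)])


class TestPermutationNull:
    def _track(self, intervals, genome):
        return ConservedElementTrack(intervals, genome)

    def test_track_covering_whole_genome(self):
        genome = {"chr1": 1000}
        track = self._track([GenomicInterval("chr1", 1, 1000)], genome)
        null = permutation_null([GenomicInterval("chr1", 10, 60)], track,
                                n_replicates=20, seed=0)
        assert (null.replicates == 1.0).all()

    def test_empty_track(self):
        genome = {"chr1": 1000}
        track = self._track([], genome)
        null = permutation_null([GenomicInterval("chr1", 10, 60)], track,
                                n_replicates=20, seed=0)
        assert (null.replicates == 0.0).all()

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(4)
        genome = {"chr1": 100_000, "chr2": 50_000}
        elements = [GenomicInterval("chr1", int(s), int(s) + 99)
                    for s in rng.integers(1, 99_000, size=40)]
        track = self._track(elements, genome)
        query = [GenomicInterval("chr1", 500, 800), GenomicInterval("chr2", 100, 350)]
        a = permutation_null(query, track, n_replicates=50, seed=7)
        b = permutation_null(query, track, n_replicates=50, seed=7)
        assert np.array_equal(a.replicates, b.replicates)
        c = permutation_null(query, track, n_replicates=50, seed=8)
        assert not np.array_equal(a.replicates, c.replicates)

    def test_replicate_mean_tracks_density(self):
        """Mean replicate overlap is within 3 standard errors of the
        track density at 1000 replicates."""
        cfg = SimulationConfig(seed=21, track_density=0.05)
        genome = {"chr1": 2_000_000}
        track, _ = simulate_track_and_mutability(cfg, genome)
        query = [GenomicInterval("chr1", 10_000 + 5_000 * i, 10_499 + 5_000 * i)
                 for i in range(10)]
        null = permutation_null(query, track, n_replicates=1000, seed=3)
        density = track.density()
        se = null.replicates.std(ddof=1) / np.sqrt(len(null.replicates))
        assert abs(null.replicates.mean() - density) < 3 * se + 1e-3

    def test_oversized_interval_rejected(self):
        track = self._track([], {"chr1": 100})
        with pytest.raises(ValueError, match="exceeds"):
            permutation_null([GenomicInterval("chr1", 1, 200)], track, 5, 0)


class TestEnrichmentTTest:
    def test_zero_variance_is_degenerate(self):
        from exon_unmask.evidence import OverlapNull

        null = OverlapNull(observed=0.5, replicates=np.full(100, 0.5), seed=0)
        with pytest.raises(ValueError, match="variance"):
            enrichment_t_test(null)

    def test_enriched_observation_gives_tiny_p(self):
        from exon_unmask.evidence import OverlapNull

        rng = np.random.default_rng(0)
        reps = rng.normal(0.05, 0.01, size=1000).clip(0, 1)
        null = enrichment_t_test(OverlapNull(0.127, reps, seed=0))
        assert null.p_value < 1e-10

    def test_observation_below_null_gives_p_near_one(self):
        from exon_unmask.evidence import OverlapNull

        rng = np.random.default_rng(1)
        reps = rng.normal(0.05, 0.01, size=500).clip(0, 1)
        null = enrichment_t_test(OverlapNull(0.01, reps, seed=0))
        assert null.p_value > 0.999


class TestNormalization:
    def test_counts_per_million(self):
        m = _matrix({"chr1:10-20": [20, 0, 0, 0, 0, 0]})
        norm = normalize_junctions(m)
        assert norm.iloc[0, 0] == pytest.approx(10.0)  # 20 / 2e6 * 1e6
        assert norm.iloc[0, 1] == 0.0

    def test_random_matrix_matches_direct_arithmetic(self):
        rng = np.random.default_rng(2)
        counts = {f"chr1:{i * 100}-{i * 100 + 50}": rng.integers(0, 100, 6).tolist()
                  for i in range(1, 6)}
        totals = None
        m = _matrix(counts)
        norm = normalize_junctions(m)
        for key, vals in counts.items():
            for j, v in enumerate(vals):
                assert norm.loc[key].iloc[j] == pytest.approx(v * 1e6 / 2_000_000)


class TestStageEnrichment:
    def test_exact_fivefold_boundary_flags(self):
        # foetal CPM 10 vs infant CPM 2 (samples_per_stage=1)
        m = _matrix({"chr1:10-20": [20, 4, 4, 4, 4, 4]})
        assert stage_enrichment(m).iloc[0]

    def test_just_below_fivefold_does_not_flag(self):
        m = _matrix({"chr1:10-20": [19, 4, 4, 4, 4, 4]})
        assert not stage_enrichment(m).iloc[0]

    def test_zero_reference_with_positive_numerator_flags(self):
        m = _matrix({"chr1:10-20": [3, 0, 5, 5, 5, 5]})
        assert stage_enrichment(m).iloc[0]

    def test_unknown_stage_rejected(self):
        m = _matrix({"chr1:10-20": [1, 1, 1, 1, 1, 1]})
        with pytest.raises(ValueError, match="life stage"):
            stage_enrichment(m, numerator="Larva")

    def test_combined_mode_pools_reads_and_totals(self):
        m = _matrix({"chr1:10-20": [60, 2, 2, 2, 2, 2]})
        flags = stage_enrichment(m, combined=True)
        # pooled reference: 10 reads over 10e6 -> 1 CPM; foetal 30 CPM
        assert flags.iloc[0]

    def test_flag_count_monotone_in_fold(self):
        rng = np.random.default_rng(3)
        counts = {f"chr1:{i * 100}-{i * 100 + 50}": rng.integers(0, 200, 6).tolist()
                  for i in range(1, 30)}
        m = _matrix(counts)
        flagged = [int(stage_enrichment(m, fold=f).sum()) for f in (2, 5, 10, 20)]
        assert flagged == sorted(flagged, reverse=True)

    def test_planted_enrichment_recovered_exactly(self):
        """With no near-zero introns, flagged set == planted set."""
        cfg = SimulationConfig(seed=31, fraction_low_support=0.0)
        _, new, truth = simulate_locus_pair(cfg)
        m = simulate_junction_counts(new, cfg, truth)
        flags = stage_enrichment(m)
        assert sorted(flags[flags].index) == sorted(truth.enriched_introns)


class TestSupportClass:
    def test_min_reads_boundary(self):
        m = _matrix({
            "chr1:10-20": [5, 5, 0, 0, 0, 0],    # 10 reads: supported
            "chr1:30-40": [5, 4, 0, 0, 0, 0],    # 9 reads: not
        })
        res = support_class(m)
        assert res.supported.loc["chr1:10-20"]
        assert not res.supported.loc["chr1:30-40"]
        assert res.fraction_supported == 0.5

    def test_cumulative_table_matches_hand_count(self):
        totals = {"chr1:1-2": 0, "chr1:3-4": 2, "chr1:5-6": 9,
                  "chr1:7-8": 10, "chr1:9-10": 50}
        m = _matrix({k: [v, 0, 0, 0, 0, 0] for k, v in totals.items()})
        res = support_class(m, thresholds=[0, 1, 5, 10, 100])
        table = dict(zip(res.cumulative["threshold"], res.cumulative["fraction_at_least"]))
        assert table[0] == 1.0
        assert table[1] == 4 / 5
        assert table[5] == 3 / 5
        assert table[10] == 2 / 5
        assert table[100] == 0.0
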