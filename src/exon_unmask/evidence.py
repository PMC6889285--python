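"""Conservation-overlap and developmental-expression evidence for deltas.

Two families of metric:

* **Conservation** — the fraction of query bases (typically the novel
  exonic footprint) covered by a conserved-element track, compared
  against a random-placement null: every query interval is re-placed
  uniformly at random on the genome (length preserved) for each
  replicate, giving a background overlap distribution which a one-sample
  t-test compares to the observed fraction.
* **Expression** — splice-junction read counts per sample across brain
  developmental stages, normalised to counts per million mapped reads,
  with a foetal-versus-infant fold-enrichment flag and a read-support
  cumulative distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, covered_bases, merge, total_bases

#: Developmental stages of the pre-frontal-cortex RNA-Seq panel.
LIFE_STAGES = ("Foetal", "Infant", "Child", "Teen", "Adult", "Old")

DEFAULT_FOLD = 5.0
DEFAULT_MIN_READS = 10
DEFAULT_REPLICATES = 1000


@dataclass
class ConservedElementTrack:
    """Unstranded conserved-element intervals plus chromosome lengths."""

    intervals: list[GenomicInterval]
    genome: dict[str, int]

    def __post_init__(self) -> None:
        for iv in self.intervals:
            if iv.chrom not in self.genome:
                raise ValueError(f"track interval on unknown chromosome {iv.chrom}")
            if iv.end > self.genome[iv.chrom]:
                raise ValueError(
                    f"track interval {iv.chrom}:{iv.start}-{iv.end} exceeds "
                    f"chromosome length {self.genome[iv.chrom]}"
                )
        self.intervals = merge(self.intervals)

    def density(self) -> float:
        return total_bases(self.intervals) / sum(self.genome.values())


def overlap_fraction(
    query: Sequence[GenomicInterval], track: Sequence[GenomicInterval]
) -> float:
    """Fraction of the query base-union covered by the track."""
    if not query:
        raise ValueError("empty query")
    q = total_bases(query)
    return covered_bases(query, track) / q


class _TrackIndex:
    """Prefix-sum coverage index for O(log n) interval-coverage queries."""

    def __init__(self, track: Sequence[GenomicInterval]):
        self.by_chrom: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
        for iv in merge(track):
            self.by_chrom.setdefault(iv.chrom, []).append(iv)  # type: ignore[attr-defined]
        for chrom, ivs in list(self.by_chrom.items()):
            starts = np.array([iv.start for iv in ivs], dtype=np.int64)
            ends = np.array([iv.end for iv in ivs], dtype=np.int64)
            prefix = np.concatenate([[0], np.cumsum(ends - starts + 1)])
            self.by_chrom[chrom] = (starts, ends, prefix)

    def covered(self, chrom: str, start: int, end: int) -> int:
        entry = self.by_chrom.get(chrom)
        if entry is None:
            return 0
        starts, ends, prefix = entry
        lo = int(np.searchsorted(ends, start, side="left"))
        hi = int(np.searchsorted(starts, end, side="right"))
        if lo >= hi:
            return 0
        full = int(prefix[hi] - prefix[lo])
        full -= max(0, start - int(starts[lo]))
        full -= max(0, int(ends[hi - 1]) - end)
        return full


@dataclass
class OverlapNull:
    observed: float
    replicates: np.ndarray
    seed: int
    t_statistic: Optional[float] = None
    p_value: Optional[float] = None


def permutation_null(
    query: Sequence[GenomicInterval],
    track: ConservedElementTrack,
    n_replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
) -> OverlapNull:
    """Random-placement null for the query/track overlap fraction.

    Each replicate independently re-places every query interval (length
    preserved) uniformly over the genome, choosing the chromosome with
    probability proportional to its number of valid start positions, and
    records the overlap fraction.  Placements within a replicate are
    independent and may overlap one another.  Deterministic for a fixed
    seed.
    """
    if not query:
        raise ValueError("empty query")
    rng = np.random.default_rng(seed)
    chroms = sorted(track.genome)
    lengths = np.array([track.genome[c] for c in chroms], dtype=np.int64)
    q_lengths = np.array([len(iv) for iv in query], dtype=np.int64)
    total_q = int(q_lengths.sum())
    for L in q_lengths:
        if not (lengths >= L).any():
            raise ValueError(f"query interval of length {L} exceeds every chromosome")
    index = _TrackIndex(track.intervals)
    observed = overlap_fraction(query, track.intervals)
    fractions = np.empty(n_replicates, dtype=float)
    for r in range(n_replicates):
        covered = 0
        for L in q_lengths:
            slots = np.maximum(lengths - L + 1, 0)
            ci = rng.choice(len(chroms), p=slots / slots.sum())
            start = int(rng.integers(1, slots[ci] + 1))
            covered += index.covered(chroms[ci], start, start + int(L) - 1)
        fractions[r] = covered / total_q
    return OverlapNull(observed=observed, replicates=fractions, seed=seed)


def enrichment_t_test(null: OverlapNull) -> OverlapNull:
    """One-sample t-test of the null replicates against the observed value.

    The replicate overlap fractions are tested against the observed
    fraction as the hypothesised mean, one-sided in the direction
    "replicates below observed" (i.e. small p means the observed overlap
    exceeds the random-placement background).
    """
    reps = np.asarray(null.replicates, dtype=float)
    if len(reps) < 2 or float(np.std(reps)) == 0.0:
        raise ValueError("degenerate null: need >= 2 replicates with nonzero variance")
    res = stats.ttest_1samp(reps, popmean=null.observed, alternative="less")
    null.t_statistic = float(res.statistic)
    null.p_value = float(res.pvalue)
    return null


# ---------------------------------------------------------------------------
# Junction expression
# ---------------------------------------------------------------------------


@dataclass
class JunctionCountMatrix:
    """Per-intron, per-sample splice-junction read counts.

    ``counts`` is indexed by intron key ``"chrom:start-end"`` with one
    column per sample; ``stages`` maps sample to life stage and
    ``totals`` to its total mapped reads.
    """

    introns: list[GenomicInterval]
    counts: pd.DataFrame
    stages: dict[str, str]
    totals: dict[str, int]

    def __post_init__(self) -> None:
        for s in self.counts.columns:
            if s not in self.stages:
                raise ValueError(f"sample {s} has no life-stage label")
            if self.stages[s] not in LIFE_STAGES:
                raise ValueError(f"unknown life stage {self.stages[s]!r} for sample {s}")
            if self.totals.get(s, 0) <= 0:
                raise ValueError(f"sample {s} has no positive total read count")
        if (self.counts.values < 0).any():
            raise ValueError("negative junction counts")

    @staticmethod
    def intron_key(iv: GenomicInterval) -> str:
        return f"{iv.chrom}:{iv.start}-{iv.end}"

    @classmethod
    def from_tsv(cls, counts_path, stages_path) -> "JunctionCountMatrix":
        """Load from long-format counts (chrom, start, end, sample, count)
        and a stages table (sample, stage, total_reads)."""
        long = pd.read_csv(counts_path, sep="\t", dtype={"chrom": str})
        meta = pd.read_csv(stages_path, sep="\t", dtype={"sample": str})
        introns = [
            GenomicInterval(r.chrom, int(r.start), int(r.end), ".")
            for r in long[["chrom", "start", "end"]].drop_duplicates().itertuples()
        ]
        long["key"] = long["chrom"] + ":" + long["start"].astype(str) + "-" + long["end"].astype(str)
        wide = long.pivot_table(index="key", columns="sample", values="count",
                                aggfunc="sum", fill_value=0)
        wide = wide.reindex([cls.intron_key(iv) for iv in introns], fill_value=0)
        wide.columns.name = None
        return cls(
            introns=introns,
            counts=wide,
            stages=dict(zip(meta["sample"], meta["stage"])),
            totals=dict(zip(meta["sample"], meta["total_reads"].astype(int))),
        )

    def to_tsv(self, counts_path, stages_path) -> None:
        rows = []
        for iv in self.introns:
            key = self.intron_key(iv)
            for s in self.counts.columns:
                rows.append((iv.chrom, iv.start, iv.end, s, int(self.counts.at[key, s])))
        pd.DataFrame(rows, columns=["chrom", "start", "end", "sample", "count"]).to_csv(
            counts_path, sep="\t", index=False
        )
        meta = pd.DataFrame(
            {
                "sample": list(self.counts.columns),
                "stage": [self.stages[s] for s in self.counts.columns],
                "total_reads": [self.totals[s] for s in self.counts.columns],
            }
        )
        meta.to_csv(stages_path, sep="\t", index=False)


def normalize_junctions(m: JunctionCountMatrix) -> pd.DataFrame:
    """Counts per million total mapped reads, per sample."""
    for s in m.counts.columns:
        if m.totals[s] <= 0:
            raise ValueError(f"sample {s} has zero total reads")
    scale = pd.Series({s: 1e6 / m.totals[s] for s in m.counts.columns})
    return m.counts * scale


def stage_enrichment(
    m: JunctionCountMatrix,
    numerator: str = "Foetal",
    denominator: str = "Infant",
    fold: float = DEFAULT_FOLD,
    combined: bool = False,
) -> pd.Series:
    """Flag introns whose numerator-stage expression is >= fold x reference.

    Stage expression is the mean normalised (CPM) value over samples of
    the stage.  With ``combined=True`` the reference pools the raw reads
    and totals of all non-numerator samples before normalising.  A zero
    reference with a positive numerator also flags.
    """
    if numerator not in LIFE_STAGES:
        raise ValueError(f"unknown life stage {numerator!r}")
    if not combined and denominator not in LIFE_STAGES:
        raise ValueError(f"unknown life stage {denominator!r}")
    norm = normalize_junctions(m)
    num_samples = [s for s in m.counts.columns if m.stages[s] == numerator]
    if not num_samples:
        raise ValueError(f"no samples in stage {numerator!r}")
    num_mean = norm[num_samples].mean(axis=1)
    if combined:
        other = [s for s in m.counts.columns if m.stages[s] != numerator]
        if not other:
            raise ValueError("no non-numerator samples to pool")
        pooled_total = sum(m.totals[s] for s in other)
        ref = m.counts[other].sum(axis=1) * 1e6 / pooled_total
    else:
        den_samples = [s for s in m.counts.columns if m.stages[s] == denominator]
        if not den_samples:
            raise ValueError(f"no samples in stage {denominator!r}")
        ref = norm[den_samples].mean(axis=1)
    flagged = (num_mean >= fold * ref) & (num_mean > 0)
    return flagged


@dataclass
class SupportSummary:
    supported: pd.Series              # bool per intron key
    fraction_supported: float
    cumulative: pd.DataFrame          # columns: threshold, fraction_at_least


def support_class(
    m: JunctionCountMatrix,
    min_reads: int = DEFAULT_MIN_READS,
    thresholds: Optional[Sequence[int]] = None,
) -> SupportSummary:
    """Read-support flag and cumulative support-distribution table.

    An intron is *supported* when its total read count across all samples
    is at least ``min_reads``.  The cumulative table gives, for each
    threshold, the fraction of introns with at least that many supporting
    reads (the cumulative curves used to compare annotation versions).
    """
    totals = m.counts.sum(axis=1)
    supported = totals >= min_reads
    if thresholds is None:
        upper = max(1, int(totals.max()))
        thresholds = sorted({0, 1, min_reads, *np.unique(totals.values).tolist(), upper})
    frac = [(t, float((totals >= t).mean())) for t in thresholds]
    table = pd.DataFrame(frac, columns=["threshold", "fraction_at_least"])
    return SupportSummary(
        supported=supported,
        fraction_supported=float(supported.mean()),
        cumulative=table,
    )
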