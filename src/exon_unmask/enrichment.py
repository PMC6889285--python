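"""Unweighted-Poisson de novo variant enrichment on a concatenated region.

The test concatenates a set of disjoint features into one test sequence of
length ``L``, sums per-site, per-allele de novo mutability over the region
to obtain the expected count

    lambda = ploidy_factor * N * sum_{pos, alt} mu(pos, alt)

for ``N`` probands, and reports the Poisson upper tail
``P(X >= k)`` for the observed count ``k``, Bonferroni-corrected for an
exome-wide number of tests (default 18,000 protein-coding genes).  Only
the unweighted path is implemented; pathogenicity-weighted variants of the
statistic are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd
from scipy import stats

from .intervals import GenomicInterval, interval_length

#: Exome-wide number of tests used for the conservative Bonferroni correction.
DEFAULT_N_TESTS = 18_000

MUTABILITY_COLUMNS = ("chrom", "pos", "ref", "alt", "mu")


@dataclass
class MutabilityTable:
    """Per-position, per-alternate-allele de novo substitution probabilities.

    ``mu`` is the probability of that substitution per site per generation
    per chromosome copy; at most three alternate alleles per (pos, ref).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in MUTABILITY_COLUMNS if c not in self.table.columns]
        if missing:
            raise ValueError(f"mutability table lacks columns {missing}")
        mu = self.table["mu"]
        if ((mu < 0) | (mu >= 1)).any():
            raise ValueError("mutability values must satisfy 0 <= mu < 1")
        n_alts = self.table.groupby(["chrom", "pos", "ref"])["alt"].nunique()
        if (n_alts > 3).any():
            raise ValueError("more than 3 alternate alleles at a site")

    @classmethod
    def from_tsv(cls, path) -> "MutabilityTable":
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
        return cls(df)

    def to_tsv(self, path) -> None:
        out = self.table.sort_values(["chrom", "pos", "alt"]).reset_index(drop=True)
        out.to_csv(path, sep="\t", index=False)

    def site_rate(self, chrom: str, pos: int) -> Optional[float]:
        """Total mutability over alternate alleles at a site, or None."""
        sel = self.table[(self.table["chrom"] == chrom) & (self.table["pos"] == pos)]
        if sel.empty:
            return None
        return float(sel["mu"].sum())


@dataclass(frozen=True)
class ConcatenatedRegion:
    """Disjoint features laid end to end into one test sequence."""

    features: tuple[GenomicInterval, ...]
    length: int
    offsets: tuple[int, ...]  # concatenated offset of each feature's first base

    def genomic_position(self, offset: int) -> tuple[str, int]:
        """Map a 1-based concatenated offset back to (chrom, genomic pos)."""
        if not 1 <= offset <= self.length:
            raise ValueError(f"offset {offset} outside 1..{self.length}")
        for feat, start in zip(self.features, self.offsets):
            if start <= offset < start + len(feat):
                return feat.chrom, feat.start + (offset - start)
        raise AssertionError("unreachable")

    def positions(self):
        for feat in self.features:
            for pos in range(feat.start, feat.end + 1):
                yield feat.chrom, pos


def concat_region(features: Sequence[GenomicInterval]) -> ConcatenatedRegion:
    """Concatenate non-overlapping features; L is the summed length."""
    feats = tuple(sorted(features, key=lambda f: (f.chrom, f.start)))
    for a, b in zip(feats, feats[1:]):
        if a.overlaps(b):
            raise ValueError(
                f"features overlap: {a.chrom}:{a.start}-{a.end} and "
                f"{b.chrom}:{b.start}-{b.end}"
            )
    offsets = []
    cum = 1
    for f in feats:
        offsets.append(cum)
        cum += interval_length(f)
    return ConcatenatedRegion(feats, cum - 1, tuple(offsets))


def expected_count(
    mutability: Optional[MutabilityTable],
    region: ConcatenatedRegion,
    n_probands: int,
    ploidy_factor: float = 2.0,
    default_site_rate: Optional[float] = None,
) -> float:
    """Expected de novo count lambda over the region for ``n_probands``.

    Each region position contributes its summed per-allele mutability;
    positions absent from the table fall back to ``default_site_rate``
    (per site, summed over alleles) or raise if none is given.
    """
    if n_probands < 0:
        raise ValueError("n_probands must be >= 0")
    site_totals: dict[tuple[str, int], float] = {}
    if mutability is not None:
        grouped = mutability.table.groupby(["chrom", "pos"])["mu"].sum()
        site_totals = {(str(c), int(p)): float(m) for (c, p), m in grouped.items()}
    total = 0.0
    for chrom, pos in region.positions():
        rate = site_totals.get((chrom, pos))
        if rate is None:
            if default_site_rate is None:
                raise ValueError(
                    f"no mutability for {chrom}:{pos} and no default rate supplied"
                )
            rate = default_site_rate
        total += rate
    return ploidy_factor * n_probands * total


def poisson_upper_tail(lam: float, k: int) -> float:
    """P(X >= k) for X ~ Poisson(lam), stable down to lam ~ 1e-9.

    Uses the regularized incomplete gamma function via
    ``scipy.stats.poisson.sf``, which keeps full relative precision for
    tiny lambda where the naive ``1 - CDF`` would cancel.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if k < 0 or int(k) != k:
        raise ValueError("k must be a non-negative integer")
    k = int(k)
    if k == 0:
        return 1.0
    if lam == 0:
        return 0.0
    return float(stats.poisson.sf(k - 1, lam))


def bonferroni(p: float, n_tests: int = DEFAULT_N_TESTS) -> float:
    """Bonferroni-adjusted p-value, capped at 1."""
    if not 0 <= p <= 1:
        raise ValueError("p must lie in [0, 1]")
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p * n_tests)


def format_p(p: float) -> str:
    """Report a p-value at 2 significant figures (e.g. 0.017)."""
    return f"{p:.2g}"


@dataclass(frozen=True)
class EnrichmentResult:
    region_length: int
    n_probands: int
    observed: int
    expected: float
    p_unadjusted: float
    n_tests: int
    p_adjusted: float


def run_enrichment(
    mutability: Optional[MutabilityTable],
    features: Sequence[GenomicInterval],
    n_probands: int,
    observed: int,
    n_tests: int = DEFAULT_N_TESTS,
    ploidy_factor: float = 2.0,
    default_site_rate: Optional[float] = None,
) -> EnrichmentResult:
    """Full enrichment test: concatenate, sum mutability, Poisson tail,
    Bonferroni."""
    region = concat_region(features)
    lam = expected_count(
        mutability, region, n_probands, ploidy_factor, default_site_rate
    )
    p = poisson_upper_tail(lam, observed)
    return EnrichmentResult(
        region_length=region.length,
        n_probands=n_probands,
        observed=observed,
        expected=lam,
        p_unadjusted=p,
        n_tests=n_tests,
        p_adjusted=bonferroni(p, n_tests),
    )
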