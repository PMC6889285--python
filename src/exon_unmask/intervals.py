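"""Genomic interval primitives.

All coordinates inside the package are 1-based and inclusive on both ends,
matching GTF/GFF convention; a single base is ``start == end`` and has
length 1.  Conversion to BED's 0-based half-open convention happens only in
:mod:`exon_unmask.io` at the file boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

STRANDS = ("+", "-", ".")


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 1-based inclusive span on one chromosome.

    Parameters
    ----------
    chrom : str
        Chromosome / contig name.
    start, end : int
        1-based inclusive boundaries, ``start <= end``.
    strand : str
        ``"+"``, ``"-"`` or ``"."`` (unstranded, allowed for tracks only).
    """

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.start > self.end:
            raise ValueError(
                f"interval start > end: {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True if the two intervals share at least one base."""
        return (
            self.chrom == other.chrom
            and self.start <= other.end
            and other.start <= self.end
        )

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos <= self.end

    def shifted(self, offset: int) -> "GenomicInterval":
        return GenomicInterval(self.chrom, self.start + offset, self.end + offset, self.strand)


def interval_length(iv: GenomicInterval) -> int:
    """Number of bases covered by ``iv`` (end - start + 1)."""
    return len(iv)


# ---------------------------------------------------------------------------
# Set arithmetic on interval lists.  These operate per chromosome and ignore
# strand; callers that care about strand filter first.  All helpers accept
# any iterable of GenomicInterval and return sorted merged lists.
# ---------------------------------------------------------------------------


def merge(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Union of intervals as a minimal sorted list of disjoint intervals.

    Adjacent intervals (end + 1 == next start) are coalesced, since the
    covered base set is what matters.
    """
    by_pos = sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
    out: list[GenomicInterval] = []
    for iv in by_pos:
        if out and out[-1].chrom == iv.chrom and iv.start <= out[-1].end + 1:
            prev = out[-1]
            if iv.end > prev.end:
                out[-1] = GenomicInterval(prev.chrom, prev.start, iv.end, ".")
        else:
            out.append(GenomicInterval(iv.chrom, iv.start, iv.end, "."))
    return out


def total_bases(intervals: Iterable[GenomicInterval]) -> int:
    """Number of distinct bases covered by the union of ``intervals``."""
    return sum(len(iv) for iv in merge(intervals))


def intersect(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Base-level intersection of two interval sets (merged, sorted)."""
    am, bm = merge(a), merge(b)
    out: list[GenomicInterval] = []
    i = j = 0
    while i < len(am) and j < len(bm):
        x, y = am[i], bm[j]
        if x.chrom != y.chrom:
            if (x.chrom, x.start) < (y.chrom, y.start):
                i += 1
            else:
                j += 1
            continue
        lo, hi = max(x.start, y.start), min(x.end, y.end)
        if lo <= hi:
            out.append(GenomicInterval(x.chrom, lo, hi, "."))
        if x.end < y.end:
            i += 1
        else:
            j += 1
    return out


def subtract(
    a: Iterable[GenomicInterval], b: Iterable[GenomicInterval]
) -> list[GenomicInterval]:
    """Bases covered by ``a`` but not by ``b`` (merged, sorted)."""
    am = merge(a)
    bm = merge(b)
    out: list[GenomicInterval] = []
    for x in am:
        pieces = [(x.start, x.end)]
        for y in bm:
            if y.chrom != x.chrom:
                continue
            nxt: list[tuple[int, int]] = []
            for s, e in pieces:
                if y.end < s or y.start > e:
                    nxt.append((s, e))
                    continue
                if y.start > s:
                    nxt.append((s, y.start - 1))
                if y.end < e:
                    nxt.append((y.end + 1, e))
            pieces = nxt
            if not pieces:
                break
        out.extend(GenomicInterval(x.chrom, s, e, ".") for s, e in pieces)
    return merge(out)


def covered_bases(
    query: Sequence[GenomicInterval], track: Sequence[GenomicInterval]
) -> int:
    """Bases of the union of ``query`` that fall inside ``track``."""
    return total_bases(intersect(query, track))
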