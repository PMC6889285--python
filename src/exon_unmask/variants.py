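"""Re-intersection of variants against an annotation delta.

The two-pass "made exonic" analysis: variants are intersected with the
exons of the old and the new annotation separately; those exonic only in
the new annotation are candidate re-annotations, and a second pass demotes
candidates lying within a short flank (default 8 nt) of a splice site to
``splice_proximal``, since their pathogenicity may act through splicing
disruption rather than through the new exon.  Also implements the
amplicon-screen masking and cohort quality filters and the diagnostic
yield.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional

from .intervals import GenomicInterval
from .models import AnnotationSet, TranscriptModel, VariantRecord

#: Splice-flank width in nt used to demote candidates (the "8-nt flank").
SPLICE_FLANK_NT = 8


@dataclass(frozen=True)
class FilterThresholds:
    """Caller-quality thresholds of the amplicon screen.

    ``min_coverage_called``/``min_score_called`` define sequenced
    positions (strict ``<`` masks); ``min_coverage_keep`` /
    ``min_gatk_quality_keep`` are strict ``>`` cutoffs for the cohort
    filter.  Homopolymer runs longer than ``homopolymer_max`` and simple
    repeat or database-present variants are excluded.
    """

    min_coverage_called: int = 5
    min_score_called: float = 30.0
    min_coverage_keep: int = 7
    min_gatk_quality_keep: float = 50.0
    required_callers: frozenset[str] = frozenset({"gatk", "samtools"})
    homopolymer_max: int = 8
    exclude_simple_repeats: bool = True
    exclude_database_present: bool = True


@dataclass(frozen=True)
class ReannotationCall:
    variant_id: str
    chrom: str
    pos: int
    status: str                       # newly_exonic | splice_proximal | unchanged
    old_consequence: str              # exonic | intronic
    new_consequence: str
    distance_to_old_splice_site: Optional[int]
    containing_feature: Optional[GenomicInterval] = None
    gene_id: Optional[str] = None
    warning: Optional[str] = None


def _exon_lookup(annotation: AnnotationSet):
    """Per-chromosome sorted exon lists with owning gene ids."""
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for tx in annotation:
        for exon in tx.exons:
            by_chrom.setdefault(exon.chrom, []).append((exon.start, exon.end, tx.gene_id))
    for lst in by_chrom.values():
        lst.sort()
    return by_chrom


def _splice_site_positions(annotation: AnnotationSet) -> dict[str, list[int]]:
    """Internal exon-boundary bases (positions adjoining an intron)."""
    sites: dict[str, set[int]] = {}
    for tx in annotation:
        chrom_sites = sites.setdefault(tx.chrom, set())
        for i, exon in enumerate(tx.exons):
            if i > 0:
                chrom_sites.add(exon.start)
            if i < len(tx.exons) - 1:
                chrom_sites.add(exon.end)
    return {c: sorted(s) for c, s in sites.items()}


def _containing_exon(lookup, chrom: str, pos: int):
    for start, end, gene_id in lookup.get(chrom, []):
        if start > pos:
            break
        if start <= pos <= end:
            return GenomicInterval(chrom, start, end, "."), gene_id
    return None, None


def _nearest_distance(sites: dict[str, list[int]], chrom: str, pos: int) -> Optional[int]:
    import bisect

    positions = sites.get(chrom)
    if not positions:
        return None
    i = bisect.bisect_left(positions, pos)
    best = None
    for j in (i - 1, i):
        if 0 <= j < len(positions):
            d = abs(positions[j] - pos)
            best = d if best is None else min(best, d)
    return best


def made_exonic(
    variants: Iterable[VariantRecord],
    old: AnnotationSet,
    new: AnnotationSet,
    flank: int = SPLICE_FLANK_NT,
    splice_site_source: str = "both",
) -> list[ReannotationCall]:
    """Two-pass re-intersection of variants against old and new exons.

    Pass 1 flags variants exonic in the new annotation but intronic in the
    old.  Pass 2 demotes flagged variants within ``flank`` nt of a splice
    site (boundary base inclusive, intronic or exonic side) to
    ``splice_proximal``; ``splice_site_source`` selects whether the flank
    test uses boundaries from ``"both"`` annotation versions (default) or
    the ``"old"`` one only.  The reported distance is always to the
    nearest old splice site.
    """
    if splice_site_source not in ("both", "old"):
        raise ValueError("splice_site_source must be 'both' or 'old'")
    old_exons = _exon_lookup(old)
    new_exons = _exon_lookup(new)
    old_sites = _splice_site_positions(old)
    if splice_site_source == "both":
        merged: dict[str, list[int]] = {}
        new_sites = _splice_site_positions(new)
        for c in set(old_sites) | set(new_sites):
            merged[c] = sorted(set(old_sites.get(c, [])) | set(new_sites.get(c, [])))
        flank_sites = merged
    else:
        flank_sites = old_sites

    known_chroms = set(old_exons) | set(new_exons)
    calls = []
    for v in variants:
        pos = v.pos  # leftmost affected base (VCF left alignment)
        old_hit, _ = _containing_exon(old_exons, v.chrom, pos)
        new_hit, gene_id = _containing_exon(new_exons, v.chrom, pos)
        d_old = _nearest_distance(old_sites, v.chrom, pos)
        warning = None
        if v.chrom not in known_chroms:
            warning = f"chromosome {v.chrom} absent from annotation"
        old_c = "exonic" if old_hit else "intronic"
        new_c = "exonic" if new_hit else "intronic"
        if old_hit is None and new_hit is not None:
            d_flank = _nearest_distance(flank_sites, v.chrom, pos)
            if d_flank is not None and d_flank <= flank:
                status = "splice_proximal"
            else:
                status = "newly_exonic"
        else:
            status = "unchanged"
        calls.append(
            ReannotationCall(
                variant_id=v.variant_id,
                chrom=v.chrom,
                pos=pos,
                status=status,
                old_consequence=old_c,
                new_consequence=new_c,
                distance_to_old_splice_site=d_old,
                containing_feature=new_hit,
                gene_id=gene_id,
                warning=warning,
            )
        )
    return calls


@dataclass
class MaskResult:
    kept: list[VariantRecord]
    masked: list[VariantRecord] = field(default_factory=list)

    @property
    def n_masked(self) -> int:
        return len(self.masked)


def _best_score(v: VariantRecord) -> float:
    if "gatk" in v.caller_scores:
        return v.caller_scores["gatk"]
    if v.caller_scores:
        return max(v.caller_scores.values())
    raise ValueError(f"variant {v.variant_id} at {v.chrom}:{v.pos} has no caller score")


def mask_unsequenced(
    variants: Iterable[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> MaskResult:
    """Drop variants at positions considered unsequenced.

    A position is unsequenced when coverage < ``min_coverage_called`` or
    the caller score < ``min_score_called`` (strict, so equality passes).
    """
    kept, masked = [], []
    for v in variants:
        if v.coverage is None:
            raise ValueError(f"variant {v.variant_id} at {v.chrom}:{v.pos} has no coverage")
        score = _best_score(v)
        if v.coverage < thresholds.min_coverage_called or score < thresholds.min_score_called:
            masked.append(v)
        else:
            kept.append(v)
    return MaskResult(kept=kept, masked=masked)


def cohort_filter(
    variants: Iterable[VariantRecord],
    thresholds: FilterThresholds = FilterThresholds(),
) -> list[VariantRecord]:
    """Amplicon-screen quality filter; rules are conjunctive and
    order-independent.

    Keeps variants with coverage strictly above ``min_coverage_keep``, a
    GATK quality strictly above ``min_gatk_quality_keep``, reported by all
    required callers, absent from population databases, with homopolymer
    run <= ``homopolymer_max`` and outside simple repeats.
    """
    out = []
    for v in variants:
        if v.coverage is None or v.coverage <= thresholds.min_coverage_keep:
            continue
        if v.caller_scores.get("gatk", float("-inf")) <= thresholds.min_gatk_quality_keep:
            continue
        if not thresholds.required_callers <= v.caller_set:
            continue
        if thresholds.exclude_database_present and v.in_database:
            continue
        if v.homopolymer_run > thresholds.homopolymer_max:
            continue
        if thresholds.exclude_simple_repeats and v.in_simple_repeat:
            continue
        out.append(v)
    return out


@dataclass(frozen=True)
class TranscriptPosition:
    spliced_offset: Optional[int]   # None for intronic positions
    region: str                     # 5utr | cds | 3utr | noncoding | intronic
    intron_index: Optional[int] = None
    distance_to_junction: Optional[int] = None  # signed, + after donor, - before acceptor


def genomic_to_transcript_pos(tx: TranscriptModel, g: int) -> TranscriptPosition:
    """Map a genomic position to spliced coordinates and a region label.

    Exonic positions return the 1-based spliced offset and 5'UTR/CDS/3'UTR
    (or ``noncoding`` for CDS-less transcripts).  Intronic positions
    return the intron index (transcript order) and a signed distance to
    the nearest junction: positive counts from the donor side, negative
    towards the acceptor, HGVS-style.
    """
    from .nmd import project_cds, spliced_offset

    if not (tx.span.start <= g <= tx.span.end):
        raise ValueError(
            f"position {g} is outside the span of {tx.transcript_id} "
            f"({tx.span.start}-{tx.span.end})"
        )
    for exon in tx.exons:
        if exon.start <= g <= exon.end:
            offset = spliced_offset(tx, g)
            if tx.cds is None:
                return TranscriptPosition(offset, "noncoding")
            proj = project_cds(tx)
            if offset < proj.cds_start:
                region = "5utr"
            elif offset <= proj.stop_end:
                region = "cds"
            else:
                region = "3utr"
            return TranscriptPosition(offset, region)
    introns = tx.introns
    for i, intron in enumerate(introns):
        if intron.start <= g <= intron.end:
            if tx.strand == "+":
                d_donor = g - intron.start + 1
                d_acceptor = intron.end - g + 1
                tx_index = i
            else:
                d_donor = intron.end - g + 1
                d_acceptor = g - intron.start + 1
                tx_index = len(introns) - 1 - i
            if d_donor <= d_acceptor:
                return TranscriptPosition(None, "intronic", tx_index, d_donor)
            return TranscriptPosition(None, "intronic", tx_index, -d_acceptor)
    raise AssertionError("unreachable: position inside span but in no exon or intron")


def diagnostic_yield(n_diagnosed: int, n_cohort: int) -> float:
    """Percent of the cohort diagnosed, rounded half-up to one decimal."""
    if n_cohort <= 0:
        raise ValueError("cohort size must be positive")
    if not 0 <= n_diagnosed <= n_cohort:
        raise ValueError("diagnosed count must be between 0 and the cohort size")
    pct = Decimal(100 * n_diagnosed) / Decimal(n_cohort)
    return float(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))
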