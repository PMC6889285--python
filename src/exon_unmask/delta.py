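"""Detection of splicing-feature differences between two annotation versions.

Given an *old* and a *new* :class:`~exon_unmask.models.AnnotationSet` of
the same genes, three categories of change are detected:

* **novel exon** — a new exon sharing no base with any old exon of the
  same gene;
* **novel intron** — a new intron with no exact-coordinate match among the
  old introns of the gene;
* **shifted splice junction** — a new exon overlapping an old exon with at
  least one internal (intron-adjoining) boundary at a different position.

Retained-intron transcripts are excluded before comparison, since their
exonic footprint blankets introns and would mask genuine novelty.  All
comparisons are within gene (matched by ``gene_id``) and strand; genes
present only in the new set are reported separately, not as novel exons.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .intervals import GenomicInterval, merge, subtract, total_bases
from .models import AnnotationSet, TranscriptModel


@dataclass(frozen=True)
class SpliceFeatureDelta:
    """One classified difference between annotation versions."""

    category: str                # novel_exon | novel_intron | shifted_splice_junction
    interval: GenomicInterval    # the feature; for shifts, the changed bases
    gene_id: str
    transcript_ids: tuple[str, ...]       # supporting transcripts in the new set
    side: Optional[str] = None            # donor | acceptor (shifts only)
    direction: Optional[str] = None       # extension | truncation (shifts only)
    shift_nt: Optional[int] = None        # shift length in nt (shifts only)


@dataclass
class DeltaSummary:
    counts: dict[str, int]
    footprint_gain_bases: int
    cds_gain_bases: int
    per_gene: dict[str, dict[str, int]]
    new_genes: tuple[str, ...] = ()


def exclude_retained_introns(annotation: AnnotationSet) -> AnnotationSet:
    """Drop retained-intron transcripts before delta comparison."""
    return annotation.without_retained_introns()


def _gene_exons(annotation: AnnotationSet, gene_id: str) -> list[GenomicInterval]:
    out = []
    for tx in annotation.gene_transcripts(gene_id):
        out.extend(tx.exons)
    return out


def _splice_boundaries(tx: TranscriptModel, exon_index: int) -> tuple[bool, bool]:
    """Which sides of exon ``exon_index`` adjoin an intron (start side, end side).

    Transcript ends are not splice sites, so the first exon's start side and
    the last exon's end side (in genomic order) never qualify.
    """
    return exon_index > 0, exon_index < len(tx.exons) - 1


def novel_exons(
    old: AnnotationSet, new: AnnotationSet
) -> tuple[list[SpliceFeatureDelta], list[str]]:
    """New exons sharing no base with any old exon of the same gene.

    Returns ``(deltas, new_gene_ids)``; exons of genes absent from the old
    set go into the new-gene bucket rather than the delta list.
    """
    old = exclude_retained_introns(old)
    new = exclude_retained_introns(new)
    deltas: list[SpliceFeatureDelta] = []
    new_genes: list[str] = []
    for gene_id in sorted(new.genes):
        if gene_id not in old.genes:
            new_genes.append(gene_id)
            continue
        old_union = merge(_gene_exons(old, gene_id))
        seen: dict[GenomicInterval, list[str]] = {}
        for tx in new.gene_transcripts(gene_id):
            for exon in tx.exons:
                if not subtract([exon], old_union) == merge([exon]):
                    continue  # shares at least one base with an old exon
                seen.setdefault(exon, []).append(tx.transcript_id)
        for exon in sorted(seen):
            deltas.append(
                SpliceFeatureDelta(
                    category="novel_exon",
                    interval=exon,
                    gene_id=gene_id,
                    transcript_ids=tuple(sorted(seen[exon])),
                )
            )
    return deltas, new_genes


def novel_introns(old: AnnotationSet, new: AnnotationSet) -> list[SpliceFeatureDelta]:
    """New introns with no exact match (chrom, start, end, strand) in the old gene."""
    old = exclude_retained_introns(old)
    new = exclude_retained_introns(new)
    deltas: list[SpliceFeatureDelta] = []
    for gene_id in sorted(new.genes):
        if gene_id not in old.genes:
            continue
        old_introns = {
            (iv.chrom, iv.start, iv.end, iv.strand)
            for tx in old.gene_transcripts(gene_id)
            for iv in tx.introns
        }
        seen: dict[GenomicInterval, list[str]] = {}
        for tx in new.gene_transcripts(gene_id):
            for intron in tx.introns:
                key = (intron.chrom, intron.start, intron.end, intron.strand)
                if key in old_introns:
                    continue
                seen.setdefault(intron, []).append(tx.transcript_id)
        for intron in sorted(seen):
            deltas.append(
                SpliceFeatureDelta(
                    category="novel_intron",
                    interval=intron,
                    gene_id=gene_id,
                    transcript_ids=tuple(sorted(seen[intron])),
                )
            )
    return deltas


def _best_overlap(exon: GenomicInterval, candidates: list[GenomicInterval]):
    """Old exon with the largest base overlap; ties break to smaller start."""
    best, best_ov = None, 0
    for cand in sorted(candidates, key=lambda c: (c.start, c.end)):
        ov = min(exon.end, cand.end) - max(exon.start, cand.start) + 1
        if ov > best_ov:
            best, best_ov = cand, ov
    return best


def _side_label(boundary: str, strand: str) -> str:
    """Map a genomic boundary (start/end of an exon) to donor/acceptor.

    On the plus strand an exon's end is the donor and its start the
    acceptor; on the minus strand the roles swap.
    """
    if strand == "-":
        return "acceptor" if boundary == "end" else "donor"
    return "acceptor" if boundary == "start" else "donor"


def shifted_splice_junctions(
    old: AnnotationSet, new: AnnotationSet
) -> list[SpliceFeatureDelta]:
    """New exons overlapping an old exon with a moved splice boundary.

    Each changed internal boundary of a qualifying new exon yields one
    delta, with the shift length, extension/truncation direction and the
    donor/acceptor side.  The comparison exon is the old exon with the
    largest overlap (ties to the smaller start).  Transcript-end changes
    are not junction shifts and are ignored here.
    """
    old = exclude_retained_introns(old)
    new = exclude_retained_introns(new)
    deltas: list[SpliceFeatureDelta] = []
    reported: dict[tuple, list[str]] = {}
    order: list[tuple] = []
    for gene_id in sorted(new.genes):
        if gene_id not in old.genes:
            continue
        old_exons = _gene_exons(old, gene_id)
        old_exact = {(e.start, e.end) for e in old_exons}
        for tx in new.gene_transcripts(gene_id):
            for idx, exon in enumerate(tx.exons):
                if (exon.start, exon.end) in old_exact:
                    continue
                overlapping = [c for c in old_exons if exon.overlaps(c)]
                if not overlapping:
                    continue  # novel_exons territory
                ref = _best_overlap(exon, overlapping)
                start_is_ss, end_is_ss = _splice_boundaries(tx, idx)
                for boundary, is_ss, new_pos, ref_pos in (
                    ("start", start_is_ss, exon.start, ref.start),
                    ("end", end_is_ss, exon.end, ref.end),
                ):
                    if not is_ss or new_pos == ref_pos:
                        continue
                    if boundary == "start":
                        direction = "extension" if new_pos < ref_pos else "truncation"
                        lo, hi = min(new_pos, ref_pos), max(new_pos, ref_pos) - 1
                    else:
                        direction = "extension" if new_pos > ref_pos else "truncation"
                        lo, hi = min(new_pos, ref_pos) + 1, max(new_pos, ref_pos)
                    changed = GenomicInterval(exon.chrom, lo, hi, exon.strand)
                    key = (
                        gene_id, changed, _side_label(boundary, tx.strand),
                        direction, abs(new_pos - ref_pos),
                    )
                    if key not in reported:
                        reported[key] = []
                        order.append(key)
                    reported[key].append(tx.transcript_id)
    for key in sorted(order, key=lambda k: (k[0], k[1])):
        gene_id, changed, side, direction, shift = key
        deltas.append(
            SpliceFeatureDelta(
                category="shifted_splice_junction",
                interval=changed,
                gene_id=gene_id,
                transcript_ids=tuple(sorted(set(reported[key]))),
                side=side,
                direction=direction,
                shift_nt=shift,
            )
        )
    return deltas


def _cds_intervals(annotation: AnnotationSet) -> list[GenomicInterval]:
    out = []
    for tx in annotation:
        if tx.cds is None:
            continue
        for exon in tx.exons:
            lo, hi = max(exon.start, tx.cds.start), min(exon.end, tx.cds.end)
            if lo <= hi:
                out.append(GenomicInterval(exon.chrom, lo, hi, "."))
    return out


def footprint_and_cds_gain(old: AnnotationSet, new: AnnotationSet) -> DeltaSummary:
    """Per-gene exonic and CDS base gain of the new set over the old.

    The gain is the number of bases in the union of new exons not covered
    by the union of old exons, summed per gene (and analogously for CDS
    sub-intervals); it is always >= 0.
    """
    old_f = exclude_retained_introns(old)
    new_f = exclude_retained_introns(new)
    ne, new_genes = novel_exons(old, new)
    ni = novel_introns(old, new)
    sj = shifted_splice_junctions(old, new)

    per_gene: dict[str, dict[str, int]] = {}
    footprint = cds_gain = 0
    for gene_id in sorted(new_f.genes):
        old_ex = _gene_exons(old_f, gene_id) if gene_id in old_f.genes else []
        new_ex = _gene_exons(new_f, gene_id)
        gain = total_bases(subtract(new_ex, old_ex))
        old_cds = [
            iv for tx in (old_f.gene_transcripts(gene_id) if gene_id in old_f.genes else [])
            if tx.cds is not None
            for iv in _cds_intervals(AnnotationSet.from_transcripts("tmp", [tx]))
        ]
        new_cds = [
            iv for tx in new_f.gene_transcripts(gene_id) if tx.cds is not None
            for iv in _cds_intervals(AnnotationSet.from_transcripts("tmp", [tx]))
        ]
        cg = total_bases(subtract(new_cds, old_cds))
        per_gene[gene_id] = {"footprint_gain": gain, "cds_gain": cg}
        footprint += gain
        cds_gain += cg

    counts = {
        "novel_exon": len(ne),
        "novel_intron": len(ni),
        "shifted_splice_junction": len(sj),
        "new_gene": len(new_genes),
    }
    return DeltaSummary(
        counts=counts,
        footprint_gain_bases=footprint,
        cds_gain_bases=cds_gain,
        per_gene=per_gene,
        new_genes=tuple(new_genes),
    )


@dataclass
class DeltaResult:
    """All deltas plus the summary, as produced by :func:`detect_deltas`."""

    novel_exons: list[SpliceFeatureDelta]
    novel_introns: list[SpliceFeatureDelta]
    shifted_junctions: list[SpliceFeatureDelta]
    summary: DeltaSummary
    new_genes: tuple[str, ...] = field(default_factory=tuple)


def detect_deltas(old: AnnotationSet, new: AnnotationSet) -> DeltaResult:
    """Run all three detectors and the base-gain summary."""
    ne, new_genes = novel_exons(old, new)
    ni = novel_introns(old, new)
    sj = shifted_splice_junctions(old, new)
    summary = footprint_and_cds_gain(old, new)
    return DeltaResult(ne, ni, sj, summary, tuple(new_genes))
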