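"""Poison-exon calling: CDS projection and nonsense-mediated-decay prediction.

A transcript is predicted to be degraded by NMD when its stop codon ends
more than ``ptc_distance`` nucleotides (canonically 50) upstream of the
final exon-exon junction in spliced coordinates.  A cassette exon is a
*poison exon* when its inclusion in a host transcript introduces a
frameshift and/or premature termination codon that triggers this rule.

Spliced coordinates are 1-based along the mature transcript read 5'->3';
minus-strand transcripts are projected accordingly.  A junction at offset
``j`` sits between spliced bases ``j`` and ``j+1``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .intervals import GenomicInterval
from .models import TranscriptModel

#: Default distance threshold of the PTC rule, in nucleotides.
PTC_DISTANCE_NT = 50

STOP_CODONS = ("TAA", "TAG", "TGA")


@dataclass(frozen=True)
class CdsProjection:
    """A transcript's CDS mapped into spliced coordinates."""

    transcript_id: str
    spliced_length: int
    cds_start: int          # spliced offset of the first CDS base (1-based)
    stop_end: int           # spliced offset of the last base of the stop codon
    junctions: tuple[int, ...]  # offsets j: junction between bases j and j+1

    def __post_init__(self) -> None:
        if not (1 <= self.cds_start < self.stop_end <= self.spliced_length):
            raise ValueError(
                f"{self.transcript_id}: invalid CDS projection "
                f"(start {self.cds_start}, stop {self.stop_end}, "
                f"length {self.spliced_length})"
            )
        if any(b <= a for a, b in zip(self.junctions, self.junctions[1:])):
            raise ValueError(f"{self.transcript_id}: junction offsets not increasing")

    def frame_at(self, spliced_offset: int) -> int:
        """Reading-frame phase (0/1/2) of the base at ``spliced_offset``."""
        return (spliced_offset - self.cds_start) % 3


def _exons_in_transcript_order(tx: TranscriptModel) -> list[GenomicInterval]:
    exons = list(tx.exons)
    return exons[::-1] if tx.strand == "-" else exons


def spliced_offset(tx: TranscriptModel, genomic_pos: int) -> int:
    """1-based spliced offset of an exonic genomic position (strand-aware)."""
    cum = 0
    for exon in _exons_in_transcript_order(tx):
        if exon.start <= genomic_pos <= exon.end:
            if tx.strand == "-":
                return cum + (exon.end - genomic_pos) + 1
            return cum + (genomic_pos - exon.start) + 1
        cum += len(exon)
    raise ValueError(f"position {genomic_pos} is not exonic in {tx.transcript_id}")


def genomic_position(tx: TranscriptModel, offset: int) -> int:
    """Genomic position of 1-based spliced ``offset`` (inverse of
    :func:`spliced_offset`)."""
    if offset < 1:
        raise ValueError("spliced offset must be >= 1")
    cum = 0
    for exon in _exons_in_transcript_order(tx):
        if offset <= cum + len(exon):
            within = offset - cum - 1
            if tx.strand == "-":
                return exon.end - within
            return exon.start + within
        cum += len(exon)
    raise ValueError(
        f"spliced offset {offset} beyond length {tx.spliced_length()} of "
        f"{tx.transcript_id}"
    )


def junction_offsets(tx: TranscriptModel) -> tuple[int, ...]:
    """Spliced offsets of all exon-exon junctions, 5'->3'."""
    offsets = []
    cum = 0
    exons = _exons_in_transcript_order(tx)
    for exon in exons[:-1]:
        cum += len(exon)
        offsets.append(cum)
    return tuple(offsets)


def project_cds(tx: TranscriptModel) -> CdsProjection:
    """Project a transcript's CDS span into spliced coordinates."""
    if tx.cds is None:
        raise ValueError(f"transcript {tx.transcript_id} has no CDS")
    five_prime = tx.cds.start if tx.strand == "+" else tx.cds.end
    three_prime = tx.cds.end if tx.strand == "+" else tx.cds.start
    return CdsProjection(
        transcript_id=tx.transcript_id,
        spliced_length=tx.spliced_length(),
        cds_start=spliced_offset(tx, five_prime),
        stop_end=spliced_offset(tx, three_prime),
        junctions=junction_offsets(tx),
    )


def classify_nmd(proj: CdsProjection, ptc_distance: int = PTC_DISTANCE_NT) -> str:
    """Apply the PTC distance rule: ``NMD`` or ``coding``.

    NMD iff the stop codon ends more than ``ptc_distance`` nt upstream of
    the final exon-exon junction.  Junction-free (single-exon) transcripts
    are never NMD.
    """
    if not proj.junctions:
        return "coding"
    final_junction = proj.junctions[-1]
    if final_junction - proj.stop_end > ptc_distance:
        return "NMD"
    return "coding"


@dataclass(frozen=True)
class InclusionCall:
    """Outcome of classifying a cassette-exon inclusion event."""

    biotype: str                 # coding | NMD | processed_transcript
    frame_preserving: bool       # inserted length % 3 == 0
    introduced_stop: bool        # a PTC was found (or assumed) in/after the exon
    mode: str                    # sequence | exon_scan | frame_only
    projection: Optional[CdsProjection] = None


def _host_intron_index(host: TranscriptModel, exon: GenomicInterval) -> int:
    for exon_iv in host.exons:
        if exon.overlaps(exon_iv):
            raise ValueError(
                f"inserted exon {exon.chrom}:{exon.start}-{exon.end} overlaps a "
                f"host exon of {host.transcript_id}; that is a junction shift, "
                "not a cassette inclusion"
            )
    for i, intron in enumerate(host.introns):
        if intron.start <= exon.start and exon.end <= intron.end:
            return i
    raise ValueError(
        f"inserted exon {exon.chrom}:{exon.start}-{exon.end} does not lie "
        f"within an intron of {host.transcript_id}"
    )


def _first_stop_from(sequence: str, start0: int) -> Optional[int]:
    """0-based index of the first in-frame stop codon at or after ``start0``."""
    seq = sequence.upper()
    for i in range(start0, len(seq) - 2, 3):
        if seq[i : i + 3] in STOP_CODONS:
            return i
    return None


def classify_inclusion(
    host: TranscriptModel,
    exon: GenomicInterval,
    exon_sequence: Optional[str] = None,
    host_spliced_sequence: Optional[str] = None,
    ptc_distance: int = PTC_DISTANCE_NT,
) -> InclusionCall:
    """Classify the transcript created by including a cassette exon.

    The exon must lie wholly within one intron of the host.  Sequences,
    when given, are in transcript orientation (5'->3' of the mRNA).  Three
    precision levels:

    * ``sequence`` — full host spliced sequence and exon sequence given:
      the inclusion mRNA is rebuilt and scanned codon-by-codon from the
      start codon for the first stop.
    * ``exon_scan`` — only the exon sequence given: stops are sought
      within the inserted exon at the insertion frame; a frameshifting
      exon without an internal stop assumes a PTC at the first
      opportunity downstream (end of the exon).
    * ``frame_only`` — no sequence: pure frame arithmetic with the same
      frameshift assumption.

    Hosts without a CDS yield ``processed_transcript``.
    """
    if host.cds is None:
        return InclusionCall(
            biotype="processed_transcript",
            frame_preserving=len(exon) % 3 == 0,
            introduced_stop=False,
            mode="frame_only",
        )
    intron_idx = _host_intron_index(host, exon)
    proj0 = project_cds(host)
    ins_len = len(exon)
    frame_preserving = ins_len % 3 == 0

    # Spliced offset of the junction the exon is inserted into: genomic
    # intron i separates genomic exons i and i+1; in transcript order on
    # the minus strand that junction is counted from the other end.
    n_ex = len(host.exons)
    junction_rank = intron_idx if host.strand == "+" else n_ex - 2 - intron_idx
    u = junction_offsets(host)[junction_rank]  # bases upstream of insertion

    # Junction set of the inclusion transcript: the junction at u splits
    # into u and u + ins_len; later junctions shift by ins_len.
    old_j = proj0.junctions
    new_junctions = tuple(
        sorted(
            [j for j in old_j if j < u]
            + [u, u + ins_len]
            + [j + ins_len for j in old_j if j > u]
        )
    )
    new_length = proj0.spliced_length + ins_len

    def call(cds_start: int, stop_end: int, introduced: bool, mode: str) -> InclusionCall:
        proj = CdsProjection(
            transcript_id=f"{host.transcript_id}+incl",
            spliced_length=new_length,
            cds_start=cds_start,
            stop_end=stop_end,
            junctions=new_junctions,
        )
        return InclusionCall(
            biotype=classify_nmd(proj, ptc_distance),
            frame_preserving=frame_preserving,
            introduced_stop=introduced,
            mode=mode,
            projection=proj,
        )

    # Insertion upstream of the CDS (5' UTR) or downstream of the stop
    # (3' UTR): the reading frame is untouched; only offsets move.
    if u < proj0.cds_start:
        return call(proj0.cds_start + ins_len, proj0.stop_end + ins_len, False, "frame_only")
    if u >= proj0.stop_end:
        return call(proj0.cds_start, proj0.stop_end, False, "frame_only")

    # Insertion inside the CDS.
    if host_spliced_sequence is not None and exon_sequence is not None:
        if len(host_spliced_sequence) != proj0.spliced_length:
            raise ValueError(
                f"host sequence length {len(host_spliced_sequence)} != spliced "
                f"length {proj0.spliced_length} of {host.transcript_id}"
            )
        if len(exon_sequence) != ins_len:
            raise ValueError("exon sequence length does not match the exon interval")
        mrna = host_spliced_sequence[:u] + exon_sequence + host_spliced_sequence[u:]
        stop0 = _first_stop_from(mrna, proj0.cds_start - 1)
        if stop0 is None:
            return InclusionCall(
                biotype="processed_transcript",
                frame_preserving=frame_preserving,
                introduced_stop=False,
                mode="sequence",
            )
        stop_end = stop0 + 3
        introduced = stop_end != proj0.stop_end + ins_len
        return call(proj0.cds_start, stop_end, introduced, "sequence")

    if exon_sequence is not None:
        if len(exon_sequence) != ins_len:
            raise ValueError("exon sequence length does not match the exon interval")
        # Frame phase already consumed at the insertion point; the first
        # complete codon inside the exon starts after the spillover bases.
        phase = (u - (proj0.cds_start - 1)) % 3
        spill = (3 - phase) % 3
        stop_in_exon = _first_stop_from(exon_sequence.upper(), spill)
        if stop_in_exon is not None:
            return call(proj0.cds_start, u + stop_in_exon + 3, True, "exon_scan")
        if frame_preserving:
            return call(proj0.cds_start, proj0.stop_end + ins_len, False, "exon_scan")
        # Frameshift, no stop inside the exon: assume a PTC at the first
        # opportunity downstream of the exon.
        return call(proj0.cds_start, u + ins_len, True, "frame_only")

    # No sequence at all: frame arithmetic only.
    if frame_preserving:
        return call(proj0.cds_start, proj0.stop_end + ins_len, False, "frame_only")
    return call(proj0.cds_start, u + ins_len, True, "frame_only")


def is_poison_exon(
    host: TranscriptModel,
    exon: GenomicInterval,
    exon_sequence: Optional[str] = None,
    host_spliced_sequence: Optional[str] = None,
    ptc_distance: int = PTC_DISTANCE_NT,
) -> bool:
    """True iff including ``exon`` routes the host transcript to NMD."""
    return (
        classify_inclusion(
            host, exon, exon_sequence, host_spliced_sequence, ptc_distance
        ).biotype
        == "NMD"
    )
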