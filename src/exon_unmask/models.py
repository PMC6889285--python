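"""Transcript models, annotation sets and variant records."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional

from .intervals import GenomicInterval

#: Canonical transcript biotypes used throughout the package.
BIOTYPES = ("coding", "NMD", "retained_intron", "processed_transcript")

#: GENCODE-style biotype strings mapped onto the canonical four.
BIOTYPE_ALIASES = {
    "protein_coding": "coding",
    "coding": "coding",
    "nonsense_mediated_decay": "NMD",
    "nmd": "NMD",
    "NMD": "NMD",
    "retained_intron": "retained_intron",
    "processed_transcript": "processed_transcript",
}


def normalize_biotype(label: str) -> str:
    try:
        return BIOTYPE_ALIASES[label]
    except KeyError:
        raise ValueError(f"unknown transcript biotype {label!r}") from None


class AnnotationError(ValueError):
    """A transcript or annotation set violates a structural invariant."""


@dataclass(frozen=True)
class TranscriptModel:
    """An exon chain with an optional CDS span and a biotype.

    Exons are stored in genomic order (ascending start) regardless of
    strand; introns are the gaps between consecutive exons.  The CDS span
    gives the genomic extent of translation: its start and end must each
    fall inside an exon.
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: tuple[GenomicInterval, ...]
    cds: Optional[GenomicInterval] = None
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"transcript {self.transcript_id}: strand must be + or -, got "
                f"{self.strand!r}"
            )
        if not self.exons:
            raise AnnotationError(f"transcript {self.transcript_id} has no exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        object.__setattr__(self, "exons", exons)
        chroms = {e.chrom for e in exons}
        if len(chroms) > 1:
            raise AnnotationError(
                f"transcript {self.transcript_id} spans chromosomes {sorted(chroms)}"
            )
        for a, b in zip(exons, exons[1:]):
            if b.start <= a.end:
                raise AnnotationError(
                    f"transcript {self.transcript_id}: exons {a.start}-{a.end} and "
                    f"{b.start}-{b.end} overlap or touch"
                )
        if self.biotype not in BIOTYPES:
            object.__setattr__(self, "biotype", normalize_biotype(self.biotype))
        if self.cds is not None:
            if not any(e.start <= self.cds.start <= e.end for e in exons):
                raise AnnotationError(
                    f"transcript {self.transcript_id}: CDS start {self.cds.start} "
                    "is not inside any exon"
                )
            if not any(e.start <= self.cds.end <= e.end for e in exons):
                raise AnnotationError(
                    f"transcript {self.transcript_id}: CDS end {self.cds.end} "
                    "is not inside any exon"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    @property
    def introns(self) -> tuple[GenomicInterval, ...]:
        """Gaps between consecutive exons, in genomic order."""
        return tuple(
            GenomicInterval(self.chrom, a.end + 1, b.start - 1, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        )

    def spliced_length(self) -> int:
        return sum(len(e) for e in self.exons)

    def with_biotype(self, biotype: str) -> "TranscriptModel":
        return replace(self, biotype=biotype)


@dataclass
class AnnotationSet:
    """A versioned collection of transcript models grouped by gene."""

    version_tag: str
    transcripts: dict[str, TranscriptModel] = field(default_factory=dict)
    genes: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def from_transcripts(
        cls, version_tag: str, transcripts: Iterable[TranscriptModel]
    ) -> "AnnotationSet":
        out = cls(version_tag)
        for tx in transcripts:
            out.add(tx)
        return out

    def add(self, tx: TranscriptModel) -> None:
        if tx.transcript_id in self.transcripts:
            raise AnnotationError(f"duplicate transcript_id {tx.transcript_id}")
        self.transcripts[tx.transcript_id] = tx
        self.genes.setdefault(tx.gene_id, []).append(tx.transcript_id)

    def gene_transcripts(self, gene_id: str) -> list[TranscriptModel]:
        return [self.transcripts[t] for t in self.genes.get(gene_id, [])]

    def __len__(self) -> int:
        return len(self.transcripts)

    def __iter__(self):
        return iter(self.transcripts.values())

    def without_retained_introns(self) -> "AnnotationSet":
        """Copy of the set with retained-intron transcripts dropped.

        Retained-intron models blanket whole introns with exonic sequence
        and would mask genuine novel exons, so delta detection removes them
        up front.
        """
        keep = [tx for tx in self if tx.biotype != "retained_intron"]
        return AnnotationSet.from_transcripts(self.version_tag, keep)


@dataclass
class VariantRecord:
    """A single variant with caller-quality and context annotations.

    ``pos`` is the 1-based leftmost affected base (VCF-style left aligned
    for indels).  ``caller_scores`` maps caller name (e.g. ``"gatk"``,
    ``"samtools"``) to its quality score; ``caller_set`` lists which
    callers reported the variant.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    variant_id: str = "."
    de_novo: bool = False
    clinical_significance: Optional[str] = None
    coverage: Optional[int] = None
    caller_scores: Mapping[str, float] = field(default_factory=dict)
    caller_set: frozenset[str] = frozenset()
    homopolymer_run: int = 0
    in_simple_repeat: bool = False
    in_database: bool = False

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.variant_id}: pos must be >= 1")
        if not self.ref or not self.alt:
            raise ValueError(f"variant {self.variant_id}: empty allele")
        if self.ref == self.alt:
            raise ValueError(f"variant {self.variant_id}: ref == alt ({self.ref})")
        self.caller_set = frozenset(c.lower() for c in self.caller_set)
        self.caller_scores = {k.lower(): float(v) for k, v in dict(self.caller_scores).items()}
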