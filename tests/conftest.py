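"""Shared fixtures: toy transcripts and a seeded synthetic bundle."""

from __future__ import annotations

import pytest

from exon_unmask.intervals import GenomicInterval
from exon_unmask.models import AnnotationSet, TranscriptModel
from exon_unmask.simulate import SimulationConfig, simulate_locus_pair


def make_tx(
    exons,
    strand: str = "+",
    cds: tuple[int, int] | None = None,
    transcript_id: str = "T1",
    gene_id: str = "G1",
    chrom: str = "chr1",
    biotype: str = "coding",
) -> TranscriptModel:
    """Build a transcript from (start, end) exon tuples."""
    ivs = tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons)
    cds_iv = GenomicInterval(chrom, cds[0], cds[1], strand) if cds else None
    return TranscriptModel(transcript_id, gene_id, strand, ivs, cds_iv, biotype)


def make_set(*transcripts, tag: str = "v") -> AnnotationSet:
    return AnnotationSet.from_transcripts(tag, transcripts)


@pytest.fixture(scope="session")
def sim_bundle():
    """One deterministic synthetic locus pair with its truth set."""
    cfg = SimulationConfig(seed=11)
    old, new, truth = simulate_locus_pair(cfg)
    return cfg, old, new, truth
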