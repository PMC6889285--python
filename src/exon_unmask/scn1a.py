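"""Published SCN1A splicing-feature table used as worked example and fixture.

The 15 features below are the novel exons, shifted splice junctions and
intron events added to the SCN1A locus (GRCh38, chr2, minus strand) by the
manual re-annotation of epilepsy genes, with the coordinates, printed
feature lengths and transcript biotypes as published.  Three rows are
internally inconsistent in the published table — the coordinate span does
not equal the printed length — and are carried verbatim with
``length_discrepancy=True`` rather than silently corrected.

Features 7, 9, 12 and 14 are the four cassette exons whose concatenation
forms the 450-bp region used by the de novo enrichment test; features 7
and 14 are the poison exons harbouring the two cohort de novo variants
(chr2:166,060,831 and chr2:165,999,107).
"""

from __future__ import annotations

from dataclasses import dataclass

from .intervals import GenomicInterval, interval_length


@dataclass(frozen=True)
class Scn1aFeature:
    number: int
    feature_type: str       # exon | splice_acceptor | splice_donor | intron | intron_retention
    printed_length: int     # nt, as published
    interval: GenomicInterval
    position: str           # internal | terminal
    biotype: str            # coding | NMD | retained_intron | processed_transcript | n/a
    region: str             # 5utr | cds | n/a
    conserved: str          # yes | no | partial

    @property
    def span_length(self) -> int:
        return interval_length(self.interval)

    @property
    def length_discrepancy(self) -> bool:
        """True when the printed length disagrees with the coordinate span."""
        return self.span_length != self.printed_length


def _f(num, ftype, length, start, end, position, biotype, region, conserved):
    return Scn1aFeature(
        number=num,
        feature_type=ftype,
        printed_length=length,
        interval=GenomicInterval("chr2", start, end, "-"),
        position=position,
        biotype=biotype,
        region=region,
        conserved=conserved,
    )


SCN1A_FEATURES: tuple[Scn1aFeature, ...] = (
    _f(1, "exon", 168, 166_149_047, 166_149_214, "terminal", "coding", "5utr", "yes"),
    _f(2, "exon", 87, 166_126_924, 166_127_010, "internal", "coding", "5utr", "partial"),
    _f(3, "exon", 73, 166_126_982, 166_127_055, "terminal", "coding", "5utr", "no"),
    _f(4, "exon", 111, 166_126_924, 166_127_034, "terminal", "retained_intron", "5utr", "yes"),
    _f(5, "splice_acceptor", 46, 166_077_802, 166_077_848, "internal", "coding", "5utr", "no"),
    _f(6, "exon", 264, 166_071_623, 166_071_886, "internal", "processed_transcript", "n/a", "no"),
    _f(7, "exon", 228, 166_060_640, 166_060_867, "internal", "NMD", "cds", "no"),
    _f(8, "splice_acceptor", 4, 166_056_501, 166_056_504, "internal", "NMD", "cds", "yes"),
    _f(9, "exon", 92, 166_053_039, 166_053_130, "internal", "coding", "cds", "partial"),
    _f(10, "splice_acceptor", 3, 166_045_325, 166_045_327, "internal", "coding", "cds", "yes"),
    _f(11, "splice_donor", 16, 166_041_215, 166_041_230, "internal", "NMD", "cds", "yes"),
    _f(12, "exon", 64, 166_007_230, 166_007_293, "internal", "NMD", "cds", "yes"),
    _f(13, "intron", 282, 166_002_471, 166_002_752, "internal", "coding", "cds", "yes"),
    _f(14, "exon", 66, 165_999_051, 165_999_116, "internal", "NMD", "cds", "no"),
    _f(15, "intron_retention", 1723, 165_992_413, 165_994_147, "terminal", "coding", "cds", "yes"),
)

#: Feature numbers whose published length and coordinate span disagree.
DISCREPANT_FEATURES = tuple(f.number for f in SCN1A_FEATURES if f.length_discrepancy)

#: The four coding/NMD cassette exons concatenated for the enrichment test.
ENRICHMENT_FEATURE_NUMBERS = (7, 9, 12, 14)

#: The two de novo variant positions found in the 122-proband cohort screen
#: (inside poison exons 7 and 14) and the size of that cohort.
COHORT_DE_NOVO_POSITIONS = (166_060_831, 165_999_107)
COHORT_SIZE = 122
COHORT_DIAGNOSED = 2

#: Exome-wide number of protein-coding genes used for Bonferroni correction.
EXOME_WIDE_TESTS = 18_000


def feature(number: int) -> Scn1aFeature:
    for f in SCN1A_FEATURES:
        if f.number == number:
            return f
    raise KeyError(f"no SCN1A feature {number}")


def enrichment_features() -> list[Scn1aFeature]:
    """The cassette exons forming the concatenated 450-bp test region."""
    return [feature(n) for n in ENRICHMENT_FEATURE_NUMBERS]
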