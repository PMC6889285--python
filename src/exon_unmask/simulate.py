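"""Synthetic inputs with known ground truth for every pipeline stage.

The generator emulates the study's real inputs at desk scale: a pair of
annotation versions for a panel of genes (the re-annotation delta), a
clinical/cohort variant table, a per-site mutability table, a
conserved-element track and a splice-junction count matrix over 36
pre-frontal-cortex samples in six developmental stages.  Every planted
feature is recorded in a :class:`TruthSet` so the analysis modules can be
checked for exact truth recovery.

All randomness flows from ``SimulationConfig.seed`` through named
:func:`numpy.random.default_rng` streams (one per subsystem), so repeated
runs are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from . import io as um_io
from .evidence import LIFE_STAGES, ConservedElementTrack, JunctionCountMatrix
from .intervals import GenomicInterval
from .models import AnnotationSet, TranscriptModel, VariantRecord
from .nmd import genomic_position, junction_offsets, project_cds

BASES = np.array(list("ACGT"))
STOPS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class VariantPlan:
    """How many variants to plant in each re-annotation / filter category."""

    newly_exonic: int = 3
    splice_proximal: int = 2       # at distances 1..8 from an old splice site
    deep_intronic: int = 2
    old_exonic: int = 2
    mask_low_coverage: int = 1     # coverage < 5 -> unsequenced
    mask_low_score: int = 1        # score < 30 -> unsequenced
    cohort_low_coverage: int = 1   # coverage == 7, fails the strict > 7 keep rule
    cohort_low_gatk: int = 1       # GATK quality == 50, fails the strict > 50 rule
    cohort_single_caller: int = 1
    cohort_in_database: int = 1
    cohort_homopolymer: int = 1    # run of 9 (> 8 excluded)
    cohort_simple_repeat: int = 1


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic locus panel.

    Defaults mirror the real analysis where it states a number (122
    probands, 36 samples in 6 stages, fivefold stage-enrichment calls, a
    ~5% background conservation density, a genome-average per-copy
    mutability of 1.2e-8/site) and otherwise use gene structures typical
    of the large brain-expressed channel genes the panel targets.
    """

    seed: int
    n_genes: int = 8
    exons_per_transcript: tuple[int, int] = (6, 10)
    exon_length: tuple[int, int] = (90, 300)
    intron_length: tuple[int, int] = (600, 2000)
    n_novel_exons: int = 5
    n_poison_stop: int = 2         # stop-carrying, frame-preserving poison exons
    n_poison_frameshift: int = 1   # frameshifting poison exons (stop in new frame)
    n_novel_introns: int = 3       # exon-skipping events
    n_shifted_junctions: int = 4
    shift_range: tuple[int, int] = (10, 40)
    n_retained_intron_transcripts: int = 2
    variant_plan: VariantPlan = VariantPlan()
    mutability_site_rate: float = 1.2e-8   # per copy per site, summed over alts
    mutability_jitter: float = 0.0
    track_density: float = 0.05
    element_length: tuple[int, int] = (100, 1000)
    query_overlap_fraction: Optional[float] = None  # plant excess overlap on a query
    n_samples_per_stage: int = 6
    library_size: int = 2_000_000
    baseline_cpm: float = 5.0
    low_support_cpm: float = 0.02
    fraction_low_support: float = 0.2
    foetal_fold: float = 10.0
    n_enriched_introns: int = 3

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.n_poison_stop + self.n_poison_frameshift > self.n_novel_exons:
            raise ValueError("more poison exons requested than novel exons")
        if not 0 < self.track_density <= 1:
            raise ValueError("track density must be in (0, 1]")
        if self.exon_length[0] < 19:
            raise ValueError("exons must be >= 19 nt to host interior variants")
        if self.intron_length[0] < self.exon_length[1] + 2 * _EXON_MARGIN:
            raise ValueError("introns too short to host planted exons")


_EXON_MARGIN = 50  # min distance of a planted exon from old intron boundaries


@dataclass
class PlantedExon:
    gene_id: str
    host_transcript_id: str
    transcript_id: str
    interval: GenomicInterval
    kind: str                 # poison_stop | poison_frameshift | benign
    expected_biotype: str     # NMD | coding
    exon_sequence: str
    host_spliced_sequence: str


@dataclass
class PlantedIntron:
    gene_id: str
    transcript_id: str
    interval: GenomicInterval


@dataclass
class PlantedShift:
    gene_id: str
    transcript_id: str
    changed: GenomicInterval
    side: str                 # donor | acceptor
    direction: str            # extension | truncation
    shift_nt: int
    old_boundary: int         # genomic position of the replaced splice site


@dataclass
class TruthSet:
    novel_exons: list[PlantedExon] = field(default_factory=list)
    novel_introns: list[PlantedIntron] = field(default_factory=list)
    shifted_junctions: list[PlantedShift] = field(default_factory=list)
    retained_intron_transcripts: list[str] = field(default_factory=list)
    #: novel introns created as a side effect of planting exons (the host
    #: intron splits in two) or shifting boundaries (the adjacent intron
    #: moves); the full expected novel-intron set is planted + induced.
    induced_novel_introns: list[PlantedIntron] = field(default_factory=list)
    expected_footprint_gain: int = 0
    expected_cds_gain: int = 0
    variant_status: dict[str, str] = field(default_factory=dict)
    variant_filter_fate: dict[str, str] = field(default_factory=dict)
    enriched_introns: list[str] = field(default_factory=list)
    genome: dict[str, int] = field(default_factory=dict)

    def to_json(self, path) -> None:
        def enc(obj):
            if isinstance(obj, GenomicInterval):
                return {"chrom": obj.chrom, "start": obj.start, "end": obj.end,
                        "strand": obj.strand}
            if dataclasses.is_dataclass(obj):
                return dataclasses.asdict(obj)
            raise TypeError(type(obj))

        Path(path).write_text(
            json.dumps(dataclasses.asdict(self), default=enc, indent=1, sort_keys=True)
        )


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def _random_seq(rng, n: int) -> str:
    return "".join(rng.choice(BASES, size=n))


def _random_codons(rng, n_codons: int) -> str:
    """``n_codons`` random codons, none of them stops."""
    out = []
    while len(out) < n_codons:
        codon = _random_seq(rng, 3)
        if codon not in STOPS:
            out.append(codon)
    return "".join(out)


def _build_gene(rng, cfg: SimulationConfig, gene_id: str, chrom: str,
                origin: int, strand: str) -> TranscriptModel:
    n_ex = int(rng.integers(cfg.exons_per_transcript[0], cfg.exons_per_transcript[1] + 1))
    exon_lens = rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1, size=n_ex)
    intron_lens = rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1, size=n_ex - 1)
    exons = []
    pos = origin
    for i in range(n_ex):
        exons.append(GenomicInterval(chrom, pos, pos + int(exon_lens[i]) - 1, strand))
        pos = exons[-1].end + 1
        if i < n_ex - 1:
            pos += int(intron_lens[i])
    tx = TranscriptModel(f"{gene_id}.T1", gene_id, strand, tuple(exons), biotype="coding")
    # CDS: 30 nt of 5' UTR, stop codon ending 30 nt short of the 3' end,
    # total CDS length a multiple of 3.
    spliced = tx.spliced_length()
    cds_start_s = 31
    cds_end_s = spliced - 30
    cds_len = cds_end_s - cds_start_s + 1
    cds_end_s -= cds_len % 3
    g1 = genomic_position(tx, cds_start_s)
    g2 = genomic_position(tx, cds_end_s)
    cds = GenomicInterval(chrom, min(g1, g2), max(g1, g2), strand)
    return dataclasses.replace(tx, cds=cds)


def _host_sequence(rng, tx: TranscriptModel) -> str:
    """Spliced mRNA: random UTRs around ATG + non-stop codons + TAA."""
    proj = project_cds(tx)
    cds_len = proj.stop_end - proj.cds_start + 1
    assert cds_len % 3 == 0
    utr5 = _random_seq(rng, proj.cds_start - 1)
    body = "ATG" + _random_codons(rng, cds_len // 3 - 2) + "TAA"
    utr3 = _random_seq(rng, proj.spliced_length - proj.stop_end)
    return utr5 + body + utr3


def _insertion_context(host: TranscriptModel, intron_idx: int) -> int:
    """Spliced offset of the junction at genomic intron ``intron_idx``."""
    n_ex = len(host.exons)
    rank = intron_idx if host.strand == "+" else n_ex - 2 - intron_idx
    return junction_offsets(host)[rank]


def _plant_exon_sequence(rng, kind: str, length: int, phase: int,
                         host_seq: str, u: int) -> str:
    """Sequence for a planted cassette exon, in transcript orientation.

    ``phase`` is the number of codon bases already consumed at the
    insertion point and ``u`` the spliced insertion offset into
    ``host_seq``.  Stop-carrying kinds place a TAA at the first complete
    codon inside the exon; benign exons avoid stops in every codon that
    touches the exon, including the two codons spanning its boundaries.
    """
    spill = (3 - phase) % 3
    if kind in ("poison_stop", "poison_frameshift"):
        if spill + 3 > length:
            raise ValueError("exon too short to carry an in-frame stop")
        seq = list(_random_seq(rng, length))
        seq[spill : spill + 3] = "TAA"
        return "".join(seq)
    # Benign: build codon-by-codon so no codon touching the exon —
    # including the two spanning its boundaries — is a stop.
    upstream = host_seq[u - phase : u]  # codon bases already consumed
    for _ in range(100):
        head = _random_seq(rng, spill)
        if (upstream + head) not in STOPS or phase == 0:
            break
    else:
        raise RuntimeError("could not pick stop-free boundary bases")
    n_full, tail_len = divmod(length - spill, 3)
    body = _random_codons(rng, n_full)
    downstream = host_seq[u : u + 3 - tail_len] if tail_len else ""
    for _ in range(100):
        tail = _random_seq(rng, tail_len)
        if tail_len == 0 or (tail + downstream) not in STOPS:
            break
    else:
        raise RuntimeError("could not pick stop-free boundary bases")
    return head + body + tail


def simulate_locus_pair(cfg: SimulationConfig):
    """Generate (old AnnotationSet, new AnnotationSet, TruthSet).

    The new set is the old set plus planted novel exons (with known
    poison/benign status and sequences), exon-skipping novel introns,
    shifted splice junctions and retained-intron transcripts, each
    recorded in the truth set.
    """
    rng = _rng(cfg, 1)
    truth = TruthSet()
    old_tx: list[TranscriptModel] = []
    new_tx: list[TranscriptModel] = []
    genome: dict[str, int] = {}

    genes = []
    chrom_cursor = {"chrA": 10_000, "chrB": 10_000}
    for i in range(cfg.n_genes):
        gene_id = f"GENE{i + 1:02d}"
        chrom = "chrA" if i % 2 == 0 else "chrB"
        strand = "+" if i % 4 < 2 else "-"
        tx = _build_gene(rng, cfg, gene_id, chrom, chrom_cursor[chrom], strand)
        chrom_cursor[chrom] = tx.span.end + 10_000
        genes.append(tx)
        old_tx.append(tx)
        new_tx.append(tx)
    for chrom, cursor in chrom_cursor.items():
        genome[chrom] = cursor + 10_000
    truth.genome = genome

    host_seqs = {tx.transcript_id: _host_sequence(rng, tx) for tx in genes}

    # Reserve introns so planted features never collide within a gene.
    reserved: set[tuple[str, int]] = set()

    def free_intron(tx: TranscriptModel, allow_last=0, allow_first=0):
        """A random unreserved intron index, keeping the requested distance
        from the transcript ends in *transcript* order (so poison exons
        keep >= 2 downstream junctions on either strand)."""
        n = len(tx.introns)

        def rank(j):  # transcript-order rank of genomic intron j
            return j if tx.strand == "+" else n - 1 - j

        candidates = [j for j in range(n)
                      if allow_first <= rank(j) < n - allow_last
                      and (tx.gene_id, j) not in reserved]
        if not candidates:
            return None
        j = int(rng.choice(candidates))
        reserved.add((tx.gene_id, j))
        return j

    # --- novel (cassette) exons -------------------------------------------
    kinds = (["poison_stop"] * cfg.n_poison_stop
             + ["poison_frameshift"] * cfg.n_poison_frameshift)
    kinds += ["benign"] * (cfg.n_novel_exons - len(kinds))
    for k, kind in enumerate(kinds):
        for _ in range(10 * cfg.n_genes):
            host = genes[int(rng.integers(len(genes)))]
            j = free_intron(host, allow_last=2)
            if j is not None:
                break
        else:
            raise ValueError("config infeasible: no free intron for a novel exon")
        intron = host.introns[j]
        length = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1]))
        if kind == "poison_frameshift":
            if length % 3 == 0:
                length += 1  # force a frameshift
        else:
            length -= length % 3  # frame-preserving
        lo = intron.start + _EXON_MARGIN
        hi = intron.end - _EXON_MARGIN - length
        start = int(rng.integers(lo, hi + 1))
        exon = GenomicInterval(intron.chrom, start, start + length - 1, host.strand)
        u = _insertion_context(host, j)
        proj = project_cds(host)
        phase = (u - (proj.cds_start - 1)) % 3
        seq = _plant_exon_sequence(rng, kind, length, phase,
                                   host_seqs[host.transcript_id], u)
        tx_id = f"{host.gene_id}.NE{k + 1}"
        exons = tuple(sorted(host.exons + (exon,), key=lambda e: e.start))
        expected = "NMD" if kind != "benign" else "coding"
        new_tx.append(
            TranscriptModel(tx_id, host.gene_id, host.strand, exons,
                            cds=host.cds, biotype=expected)
        )
        truth.novel_exons.append(
            PlantedExon(host.gene_id, host.transcript_id, tx_id, exon, kind,
                        expected, seq, host_seqs[host.transcript_id])
        )
        # The cassette exon splits its host intron into two new introns.
        for lo, hi in ((intron.start, exon.start - 1), (exon.end + 1, intron.end)):
            truth.induced_novel_introns.append(
                PlantedIntron(host.gene_id, tx_id,
                              GenomicInterval(intron.chrom, lo, hi, host.strand))
            )
        truth.expected_footprint_gain += len(exon)
        truth.expected_cds_gain += len(exon)

    # --- novel introns (exon skipping) ------------------------------------
    for k in range(cfg.n_novel_introns):
        for _ in range(10 * cfg.n_genes):
            host = genes[int(rng.integers(len(genes)))]
            n_ex = len(host.exons)
            skippable = [
                e for e in range(1, n_ex - 1)
                if (host.gene_id, e - 1) not in reserved
                and (host.gene_id, e) not in reserved
            ]
            if skippable:
                break
        else:
            raise ValueError("config infeasible: no skippable exon left")
        e = int(rng.choice(skippable))
        reserved.add((host.gene_id, e - 1))
        reserved.add((host.gene_id, e))
        exons = tuple(x for i, x in enumerate(host.exons) if i != e)
        tx_id = f"{host.gene_id}.NI{k + 1}"
        new_tx.append(
            TranscriptModel(tx_id, host.gene_id, host.strand, exons,
                            cds=host.cds, biotype="coding")
        )
        novel = GenomicInterval(
            host.chrom, host.exons[e - 1].end + 1, host.exons[e + 1].start - 1,
            host.strand,
        )
        truth.novel_introns.append(PlantedIntron(host.gene_id, tx_id, novel))

    # --- shifted splice junctions ------------------------------------------
    for k in range(cfg.n_shifted_junctions):
        for _ in range(10 * cfg.n_genes):
            host = genes[int(rng.integers(len(genes)))]
            n_ex = len(host.exons)
            e = int(rng.integers(1, n_ex - 1))  # internal exon
            boundary = "end" if rng.random() < 0.5 else "start"
            j = e if boundary == "end" else e - 1  # adjacent intron index
            if (host.gene_id, j) not in reserved:
                reserved.add((host.gene_id, j))
                break
        else:
            raise ValueError("config infeasible: no free junction to shift")
        shift = int(rng.integers(cfg.shift_range[0], cfg.shift_range[1] + 1))
        direction = "extension" if rng.random() < 0.7 else "truncation"
        exon = host.exons[e]
        if boundary == "end":
            new_end = exon.end + shift if direction == "extension" else exon.end - shift
            new_exon = GenomicInterval(exon.chrom, exon.start, new_end, exon.strand)
            lo = min(exon.end, new_end) + 1
            hi = max(exon.end, new_end)
            old_boundary = exon.end
        else:
            new_start = exon.start - shift if direction == "extension" else exon.start + shift
            new_exon = GenomicInterval(exon.chrom, new_start, exon.end, exon.strand)
            lo = min(exon.start, new_start)
            hi = max(exon.start, new_start) - 1
            old_boundary = exon.start
        exons = tuple(x if i != e else new_exon for i, x in enumerate(host.exons))
        tx_id = f"{host.gene_id}.SJ{k + 1}"
        # Keep the CDS span valid: shrink it if a truncation removed its edge.
        cds = host.cds
        new_tx.append(
            TranscriptModel(tx_id, host.gene_id, host.strand, exons,
                            cds=cds, biotype="coding")
        )
        if host.strand == "-":
            side = "donor" if boundary == "start" else "acceptor"
        else:
            side = "donor" if boundary == "end" else "acceptor"
        truth.shifted_junctions.append(
            PlantedShift(host.gene_id, tx_id,
                         GenomicInterval(exon.chrom, lo, hi, exon.strand),
                         side, direction, shift, old_boundary)
        )
        # The adjacent intron moves with the boundary, becoming novel.
        if boundary == "end":
            moved = GenomicInterval(exon.chrom, new_exon.end + 1,
                                    host.exons[e + 1].start - 1, host.strand)
        else:
            moved = GenomicInterval(exon.chrom, host.exons[e - 1].end + 1,
                                    new_exon.start - 1, host.strand)
        truth.induced_novel_introns.append(PlantedIntron(host.gene_id, tx_id, moved))
        if direction == "extension":
            truth.expected_footprint_gain += shift
            truth.expected_cds_gain += shift

    # --- retained-intron transcripts ----------------------------------------
    for k in range(cfg.n_retained_intron_transcripts):
        host = genes[int(rng.integers(len(genes)))]
        n_ex = len(host.exons)
        e = int(rng.integers(0, n_ex - 1))
        merged = GenomicInterval(host.chrom, host.exons[e].start,
                                 host.exons[e + 1].end, host.strand)
        exons = tuple([x for i, x in enumerate(host.exons) if i not in (e, e + 1)]
                      + [merged])
        tx_id = f"{host.gene_id}.RI{k + 1}"
        new_tx.append(
            TranscriptModel(tx_id, host.gene_id, host.strand, exons,
                            cds=None, biotype="retained_intron")
        )
        truth.retained_intron_transcripts.append(tx_id)

    old_set = AnnotationSet.from_transcripts("old", old_tx)
    new_set = AnnotationSet.from_transcripts("new", new_tx)
    return old_set, new_set, truth


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------


def _snv(rng, chrom, pos, vid, **kw) -> VariantRecord:
    ref, alt = rng.choice(BASES, size=2, replace=False)
    defaults = dict(
        coverage=30,
        caller_scores={"gatk": 99.0, "samtools": 80.0},
        caller_set=frozenset({"gatk", "samtools"}),
    )
    defaults.update(kw)
    return VariantRecord(chrom=chrom, pos=int(pos), ref=str(ref), alt=str(alt),
                         variant_id=vid, **defaults)


def simulate_variants(
    truth: TruthSet, cfg: SimulationConfig, old: AnnotationSet, new: AnnotationSet
) -> list[VariantRecord]:
    """Plant variants according to ``cfg.variant_plan``.

    Re-annotation categories are placed against the planted features
    (novel-exon interiors, shift-extension flanks, deep introns, old
    exons); filter categories get caller fields crafted to fail exactly
    one rule.  Planned statuses and filter fates go into the truth set.
    """
    rng = _rng(cfg, 2)
    plan = cfg.variant_plan
    out: list[VariantRecord] = []
    counter = 0

    def vid(prefix):
        nonlocal counter
        counter += 1
        return f"{prefix}{counter:03d}"

    # newly exonic: interior of planted novel exons, > 8 nt from every
    # splice boundary in either annotation version.
    if plan.newly_exonic > len(truth.novel_exons) * 5:
        raise ValueError("plan requests more newly_exonic variants than exon space")
    for i in range(plan.newly_exonic):
        pe = truth.novel_exons[i % len(truth.novel_exons)]
        pos = int(rng.integers(pe.interval.start + 9, pe.interval.end - 8))
        v = _snv(rng, pe.interval.chrom, pos, vid("NE"),
                 clinical_significance="pathogenic", de_novo=True)
        out.append(v)
        truth.variant_status[v.variant_id] = "newly_exonic"
        truth.variant_filter_fate[v.variant_id] = "pass"

    # splice proximal: inside a planted extension, 1..8 nt beyond the old
    # exon boundary (exonic in new, intronic in old, within the flank).
    extensions = [s for s in truth.shifted_junctions
                  if s.direction == "extension" and s.shift_nt >= 9]
    if plan.splice_proximal > 0 and not extensions:
        raise ValueError("plan requests splice_proximal variants but no "
                         "extension >= 9 nt was planted")
    for i in range(plan.splice_proximal):
        s = extensions[i % len(extensions)]
        d = int(rng.integers(1, 9))
        pos = s.old_boundary + d if s.changed.start > s.old_boundary else s.old_boundary - d
        v = _snv(rng, s.changed.chrom, pos, vid("SP"),
                 clinical_significance="uncertain")
        out.append(v)
        truth.variant_status[v.variant_id] = "splice_proximal"
        truth.variant_filter_fate[v.variant_id] = "pass"

    # deep intronic / old exonic: unchanged either way.
    canonical = [tx for tx in old]
    # every exon base present only in the new set (incl. retained-intron
    # models): deep-intronic variants must stay clear of all of it.
    feature_ivs = [
        exon
        for tx in new
        if tx.transcript_id not in old.transcripts
        for exon in tx.exons
    ]
    for i in range(plan.deep_intronic):
        for _ in range(200):
            tx = canonical[int(rng.integers(len(canonical)))]
            introns = tx.introns
            intron = introns[int(rng.integers(len(introns)))]
            pos = (intron.start + intron.end) // 2
            clear = all(not f.contains(tx.chrom, pos) for f in feature_ivs)
            if clear and pos - intron.start > 8 and intron.end - pos > 8:
                break
        v = _snv(rng, tx.chrom, pos, vid("DI"))
        out.append(v)
        truth.variant_status[v.variant_id] = "unchanged"
        truth.variant_filter_fate[v.variant_id] = "pass"

    def old_exon_pos():
        tx = canonical[int(rng.integers(len(canonical)))]
        exon = tx.exons[int(rng.integers(len(tx.exons)))]
        return tx.chrom, int(rng.integers(exon.start + 9, exon.end - 8))

    for i in range(plan.old_exonic):
        chrom, pos = old_exon_pos()
        v = _snv(rng, chrom, pos, vid("OE"))
        out.append(v)
        truth.variant_status[v.variant_id] = "unchanged"
        truth.variant_filter_fate[v.variant_id] = "pass"

    fail_specs = [
        ("mask_low_coverage", "masked", dict(coverage=4)),
        ("mask_low_score", "masked",
         dict(caller_scores={"gatk": 25.0, "samtools": 25.0})),
        ("cohort_low_coverage", "cohort_fail", dict(coverage=7)),
        ("cohort_low_gatk", "cohort_fail",
         dict(caller_scores={"gatk": 50.0, "samtools": 80.0})),
        ("cohort_single_caller", "cohort_fail",
         dict(caller_set=frozenset({"gatk"}))),
        ("cohort_in_database", "cohort_fail", dict(in_database=True)),
        ("cohort_homopolymer", "cohort_fail", dict(homopolymer_run=9)),
        ("cohort_simple_repeat", "cohort_fail", dict(in_simple_repeat=True)),
    ]
    for name, fate, kw in fail_specs:
        for _ in range(getattr(plan, name)):
            chrom, pos = old_exon_pos()
            v = _snv(rng, chrom, pos, vid("FF"), **kw)
            out.append(v)
            truth.variant_status[v.variant_id] = "unchanged"
            truth.variant_filter_fate[v.variant_id] = fate
    return out


# ---------------------------------------------------------------------------
# Junction counts
# ---------------------------------------------------------------------------


def simulate_junction_counts(
    new: AnnotationSet, cfg: SimulationConfig, truth: Optional[TruthSet] = None
) -> JunctionCountMatrix:
    """Poisson junction counts over all unique introns of the new set.

    Every stage has ``n_samples_per_stage`` samples with a fixed library
    size.  A configured number of introns get a ``foetal_fold`` expression
    boost in foetal samples (recorded in the truth set); a configured
    fraction get near-zero expression to populate the unsupported class.
    """
    rng = _rng(cfg, 3)
    introns = sorted(
        {(iv.chrom, iv.start, iv.end) for tx in new for iv in tx.introns}
    )
    ivs = [GenomicInterval(c, s, e, ".") for c, s, e in introns]
    keys = [JunctionCountMatrix.intron_key(iv) for iv in ivs]
    samples = []
    stages = {}
    totals = {}
    for si, stage in enumerate(LIFE_STAGES):
        for r in range(cfg.n_samples_per_stage):
            name = f"S{si * cfg.n_samples_per_stage + r + 1:02d}"
            samples.append(name)
            stages[name] = stage
            totals[name] = cfg.library_size

    n = len(ivs)
    n_enriched = min(cfg.n_enriched_introns, n)
    enriched_idx = set(rng.choice(n, size=n_enriched, replace=False).tolist())
    remaining = [i for i in range(n) if i not in enriched_idx]
    n_low = int(round(cfg.fraction_low_support * len(remaining)))
    low_idx = set(rng.choice(remaining, size=n_low, replace=False).tolist()) if n_low else set()

    import pandas as pd

    data = np.zeros((n, len(samples)), dtype=np.int64)
    for i in range(n):
        base = cfg.low_support_cpm if i in low_idx else cfg.baseline_cpm
        for j, s in enumerate(samples):
            mean = base * totals[s] / 1e6
            if i in enriched_idx and stages[s] == "Foetal":
                mean *= cfg.foetal_fold
            data[i, j] = rng.poisson(mean)
    counts = pd.DataFrame(data, index=keys, columns=samples)
    if truth is not None:
        truth.enriched_introns = [keys[i] for i in sorted(enriched_idx)]
    return JunctionCountMatrix(introns=ivs, counts=counts, stages=stages, totals=totals)


# ---------------------------------------------------------------------------
# Conservation track and mutability table
# ---------------------------------------------------------------------------


def simulate_track_and_mutability(
    cfg: SimulationConfig,
    genome: dict[str, int],
    region_features: Optional[list[GenomicInterval]] = None,
    query: Optional[list[GenomicInterval]] = None,
):
    """Generate (ConservedElementTrack, MutabilityTable).

    The track tiles each chromosome with elements whose mean spacing
    realises ``track_density``; if ``query`` and
    ``cfg.query_overlap_fraction`` are given, extra elements are planted
    over the query until it reaches that overlap fraction (an enriched
    foreground over the background density).  The mutability table covers
    ``region_features`` at ``mutability_site_rate`` per site (split
    equally over the three alternate alleles, optionally jittered).
    """
    from .enrichment import MutabilityTable
    from .intervals import covered_bases, total_bases

    rng = _rng(cfg, 4)
    elem_mean = (cfg.element_length[0] + cfg.element_length[1]) / 2
    gap_mean = elem_mean * (1 - cfg.track_density) / cfg.track_density
    elements: list[GenomicInterval] = []
    for chrom in sorted(genome):
        pos = 1
        length = genome[chrom]
        while pos < length:
            gap = int(rng.exponential(gap_mean)) + 1
            start = pos + gap
            size = int(rng.integers(cfg.element_length[0], cfg.element_length[1] + 1))
            end = min(start + size - 1, length)
            if start > length:
                break
            elements.append(GenomicInterval(chrom, start, end, "."))
            pos = end + 1

    if query and cfg.query_overlap_fraction:
        target = cfg.query_overlap_fraction
        qbases = total_bases(query)
        for _ in range(10_000):
            deficit = int(np.ceil(target * qbases)) - covered_bases(query, elements)
            if deficit <= 0:
                break
            iv = query[int(rng.integers(len(query)))]
            # never plant more bases than still needed, so the realised
            # fraction lands just at the configured target
            size = min(max(1, int(rng.integers(1, max(2, len(iv) // 2)))), deficit, len(iv))
            start = int(rng.integers(iv.start, iv.end - size + 2))
            elements.append(
                GenomicInterval(iv.chrom, start, min(start + size - 1, iv.end), ".")
            )

    track = ConservedElementTrack(intervals=elements, genome=dict(genome))

    import pandas as pd

    rows = []
    for feat in region_features or []:
        for pos in range(feat.start, feat.end + 1):
            ref = str(rng.choice(BASES))
            alts = [b for b in "ACGT" if b != ref]
            for alt in alts:
                mu = cfg.mutability_site_rate / 3
                if cfg.mutability_jitter > 0:
                    mu *= float(rng.lognormal(0.0, cfg.mutability_jitter))
                rows.append((feat.chrom, pos, ref, alt, mu))
    table = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "mu"])
    return track, (MutabilityTable(table) if rows else None)


def simulate_all(cfg: SimulationConfig, out_dir) -> dict[str, str]:
    """Run every generator and write the full input bundle to ``out_dir``.

    Emits old.gtf, new.gtf, truth.json, variants.vcf, junctions.tsv,
    stages.tsv, elements.bed, genome.tsv and mutability.tsv; returns the
    path map.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    old, new, truth = simulate_locus_pair(cfg)
    variants = simulate_variants(truth, cfg, old, new)
    junctions = simulate_junction_counts(new, cfg, truth)
    region = [p.interval for p in truth.novel_exons]
    track, mutability = simulate_track_and_mutability(
        cfg, truth.genome, region_features=region, query=region
    )
    paths = {
        "old_gtf": str(out / "old.gtf"),
        "new_gtf": str(out / "new.gtf"),
        "truth": str(out / "truth.json"),
        "variants_vcf": str(out / "variants.vcf"),
        "junctions_tsv": str(out / "junctions.tsv"),
        "stages_tsv": str(out / "stages.tsv"),
        "elements_bed": str(out / "elements.bed"),
        "genome_tsv": str(out / "genome.tsv"),
        "mutability_tsv": str(out / "mutability.tsv"),
    }
    um_io.write_gtf(old, paths["old_gtf"])
    um_io.write_gtf(new, paths["new_gtf"])
    truth.to_json(paths["truth"])
    um_io.write_variants_vcf(variants, paths["variants_vcf"])
    junctions.to_tsv(paths["junctions_tsv"], paths["stages_tsv"])
    um_io.write_intervals_bed(track.intervals, paths["elements_bed"])
    um_io.write_genome_tsv(truth.genome, paths["genome_tsv"])
    if mutability is not None:
        mutability.to_tsv(paths["mutability_tsv"])
    return paths
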