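"""Readers and writers for GTF/GFF3, BED, VCF and the TSV side formats.

Annotation parsing is delegated to :mod:`gffutils` (in-memory sqlite DB),
which autodetects the GTF vs GFF3 attribute dialect.  All writers sort
their output (chrom, start, end, id) so files are deterministic.
"""

from __future__ import annotations

import csv
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import gffutils
import pandas as pd

from .intervals import GenomicInterval
from .models import AnnotationError, AnnotationSet, TranscriptModel, VariantRecord


class ParseError(ValueError):
    """An input file could not be parsed."""


# ---------------------------------------------------------------------------
# GTF / GFF3
# ---------------------------------------------------------------------------

_TRANSCRIPT_TYPES = ("transcript", "mRNA")
_BIOTYPE_KEYS = ("transcript_biotype", "transcript_type", "biotype")


def _first(attrs, *keys) -> Optional[str]:
    for k in keys:
        if k in attrs:
            return attrs[k][0]
    return None


def read_annotation(path, version_tag: Optional[str] = None) -> AnnotationSet:
    """Read a GTF or GFF3 file into a validated :class:`AnnotationSet`.

    GTF records must carry ``transcript_id``/``gene_id`` attributes on exon
    and CDS lines; GFF3 records are resolved through ``Parent`` links.
    Coordinates are kept 1-based inclusive, exactly as in the file.
    """
    path = Path(path)
    try:
        db = gffutils.create_db(
            str(path),
            ":memory:",
            disable_infer_genes=True,
            disable_infer_transcripts=True,
            merge_strategy="create_unique",
        )
    except Exception as exc:  # gffutils raises a zoo of types
        raise ParseError(f"{path}: cannot parse annotation: {exc}") from exc

    is_gff3 = db.dialect.get("fmt") == "gff3"

    def resolve_ids(feature):
        tid = _first(feature.attributes, "transcript_id")
        gid = _first(feature.attributes, "gene_id")
        biotype = _first(feature.attributes, *_BIOTYPE_KEYS)
        if tid is None and is_gff3:
            parent_ids = feature.attributes.get("Parent", [])
            for pid in parent_ids:
                try:
                    parent = db[pid]
                except gffutils.FeatureNotFoundError:
                    continue
                if parent.featuretype in _TRANSCRIPT_TYPES:
                    tid = parent.id
                    gid = gid or _first(parent.attributes, "Parent", "gene_id")
                    biotype = biotype or _first(parent.attributes, *_BIOTYPE_KEYS)
        if tid is None:
            raise ParseError(
                f"{path}: {feature.featuretype} record at "
                f"{feature.seqid}:{feature.start} has no transcript attribution"
            )
        return tid, gid or tid, biotype

    exons: dict[str, list[GenomicInterval]] = {}
    cds: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, dict] = {}
    for feature in db.all_features(order_by=("seqid", "start")):
        if feature.featuretype not in ("exon", "CDS"):
            continue
        tid, gid, biotype = resolve_ids(feature)
        info = meta.setdefault(tid, {"gene_id": gid, "strand": feature.strand, "biotype": None})
        if biotype:
            info["biotype"] = biotype
        iv = GenomicInterval(feature.seqid, feature.start, feature.end, feature.strand)
        (exons if feature.featuretype == "exon" else cds).setdefault(tid, []).append(iv)

    transcripts = []
    for tid, exon_list in exons.items():
        info = meta[tid]
        cds_span = None
        if tid in cds:
            parts = cds[tid]
            cds_span = GenomicInterval(
                parts[0].chrom,
                min(p.start for p in parts),
                max(p.end for p in parts),
                info["strand"],
            )
        transcripts.append(
            TranscriptModel(
                transcript_id=tid,
                gene_id=info["gene_id"],
                strand=info["strand"],
                exons=tuple(exon_list),
                cds=cds_span,
                biotype=info["biotype"] or ("coding" if tid in cds else "processed_transcript"),
            )
        )
    tag = version_tag or path.stem
    try:
        return AnnotationSet.from_transcripts(tag, transcripts)
    except AnnotationError as exc:
        raise AnnotationError(f"{path}: {exc}") from exc


_GTF_BIOTYPE = {
    "coding": "protein_coding",
    "NMD": "nonsense_mediated_decay",
    "retained_intron": "retained_intron",
    "processed_transcript": "processed_transcript",
}


def write_gtf(annotation: AnnotationSet, path) -> None:
    """Write an AnnotationSet as a sorted GTF file."""
    lines = []
    for tx in annotation:
        attrs = (
            f'gene_id "{tx.gene_id}"; transcript_id "{tx.transcript_id}"; '
            f'transcript_biotype "{_GTF_BIOTYPE[tx.biotype]}";'
        )
        for exon in tx.exons:
            lines.append(
                (exon.chrom, exon.start, exon.end, tx.transcript_id, "exon",
                 f"{exon.chrom}\texon_unmask\texon\t{exon.start}\t{exon.end}\t.\t{tx.strand}\t.\t{attrs}")
            )
        if tx.cds is not None:
            for exon in tx.exons:
                lo = max(exon.start, tx.cds.start)
                hi = min(exon.end, tx.cds.end)
                if lo <= hi:
                    lines.append(
                        (exon.chrom, lo, hi, tx.transcript_id, "CDS",
                         f"{exon.chrom}\texon_unmask\tCDS\t{lo}\t{hi}\t.\t{tx.strand}\t.\t{attrs}")
                    )
    lines.sort()
    Path(path).write_text("".join(line + "\n" for *_, line in lines))


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def write_intervals_bed(
    items: Iterable[GenomicInterval], path, names: Optional[Sequence[str]] = None
) -> None:
    """Write intervals as BED (0-based half-open), sorted deterministically.

    Emits BED6 when ``names`` are given or any interval is stranded,
    else BED3.  Round-tripping through :func:`read_intervals_bed` restores
    the 1-based inclusive coordinates exactly.
    """
    items = list(items)
    if names is not None and len(names) != len(items):
        raise ValueError("names must match items one-to-one")
    rows = []
    for i, iv in enumerate(items):
        name = names[i] if names is not None else f"iv{i}"
        rows.append((iv.chrom, iv.start - 1, iv.end, name, iv.strand))
    rows.sort()
    bed6 = names is not None or any(strand != "." for *_, strand in rows)
    with open(path, "w") as fh:
        for chrom, start0, end, name, strand in rows:
            if bed6:
                fh.write(f"{chrom}\t{start0}\t{end}\t{name}\t0\t{strand}\n")
            else:
                fh.write(f"{chrom}\t{start0}\t{end}\n")


def read_intervals_bed(path) -> list[GenomicInterval]:
    """Read BED3/BED6 into 1-based inclusive intervals."""
    out = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{ln}: BED line has <3 fields")
            chrom, start0, end = fields[0], int(fields[1]), int(fields[2])
            strand = fields[5] if len(fields) >= 6 else "."
            out.append(GenomicInterval(chrom, start0 + 1, end, strand))
    return out


# ---------------------------------------------------------------------------
# VCF and the TSV variant dialect
# ---------------------------------------------------------------------------

_VCF_HEADER = """##fileformat=VCFv4.2
{contigs}##INFO=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##INFO=<ID=GQ,Number=1,Type=Float,Description="GATK quality score">
##INFO=<ID=SQ,Number=1,Type=Float,Description="Samtools quality score">
##INFO=<ID=CALLERS,Number=.,Type=String,Description="Callers reporting the variant">
##INFO=<ID=CLNSIG,Number=1,Type=String,Description="Clinical significance">
##INFO=<ID=DENOVO,Number=0,Type=Flag,Description="De novo variant">
##INFO=<ID=HRUN,Number=1,Type=Integer,Description="Homopolymer run length at site">
##INFO=<ID=REPEAT,Number=0,Type=Flag,Description="Simple repeat membership">
##INFO=<ID=INDB,Number=0,Type=Flag,Description="Present in population databases">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
"""


def write_variants_vcf(variants: Iterable[VariantRecord], path) -> None:
    """Write variants as an uncompressed, sorted VCF 4.2 file."""
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt))
    contigs = "".join(
        f"##contig=<ID={c}>\n" for c in sorted({v.chrom for v in variants})
    )
    rows = []
    for v in variants:
        info = []
        if v.coverage is not None:
            info.append(f"DP={v.coverage}")
        if "gatk" in v.caller_scores:
            info.append(f"GQ={v.caller_scores['gatk']:g}")
        if "samtools" in v.caller_scores:
            info.append(f"SQ={v.caller_scores['samtools']:g}")
        if v.caller_set:
            info.append("CALLERS=" + ",".join(sorted(v.caller_set)))
        if v.clinical_significance:
            info.append(f"CLNSIG={v.clinical_significance}")
        if v.de_novo:
            info.append("DENOVO")
        if v.homopolymer_run:
            info.append(f"HRUN={v.homopolymer_run}")
        if v.in_simple_repeat:
            info.append("REPEAT")
        if v.in_database:
            info.append("INDB")
        rows.append(
            f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\t.\t"
            + (";".join(info) or ".")
        )
    Path(path).write_text(
        _VCF_HEADER.format(contigs=contigs) + "".join(r + "\n" for r in rows)
    )


def read_variants_vcf(path) -> list[VariantRecord]:
    """Read a VCF 4.x file via pysam into :class:`VariantRecord` objects."""
    import pysam

    out = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            scores = {}
            if "GQ" in info:
                scores["gatk"] = float(info["GQ"])
            if "SQ" in info:
                scores["samtools"] = float(info["SQ"])
            callers = info.get("CALLERS", ())
            if isinstance(callers, str):
                callers = (callers,)
            clnsig = info.get("CLNSIG")
            for alt in rec.alts or ():
                out.append(
                    VariantRecord(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        variant_id=rec.id or ".",
                        de_novo=bool(info.get("DENOVO", False)),
                        clinical_significance=clnsig,
                        coverage=int(info["DP"]) if "DP" in info else None,
                        caller_scores=scores,
                        caller_set=frozenset(callers),
                        homopolymer_run=int(info.get("HRUN", 0)),
                        in_simple_repeat=bool(info.get("REPEAT", False)),
                        in_database=bool(info.get("INDB", False)),
                    )
                )
    return out


_TSV_COLUMNS = [
    "chrom", "pos", "ref", "alt", "variant_id", "de_novo", "clinical_significance",
    "coverage", "gatk_score", "samtools_score", "callers", "homopolymer_run",
    "in_simple_repeat", "in_database",
]


def write_variants_tsv(variants: Iterable[VariantRecord], path) -> None:
    rows = []
    for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.ref, v.alt)):
        rows.append({
            "chrom": v.chrom, "pos": v.pos, "ref": v.ref, "alt": v.alt,
            "variant_id": v.variant_id, "de_novo": int(v.de_novo),
            "clinical_significance": v.clinical_significance or "",
            "coverage": "" if v.coverage is None else v.coverage,
            "gatk_score": v.caller_scores.get("gatk", ""),
            "samtools_score": v.caller_scores.get("samtools", ""),
            "callers": ",".join(sorted(v.caller_set)),
            "homopolymer_run": v.homopolymer_run,
            "in_simple_repeat": int(v.in_simple_repeat),
            "in_database": int(v.in_database),
        })
    with open(path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=_TSV_COLUMNS, delimiter="\t")
        writer.writeheader()
        writer.writerows(rows)


def read_variants_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = []
    for row in df.to_dict("records"):
        scores = {}
        if row.get("gatk_score"):
            scores["gatk"] = float(row["gatk_score"])
        if row.get("samtools_score"):
            scores["samtools"] = float(row["samtools_score"])
        out.append(
            VariantRecord(
                chrom=row["chrom"], pos=int(row["pos"]), ref=row["ref"], alt=row["alt"],
                variant_id=row.get("variant_id") or ".",
                de_novo=bool(int(row.get("de_novo") or 0)),
                clinical_significance=row.get("clinical_significance") or None,
                coverage=int(row["coverage"]) if row.get("coverage") else None,
                caller_scores=scores,
                caller_set=frozenset(c for c in (row.get("callers") or "").split(",") if c),
                homopolymer_run=int(row.get("homopolymer_run") or 0),
                in_simple_repeat=bool(int(row.get("in_simple_repeat") or 0)),
                in_database=bool(int(row.get("in_database") or 0)),
            )
        )
    return out


# ---------------------------------------------------------------------------
# Small TSV side files
# ---------------------------------------------------------------------------


def read_genome_tsv(path) -> dict[str, int]:
    """chromosome-length table: two columns, chromosome and length."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "length"],
                     comment="#", dtype={"chrom": str, "length": int})
    return dict(zip(df["chrom"], df["length"]))


def write_genome_tsv(genome: Mapping[str, int], path) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f"{chrom}\t{genome[chrom]}\n")
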