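"""End-to-end pipeline: simulate/load inputs, run every stage, write a report.

Stages run in a fixed order — annotation delta, poison-exon biotypes,
variant re-intersection and filters, de novo enrichment, conservation and
expression evidence — with each stage's artifacts written before the next
starts, so a failure in stage *k* leaves stages < *k* on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from . import __version__
from . import io as um_io
from .delta import detect_deltas
from .enrichment import MutabilityTable, run_enrichment
from .evidence import (
    ConservedElementTrack,
    JunctionCountMatrix,
    enrichment_t_test,
    permutation_null,
    stage_enrichment,
    support_class,
)
from .nmd import classify_inclusion
from .simulate import SimulationConfig, simulate_all
from .variants import (
    FilterThresholds,
    cohort_filter,
    diagnostic_yield,
    made_exonic,
    mask_unsequenced,
)

log = logging.getLogger("exon_unmask")


class ConfigError(ValueError):
    """The pipeline configuration is invalid or names missing inputs."""


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int = 0
    simulate: Optional[dict] = None      # SimulationConfig fields, or None
    inputs: dict = field(default_factory=dict)   # explicit input paths
    flank: int = 8
    n_probands: int = 122
    observed_de_novo: int = 2
    n_tests: int = 18_000
    ploidy_factor: float = 2.0
    default_site_rate: Optional[float] = None
    replicates: int = 1000
    fold: float = 5.0
    min_reads: int = 10

    @classmethod
    def from_json(cls, path) -> "PipelineConfig":
        try:
            raw = json.loads(Path(path).read_text())
        except (OSError, json.JSONDecodeError) as exc:
            raise ConfigError(f"cannot read config {path}: {exc}") from exc
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "out_dir" not in raw:
            raise ConfigError("config must name out_dir")
        return cls(**raw)


def _checksum(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()[:16]


def run_all(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the report dictionary.

    The report (also written to ``out_dir/report.json``) carries the
    delta summary, biotype counts, re-annotation call counts, the
    enrichment result, the conservation-null summary, junction metrics,
    the diagnostic yield, input checksums, the seed and the tool version.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        sim_cfg = SimulationConfig(seed=config.simulate.get("seed", config.seed),
                                   **{k: v for k, v in config.simulate.items()
                                      if k != "seed"})
        log.info("stage simulate: writing inputs to %s", out / "inputs")
        paths = simulate_all(sim_cfg, out / "inputs")
    else:
        paths = dict(config.inputs)
        required = ["old_gtf", "new_gtf", "variants_vcf", "junctions_tsv",
                    "stages_tsv", "elements_bed", "genome_tsv"]
        missing = [k for k in required if k not in paths]
        if missing:
            raise ConfigError(f"config lacks input paths: {missing}")
        absent = [p for p in paths.values() if not Path(p).exists()]
        if absent:
            raise ConfigError(f"input paths do not exist: {absent}")

    report: dict = {
        "tool_version": __version__,
        "seed": config.seed,
        "input_checksums": {k: _checksum(p) for k, p in sorted(paths.items())
                            if Path(p).exists()},
    }

    # --- delta -------------------------------------------------------------
    try:
        log.info("stage delta: comparing annotation versions")
        old = um_io.read_annotation(paths["old_gtf"], "old")
        new = um_io.read_annotation(paths["new_gtf"], "new")
        deltas = detect_deltas(old, new)
        um_io.write_intervals_bed(
            [d.interval for d in deltas.novel_exons], out / "novel_exons.bed",
            names=[f"{d.gene_id}|{','.join(d.transcript_ids)}" for d in deltas.novel_exons],
        )
        um_io.write_intervals_bed(
            [d.interval for d in deltas.novel_introns], out / "novel_introns.bed",
            names=[d.gene_id for d in deltas.novel_introns],
        )
        with open(out / "shifted_junctions.tsv", "w") as fh:
            fh.write("gene_id\tchrom\tstart\tend\tside\tdirection\tshift_nt\n")
            for d in deltas.shifted_junctions:
                fh.write(f"{d.gene_id}\t{d.interval.chrom}\t{d.interval.start}\t"
                         f"{d.interval.end}\t{d.side}\t{d.direction}\t{d.shift_nt}\n")
        report["delta"] = {
            "counts": deltas.summary.counts,
            "footprint_gain_bases": deltas.summary.footprint_gain_bases,
            "cds_gain_bases": deltas.summary.cds_gain_bases,
        }
        (out / "summary.json").write_text(json.dumps(report["delta"], indent=1))
    except Exception as exc:
        raise StageError("delta", exc) from exc

    # --- biotypes ------------------------------------------------------------
    try:
        log.info("stage nmd: classifying cassette inclusions")
        biotype_counts: dict[str, int] = {}
        rows = []
        for d in deltas.novel_exons:
            host = None
            for tx in old.gene_transcripts(d.gene_id):
                if tx.cds is not None and any(
                    iv.start <= d.interval.start and d.interval.end <= iv.end
                    for iv in tx.introns
                ):
                    host = tx
                    break
            if host is None:
                call_biotype = "processed_transcript"
            else:
                call_biotype = classify_inclusion(host, d.interval).biotype
            biotype_counts[call_biotype] = biotype_counts.get(call_biotype, 0) + 1
            rows.append((d.gene_id, d.interval, call_biotype))
        with open(out / "biotypes.tsv", "w") as fh:
            fh.write("gene_id\tchrom\tstart\tend\tbiotype\n")
            for gene_id, iv, bt in rows:
                fh.write(f"{gene_id}\t{iv.chrom}\t{iv.start}\t{iv.end}\t{bt}\n")
        report["biotype_counts"] = biotype_counts
    except Exception as exc:
        raise StageError("nmd", exc) from exc

    # --- variants ------------------------------------------------------------
    try:
        log.info("stage variants: re-intersecting against the delta")
        variant_list = um_io.read_variants_vcf(paths["variants_vcf"])
        thresholds = FilterThresholds()
        masked = mask_unsequenced(variant_list, thresholds)
        survivors = cohort_filter(masked.kept, thresholds)
        calls = made_exonic(survivors, old, new, flank=config.flank)
        status_counts: dict[str, int] = {}
        for c in calls:
            status_counts[c.status] = status_counts.get(c.status, 0) + 1
        with open(out / "calls.tsv", "w") as fh:
            fh.write("variant_id\tchrom\tpos\tstatus\told\tnew\tdistance_to_old_splice\n")
            for c in calls:
                fh.write(f"{c.variant_id}\t{c.chrom}\t{c.pos}\t{c.status}\t"
                         f"{c.old_consequence}\t{c.new_consequence}\t"
                         f"{c.distance_to_old_splice_site}\n")
        n_newly = status_counts.get("newly_exonic", 0)
        report["variants"] = {
            "input": len(variant_list),
            "masked_unsequenced": masked.n_masked,
            "cohort_filtered_out": len(masked.kept) - len(survivors),
            "status_counts": status_counts,
        }
        report["diagnostic_yield_percent"] = diagnostic_yield(
            min(n_newly, config.n_probands), config.n_probands
        )
    except Exception as exc:
        raise StageError("variants", exc) from exc

    # --- enrichment ----------------------------------------------------------
    try:
        log.info("stage enrich: Poisson de novo enrichment")
        features = [d.interval for d in deltas.novel_exons]
        mut = None
        if "mutability_tsv" in paths and Path(paths["mutability_tsv"]).exists():
            mut = MutabilityTable.from_tsv(paths["mutability_tsv"])
        result = run_enrichment(
            mut,
            features,
            n_probands=config.n_probands,
            observed=config.observed_de_novo,
            n_tests=config.n_tests,
            ploidy_factor=config.ploidy_factor,
            default_site_rate=config.default_site_rate,
        )
        report["enrichment"] = dataclasses.asdict(result)
        (out / "enrichment.json").write_text(json.dumps(report["enrichment"], indent=1))
    except Exception as exc:
        raise StageError("enrich", exc) from exc

    # --- evidence ------------------------------------------------------------
    try:
        log.info("stage evidence: conservation null and junction expression")
        genome = um_io.read_genome_tsv(paths["genome_tsv"])
        track = ConservedElementTrack(
            um_io.read_intervals_bed(paths["elements_bed"]), genome
        )
        query = [d.interval for d in deltas.novel_exons]
        null = permutation_null(query, track, n_replicates=config.replicates,
                                seed=config.seed)
        null = enrichment_t_test(null)
        matrix = JunctionCountMatrix.from_tsv(paths["junctions_tsv"], paths["stages_tsv"])
        flags = stage_enrichment(matrix, fold=config.fold)
        support = support_class(matrix, min_reads=config.min_reads)
        report["conservation"] = {
            "observed_overlap_fraction": null.observed,
            "null_mean": float(null.replicates.mean()),
            "null_sd": float(null.replicates.std(ddof=1)),
            "replicates": config.replicates,
            "t_statistic": null.t_statistic,
            "p_value": null.p_value,
        }
        report["junctions"] = {
            "n_introns": len(matrix.introns),
            "stage_enriched": int(flags.sum()),
            "fraction_supported": support.fraction_supported,
        }
    except Exception as exc:
        raise StageError("evidence", exc) from exc

    report_path = out / "report.json"
    report_path.write_text(json.dumps(report, indent=1, sort_keys=True))
    log.info("report written to %s", report_path)
    return report


def setup_logging(verbose: bool = False, quiet: bool = False) -> None:
    level = logging.DEBUG if verbose else logging.ERROR if quiet else logging.INFO
    logging.basicConfig(
        stream=sys.stderr,
        level=level,
        format="[%(name)s %(levelname)s] %(message)s",
        force=True,
    )
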