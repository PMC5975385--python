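"""Pipeline orchestration: QC → consensus → cohort → annotation → stats.

The configuration is one declarative YAML document; every stage writes TSV
reports plus a run log recording parameters and per-stage record counts, so
a rerun on the same config reproduces identical reports.

Config keys::

    inputs:
      manifest: manifest.tsv          # required
      build: build.tsv                # required
      read_depth_dir: read_depth/     # required; <sample_id>.txt per sample
      split_read_dir: split_read/     # required; <sample_id>.tsv per sample
      gff3: genes.gff3                # optional
      qtl_bed: qtl.bed                # optional
      reference_cnvs: refdb.tsv       # optional
      term_map: terms.tsv             # optional
    params:
      tolerance_bp: 100
      min_coverage: 7
      min_shared: 2
      flank_bp: 5000
      known_mode: overlap
      breeds_considered: []           # default: five most numerous kept breeds
      seed: 0
    outdir: out/
"""
from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd
import yaml

from . import __version__, annotation, cohort, consensus, io_formats, qc, stats
from .models import ConsensusSet, GenomeBuild, SampleRecord

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "tolerance_bp": 100,
    "min_coverage": 7.0,
    "min_shared": 2,
    "flank_bp": 5000,
    "known_mode": "overlap",
    "breeds_considered": None,
    "seed": 0,
}


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cfg.setdefault("params", {})
    for key, value in DEFAULT_PARAMS.items():
        cfg["params"].setdefault(key, value)
    inputs = cfg.get("inputs", {})
    for required in ("manifest", "build", "read_depth_dir", "split_read_dir"):
        if required not in inputs:
            raise ValueError(f"config missing required input {required!r}")
    if "outdir" not in cfg:
        raise ValueError("config missing 'outdir'")
    base = Path(path).parent
    for key, value in list(inputs.items()):
        if value is not None:
            inputs[key] = str((base / value) if not Path(value).is_absolute() else Path(value))
    cfg["outdir"] = str(
        (base / cfg["outdir"]) if not Path(cfg["outdir"]).is_absolute() else Path(cfg["outdir"])
    )
    return cfg


def run_pipeline(config, outdir: Optional[str] = None) -> Path:
    """Run the full post-detection analysis; returns the report directory."""
    if not isinstance(config, dict):
        config = load_config(config)
    params = config["params"]
    inputs = config["inputs"]
    out = Path(outdir or config["outdir"])
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("cnvcohort")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    summary: Dict[str, object] = {"version": __version__, "params": dict(params)}
    try:
        logger.info("cnvcohort v%s params=%s", __version__, params)

        build = io_formats.read_genome_build(inputs["build"])
        manifest = io_formats.read_manifest(inputs["manifest"])
        logger.info("inputs: %d samples, genome %d bp", len(manifest), build.total_length)

        # --- QC ---------------------------------------------------------
        kept, excluded = qc.filter_samples(manifest, build, params["min_coverage"])
        cohort.write_table(qc.qc_report(manifest, build, params["min_coverage"]), out / "qc_report.tsv")
        logger.info("qc: kept %d, excluded %d", len(kept), len(excluded))
        summary["n_samples"] = len(manifest)
        summary["n_kept"] = len(kept)

        # --- consensus --------------------------------------------------
        tol = params["tolerance_bp"]
        refdb = (
            io_formats.read_reference_cnvs(inputs["reference_cnvs"])
            if inputs.get("reference_cnvs")
            else None
        )
        csets: List[ConsensusSet] = []
        for s in kept:
            rd = io_formats.read_read_depth_calls(
                Path(inputs["read_depth_dir"]) / f"{s.sample_id}.txt", s.sample_id
            )
            sr = io_formats.read_split_read_calls(
                Path(inputs["split_read_dir"]) / f"{s.sample_id}.tsv", s.sample_id
            )
            io_formats.validate_calls(rd, build)
            io_formats.validate_calls(sr, build)
            rd = consensus.filter_by_length(rd)
            sr = consensus.filter_by_length(sr)
            cs = consensus.build_consensus(rd, sr, tol=tol)
            if refdb is not None:
                cs = consensus.flag_known(cs, refdb, tol=tol, mode=params["known_mode"])
            csets.append(cs)
        consensus.write_consensus_tsv(csets, out / "consensus.tsv")
        n_calls = sum(len(c.calls) for c in csets)
        n_validated = sum(sum(c.validated) for c in csets)
        logger.info("consensus: %d baseline calls, %d validated", n_calls, n_validated)
        summary["n_baseline_calls"] = n_calls
        summary["n_validated_calls"] = n_validated
        summary["validated_fraction"] = n_validated / n_calls if n_calls else None

        # --- cohort -----------------------------------------------------
        clusters = cohort.cluster_calls(csets, tol=tol, manifest=kept)
        cohort.write_table(cohort.cluster_frame(clusters), out / "clusters.tsv")
        specific = cohort.breed_specific(
            clusters,
            kept,
            min_shared=params["min_shared"],
            breeds_considered=params["breeds_considered"],
            tol=tol,
        )
        cohort.write_table(cohort.breed_specific_frame(specific), out / "breed_specific.tsv")
        cov_rows = []
        for cs in csets:
            for cnv_type in ("DUP", "DEL"):
                cov_rows.append(
                    {
                        "sample_id": cs.sample_id,
                        "cnv_type": cnv_type,
                        "genome_covered_pct": cohort.genome_covered_pct(cs, build, cnv_type),
                    }
                )
        cohort.write_table(pd.DataFrame(cov_rows), out / "genome_covered.tsv")
        logger.info("cohort: %d clusters, %d breed-specific", len(clusters), len(specific))
        summary["n_clusters"] = len(clusters)
        summary["n_breed_specific"] = len(specific)
        for cnv_type in ("DUP", "DEL"):
            try:
                summary[f"singleton_pct_{cnv_type}"] = cohort.singleton_fraction(clusters, cnv_type)
            except ValueError:
                summary[f"singleton_pct_{cnv_type}"] = None

        # --- annotation -------------------------------------------------
        if inputs.get("gff3"):
            genes = io_formats.read_gene_models(inputs["gff3"], build)
            annos = [
                annotation.annotate_call(cl.representative, genes, flank=params["flank_bp"])
                for cl in clusters
            ]
            adf = pd.DataFrame(
                {
                    "chrom": [a.call.chrom for a in annos],
                    "start": [a.call.start for a in annos],
                    "end": [a.call.end for a in annos],
                    "cnv_type": [a.call.cnv_type for a in annos],
                    "category": [a.category for a in annos],
                    "gene_id": [a.gene_id for a in annos],
                    "genic": [a.genic for a in annos],
                }
            )
            cohort.write_table(adf, out / "annotations.tsv")
            _, genic_pct = annotation.category_counts(annos)
            summary["genic_pct"] = genic_pct
            logger.info("annotation: %d clusters annotated", len(annos))

            if inputs.get("term_map"):
                terms = io_formats.read_term_map(inputs["term_map"])
                universe = {g.gene_id for g in genes}
                hit_genes = {
                    a.gene_id for a, s in zip(annos, clusters) if a.gene_id in universe
                }
                selected_specific = set()
                specific_reps = {id(s.cluster) for s in specific}
                for a, cl in zip(annos, clusters):
                    if id(cl) in specific_reps and a.gene_id in universe:
                        selected_specific.add(a.gene_id)
                selected = selected_specific or hit_genes
                if selected:
                    edf = annotation.term_enrichment(selected, universe, terms)
                    cohort.write_table(edf, out / "enrichment.tsv")
                    logger.info("enrichment: %d terms tested", len(edf))

        if inputs.get("qtl_bed"):
            qtl = io_formats.read_qtl_bed(inputs["qtl_bed"])
            qdf = annotation.qtl_overlap([s.cluster for s in specific], qtl)
            cohort.write_table(qdf, out / "qtl_overlap.tsv")
            logger.info("qtl: %d overlaps", len(qdf))

        # --- stats ------------------------------------------------------
        report = stats.run_variation_suite(
            csets,
            kept,
            build,
            breeds=params["breeds_considered"],
            seed=params["seed"],
        )
        cohort.write_table(report, out / "stats_report.tsv")
        logger.info("stats: %d test rows", len(report))
        summary["n_stat_tests"] = len(report)

        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2, sort_keys=True)
    finally:
        root.removeHandler(handler)
        handler.close()
    return out
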