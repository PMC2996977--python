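"""End-to-end orchestration: score -> calibrate -> call -> enrich -> express.

``run_pipeline`` reads the standard input tables from a directory, executes
every stage, writes all result tables plus a machine-readable manifest and a
human-readable summary, and aborts with the stage name on the first error.
"""
from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__, io
from .calling import (assign_sites_to_genes, call_hypo_sites, classify_tissue_hypo,
                      summarize_genes)
from .cobra import ThresholdSet, calibrate_thresholds
from .config import PipelineConfig
from .enrichment import tf_target_enrichment
from .errors import PipelineError, TdmrError
from .expression import position_class_report
from .mat import fit_affinity_model, score_all_sites, standardize

__all__ = ["run_pipeline"]

log = logging.getLogger(__name__)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except TdmrError as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            log.info("stage %s done in %.1fs", name, time.perf_counter() - t0)
            return out
        return wrapped
    return deco


@_stage("score")
def _score(config, indir):
    probes = io.read_probes(indir / "probes.tsv")
    intensities = io.read_matrix(indir / "intensities.tsv")
    sites = io.read_sites_bed(indir / "sites.bed")
    model = fit_affinity_model(probes, intensities)
    tvalues = standardize(intensities, model)
    scores = score_all_sites(
        tvalues, probes, sites,
        window_bp=config.window_bp, trim=config.trim,
        min_probes=config.min_probes, max_copy_number=config.max_copy_number)
    return sites, scores


@_stage("calibrate")
def _calibrate(config, indir, scores):
    thr_path = indir / "thresholds.tsv"
    if thr_path.exists():
        return ThresholdSet.from_frame(io.read_thresholds(thr_path),
                                       prefilter=config.prefilter)
    cobra_path = indir / "cobra.tsv"
    if not cobra_path.exists():
        raise PipelineError("stage 'calibrate' failed: neither thresholds.tsv nor "
                            "cobra.tsv present in the input directory")
    measurements = io.read_cobra(cobra_path)
    return calibrate_thresholds(scores, measurements, delta=config.cobra_delta,
                                prefilter_score=config.prefilter)


@_stage("call")
def _call(config, scores, thresholds, sites, annotation):
    assignments = assign_sites_to_genes(sites, annotation,
                                        upstream_bp=config.upstream_bp,
                                        downstream_bp=config.downstream_bp)
    calls = call_hypo_sites(scores, thresholds)
    tissue_hypo = classify_tissue_hypo(calls)
    summary, stats = summarize_genes(assignments, calls, tissue_hypo, annotation)
    return assignments, calls, tissue_hypo, summary, stats


@_stage("enrich")
def _enrich(indir, summary, annotation):
    targets_path = indir / "tf_targets.txt"
    if not targets_path.exists():
        return None
    targets = set(io.read_targets(targets_path))
    mt = summary[summary["is_nuclear_mt"]]
    background = set(mt["gene_id"])
    rows = []
    for col in [c for c in summary.columns if c.startswith("hypo_")
                and not c.endswith(("_upstream", "_downstream"))]:
        tissue = col.removeprefix("hypo_")
        focal = set(mt.loc[mt[col], "gene_id"])
        if not focal:
            continue
        r = tf_target_enrichment(targets, focal, background)
        rows.append((tissue, r.set_hits, r.set_size, r.background_hits,
                     r.background_size, r.fold, r.p_value))
    return pd.DataFrame(rows, columns=["tissue", "set_hits", "set_size",
                                       "background_hits", "background_size",
                                       "fold", "p_value"])


@_stage("express")
def _express(indir, summary):
    expr_path = indir / "expression.tsv"
    if not expr_path.exists():
        return None
    expr = io.read_matrix(expr_path)
    return position_class_report(summary, expr)


def _calls_bed_frame(calls, assignments, annotation, chrom_lut):
    asg = assignments.dropna(subset=["gene_id"])
    merged = calls.merge(asg[["site_id", "gene_id", "offset", "region"]],
                         on="site_id", how="left")
    strand_lut = dict(zip(annotation["gene_id"], annotation["strand"]))
    name = merged.apply(
        lambda r: f"{r['gene_id']}:{r['hypo_tissue']}" if pd.notna(r["gene_id"])
        else f"{r['site_id']}:{r['hypo_tissue']}", axis=1)
    return pd.DataFrame({
        "chrom": merged["site_id"].map(chrom_lut),
        "start": merged["pos"],
        "end": merged["pos"] + 1,
        "name": name,
        "score": merged["score"].round(4),
        "strand": merged["gene_id"].map(strand_lut).fillna("."),
        "offset": merged["offset"],
        "region": merged["region"],
        "versus": merged["versus"],
    })


def _recovery_metrics(tissue_hypo, assignments, planted):
    """Sensitivity / false-discovery proportion for planted (gene, tissue)."""
    asg = assignments.dropna(subset=["gene_id"])
    merged = tissue_hypo.merge(asg[["site_id", "gene_id"]], on="site_id")
    recovered = set(zip(merged["gene_id"], merged["tissue"]))
    truth = set(zip(planted["gene_id"], planted["tissue"]))
    tp = len(recovered & truth)
    sens = tp / len(truth) if truth else float("nan")
    fdp = (len(recovered) - tp) / len(recovered) if recovered else 0.0
    return {"n_planted": len(truth), "n_recovered": len(recovered),
            "sensitivity": sens, "false_discovery_proportion": fdp}


def run_pipeline(config: PipelineConfig, indir: str | Path,
                 outdir: str | Path) -> Path:
    """Run all stages on the tables in ``indir``; write results to ``outdir``."""
    config.validate()
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    annotation = io.read_annotation(indir / "annotation.tsv")
    sites, scores = _score(config, indir)
    io.write_scores(scores, outdir / "scores.tsv")

    thresholds = _calibrate(config, indir, scores)
    io.write_thresholds(thresholds.to_frame(), outdir / "thresholds.tsv")

    assignments, calls, tissue_hypo, summary, stats = _call(
        config, scores, thresholds, sites, annotation)
    io.write_assignments(assignments, outdir / "assignments.tsv")
    calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
    tissue_hypo.to_csv(outdir / "tissue_hypo.tsv", sep="\t", index=False)
    io.write_summary(summary, outdir / "gene_summary.tsv")
    chrom_lut = dict(zip(sites["site_id"], sites["chrom"]))
    io.write_calls_bed(_calls_bed_frame(calls, assignments, annotation, chrom_lut),
                       outdir / "calls.bed")

    tf_report = _enrich(indir, summary, annotation)
    if tf_report is not None:
        tf_report.to_csv(outdir / "tf_enrichment.tsv", sep="\t", index=False)

    expr_report = _express(indir, summary)
    if expr_report is not None:
        expr_report.to_csv(outdir / "expression_report.tsv", sep="\t", index=False)

    planted_path = indir / "planted.tsv"
    recovery = None
    if planted_path.exists():
        planted = pd.read_csv(planted_path, sep="\t")
        recovery = _recovery_metrics(tissue_hypo, assignments, planted)

    manifest = {
        "tdmr_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.content_hash(),
        "seed": config.seed,
        "inputs": sorted(p.name for p in indir.iterdir() if p.is_file()),
        "stats": stats,
    }
    if recovery is not None:
        manifest["recovery"] = recovery
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    lines = [
        f"genes: {stats['n_genes']}",
        f"nuclear-mt genes: {stats['n_nuclear_mt']}",
        f"nuclear-mt genes with T-DMRs: {stats['n_nuclear_mt_with_tdmr']} "
        f"({stats['pct_nuclear_mt_with_tdmr']}%)",
    ]
    for key, val in stats.items():
        if key.startswith("n_nuclear_mt_") and key.endswith("_hypo"):
            lines.append(f"{key.removeprefix('n_nuclear_mt_').removesuffix('_hypo')}"
                         f"-hypo nuclear-mt genes: {val}")
    if recovery is not None:
        lines.append(f"planted recovery: sensitivity {recovery['sensitivity']:.3f}, "
                     f"FDP {recovery['false_discovery_proportion']:.3f}")
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    return outdir
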