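"""Shared fixtures: small and default-scale synthetic runs."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from tdmr.calling import (assign_sites_to_genes, call_hypo_sites,
                          classify_tissue_hypo, summarize_genes)
from tdmr.cobra import calibrate_thresholds
from tdmr.mat import fit_affinity_model, score_all_sites, standardize
from tdmr.synthetic import (SimConfig, generate_genome, plant_methylation,
                            simulate_cobra, simulate_expression,
                            simulate_intensities)


def run_full_pipeline(cfg: SimConfig) -> dict:
    """Simulate and analyse one dataset; return every intermediate table."""
    annotation, sites, probes = generate_genome(cfg)
    truth = plant_methylation(annotation, sites, cfg)
    intensities = simulate_intensities(truth, probes, sites, cfg)
    model = fit_affinity_model(probes, intensities)
    tvalues = standardize(intensities, model)
    scores = score_all_sites(tvalues, probes, sites)
    measurements = simulate_cobra(truth, sites, noise=cfg.cobra_noise, seed=cfg.seed)
    thresholds = calibrate_thresholds(scores, measurements)
    calls = call_hypo_sites(scores, thresholds)
    tissue_hypo = classify_tissue_hypo(calls)
    assignments = assign_sites_to_genes(sites, annotation)
    summary, stats = summarize_genes(assignments, calls, tissue_hypo, annotation)
    expression = simulate_expression(truth, annotation, cfg)
    return {
        "cfg": cfg, "annotation": annotation, "sites": sites, "probes": probes,
        "truth": truth, "intensities": intensities, "model": model,
        "tvalues": tvalues, "scores": scores, "measurements": measurements,
        "thresholds": thresholds, "calls": calls, "tissue_hypo": tissue_hypo,
        "assignments": assignments, "summary": summary, "stats": stats,
        "expression": expression,
    }


def recovered_pairs(run: dict) -> set[tuple[str, str]]:
    asg = run["assignments"].dropna(subset=["gene_id"])
    merged = run["tissue_hypo"].merge(asg[["site_id", "gene_id"]], on="site_id")
    return set(zip(merged["gene_id"], merged["tissue"]))


@pytest.fixture(scope="session")
def small_cfg() -> SimConfig:
    return SimConfig(n_genes=60, chrom_length=1_500_000, seed=11)


@pytest.fixture(scope="session")
def small_sim(small_cfg):
    annotation, sites, probes = generate_genome(small_cfg)
    truth = plant_methylation(annotation, sites, small_cfg)
    return {"cfg": small_cfg, "annotation": annotation, "sites": sites,
            "probes": probes, "truth": truth}


@pytest.fixture(scope="session")
def small_run(small_cfg):
    return run_full_pipeline(small_cfg)


@pytest.fixture(scope="session")
def default_run():
    """Default-scale run: 3 tissues x 2 replicates, ~500 genes,
    planted contrast 0.8 (0.1 vs 0.9), replicate noise 0.3."""
    cfg = SimConfig(n_genes=500, chrom_length=12_000_000, noise_sd=0.3,
                    hypo_level=0.1, hyper_level=0.9, seed=42)
    return run_full_pipeline(cfg)


def make_annotation(rows) -> pd.DataFrame:
    """Annotation from (gene_id, chrom, strand, tss, start, end, is_mt, cats)."""
    recs = []
    for gene_id, chrom, strand, tss, start, end, is_mt, cats in rows:
        tpe = end if strand == "+" else start
        recs.append((gene_id, chrom, strand, tss, start, end, tpe, is_mt, cats))
    return pd.DataFrame(recs, columns=[
        "gene_id", "chrom", "strand", "tss", "span_start", "span_end",
        "three_prime_end", "is_nuclear_mt", "categories"])


def make_sites(positions, chrom="chrS") -> pd.DataFrame:
    return pd.DataFrame({
        "site_id": [f"s{i:04d}" for i in range(len(positions))],
        "chrom": chrom, "pos": np.asarray(positions, dtype=np.int64),
        "motif": "ACGT"})


def make_scores(rows) -> pd.DataFrame:
    """Score table from (site_id, pos, tissue_a, tissue_b, score)."""
    recs = [(sid, pos, a, b, s, 10, 20, 20, True) for sid, pos, a, b, s in rows]
    return pd.DataFrame(recs, columns=[
        "site_id", "pos", "tissue_a", "tissue_b", "score",
        "n_probes", "n_a", "n_b", "usable"])
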