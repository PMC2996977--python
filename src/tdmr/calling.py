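"""Site-to-gene assignment, hypo T-DMR calling and gene summaries.

Coordinates are 0-based half-open throughout. A site belongs to a gene's
TSS flanking window when its signed offset in transcription direction lies
in [-upstream_bp, +downstream_bp); offset 0 (the TSS itself) counts as
downstream. A site is hypomethylated in tissue A versus B when its directed
score reaches the calibrated threshold, and is an A-hypo T-DMR when this
holds against every other tissue.
"""
from __future__ import annotations

import math
from itertools import permutations

import numpy as np
import pandas as pd

from .cobra import ThresholdSet
from .errors import ValidationError

__all__ = [
    "assign_sites_to_genes",
    "call_hypo_sites",
    "classify_tissue_hypo",
    "summarize_genes",
    "positional_density",
    "percent_with_tdmr",
]


def assign_sites_to_genes(sites: pd.DataFrame, annotation: pd.DataFrame,
                          upstream_bp: int = 7000,
                          downstream_bp: int = 3000) -> pd.DataFrame:
    """Map sites into strand-aware TSS flanking windows.

    A site may fall in the windows of several genes and is then assigned to
    each. Sites in no window are retained with a null gene. Returns columns
    site_id, pos, gene_id, offset, region.
    """
    pos = sites["pos"].to_numpy()
    order = np.argsort(pos, kind="stable")
    pos_sorted = pos[order]
    ids_sorted = sites["site_id"].to_numpy()[order]
    rows = []
    assigned: set[str] = set()
    for _, gene in annotation.iterrows():
        tss = int(gene["tss"])
        if gene["strand"] == "+":
            lo, hi = tss - upstream_bp, tss + downstream_bp  # pos in [lo, hi)
        elif gene["strand"] == "-":
            lo, hi = tss - downstream_bp + 1, tss + upstream_bp + 1
        else:
            raise ValidationError(f"gene {gene['gene_id']}: bad strand {gene['strand']!r}")
        i = np.searchsorted(pos_sorted, lo, side="left")
        j = np.searchsorted(pos_sorted, hi, side="left")
        for k in range(i, j):
            p = int(pos_sorted[k])
            off = p - tss if gene["strand"] == "+" else tss - p
            rows.append((ids_sorted[k], p, gene["gene_id"], off,
                         "downstream" if off >= 0 else "upstream"))
            assigned.add(ids_sorted[k])
    for sid, p in zip(sites["site_id"], sites["pos"]):
        if sid not in assigned:
            rows.append((sid, int(p), pd.NA, pd.NA, pd.NA))
    return pd.DataFrame(rows, columns=["site_id", "pos", "gene_id", "offset", "region"])


def call_hypo_sites(scores: pd.DataFrame, thresholds: ThresholdSet) -> pd.DataFrame:
    """Directed hypo calls: score(hypo, versus) >= threshold(hypo, versus).

    Every tissue pair present in the score table must have thresholds in
    both directions. Unusable score rows are skipped.
    """
    tissues = sorted(set(scores["tissue_a"]) | set(scores["tissue_b"]))
    for hypo, versus in permutations(tissues, 2):
        present = ((scores["tissue_a"] == min(hypo, versus)) &
                   (scores["tissue_b"] == max(hypo, versus))).any()
        if present and (hypo, versus) not in thresholds.thresholds:
            raise ValidationError(f"missing threshold for comparison {hypo} vs {versus}")
    usable = scores[scores["usable"]] if "usable" in scores.columns else scores
    rows = []
    for (hypo, versus), thr in thresholds.thresholds.items():
        a, b = min(hypo, versus), max(hypo, versus)
        sub = usable[(usable["tissue_a"] == a) & (usable["tissue_b"] == b)]
        s = sub["score"].to_numpy()
        if hypo != a:
            s = -s
        hit = s >= thr
        for sid, p, sc in zip(sub.loc[hit, "site_id"], sub.loc[hit, "pos"], s[hit]):
            rows.append((sid, int(p), hypo, versus, float(sc)))
    out = pd.DataFrame(rows, columns=["site_id", "pos", "hypo_tissue", "versus", "score"])
    return out.sort_values(["site_id", "hypo_tissue", "versus"]).reset_index(drop=True)


def classify_tissue_hypo(calls: pd.DataFrame,
                         tissues: list[str] | None = None) -> pd.DataFrame:
    """Sites called hypo in one tissue against every other tissue."""
    if tissues is None:
        tissues = sorted(set(calls["hypo_tissue"]) | set(calls["versus"]))
    others = {t: set(tissues) - {t} for t in tissues}
    rows = []
    for (sid, hypo), grp in calls.groupby(["site_id", "hypo_tissue"], sort=True):
        if others[hypo] and others[hypo] <= set(grp["versus"]):
            rows.append((sid, int(grp["pos"].iloc[0]), hypo))
    return pd.DataFrame(rows, columns=["site_id", "pos", "tissue"])


def percent_with_tdmr(n_flagged: int, n_total: int) -> int:
    """Percentage rounded half away from zero to the nearest integer."""
    if n_total <= 0:
        raise ValidationError("empty gene universe")
    return int(math.floor(100.0 * n_flagged / n_total + 0.5))


def summarize_genes(assignments: pd.DataFrame, calls: pd.DataFrame,
                    tissue_hypo: pd.DataFrame, annotation: pd.DataFrame,
                    tissues: list[str] | None = None
                    ) -> tuple[pd.DataFrame, dict]:
    """Per-gene T-DMR flags plus headline statistics.

    A gene has a T-DMR when any site in its TSS window carries a hypo call
    in any direction; it is tissue-X hypo when such a site is an X-hypo
    T-DMR, with separate upstream/downstream flags using the site's offset
    within this gene's window. The stats include the percentage of
    nuclear-mt genes with T-DMRs, rounded to the nearest integer percent.
    """
    if tissues is None:
        tissues = sorted(set(calls["hypo_tissue"]) | set(calls["versus"])) \
            if len(calls) else []
    asg = assignments.dropna(subset=["gene_id"])
    called_sites = set(calls["site_id"])
    hypo_sites = {t: set(tissue_hypo.loc[tissue_hypo["tissue"] == t, "site_id"])
                  for t in tissues}

    summary = annotation[["gene_id", "is_nuclear_mt"]].copy()
    summary["has_tdmr"] = False
    for t in tissues:
        summary[f"hypo_{t}"] = False
        summary[f"hypo_{t}_upstream"] = False
        summary[f"hypo_{t}_downstream"] = False
    summary = summary.set_index("gene_id")

    for gene_id, grp in asg.groupby("gene_id", sort=False):
        if gene_id not in summary.index:
            continue
        gsites = set(grp["site_id"])
        if gsites & called_sites:
            summary.loc[gene_id, "has_tdmr"] = True
        for t in tissues:
            hits = grp[grp["site_id"].isin(hypo_sites[t])]
            if len(hits):
                summary.loc[gene_id, f"hypo_{t}"] = True
                if (hits["region"] == "upstream").any():
                    summary.loc[gene_id, f"hypo_{t}_upstream"] = True
                if (hits["region"] == "downstream").any():
                    summary.loc[gene_id, f"hypo_{t}_downstream"] = True

    summary = summary.reset_index()
    mt = summary[summary["is_nuclear_mt"]]
    n_mt = len(mt)
    n_mt_tdmr = int(mt["has_tdmr"].sum())
    stats = {
        "n_genes": len(summary),
        "n_nuclear_mt": n_mt,
        "n_nuclear_mt_with_tdmr": n_mt_tdmr,
        "pct_nuclear_mt_with_tdmr": percent_with_tdmr(n_mt_tdmr, n_mt) if n_mt else 0,
    }
    for t in tissues:
        stats[f"n_nuclear_mt_{t}_hypo"] = int(mt[f"hypo_{t}"].sum())
    return summary, stats


def positional_density(tissue_hypo: pd.DataFrame, assignments: pd.DataFrame,
                       gene_set: set[str], tissue: str, *, bin_bp: int = 1000,
                       upstream_bp: int = 7000,
                       downstream_bp: int = 3000) -> pd.Series:
    """Average tissue-hypo T-DMR count per gene in 1 kb offset bins.

    Bins tile [-upstream_bp, +downstream_bp); the value of a bin is the
    number of focal-tissue hypo sites of genes in ``gene_set`` whose offset
    falls in the bin, divided by the number of genes in the set.
    """
    if not gene_set:
        raise ValidationError("empty gene set")
    if (upstream_bp + downstream_bp) % bin_bp:
        raise ValidationError("bin_bp must tile the window exactly")
    edges = np.arange(-upstream_bp, downstream_bp + bin_bp, bin_bp)
    counts = pd.Series(0.0, index=pd.Index(edges[:-1], name="bin_start"))
    hypo = set(tissue_hypo.loc[tissue_hypo["tissue"] == tissue, "site_id"])
    sub = assignments.dropna(subset=["gene_id"])
    sub = sub[sub["gene_id"].isin(gene_set) & sub["site_id"].isin(hypo)]
    for off in sub["offset"]:
        b = int(math.floor((int(off) + upstream_bp) / bin_bp)) * bin_bp - upstream_bp
        counts.loc[b] += 1
    return counts / len(gene_set)
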