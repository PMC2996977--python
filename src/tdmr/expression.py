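"""Expression ratios and rank-based shift tests for T-DMR position classes.

Per-gene tissue expression ratios are replicate means on the log2 scale; a
two-sample rank-sum test compares the ratios of genes with upstream or
downstream hypo T-DMRs against all nuclear-mt genes.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu

from .errors import ValidationError

__all__ = [
    "expression_log2_ratio",
    "ratio_shift_test",
    "position_class_report",
]

log = logging.getLogger(__name__)

EXACT_MAX_N = 20


def _tissue_of(column: str) -> str:
    return column.rsplit("_", 1)[0]


def expression_log2_ratio(expr: pd.DataFrame, genes, tissue_a: str,
                          tissue_b: str) -> pd.Series:
    """Per-gene replicate-mean log2 ratio of tissue_a over tissue_b."""
    cols_a = [c for c in expr.columns if _tissue_of(c) == tissue_a]
    cols_b = [c for c in expr.columns if _tissue_of(c) == tissue_b]
    if not cols_a or not cols_b:
        raise ValidationError(f"expression matrix lacks samples for "
                              f"{tissue_a!r} or {tissue_b!r}")
    genes = pd.Index(genes)
    missing = genes.difference(expr.index)
    if len(missing):
        log.warning("%d genes lack expression values and are excluded", len(missing))
        genes = genes.intersection(expr.index)
    sub = expr.loc[genes]
    ratio = sub[cols_a].mean(axis=1) - sub[cols_b].mean(axis=1)
    ratio.name = f"{tissue_a}_vs_{tissue_b}"
    return ratio


def ratio_shift_test(ratios_subset, ratios_reference,
                     alternative: str = "two-sided") -> dict:
    """Two-sample rank-sum test plus boxplot summary of the subset.

    Uses exact enumeration when the combined sample size is at most
    ``EXACT_MAX_N`` and there are no ties, otherwise the normal
    approximation with tie correction. Degenerate all-tied input yields
    p = 1 with a warning.
    """
    x = np.asarray(ratios_subset, dtype=float)
    y = np.asarray(ratios_reference, dtype=float)
    if x.size == 0:
        raise ValidationError("empty subset")
    if x.size < 3 or y.size < 3:
        raise ValidationError("both samples need at least 3 values")
    combined = np.concatenate([x, y])
    summary = {
        "n": int(x.size),
        "median": float(np.median(x)),
        "q1": float(np.percentile(x, 25)),
        "q3": float(np.percentile(x, 75)),
    }
    if np.all(combined == combined[0]):
        log.warning("all values tied; rank-sum test is uninformative")
        summary["p_value"] = 1.0
        return summary
    has_ties = len(np.unique(combined)) < combined.size
    method = "exact" if (combined.size <= EXACT_MAX_N and not has_ties) \
        else "asymptotic"
    res = mannwhitneyu(x, y, alternative=alternative, method=method)
    summary["p_value"] = float(res.pvalue)
    return summary


def position_class_report(gene_summary: pd.DataFrame, expr: pd.DataFrame,
                          tissues: list[str] | None = None,
                          alternative: str = "two-sided") -> pd.DataFrame:
    """Ratio distributions for All / Upstream / Downstream gene classes.

    For each ordered tissue pair (hypo tissue vs comparison tissue), the
    "All" row summarizes the log2 ratios of every nuclear-mt gene with
    expression data; the "U" and "D" rows summarize nuclear-mt genes whose
    hypo T-DMRs for the focal tissue lie upstream or downstream of the TSS,
    each tested against "All". Classes with no genes are omitted; "All" has
    no p-value (it is the reference itself).
    """
    if tissues is None:
        tissues = sorted({c.removeprefix("hypo_") for c in gene_summary.columns
                          if c.startswith("hypo_")
                          and not c.endswith(("_upstream", "_downstream"))})
    mt = gene_summary[gene_summary["is_nuclear_mt"]]
    rows = []
    for hypo_t in tissues:
        for other in tissues:
            if other == hypo_t:
                continue
            all_genes = mt["gene_id"]
            ref = expression_log2_ratio(expr, all_genes, hypo_t, other)
            rows.append((f"{hypo_t}_vs_{other}", "All", len(ref),
                         float(np.median(ref)), float(np.percentile(ref, 25)),
                         float(np.percentile(ref, 75)), np.nan))
            for label, col in (("U", f"hypo_{hypo_t}_upstream"),
                               ("D", f"hypo_{hypo_t}_downstream")):
                genes = mt.loc[mt[col], "gene_id"]
                if genes.empty:
                    continue
                sub = expression_log2_ratio(expr, genes, hypo_t, other)
                if len(sub) < 3:
                    continue
                res = ratio_shift_test(sub, ref, alternative=alternative)
                rows.append((f"{hypo_t}_vs_{other}", label, res["n"], res["median"],
                             res["q1"], res["q3"], res["p_value"]))
    return pd.DataFrame(rows, columns=[
        "pair", "group", "n", "median", "q1", "q3", "p_value"])
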