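"""Exact-test gene-set enrichment machinery.

All tests are one-sided hypergeometric tails (Fisher's exact test in the
claimed direction). Fold enrichment is computed with rational arithmetic so
that fold x background fraction equals the focal fraction exactly.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .errors import ValidationError

__all__ = [
    "EnrichmentResult",
    "fisher_exact",
    "make_result",
    "category_enrichment",
    "flag_target_genes",
    "tf_target_enrichment",
    "downstream_fraction_test",
    "nuclear_mt_ratio",
]

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """2x2 counts, fold enrichment and one-sided exact p-value."""

    set_hits: int
    set_size: int
    background_hits: int
    background_size: int
    fold: float
    fold_exact: Fraction | None
    p_value: float
    direction: str  # "over" | "under"


def _check_counts(set_hits, set_size, background_hits, background_size):
    if not (0 <= set_hits <= set_size <= background_size):
        raise ValidationError("inconsistent counts: need 0 <= set_hits <= set_size "
                              "<= background_size")
    if not (set_hits <= background_hits <= background_size):
        raise ValidationError("inconsistent counts: set hits exceed background hits")
    if (set_size - set_hits) > (background_size - background_hits):
        raise ValidationError("inconsistent counts: set misses exceed background misses")


def fisher_exact(set_hits: int, set_size: int, background_hits: int,
                 background_size: int, direction: str = "over") -> float:
    """One-sided hypergeometric tail probability of the focal set's hit count.

    ``over``: P(X >= set_hits); ``under``: P(X <= set_hits), for
    X ~ Hypergeom(N=background_size, K=background_hits, n=set_size).
    """
    _check_counts(set_hits, set_size, background_hits, background_size)
    if direction == "over":
        p = hypergeom.sf(set_hits - 1, background_size, background_hits, set_size)
    elif direction == "under":
        p = hypergeom.cdf(set_hits, background_size, background_hits, set_size)
    else:
        raise ValidationError(f"direction must be 'over' or 'under', got {direction!r}")
    return float(min(p, 1.0))


def make_result(set_hits: int, set_size: int, background_hits: int,
                background_size: int, direction: str = "over") -> EnrichmentResult:
    _check_counts(set_hits, set_size, background_hits, background_size)
    if set_size == 0:
        raise ValidationError("empty focal set")
    if background_hits > 0:
        fold_exact = Fraction(set_hits, set_size) / Fraction(background_hits,
                                                             background_size)
        fold = float(fold_exact)
    else:
        fold_exact = None
        fold = float("nan")
    p = fisher_exact(set_hits, set_size, background_hits, background_size, direction)
    return EnrichmentResult(set_hits, set_size, background_hits, background_size,
                            fold, fold_exact, p, direction)


def _split_categories(text) -> set[str]:
    if pd.isna(text) or not str(text):
        return set()
    return {c for c in str(text).split(";") if c}


def category_enrichment(gene_summary: pd.DataFrame, annotation: pd.DataFrame,
                        tissue: str, categories: list[str] | None = None
                        ) -> pd.DataFrame:
    """Functional-category over/under representation in tissue-hypo genes.

    Focal set: nuclear-mt genes flagged hypo in ``tissue``; background: all
    nuclear-mt genes. Both directions are reported per category.
    """
    col = f"hypo_{tissue}"
    if col not in gene_summary.columns:
        raise ValidationError(f"gene summary has no column {col!r}")
    merged = gene_summary.merge(annotation[["gene_id", "categories"]], on="gene_id")
    mt = merged[merged["is_nuclear_mt"]]
    focal = mt[mt[col]]
    if focal.empty:
        raise ValidationError(f"no nuclear-mt genes with {tissue}-hypo T-DMRs")
    cat_sets = mt["categories"].map(_split_categories)
    focal_sets = focal["categories"].map(_split_categories)
    if categories is None:
        categories = sorted(set().union(*cat_sets) if len(cat_sets) else set())
    rows = []
    for cat in categories:
        bg_hits = int(sum(cat in s for s in cat_sets))
        if bg_hits == 0:
            log.warning("category %r absent from the annotation; skipped", cat)
            continue
        hits = int(sum(cat in s for s in focal_sets))
        for direction in ("over", "under"):
            r = make_result(hits, len(focal), bg_hits, len(mt), direction)
            rows.append((cat, direction, r.set_hits, r.set_size, r.background_hits,
                         r.background_size, r.fold, r.p_value))
    return pd.DataFrame(rows, columns=[
        "category", "direction", "set_hits", "set_size", "background_hits",
        "background_size", "fold", "p_value"])


def flag_target_genes(binding_sites: pd.DataFrame, annotation: pd.DataFrame,
                      upstream_bp: int = 10000,
                      downstream_of_3prime_bp: int = 1000) -> set[str]:
    """Genes whose extended region overlaps at least one binding-site interval.

    The extended region spans from ``upstream_bp`` before the TSS to
    ``downstream_of_3prime_bp`` past the 3' end, in transcription direction
    (mirrored for minus-strand genes). Intervals are 0-based half-open.
    """
    targets: set[str] = set()
    starts = binding_sites["start"].to_numpy()
    ends = binding_sites["end"].to_numpy()
    chroms = binding_sites["chrom"].to_numpy()
    for _, gene in annotation.iterrows():
        tss = int(gene["tss"])
        tpe = int(gene["three_prime_end"])
        if gene["strand"] == "+":
            lo, hi = tss - upstream_bp, tpe + downstream_of_3prime_bp
        elif gene["strand"] == "-":
            lo, hi = tpe - downstream_of_3prime_bp, tss + 1 + upstream_bp
        else:
            raise ValidationError(f"gene {gene['gene_id']}: bad strand {gene['strand']!r}")
        hit = (chroms == gene["chrom"]) & (starts < hi) & (ends > lo)
        if hit.any():
            targets.add(gene["gene_id"])
    return targets


def tf_target_enrichment(target_genes: set[str], focal_genes: set[str],
                         background_genes: set[str],
                         direction: str = "over") -> EnrichmentResult:
    """Enrichment of TF targets in a focal gene set versus its background."""
    if not focal_genes:
        raise ValidationError("empty focal gene set")
    if not focal_genes <= background_genes:
        raise ValidationError("focal genes must be a subset of the background")
    return make_result(
        set_hits=len(target_genes & focal_genes),
        set_size=len(focal_genes),
        background_hits=len(target_genes & background_genes),
        background_size=len(background_genes),
        direction=direction,
    )


def downstream_fraction_test(gene_summary: pd.DataFrame, tissue_a: str,
                             tissue_b: str) -> EnrichmentResult:
    """Compare downstream-hypo fractions between two tissues' hypo gene sets.

    Focal set: genes with tissue_a-hypo T-DMRs (hits: those with a
    downstream one); background: the pooled tissue_a and tissue_b hypo gene
    lists. One-sided in the direction of tissue_a excess.
    """
    for t in (tissue_a, tissue_b):
        if f"hypo_{t}" not in gene_summary.columns:
            raise ValidationError(f"gene summary has no column hypo_{t}")
    ga = gene_summary[gene_summary[f"hypo_{tissue_a}"]]
    gb = gene_summary[gene_summary[f"hypo_{tissue_b}"]]
    if ga.empty or gb.empty:
        raise ValidationError("both tissues need non-empty hypo gene sets")
    da = int(ga[f"hypo_{tissue_a}_downstream"].sum())
    db = int(gb[f"hypo_{tissue_b}_downstream"].sum())
    return make_result(
        set_hits=da, set_size=len(ga),
        background_hits=da + db, background_size=len(ga) + len(gb),
        direction="over",
    )


def nuclear_mt_ratio(gene_summary: pd.DataFrame, tissue: str | None = None,
                     downstream_only: bool = False) -> dict[str, float]:
    """Nuclear-mt gene fraction among all genes and among hypo-T-DMR genes."""
    if gene_summary.empty:
        raise ValidationError("empty gene summary")
    if tissue is not None:
        col = f"hypo_{tissue}_downstream" if downstream_only else f"hypo_{tissue}"
        if col not in gene_summary.columns:
            raise ValidationError(f"gene summary has no column {col!r}")
        hypo = gene_summary[gene_summary[col]]
    else:
        cols = [c for c in gene_summary.columns
                if c.startswith("hypo_") and
                (c.endswith("_downstream") if downstream_only
                 else not c.endswith(("_upstream", "_downstream")))]
        if not cols:
            raise ValidationError("gene summary has no hypo flags")
        hypo = gene_summary[gene_summary[cols].any(axis=1)]
    if hypo.empty:
        raise ValidationError("no genes with hypo T-DMRs")
    return {
        "all_genes": float(gene_summary["is_nuclear_mt"].mean()),
        "hypo_genes": float(hypo["is_nuclear_mt"].mean()),
    }
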