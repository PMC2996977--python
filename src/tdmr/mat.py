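"""Probe-affinity modelling and windowed differential site scoring.

The affinity model regresses log probe intensity on positional nucleotide
indicators and log2 copy number, per sample, then averages coefficients
across samples. Residuals are standardized by a single global robust scale
(median absolute deviation x 1.4826). The directed site score for a tissue
pair is

    score = sqrt(n_a + n_b) * (TM_a - TM_b)

where TM_x is the symmetric trimmed mean of all probe-replicate t-values of
tissue x within +/- ``window_bp`` of the site; positive scores indicate
relative hypomethylation of the first tissue (more digestion, more signal).
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError

__all__ = [
    "AffinityModel",
    "SiteScore",
    "fit_affinity_model",
    "standardize",
    "site_score",
    "score_all_sites",
    "trimmed_mean",
    "directed_score",
]

log = logging.getLogger(__name__)

MIN_FIT_PROBES = 200


@dataclass
class AffinityModel:
    """Fitted probe-affinity baseline.

    ``coefficients`` holds the intercept, one effect per (position,
    non-reference base) indicator, and the log2 copy-number slope.
    ``baseline`` caches the predicted log intensity per probe of the fitted
    universe.
    """

    coefficients: np.ndarray
    probe_ids: pd.Index
    baseline: pd.Series
    residual_scale: float
    probe_length: int


def _design(probes: pd.DataFrame, probe_length: int) -> np.ndarray:
    seqs = probes["sequence"].tolist()
    if any(len(s) != probe_length for s in seqs):
        raise ValidationError(f"all probe sequences must have length {probe_length}")
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype="S1")
    arr = arr.reshape(len(seqs), probe_length)
    cols = [np.ones(len(seqs))]
    for base in (b"C", b"G", b"T"):  # A is the reference base
        cols.append((arr == base).astype(float))
    X = np.column_stack([cols[0]] + [c for block in cols[1:] for c in block.T])
    X = np.column_stack([X, np.log2(probes["copy_number"].to_numpy(dtype=float))])
    return X


def fit_affinity_model(probes: pd.DataFrame, intensities: pd.DataFrame,
                       min_probes: int = MIN_FIT_PROBES) -> AffinityModel:
    """Least-squares fit of log intensity on sequence composition.

    The model is fitted to each sample column separately and the
    coefficient vectors are averaged, which controls sample-specific
    brightness. ``residual_scale`` is the scaled MAD of the pooled
    residuals under the averaged coefficients.
    """
    if len(probes) < min_probes:
        raise ValidationError(
            f"affinity calibration needs >= {min_probes} probes, got {len(probes)}")
    probes = probes.set_index("probe_id") if "probe_id" in probes.columns else probes
    common = probes.index.intersection(intensities.index)
    if len(common) < min_probes:
        raise ValidationError("too few probes with intensities for calibration")
    probes = probes.loc[common]
    Y = intensities.loc[common].to_numpy(dtype=float)
    probe_length = len(probes["sequence"].iloc[0])
    X = _design(probes, probe_length)
    beta, _, rank, _ = np.linalg.lstsq(X, Y, rcond=None)
    if rank < X.shape[1]:
        log.warning("affinity design is rank-deficient (rank %d of %d); "
                    "predictions fall back to the minimum-norm fit", rank, X.shape[1])
    coef = beta.mean(axis=1)
    fitted = X @ coef
    resid = (Y - fitted[:, None]).ravel()
    mad = np.median(np.abs(resid - np.median(resid)))
    scale = 1.4826 * mad
    if scale <= 0:
        log.warning("zero residual spread; clamping residual_scale")
        scale = 1e-8
    return AffinityModel(
        coefficients=coef,
        probe_ids=common,
        baseline=pd.Series(fitted, index=common, name="baseline"),
        residual_scale=float(scale),
        probe_length=probe_length,
    )


def standardize(intensities: pd.DataFrame, model: AffinityModel) -> pd.DataFrame:
    """(log intensity - predicted baseline) / residual_scale, per sample."""
    missing = intensities.index.difference(model.probe_ids)
    if len(missing):
        raise ValidationError(
            f"{len(missing)} probes absent from the affinity model universe "
            f"(e.g. {list(missing[:3])})")
    base = model.baseline.loc[intensities.index]
    return intensities.sub(base, axis=0) / model.residual_scale


def trimmed_mean(values: np.ndarray, trim: float) -> float:
    """Symmetric trimmed mean dropping floor(n * trim) values per tail."""
    if not (0.0 <= trim < 0.5):
        raise ValidationError(f"trim must be in [0, 0.5), got {trim}")
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValidationError("trimmed mean of empty array")
    return float(stats.trim_mean(values, trim))


@dataclass
class SiteScore:
    """Directed differential score at one site for one tissue pair."""

    site_id: str
    pos: int
    tissue_a: str
    tissue_b: str
    score: float
    n_probes: int
    n_a: int
    n_b: int
    usable: bool


def _tissue_of(column: str) -> str:
    return column.rsplit("_", 1)[0]


def _window_score(values_a: np.ndarray, values_b: np.ndarray, trim: float) -> float:
    tm_a = trimmed_mean(values_a, trim)
    tm_b = trimmed_mean(values_b, trim)
    return math.sqrt(values_a.size + values_b.size) * (tm_a - tm_b)


def site_score(tvalues: pd.DataFrame, probes: pd.DataFrame, site_pos: int,
               tissue_a: str, tissue_b: str, *, window_bp: int = 300,
               trim: float = 0.10, min_probes: int = 4,
               max_copy_number: int = 10, site_id: str = "") -> SiteScore:
    """Score one site for one directed tissue pair; see module docstring."""
    probes = probes.set_index("probe_id") if "probe_id" in probes.columns else probes
    probes = probes.loc[tvalues.index]
    centers = probes["start"].to_numpy() + probes["sequence"].str.len().iloc[0] // 2
    mask = (np.abs(centers - site_pos) <= window_bp) & \
           (probes["copy_number"].to_numpy() <= max_copy_number)
    n_probes = int(mask.sum())
    cols_a = [c for c in tvalues.columns if _tissue_of(c) == tissue_a]
    cols_b = [c for c in tvalues.columns if _tissue_of(c) == tissue_b]
    if not cols_a or not cols_b:
        raise ValidationError(f"missing samples for tissues {tissue_a!r}/{tissue_b!r}")
    if n_probes < min_probes:
        return SiteScore(site_id, site_pos, tissue_a, tissue_b,
                         float("nan"), n_probes, 0, 0, usable=False)
    va = tvalues.loc[mask.values if hasattr(mask, "values") else mask, cols_a] \
        .to_numpy().ravel()
    vb = tvalues.loc[mask.values if hasattr(mask, "values") else mask, cols_b] \
        .to_numpy().ravel()
    return SiteScore(site_id, site_pos, tissue_a, tissue_b,
                     _window_score(va, vb, trim), n_probes,
                     int(va.size), int(vb.size), usable=True)


def score_all_sites(tvalues: pd.DataFrame, probes: pd.DataFrame,
                    sites: pd.DataFrame, *, window_bp: int = 300,
                    trim: float = 0.10, min_probes: int = 4,
                    max_copy_number: int = 10,
                    tissues: list[str] | None = None) -> pd.DataFrame:
    """Score every site for every unordered tissue pair.

    Pairs are stored once in alphabetical order; a positive score means the
    first tissue of the pair is relatively hypomethylated. The returned
    table has |sites| x C(n_tissues, 2) rows, with unusable windows flagged
    rather than silently zeroed.
    """
    if tissues is None:
        tissues = sorted({_tissue_of(c) for c in tvalues.columns})
    if len(tissues) < 2:
        raise ValidationError("need >= 2 tissues to score")
    tissues = sorted(tissues)

    probes_ix = probes.set_index("probe_id") if "probe_id" in probes.columns else probes
    probes_ix = probes_ix.loc[tvalues.index]
    plen = len(probes_ix["sequence"].iloc[0])
    centers = probes_ix["start"].to_numpy() + plen // 2
    copy_ok = probes_ix["copy_number"].to_numpy() <= max_copy_number
    order = np.argsort(centers, kind="stable")
    centers_sorted = centers[order]

    tissue_vals = {
        t: tvalues[[c for c in tvalues.columns if _tissue_of(c) == t]].to_numpy()
        for t in tissues
    }
    for t in tissues:
        if tissue_vals[t].shape[1] == 0:
            raise ValidationError(f"no samples for tissue {t!r}")

    rows = []
    site_pos = sites["pos"].to_numpy()
    site_ids = sites["site_id"].to_numpy()
    copy_ok_sorted = copy_ok[order]
    for s in range(len(sites)):
        p = site_pos[s]
        lo = np.searchsorted(centers_sorted, p - window_bp, side="left")
        hi = np.searchsorted(centers_sorted, p + window_bp, side="right")
        sel = order[lo:hi][copy_ok_sorted[lo:hi]]
        n_probes = sel.size
        if n_probes < min_probes:
            for a, b in combinations(tissues, 2):
                rows.append((site_ids[s], p, a, b, np.nan, n_probes, 0, 0, False))
            continue
        vals = {t: tissue_vals[t][sel].ravel() for t in tissues}
        tms = {t: trimmed_mean(vals[t], trim) for t in tissues}
        for a, b in combinations(tissues, 2):
            na, nb = vals[a].size, vals[b].size
            score = math.sqrt(na + nb) * (tms[a] - tms[b])
            rows.append((site_ids[s], p, a, b, score, n_probes, na, nb, True))
    return pd.DataFrame(rows, columns=[
        "site_id", "pos", "tissue_a", "tissue_b", "score",
        "n_probes", "n_a", "n_b", "usable"])


def directed_score(row, hypo: str, versus: str) -> float:
    """Directed score for (hypo vs versus) from a stored unordered-pair row."""
    if (row["tissue_a"], row["tissue_b"]) == (hypo, versus):
        return float(row["score"])
    if (row["tissue_a"], row["tissue_b"]) == (versus, hypo):
        return -float(row["score"])
    raise ValidationError(f"row is for pair {row['tissue_a']}/{row['tissue_b']}, "
                          f"not {hypo}/{versus}")
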