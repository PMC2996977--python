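"""COBRA quantification and score-threshold calibration.

COBRA digests the bisulfite PCR product where the CpG of the ACGT site was
methylated, so the methylation level is cut / (cut + uncut). Sites whose
directed score exceeds a strict prefilter are validation candidates; a
candidate is confirmed hypomethylated when its level in the focal tissue is
at least ``delta`` below the comparison tissue. The calling threshold for a
directed comparison is the minimum score among confirmed candidates.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations

import pandas as pd

from .errors import CalibrationError, MeasurementError, ValidationError
from .mat import directed_score

__all__ = [
    "ThresholdSet",
    "methylation_level",
    "confirm_hypomethylation",
    "select_validation_candidates",
    "calibrate_threshold",
    "calibrate_thresholds",
    "add_levels",
]

log = logging.getLogger(__name__)

DEFAULT_PREFILTER = 2.0
DEFAULT_DELTA = 0.2


def methylation_level(cut_amount: float, uncut_amount: float) -> float:
    """Methylation fraction from electropherogram fragment amounts."""
    if cut_amount < 0 or uncut_amount < 0:
        raise MeasurementError("fragment amounts must be non-negative")
    total = cut_amount + uncut_amount
    if total <= 0:
        raise MeasurementError("undefined measurement: cut + uncut amounts are zero")
    return cut_amount / total


def add_levels(measurements: pd.DataFrame) -> pd.DataFrame:
    """Return a copy with a ``level`` column computed per row."""
    out = measurements.copy()
    total = out["cut_amount"] + out["uncut_amount"]
    if (total <= 0).any():
        bad = out.loc[total <= 0, "site_id"].iloc[0]
        raise MeasurementError(f"undefined measurement at site {bad}: zero total amount")
    out["level"] = out["cut_amount"] / total
    return out


def _level_lookup(measurements: pd.DataFrame, site: str, tissue: str) -> float:
    rows = measurements[(measurements["site_id"] == site) &
                        (measurements["tissue"] == tissue)]
    if rows.empty:
        raise MeasurementError(f"no COBRA measurement for site {site} in tissue {tissue}")
    row = rows.iloc[0]
    return methylation_level(row["cut_amount"], row["uncut_amount"])


def confirm_hypomethylation(measurements: pd.DataFrame, site: str,
                            tissue_a: str, tissue_b: str,
                            delta: float = DEFAULT_DELTA) -> bool:
    """True iff tissue_a is hypomethylated at ``site`` relative to tissue_b.

    Requires level(a) <= level(b) - delta; with ``delta == 0`` a strict
    improvement is required, so equal levels never confirm.
    """
    if delta < 0:
        raise ValidationError("delta must be >= 0")
    la = _level_lookup(measurements, site, tissue_a)
    lb = _level_lookup(measurements, site, tissue_b)
    if delta == 0:
        return la < lb
    return la <= lb - delta


def select_validation_candidates(scores: pd.DataFrame,
                                 prefilter_score: float = DEFAULT_PREFILTER
                                 ) -> dict[tuple[str, str], list[str]]:
    """Sites whose directed score strictly exceeds the prefilter.

    Returns a mapping (hypo_tissue, versus_tissue) -> ordered site list for
    every direction of every pair present in the score table.
    """
    out: dict[tuple[str, str], list[str]] = {}
    tissues = sorted(set(scores["tissue_a"]) | set(scores["tissue_b"]))
    usable = scores[scores["usable"]] if "usable" in scores.columns else scores
    for hypo, versus in permutations(tissues, 2):
        a, b = min(hypo, versus), max(hypo, versus)
        sub = usable[(usable["tissue_a"] == a) & (usable["tissue_b"] == b)]
        if sub.empty:
            continue
        s = sub["score"].to_numpy()
        if hypo != a:
            s = -s
        out[(hypo, versus)] = list(sub.loc[s > prefilter_score, "site_id"])
    return out


def calibrate_threshold(scores: pd.DataFrame, confirmed_sites: set[str],
                        hypo: str, versus: str,
                        prefilter_score: float = DEFAULT_PREFILTER) -> float:
    """Minimum directed score among confirmed prefiltered candidates."""
    a, b = min(hypo, versus), max(hypo, versus)
    usable = scores[scores["usable"]] if "usable" in scores.columns else scores
    sub = usable[(usable["tissue_a"] == a) & (usable["tissue_b"] == b)]
    s = sub["score"].to_numpy()
    if hypo != a:
        s = -s
    ok = (s > prefilter_score) & sub["site_id"].isin(confirmed_sites).to_numpy()
    if not ok.any():
        raise CalibrationError(
            f"no confirmed candidate site for comparison {hypo} vs {versus}; "
            f"supply a threshold manually")
    return float(s[ok].min())


@dataclass
class ThresholdSet:
    """Per-directed-comparison calling thresholds with provenance."""

    thresholds: dict[tuple[str, str], float] = field(default_factory=dict)
    provenance: dict[tuple[str, str], list[str]] = field(default_factory=dict)
    prefilter: float = DEFAULT_PREFILTER

    def __post_init__(self):
        for pair, thr in self.thresholds.items():
            if thr <= self.prefilter:
                raise ValidationError(
                    f"threshold {thr} for {pair} is not above prefilter {self.prefilter}")

    def to_frame(self) -> pd.DataFrame:
        rows = [(h, v, self.thresholds[(h, v)],
                 ";".join(self.provenance.get((h, v), [])))
                for (h, v) in sorted(self.thresholds)]
        return pd.DataFrame(rows, columns=["hypo_tissue", "versus", "threshold",
                                           "provenance"])

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   prefilter: float = DEFAULT_PREFILTER) -> "ThresholdSet":
        thresholds, provenance = {}, {}
        for _, row in frame.iterrows():
            key = (row["hypo_tissue"], row["versus"])
            thresholds[key] = float(row["threshold"])
            prov = row.get("provenance", "")
            provenance[key] = [s for s in str(prov).split(";") if s and s != "nan"]
        return cls(thresholds=thresholds, provenance=provenance, prefilter=prefilter)


def calibrate_thresholds(scores: pd.DataFrame, measurements: pd.DataFrame, *,
                         delta: float = DEFAULT_DELTA,
                         prefilter_score: float = DEFAULT_PREFILTER) -> ThresholdSet:
    """Calibrate one threshold per directed tissue comparison.

    Candidates lacking a COBRA measurement in either tissue are ignored with
    a warning (they were simply not assayed). A direction with no confirmed
    candidate raises :class:`CalibrationError`.
    """
    levels = add_levels(measurements)
    lut = {(r["site_id"], r["tissue"]): r["level"] for _, r in levels.iterrows()}
    candidates = select_validation_candidates(scores, prefilter_score)
    thresholds: dict[tuple[str, str], float] = {}
    provenance: dict[tuple[str, str], list[str]] = {}
    for (hypo, versus), sites in candidates.items():
        confirmed = []
        skipped = 0
        for site in sites:
            la = lut.get((site, hypo))
            lb = lut.get((site, versus))
            if la is None or lb is None:
                skipped += 1
                continue
            ok = (la < lb) if delta == 0 else (la <= lb - delta)
            if ok:
                confirmed.append(site)
        if skipped:
            log.warning("%d candidate sites for %s vs %s lack COBRA measurements",
                        skipped, hypo, versus)
        thresholds[(hypo, versus)] = calibrate_threshold(
            scores, set(confirmed), hypo, versus, prefilter_score)
        provenance[(hypo, versus)] = confirmed
    if not thresholds:
        raise CalibrationError("no tissue comparisons present in the score table")
    return ThresholdSet(thresholds=thresholds, provenance=provenance,
                        prefilter=prefilter_score)
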