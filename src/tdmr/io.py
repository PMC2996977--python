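"""Readers and writers for the on-disk table schemas.

Everything is plain text: TSV tables, BED intervals (0-based half-open),
one-gene-per-line target lists. Readers validate and raise
:class:`~tdmr.errors.ValidationError` naming the offending line (1-based,
counting the header).
"""
from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

__all__ = [
    "read_annotation", "write_annotation",
    "read_sites_bed", "write_sites_bed",
    "read_probes", "write_probes",
    "read_matrix", "write_matrix",
    "read_cobra", "write_cobra",
    "read_scores", "write_scores",
    "read_thresholds", "write_thresholds",
    "read_assignments", "write_assignments",
    "read_calls_bed", "write_calls_bed",
    "read_summary", "write_summary",
    "read_targets", "write_targets",
    "read_truth", "write_truth",
]

_ANNOT_COLS = ["gene_id", "chrom", "strand", "tss", "span_start", "span_end",
               "three_prime_end", "is_nuclear_mt", "categories"]


def _line(path, idx: int) -> str:
    # +2: one for the header, one for 1-based numbering
    return f"{path}:{idx + 2}"


def read_annotation(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"categories": str}, keep_default_na=False,
                     na_values=[""])
    missing = set(_ANNOT_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    bad = ~df["strand"].isin(["+", "-"])
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"{_line(path, i)}: bad strand {df['strand'].iloc[i]!r}")
    dup = df["gene_id"].duplicated()
    if dup.any():
        i = int(np.flatnonzero(dup)[0])
        raise ValidationError(f"{_line(path, i)}: duplicated gene id "
                              f"{df['gene_id'].iloc[i]!r}")
    for col in ("tss", "span_start", "span_end", "three_prime_end"):
        neg = df[col] < 0
        if neg.any():
            i = int(np.flatnonzero(neg)[0])
            raise ValidationError(f"{_line(path, i)}: negative coordinate in {col}")
    bad = df["span_end"] <= df["span_start"]
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"{_line(path, i)}: span_end <= span_start")
    df["is_nuclear_mt"] = df["is_nuclear_mt"].astype(bool)
    df["categories"] = df["categories"].fillna("")
    return df


def write_annotation(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=_ANNOT_COLS)


def read_sites_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 4:
        raise ValidationError(f"{path}: sites BED needs >= 4 columns")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "site_id"]
    bad = df["end"] <= df["start"]
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"{path}:{i + 1}: BED end <= start")
    neg = df["start"] < 0
    if neg.any():
        i = int(np.flatnonzero(neg)[0])
        raise ValidationError(f"{path}:{i + 1}: negative BED start")
    out = pd.DataFrame({"site_id": df["site_id"], "chrom": df["chrom"],
                        "pos": df["start"].astype(np.int64), "motif": "ACGT"})
    return out


def write_sites_bed(sites: pd.DataFrame, path: str | Path) -> None:
    bed = pd.DataFrame({
        "chrom": sites["chrom"],
        "start": sites["pos"].astype(np.int64),
        "end": sites["pos"].astype(np.int64) + 1,
        "site_id": sites["site_id"],
    })
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_probes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    needed = {"probe_id", "chrom", "start", "sequence", "copy_number"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    bad = df["copy_number"] < 1
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"{_line(path, i)}: copy_number < 1")
    lens = df["sequence"].str.len()
    if lens.nunique() > 1:
        i = int(np.flatnonzero(lens != lens.iloc[0])[0])
        raise ValidationError(f"{_line(path, i)}: inconsistent probe sequence length")
    return df


def write_probes(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False,
              columns=["probe_id", "chrom", "start", "sequence", "copy_number"])


def read_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, float_precision="round_trip")
    if df.isna().any().any():
        raise ValidationError(f"{path}: matrix contains missing values")
    return df


def write_matrix(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")


def read_cobra(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    needed = {"site_id", "tissue", "cut_amount", "uncut_amount"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    neg = (df["cut_amount"] < 0) | (df["uncut_amount"] < 0)
    if neg.any():
        i = int(np.flatnonzero(neg)[0])
        raise ValidationError(f"{_line(path, i)}: negative fragment amount")
    return df


def write_cobra(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False,
              columns=["site_id", "tissue", "cut_amount", "uncut_amount"])


def read_scores(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    needed = {"site_id", "pos", "tissue_a", "tissue_b", "score", "n_probes", "usable"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    df["usable"] = df["usable"].astype(bool)
    return df


def write_scores(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_thresholds(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[""])
    needed = {"hypo_tissue", "versus", "threshold"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    return df


def write_thresholds(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_assignments(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_assignments(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


_CALLS_BED_COLS = ["chrom", "start", "end", "name", "score", "strand",
                   "offset", "region", "versus"]


def write_calls_bed(calls: pd.DataFrame, path: str | Path) -> None:
    """BED6+3: name is gene:hypo_tissue (site:hypo_tissue when unassigned)."""
    calls.to_csv(path, sep="\t", index=False, header=False,
                 columns=_CALLS_BED_COLS)


def read_calls_bed(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, names=_CALLS_BED_COLS,
                     keep_default_na=False, na_values=[""])
    bad = df["end"] <= df["start"]
    if bad.any():
        i = int(np.flatnonzero(bad)[0])
        raise ValidationError(f"{path}:{i + 1}: BED end <= start")
    return df


def read_summary(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in df.columns:
        if col == "has_tdmr" or col.startswith("hypo_") or col == "is_nuclear_mt":
            df[col] = df[col].astype(bool)
    return df


def write_summary(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_targets(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [ln.strip() for ln in fh if ln.strip() and not ln.startswith("#")]


def write_targets(genes, path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def read_truth(path: str | Path) -> pd.DataFrame:
    """Long-format site methylation table: site_id, tissue, methylation."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    needed = {"site_id", "tissue", "methylation"}
    missing = needed - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    bad = (df["methylation"] < 0) | (df["methylation"] > 1)
    if bad.any():
        i = int(np.flatnonzero(bad.to_numpy())[0])
        raise ValidationError(f"{_line(path, i)}: methylation outside [0, 1]")
    return df


def write_truth(site_methylation: pd.DataFrame, path: str | Path) -> None:
    long = site_methylation.reset_index().melt(
        id_vars="site_id", var_name="tissue", value_name="methylation")
    long.to_csv(path, sep="\t", index=False)
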