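"""Synthetic data with planted ground truth.

Emulates the output of a methyl-sensitive restriction tiling-array
experiment: a chromosome with non-overlapping genes on both strands, ACGT
restriction sites, 25-mer probes tiling the chromosome, per-tissue site
methylation levels with planted tissue-specific hypomethylation inside TSS
flanking windows, probe intensities driven by a sequence-affinity baseline
plus fragment amplification signal, matched COBRA quantifications, an
expression matrix linked to downstream hypomethylation, and transcription
factor target lists with a planted fold enrichment.

All randomness is derived from ``SimConfig.seed``; each operation draws from
its own seeded stream so outputs are byte-identical under a fixed seed and
insensitive to the order in which operations are called.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ParameterError, SizingError, ValidationError

__all__ = [
    "SimConfig",
    "GroundTruth",
    "generate_genome",
    "plant_methylation",
    "simulate_intensities",
    "simulate_cobra",
    "simulate_expression",
    "simulate_tf_targets",
    "default_affinity_coefficients",
]

log = logging.getLogger(__name__)

# Per-operation stream tags, combined with the config seed so each
# simulate_* call is independently reproducible.
_STREAM_GENOME = 1
_STREAM_METHYLATION = 2
_STREAM_AFFINITY = 3
_STREAM_INTENSITY = 4
_STREAM_COBRA = 5
_STREAM_EXPRESSION = 6
_STREAM_TF = 7

CATEGORY_VOCAB = (
    "metabolism",
    "respiratory_chain",
    "tca_cycle",
    "detoxification",
    "protein_sorting",
    "mito_ribosome",
    "mtdna_translation",
)

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    The default shape mirrors a three-tissue, two-replicate study.
    """

    n_genes: int = 500
    chrom_length: int = 12_000_000
    chrom: str = "chrS"
    tissues: tuple[str, ...] = ("brain", "heart", "liver")
    replicates_per_tissue: int = 2
    site_density: float = 1.0            # ACGT sites per kb
    probe_spacing: int = 35
    probe_length: int = 25
    frac_multi_copy: float = 0.05        # probes with copy number > 1
    fragment_signal: float = 2.0         # log-intensity added over amplified fragments
    max_fragment_bp: int = 1000          # amplified span cap on each side of a site
    noise_sd: float = 0.3                # replicate log-intensity noise
    affinity_coefficients: np.ndarray | None = None  # (probe_length, 4)
    affinity_intercept: float = 8.0
    copy_number_effect: float = 1.0      # log-intensity per doubling of copy number
    frac_nuclear_mt: float = 0.6
    frac_tissue_hypo_genes: float = 0.1  # per tissue
    hypo_level: float = 0.1
    hyper_level: float = 0.9
    expression_effect: float = 2.0       # log2 shift for downstream-hypo genes
    expression_noise_sd: float = 0.25
    cobra_noise: float = 0.02
    tf_base_rate: float = 0.3
    tf_planted_fold: float = 1.6
    seed: int = 0

    # window used when planting sites near TSSs; matches the analysis window
    upstream_bp: int = 7000
    downstream_bp: int = 3000

    def validate(self) -> "SimConfig":
        for name in ("frac_multi_copy", "frac_nuclear_mt", "frac_tissue_hypo_genes",
                     "hypo_level", "hyper_level", "tf_base_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ParameterError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_genes", "chrom_length", "replicates_per_tissue",
                     "probe_spacing", "probe_length", "max_fragment_bp"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be positive")
        if len(self.tissues) < 2:
            raise ParameterError("need at least 2 tissues")
        if len(set(self.tissues)) != len(self.tissues):
            raise ParameterError("tissue labels must be unique")
        if self.hypo_level >= self.hyper_level:
            raise ParameterError("hypo_level must be below hyper_level")
        if self.noise_sd < 0 or self.expression_noise_sd < 0 or self.cobra_noise < 0:
            raise ParameterError("noise parameters must be >= 0")
        if self.frac_tissue_hypo_genes * len(self.tissues) > 1.0:
            raise ParameterError("frac_tissue_hypo_genes * n_tissues must be <= 1")
        return self

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([self.seed, stream])


@dataclass
class GroundTruth:
    """Planted methylation truth.

    ``site_methylation`` is a wide table (index: site_id, one column per
    tissue) of methylation fractions in [0, 1]. ``planted`` records one row
    per planted hypomethylated site with its host gene, tissue, signed TSS
    offset and up/downstream class.
    """

    site_methylation: pd.DataFrame
    planted: pd.DataFrame  # columns: site_id, gene_id, tissue, offset, region

    @property
    def planted_hypo_sites(self) -> set[tuple[str, str]]:
        return set(zip(self.planted["site_id"], self.planted["tissue"]))

    @property
    def planted_hypo_genes(self) -> set[tuple[str, str]]:
        return set(zip(self.planted["gene_id"], self.planted["tissue"]))


def default_affinity_coefficients(seed: int, probe_length: int = 25) -> np.ndarray:
    """Per-position nucleotide affinity effects, (probe_length, 4) for ACGT."""
    rng = np.random.default_rng([seed, _STREAM_AFFINITY])
    coef = rng.normal(0.0, 0.12, size=(probe_length, 4))
    coef[:, 0] = 0.0  # A is the reference base; keeps the model identifiable
    return coef


def _random_sequences(rng: np.random.Generator, n: int, length: int) -> np.ndarray:
    codes = rng.integers(0, 4, size=(n, length))
    flat = _BASES[codes]
    return np.array(["".join(row) for row in flat])


def generate_genome(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Lay out genes, ACGT sites and tiling probes on one chromosome.

    Genes occupy disjoint slots; when the slot allows, each TSS keeps a
    7 kb margin inside its slot so planted TSS windows do not spill into
    neighbouring genes. Returns (annotation, sites, probes) tables.
    """
    config.validate()
    rng = config.rng(_STREAM_GENOME)

    slot = config.chrom_length // config.n_genes
    if slot < 3000:
        raise SizingError(
            f"chrom_length {config.chrom_length} too small for {config.n_genes} genes "
            f"(slot {slot} < 3000 bp)")

    max_len = min(8000, slot - 1000)
    lengths = rng.integers(500, max_len + 1, size=config.n_genes)
    strands = rng.choice(["+", "-"], size=config.n_genes)
    if config.n_genes >= 2 and len(set(strands)) == 1:
        strands[-1] = "-" if strands[0] == "+" else "+"

    rows = []
    for i in range(config.n_genes):
        slot_start = i * slot
        L = int(lengths[i])
        margin = min(config.upstream_bp, (slot - L) // 2)
        lo, hi = margin, slot - L - margin
        start = slot_start + int(rng.integers(lo, hi + 1)) if hi > lo else slot_start + lo
        end = start + L
        strand = strands[i]
        tss = start if strand == "+" else end - 1
        three_prime = end if strand == "+" else start
        is_mt = bool(rng.random() < config.frac_nuclear_mt)
        if is_mt:
            k = int(rng.integers(1, 3))
            cats = ";".join(sorted(rng.choice(CATEGORY_VOCAB, size=k, replace=False)))
        else:
            cats = ""
        rows.append((f"g{i:05d}", config.chrom, strand, tss, start, end,
                     three_prime, is_mt, cats))
    annotation = pd.DataFrame(rows, columns=[
        "gene_id", "chrom", "strand", "tss", "span_start", "span_end",
        "three_prime_end", "is_nuclear_mt", "categories"])

    n_sites = int(round(config.site_density * config.chrom_length / 1000))
    pos = np.array([], dtype=np.int64)
    while len(pos) < n_sites:
        draw = rng.integers(0, config.chrom_length, size=int(n_sites * 1.2) + 16)
        pos = np.unique(np.concatenate([pos, draw]))
    keep = np.sort(rng.choice(len(pos), size=n_sites, replace=False))
    pos = pos[keep]
    sites = pd.DataFrame({
        "site_id": [f"s{i:06d}" for i in range(n_sites)],
        "chrom": config.chrom,
        "pos": pos,
        "motif": "ACGT",
    })

    starts = np.arange(0, config.chrom_length - config.probe_length + 1,
                       config.probe_spacing, dtype=np.int64)
    n_probes = len(starts)
    seqs = _random_sequences(rng, n_probes, config.probe_length)
    copy = np.ones(n_probes, dtype=np.int64)
    multi = rng.random(n_probes) < config.frac_multi_copy
    copy[multi] = rng.integers(2, 16, size=int(multi.sum()))
    probes = pd.DataFrame({
        "probe_id": [f"p{i:06d}" for i in range(n_probes)],
        "chrom": config.chrom,
        "start": starts,
        "sequence": seqs,
        "copy_number": copy,
    })
    return annotation, sites, probes


def _window_offsets(positions: np.ndarray, tss: int, strand: str,
                    upstream: int, downstream: int) -> np.ndarray:
    """Signed TSS offsets (transcription direction) for positions in window."""
    off = positions - tss if strand == "+" else tss - positions
    mask = (off >= -upstream) & (off < downstream)
    return np.where(mask, off, np.iinfo(np.int64).min)


def plant_methylation(annotation: pd.DataFrame, sites: pd.DataFrame,
                      config: SimConfig) -> GroundTruth:
    """Assign per-tissue methylation fractions, planting hypo sites.

    Per tissue, ``frac_tissue_hypo_genes`` of genes (disjoint across tissues)
    receive one site inside their TSS window set to ``hypo_level`` in that
    tissue and ``hyper_level`` in every other tissue. All remaining sites
    share a common level across tissues. Selected genes whose windows
    contain no site (or only already-planted sites) are skipped with a
    warning.
    """
    config.validate()
    rng = config.rng(_STREAM_METHYLATION)
    pos = sites["pos"].to_numpy()
    if len(pos) and (pos.min() < 0 or pos.max() >= config.chrom_length):
        raise ValidationError("site positions outside chromosome")
    site_ids = sites["site_id"].to_numpy()

    tissues = list(config.tissues)
    common = rng.uniform(0.02, 0.98, size=len(sites))
    meth = pd.DataFrame({t: common.copy() for t in tissues}, index=site_ids)
    meth.index.name = "site_id"

    k = int(round(config.frac_tissue_hypo_genes * len(annotation)))
    order = rng.permutation(len(annotation))
    planted_rows = []
    taken_sites: set[int] = set()
    cursor = 0
    for tissue in tissues:
        chosen = order[cursor:cursor + k]
        cursor += k
        for gi in chosen:
            gene = annotation.iloc[gi]
            off = _window_offsets(pos, int(gene["tss"]), gene["strand"],
                                  config.upstream_bp, config.downstream_bp)
            idx = np.flatnonzero(off > np.iinfo(np.int64).min)
            idx = np.array([j for j in idx if j not in taken_sites])
            if len(idx) == 0:
                log.warning("gene %s has no available site in its TSS window; skipped",
                            gene["gene_id"])
                continue
            # prefer the most isolated site so its amplified fragment is not
            # truncated by an immediate neighbour
            iso = np.empty(len(idx))
            for m, j in enumerate(idx):
                left = pos[j] - pos[j - 1] if j > 0 else config.max_fragment_bp
                right = pos[j + 1] - pos[j] if j < len(pos) - 1 else config.max_fragment_bp
                iso[m] = min(left, right)
            j = int(idx[np.argmax(iso)])
            taken_sites.add(j)
            for t in tissues:
                meth.iloc[j, meth.columns.get_loc(t)] = (
                    config.hypo_level if t == tissue else config.hyper_level)
            o = int(off[j])
            planted_rows.append((site_ids[j], gene["gene_id"], tissue, o,
                                 "downstream" if o >= 0 else "upstream"))
    planted = pd.DataFrame(planted_rows, columns=[
        "site_id", "gene_id", "tissue", "offset", "region"])
    return GroundTruth(site_methylation=meth, planted=planted)


def _encode(seqs: Sequence[str], length: int) -> np.ndarray:
    arr = np.frombuffer("".join(seqs).encode("ascii"), dtype="S1")
    arr = arr.reshape(len(seqs), length)
    codes = np.zeros(arr.shape, dtype=np.int8)
    for code, base in enumerate(b"ACGT"):
        codes[arr == bytes([base])] = code
    return codes


def affinity_baseline(probes: pd.DataFrame, config: SimConfig) -> np.ndarray:
    """True log-intensity baseline from sequence and copy number."""
    coef = config.affinity_coefficients
    if coef is None:
        coef = default_affinity_coefficients(config.seed, config.probe_length)
    coef = np.asarray(coef, dtype=float)
    if coef.shape != (config.probe_length, 4):
        raise ParameterError(
            f"affinity_coefficients must have shape ({config.probe_length}, 4)")
    codes = _encode(probes["sequence"].tolist(), config.probe_length)
    base = coef[np.arange(config.probe_length)[None, :], codes].sum(axis=1)
    base = base + config.affinity_intercept
    base = base + config.copy_number_effect * np.log2(probes["copy_number"].to_numpy())
    return base


def simulate_intensities(truth: GroundTruth, probes: pd.DataFrame,
                         sites: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Per-probe log intensities for every tissue replicate.

    A probe reads its affinity baseline plus, when it lies within the
    amplified fragment of its nearest site (distance capped at
    ``max_fragment_bp``), ``fragment_signal * (1 - methylation)`` of that
    site in the sample's tissue, plus independent Gaussian replicate noise.
    """
    config.validate()
    missing = set(sites["site_id"]) - set(truth.site_methylation.index)
    if missing:
        raise ValidationError(f"truth does not cover {len(missing)} sites")
    rng = config.rng(_STREAM_INTENSITY)
    baseline = affinity_baseline(probes, config)

    pos = sites["pos"].to_numpy()
    order = np.argsort(pos, kind="stable")
    pos_sorted = pos[order]
    ids_sorted = sites["site_id"].to_numpy()[order]
    centers = probes["start"].to_numpy() + config.probe_length // 2
    j = np.searchsorted(pos_sorted, centers)
    left = np.clip(j - 1, 0, len(pos_sorted) - 1)
    right = np.clip(j, 0, len(pos_sorted) - 1)
    dl = np.abs(centers - pos_sorted[left])
    dr = np.abs(centers - pos_sorted[right])
    nearest = np.where(dl <= dr, left, right)
    dist = np.minimum(dl, dr)
    in_frag = dist <= config.max_fragment_bp

    meth = truth.site_methylation.loc[ids_sorted]
    cols = {}
    for tissue in config.tissues:
        unmeth = 1.0 - meth[tissue].to_numpy()
        signal = np.where(in_frag, config.fragment_signal * unmeth[nearest], 0.0)
        clean = baseline + signal
        for rep in range(1, config.replicates_per_tissue + 1):
            noise = rng.normal(0.0, config.noise_sd, size=len(probes)) \
                if config.noise_sd > 0 else 0.0
            cols[f"{tissue}_{rep}"] = clean + noise
    out = pd.DataFrame(cols, index=pd.Index(probes["probe_id"], name="probe_id"))
    return out


def simulate_cobra(truth: GroundTruth, sites: pd.DataFrame | None = None,
                   noise: float = 0.0, *, tissues: Sequence[str] | None = None,
                   seed: int = 0) -> pd.DataFrame:
    """COBRA cut/uncut fragment amounts per (site, tissue).

    The enzyme cuts the bisulfite-PCR product where the CpG was methylated,
    so cut amount tracks methylation: cut = methylation + noise,
    uncut = (1 - methylation) + noise, both truncated at zero. With
    ``noise=0`` the quantification inverts exactly to the planted level.
    """
    if noise < 0:
        raise ParameterError("noise must be >= 0")
    meth = truth.site_methylation
    if sites is not None:
        ids = sites["site_id"] if isinstance(sites, pd.DataFrame) else pd.Index(sites)
        meth = meth.loc[ids]
    if tissues is None:
        tissues = list(meth.columns)
    rng = np.random.default_rng([seed, _STREAM_COBRA])
    rows = []
    for tissue in tissues:
        m = meth[tissue].to_numpy()
        cut = m.copy()
        uncut = 1.0 - m
        if noise > 0:
            cut = np.clip(cut + rng.normal(0.0, noise, size=len(m)), 0.0, None)
            uncut = np.clip(uncut + rng.normal(0.0, noise, size=len(m)), 0.0, None)
            dead = (cut + uncut) == 0
            cut[dead] = m[dead]
            uncut[dead] = 1.0 - m[dead]
        rows.append(pd.DataFrame({
            "site_id": meth.index, "tissue": tissue,
            "cut_amount": cut, "uncut_amount": uncut}))
    return pd.concat(rows, ignore_index=True)


def simulate_expression(truth: GroundTruth, annotation: pd.DataFrame,
                        config: SimConfig) -> pd.DataFrame:
    """log2 expression matrix (genes x tissue replicates).

    Genes carrying a planted hypo site downstream of their TSS in tissue X
    are shifted by ``expression_effect`` log2 units in X; everything else
    draws from a common per-gene baseline. Replicate noise is Gaussian.
    """
    config.validate()
    rng = config.rng(_STREAM_EXPRESSION)
    genes = annotation["gene_id"].to_numpy()
    baseline = rng.normal(8.0, 1.0, size=len(genes))
    shift = pd.DataFrame(0.0, index=genes, columns=list(config.tissues))
    down = truth.planted[truth.planted["region"] == "downstream"]
    for _, row in down.iterrows():
        if row["gene_id"] in shift.index and row["tissue"] in shift.columns:
            shift.loc[row["gene_id"], row["tissue"]] += config.expression_effect
    cols = {}
    for tissue in config.tissues:
        clean = baseline + shift[tissue].to_numpy()
        for rep in range(1, config.replicates_per_tissue + 1):
            noise = rng.normal(0.0, config.expression_noise_sd, size=len(genes)) \
                if config.expression_noise_sd > 0 else 0.0
            cols[f"{tissue}_{rep}"] = clean + noise
    return pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))


def simulate_tf_targets(annotation: pd.DataFrame, hypo_genes: set[str],
                        config: SimConfig) -> list[str]:
    """Sample a TF target gene list with planted fold enrichment.

    Membership probabilities are chosen so that the expected target rate is
    ``tf_base_rate`` overall and ``tf_base_rate * tf_planted_fold`` inside
    ``hypo_genes``, i.e. the fold enrichment of targets in the hypo set
    relative to all genes equals ``tf_planted_fold`` in expectation.
    """
    config.validate()
    all_genes = list(annotation["gene_id"])
    unknown = set(hypo_genes) - set(all_genes)
    if unknown:
        raise ValidationError(f"hypo_genes not in annotation: {sorted(unknown)[:5]}")
    n = len(all_genes)
    h = len(hypo_genes) / n if n else 0.0
    p_hypo = config.tf_base_rate * config.tf_planted_fold
    if p_hypo > 1.0:
        raise ParameterError(
            f"infeasible fold: base rate {config.tf_base_rate} x fold "
            f"{config.tf_planted_fold} exceeds 1")
    if h < 1.0:
        p_other = config.tf_base_rate * (1.0 - config.tf_planted_fold * h) / (1.0 - h)
    else:
        p_other = 0.0
    if not (0.0 <= p_other <= 1.0):
        raise ParameterError(
            "infeasible fold: implied non-hypo target probability outside [0, 1]")
    rng = config.rng(_STREAM_TF)
    u = rng.random(n)
    hypo = np.array([g in hypo_genes for g in all_genes])
    p = np.where(hypo, p_hypo, p_other)
    return [g for g, keep in zip(all_genes, u < p) if keep]
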