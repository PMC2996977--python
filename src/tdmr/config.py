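"""Pipeline configuration.

A single flat config object holds every tunable of the analysis stages.
It round-trips through YAML and rejects unknown keys.
"""
from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    """Tunables for scoring, calibration, calling, enrichment and reporting.

    Defaults follow the analysis conventions: a -7 kb/+3 kb TSS flanking
    window for site assignment, a strict MATscore prefilter of 2 for
    validation candidates, and a 10 kb-upstream / 1 kb-past-3'-end extended
    gene region for binding-site target flagging.
    """

    window_bp: int = 300          # half-width of the scoring window around a site
    trim: float = 0.10            # symmetric trim fraction for the windowed mean
    min_probes: int = 4           # minimum probes in window for a usable score
    max_copy_number: int = 10     # probes with higher copy number are excluded
    prefilter: float = 2.0        # strict lower bound for validation candidates
    cobra_delta: float = 0.2      # required methylation margin for confirmation
    upstream_bp: int = 7000       # TSS window extent upstream
    downstream_bp: int = 3000     # TSS window extent downstream
    tf_upstream_bp: int = 10000   # extended gene region upstream of TSS
    tf_downstream_of_3prime_bp: int = 1000
    bin_bp: int = 1000            # positional density bin width
    alpha: float = 0.05
    seed: int = 0

    def validate(self) -> "PipelineConfig":
        if not (0.0 <= self.trim < 0.5):
            raise ConfigError(f"trim must be in [0, 0.5), got {self.trim}")
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError(f"alpha must be in (0, 1), got {self.alpha}")
        for name in ("window_bp", "min_probes", "max_copy_number", "upstream_bp",
                     "downstream_bp", "tf_upstream_bp", "tf_downstream_of_3prime_bp",
                     "bin_bp"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.cobra_delta < 0:
            raise ConfigError("cobra_delta must be >= 0")
        return self

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data).validate()

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def content_hash(self) -> str:
        """Stable hash of the canonical YAML serialization."""
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()
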