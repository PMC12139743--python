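"""Pipeline configuration.

Defaults are the constants of the standard analysis: 110-140 Hz band,
50 Hz notch, 400 Hz target rate, 500 ms bins, lags 0/0.5/1 s, a 20-value
log-spaced regularisation grid over [10, 10000], 5 CV folds, 5000
permutations, alpha = 0.05.  Every field is overridable from YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .errors import SchemaError

__all__ = ["PipelineConfig"]


@dataclass
class PipelineConfig:
    # preprocessing
    band: tuple[float, float] = (110.0, 140.0)
    notch: float = 50.0
    target_fs: float = 400.0
    # design
    bin_dur: float = 0.5
    lags: tuple[float, ...] = (0.0, 0.5, 1.0)
    # encoding
    lambda_min: float = 10.0
    lambda_max: float = 10000.0
    n_lambda: int = 20
    k_folds: int = 5
    # inference
    n_perm: int = 5000
    n_perm_inclusion: int = 199   # per-participant inclusion p for the weight stage
    alpha: float = 0.05
    # weight analysis
    five_complex: bool = False
    # synthetic cohort
    n_blocks: int = 13
    block_dur: float = 30.0
    noise_sd: float = 2.0
    weight_scale: float = 0.3   # exponential scale of per-feature true effects
    complex_age_slope: float = 0.0
    voice_gain: float = 1.0
    # reproducibility
    seed: int = 0

    def __post_init__(self) -> None:
        if self.band[0] >= self.band[1]:
            raise SchemaError("config field 'band': low edge must be below high")
        for name in ("notch", "target_fs", "bin_dur", "lambda_min", "lambda_max",
                     "block_dur", "noise_sd"):
            if getattr(self, name) <= 0:
                raise SchemaError(f"config field {name!r} must be positive")
        if self.n_lambda < 1 or self.k_folds < 2 or self.n_perm < 1:
            raise SchemaError(
                "config fields 'n_lambda'/'k_folds'/'n_perm' out of range"
            )
        if not 0 < self.alpha < 1:
            raise SchemaError("config field 'alpha' must lie in (0, 1)")
        self.band = tuple(float(v) for v in self.band)
        self.lags = tuple(float(v) for v in self.lags)

    @property
    def lambda_grid(self) -> np.ndarray:
        return np.logspace(
            np.log10(self.lambda_min), np.log10(self.lambda_max), self.n_lambda
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def digest(self) -> str:
        """Stable hash of the configuration, recorded in run manifests."""
        blob = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]
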