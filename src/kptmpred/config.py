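"""Pipeline configuration.

One flat record of every knob in the workflow, with defaults that
reproduce the reference protocol: ζ = 24 (49-residue windows), all four
encoders with CKSAAP spacings k = 0..4, 1:1 hardness undersampling,
ANOVA/IFS grid step 50 with 100 selected features, SVMs at C = 1 and
γ = 1/n_features, and 5 repeats of 5-fold cross-validation.  Configs
load from a TOML file whose keys match the field names.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from .errors import ConfigError


@dataclass
class PipelineConfig:
    zeta: int = 24
    encoders: tuple[str, ...] = ("aaf", "be", "cksaap", "coupling")
    k_values: tuple[int, ...] = (0, 1, 2, 3, 4)
    pseudocount: float = 1e-4
    undersample_ratio: float = 1.0
    undersample_folds: int = 5
    undersample_seed: int = 0
    selection_mode: str = "global"  # or "leakage-safe"
    grid_step: int = 50
    n_features: int = 100
    svm_c: float = 1.0
    svm_gamma: float | str = "auto"  # "auto" = 1/n_features
    cv_folds: int = 5
    cv_repeats: int = 5
    cv_seeds: tuple[int, ...] = (0, 1, 2, 3, 4)
    metrics_convention: str = "null"  # or "strict"

    def __post_init__(self):
        if self.selection_mode not in ("global", "leakage-safe"):
            raise ConfigError(
                f"selection_mode {self.selection_mode!r} must be "
                "'global' or 'leakage-safe'")
        if self.metrics_convention not in ("null", "strict"):
            raise ConfigError("metrics_convention must be 'null' or 'strict'")
        if len(self.cv_seeds) != self.cv_repeats:
            raise ConfigError("cv_seeds must supply one seed per repeat")

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        with open(path, "rb") as fh:
            data = tomllib.load(fh)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        for key in ("encoders", "k_values", "cv_seeds"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Short stable hash identifying this configuration."""
        text = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(text.encode()).hexdigest()[:12]
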