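"""Run configuration: one validated object that fixes every knob.

A run is fully determined by its config (seeds included), so identical
configs on identical inputs yield identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .features import FeatureConfig
from .preprocessing import PreprocessConfig


@dataclass(frozen=True)
class SelectionConfig:
    """Feature-selection knobs.

    ``scope='per_fold'`` (default) refits selection inside each
    cross-validation training fold, keeping test folds unseen;
    ``'global'`` performs one selection on the full dataset before
    cross-validation, which yields a single feature set for the whole
    study at the cost of information leakage into the folds.
    """

    C: float = 1.0
    aggregation: str = "mean_abs"
    scope: str = "per_fold"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValueError("C must be positive")
        if self.aggregation not in ("mean_abs", "max_abs"):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        if self.scope not in ("per_fold", "global"):
            raise ValueError(f"unknown selection scope {self.scope!r}")


@dataclass(frozen=True)
class CVConfig:
    k: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 2:
            raise ValueError("k must be >= 2")


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    seed: int = 0
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    cv: CVConfig = field(default_factory=CVConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def digest(self) -> str:
        """Short stable hash identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from a YAML file; absent blocks keep defaults."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(data, dict):
        raise ValueError("config file must contain a mapping")
    known = {"seed", "preprocessing", "features", "selection", "cv"}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(
        seed=int(data.get("seed", 0)),
        preprocessing=PreprocessConfig(**data.get("preprocessing", {})),
        features=FeatureConfig(**data.get("features", {})),
        selection=SelectionConfig(**data.get("selection", {})),
        cv=CVConfig(**data.get("cv", {})),
    )
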