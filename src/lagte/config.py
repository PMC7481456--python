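"""Run configuration: estimator, embedding, lag and surrogate settings.

Defaults are the analysis settings of the study this package implements:
L_max = 10 candidates per process, maximum lag 15, 100 time-shift
surrogates with maximum shift 20 and a 95th-percentile significance
threshold, k = 10 nearest neighbors.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .embedding import SelectionPolicy
from .estimators import EstimatorParams

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass
class RunConfig:
    estimator: EstimatorParams = field(default_factory=EstimatorParams)
    embedding: SelectionPolicy = field(default_factory=SelectionPolicy)
    tau_max: int = 15
    n_surrogates: int = 100
    max_shift: int = 20
    seed: int = 0
    verbose: bool = False

    def __post_init__(self):
        if self.tau_max < 0:
            raise ValueError("tau_max must be >= 0")
        if self.n_surrogates < 1 or self.max_shift < 1:
            raise ValueError("surrogate settings must be positive")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        est = d.pop("estimator", {}) or {}
        emb = d.pop("embedding", {}) or {}
        unknown = set(d) - {"tau_max", "n_surrogates", "max_shift", "seed",
                            "verbose"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(estimator=EstimatorParams(**est),
                   embedding=SelectionPolicy(**emb), **d)


def load_config(path: str | None) -> RunConfig:
    """RunConfig from a YAML/JSON file (defaults when path is None)."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return RunConfig()
    if not isinstance(data, dict):
        raise ValueError(f"config file {path} must hold a mapping")
    return RunConfig.from_dict(data)


def config_hash(config: RunConfig) -> str:
    """Stable hash of the resolved configuration (logged by every run)."""
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(blob.encode()).hexdigest()[:16]
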