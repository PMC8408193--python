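"""Run configuration: validated defaults, YAML loading, provenance hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import yaml

from .errors import ParameterError

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Pipeline parameters; every default is the pipeline's stated value."""

    fps: float = 60.0
    variance_target: float = 0.7
    n_neighbors: int = 60
    min_dist: float = 0.0
    metric: str = "euclidean"
    min_cluster_size: float = 0.01
    holdout: float = 0.2
    min_bout_samples: int = 3
    smoothing_ms: float = 60.0
    bin_ms: float = 100.0
    seed: int = 0
    signed_angles: bool = False
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ParameterError("fps must be positive")
        if not 0 < self.variance_target <= 1:
            raise ParameterError("variance_target must lie in (0, 1]")
        if self.n_neighbors < 2:
            raise ParameterError("n_neighbors must be >= 2")
        if self.min_dist < 0:
            raise ParameterError("min_dist must be >= 0")
        if self.min_cluster_size <= 0:
            raise ParameterError("min_cluster_size must be positive")
        if not 0 < self.holdout < 1:
            raise ParameterError("holdout must lie in (0, 1)")
        if self.min_bout_samples < 1:
            raise ParameterError("min_bout_samples must be >= 1")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as f:
            raw = yaml.safe_load(f) or {}
        known = cls.__dataclass_fields__
        unknown = set(raw) - set(known)
        if unknown:
            raise ParameterError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        """Short stable digest identifying this configuration."""
        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()[:12]

    def dump(self, path) -> None:
        """Echo the config (plus its hash) next to produced artifacts."""
        payload = self.to_dict() | {"config_hash": self.hash}
        with open(path, "w") as f:
            json.dump(payload, f, indent=2, sort_keys=True)
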