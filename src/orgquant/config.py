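"""Run configuration: all tunables with defaults, validation, and hashing."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields

from .errors import ParameterError


@dataclass
class RunConfig:
    erosion_radius: int = 3
    connectivity: int = 8
    min_area: int = 500
    epsilon_rel: float = 0.009
    increments: int = 10
    stationary_px: float = 2.0
    path_width: int = 3
    threshold_method: str = "otsu"
    threshold_value: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.erosion_radius < 0:
            raise ParameterError("erosion_radius must be >= 0")
        if self.connectivity not in (4, 8):
            raise ParameterError("connectivity must be 4 or 8")
        if self.min_area < 0:
            raise ParameterError("min_area must be >= 0")
        if self.epsilon_rel <= 0:
            raise ParameterError("epsilon_rel must be > 0")
        if self.increments < 2:
            raise ParameterError("increments must be >= 2")
        if self.stationary_px < 0:
            raise ParameterError("stationary_px must be >= 0")
        if self.path_width < 1:
            raise ParameterError("path_width must be >= 1")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ParameterError("threshold_method must be 'otsu' or 'fixed'")
        if self.threshold_method == "fixed" and self.threshold_value is None:
            raise ParameterError("threshold_method 'fixed' needs threshold_value")

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_file(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ParameterError(f"config file {path} must hold a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration for provenance manifests."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
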