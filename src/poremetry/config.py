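"""Pipeline configuration: one serializable record of every tunable.

Defaults reproduce the published measurement settings: 2.34 nm/px pixel
pitch, 275 nm^2 minimum lumen area, the Table-1 radius classes, and 20 nm
depth bins up to 400 nm from the cell interface.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields, replace

from .errors import InvalidParameterError


@dataclass(frozen=True)
class PipelineConfig:
    pixel_pitch_nm: float = 2.34
    background_scale_px: float = 64.0
    tv_weight: float = 18.0
    tv_max_iter: int = 200
    tv_tol: float = 2e-4
    shock_sigma_px: float = 1.0
    shock_rho_px: float = 3.0
    shock_n_iter: int = 10
    shock_dt: float = 0.25
    threshold_method: str = "otsu"
    threshold: float | None = None
    polarity: str = "auto"
    min_lumen_area_nm2: float = 275.0
    bin_scheme: str = "rpr_table1"
    depth_edges_nm: tuple[float, ...] = field(
        default_factory=lambda: tuple(float(e) for e in range(0, 401, 20)))
    n_min_per_depth: int = 30
    seed: int = 0

    def __post_init__(self):
        if self.pixel_pitch_nm <= 0:
            raise InvalidParameterError("pixel_pitch_nm must be positive")
        if self.min_lumen_area_nm2 < 0:
            raise InvalidParameterError("min_lumen_area_nm2 must be >= 0")
        object.__setattr__(self, "depth_edges_nm",
                           tuple(float(e) for e in self.depth_edges_nm))

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **{k: v for k, v in kwargs.items() if v is not None})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise InvalidParameterError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        import yaml

        data = self.to_dict()
        data["depth_edges_nm"] = list(data["depth_edges_nm"])
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=True)
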