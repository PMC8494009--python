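"""Run configuration: model, grid and detector settings with per-model defaults.

A :class:`RunConfig` bundles everything needed to reproduce an analysis
run: the kinetics and parameter set, grid spec, the thresholds
``V_star``/``R_star``, the LAT frame interval ``dt_lat``, the CBL
threshold ``dt_c``, the PDL thresholds (``dphi_crit`` on activation
phase, ``dphi_arr_crit`` on arrival-time phase), the arrival-phase
timescale ``tau``, the PS method, the tracking window and the seed.
Unset numeric fields resolve to the chosen model's defaults.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

from .kinetics import get_kinetics

__all__ = ["RunConfig"]

_MODEL_DEFAULT_KEYS = ("dx", "dt", "V_star", "R_star", "dt_lat",
                       "dt_c", "dphi_arr_crit", "tau")


@dataclass(frozen=True)
class RunConfig:
    kinetics: str = "fk"
    param_set: str | None = None
    nx: int = 100
    ny: int = 100
    nz: int | None = None
    dx: float | None = None
    dt: float | None = None
    V_star: float | None = None
    R_star: float | None = None
    dt_lat: float | None = None
    dt_c: float | None = None
    dphi_arr_crit: float | None = None
    tau: float | None = None
    dphi_crit: float = 2.22
    ps_method: str = "ring2x2_4x4"
    track_start: float | None = None
    track_stop: float | None = None
    seed: int = 0

    def resolved(self) -> "RunConfig":
        """Fill unset fields from the kinetics model's defaults."""
        kin = get_kinetics(self.kinetics, self.param_set)
        updates = {"param_set": kin.param_set}
        for key in _MODEL_DEFAULT_KEYS:
            if getattr(self, key) is None:
                updates[key] = float(kin.defaults[key])
        cfg = replace(self, **updates)
        for key in ("dt_lat", "dt_c", "tau"):
            if getattr(cfg, key) <= 0:
                raise ValueError(f"{key} must be positive")
        return cfg

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)
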