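"""Run configuration: YAML parsing, validation and default echoing."""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional, Union

import yaml
from pydantic import BaseModel, Field, ValidationError, model_validator


class ConfigError(ValueError):
    """Configuration invalid; message lists offending field paths."""


class TubeConfig(BaseModel):
    axis_point: tuple = (0.0, 0.0, 0.0)
    axis_dir: tuple = (0.0, 0.0, 1.0)
    radius: float = Field(gt=0)
    z_range: tuple

    @model_validator(mode="after")
    def _check(self):
        if len(self.axis_point) != 3 or len(self.axis_dir) != 3:
            raise ValueError("axis_point/axis_dir must be 3-vectors")
        if len(self.z_range) != 2 or not self.z_range[1] > self.z_range[0]:
            raise ValueError("z_range must be (lo, hi) with hi > lo")
        return self

    def to_geometry(self):
        from .trajectory import TubeGeometry
        return TubeGeometry(axis_point=self.axis_point, axis_dir=self.axis_dir,
                            radius=self.radius, z_range=tuple(self.z_range))


class TrajectoryEntry(BaseModel):
    temperature: float = Field(gt=0)
    path: str
    format: Optional[str] = None
    topology: Optional[str] = None


class SyntheticSweep(BaseModel):
    """Per-temperature Fickian trajectories with Arrhenius-law D(T)."""

    temperatures: list[float]
    D0: float = Field(default=50.0, gt=0)   # 1e-5 cm²/s
    dU: float = 20.0                        # kJ/mol
    n_molecules: int = Field(default=100, gt=0)
    n_frames: int = Field(default=5000, gt=1)
    shells: list[tuple[float, float, float]] = [(4.0, 0.3, 1.0)]


class HBondConfig(BaseModel):
    r_max: float = Field(default=3.50, gt=0)
    angle_max: float = Field(default=30.0, gt=0, lt=90)
    angle_vertex: Literal["donor", "hydrogen"] = "donor"


class MSDConfig(BaseModel):
    window: float = Field(default=1000.0, gt=0)
    sampling: float = Field(default=1.0, gt=0)
    n_intervals: int = Field(default=50, gt=0)


class RDFConfig(BaseModel):
    bin_width: float = Field(default=0.05, gt=0)
    r_max: Optional[float] = None


class RunConfig(BaseModel):
    dt: float = Field(gt=0)
    tube: TubeConfig
    trajectories: Optional[list[TrajectoryEntry]] = None
    synthetic: Optional[SyntheticSweep] = None
    shells: Union[Literal["auto"], list[float]] = "auto"
    hbond: HBondConfig = HBondConfig()
    msd: MSDConfig = MSDConfig()
    rdf: RDFConfig = RDFConfig()
    radial_bin_width: float = Field(default=0.2, gt=0)
    transition_threshold: float = Field(default=0.15, gt=0)
    seed: int = 0
    outdir: str = "cntwater_out"

    @model_validator(mode="after")
    def _cross_checks(self):
        if (self.trajectories is None) == (self.synthetic is None):
            raise ValueError(
                "exactly one of 'trajectories' or 'synthetic' must be given")
        if isinstance(self.shells, list):
            bounds = self.shells
            if len(bounds) < 2 or any(b2 <= b1 for b1, b2
                                      in zip(bounds, bounds[1:])):
                raise ValueError("shells: boundaries must be ascending, >= 2 values")
            if bounds[-1] > self.tube.radius + 1e-9:
                raise ValueError("shells: boundaries exceed tube radius")
            if bounds[0] < 0:
                raise ValueError("shells: boundaries must be non-negative")
        return self


def validate_config(path) -> RunConfig:
    """Parse + validate a YAML config; raise ConfigError naming each bad field."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ConfigError("config must be a YAML mapping")
    try:
        cfg = RunConfig(**raw)
    except ValidationError as exc:
        lines = []
        for err in exc.errors():
            loc = ".".join(str(p) for p in err["loc"]) or "<root>"
            lines.append(f"{loc}: {err['msg']}")
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(lines))
    if cfg.trajectories:
        missing = [e.path for e in cfg.trajectories if not Path(e.path).exists()]
        if missing:
            raise ConfigError("trajectories: missing files: " + ", ".join(missing))
    return cfg
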