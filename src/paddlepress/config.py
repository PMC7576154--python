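"""Analysis configuration: every parameter has a default; unknown keys
are rejected with the offending key named."""
from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields, asdict
from pathlib import Path

import yaml

from .errors import ConfigError


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"config section '{context}' must be a mapping")
    known = {f.name for f in dc_fields(cls)}
    for key in data:
        if key not in known:
            raise ConfigError(f"unknown config key '{context}.{key}'".lstrip("."))
    kwargs = {}
    for f in dc_fields(cls):
        if f.name not in data:
            continue
        sub = _SECTIONS.get((cls, f.name))
        if sub is not None:
            kwargs[f.name] = _build(sub, data[f.name], f"{context}.{f.name}".lstrip("."))
        else:
            kwargs[f.name] = data[f.name]
    return cls(**kwargs)


@dataclass
class PathsConfig:
    velocity: str = "velocity.txt"
    images: str | None = None
    contours: str | None = None          # pattern with {frame:03d}
    centerlines: str | None = "centerline_{frame:03d}.csv"
    cohort: str | None = None


@dataclass
class FluidConfig:
    density: float = 1025.0                  # kg/m^3, seawater 10-12 degC
    kinematic_viscosity: float = 1.35e-6     # m^2/s


@dataclass
class CalibrationConfig:
    pixel_size: float | None = None          # m; overrides TIFF tags


@dataclass
class MaskingConfig:
    threshold_method: str = "otsu"
    min_area_px: int = 50
    smoothing_window: int = 5
    dilation_cells: int = 1
    invert: bool = False
    centerline_half_width: float = 7.5e-5    # m, when masks come from centerlines


@dataclass
class ForcesConfig:
    n_segments: int = 64
    probe_offset_cells: float = 3.0


@dataclass
class ProfilesConfig:
    delta_cells: float = 4.0                 # offset distance in grid cells


@dataclass
class KinematicsConfig:
    n_points: int = 101


@dataclass
class StatsConfig:
    alpha: float = 0.05
    pairwise_method: str = "ttest"
    paired_on: str | None = "individual"


@dataclass
class AnalysisConfig:
    paths: PathsConfig = field(default_factory=PathsConfig)
    fluid: FluidConfig = field(default_factory=FluidConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    masking: MaskingConfig = field(default_factory=MaskingConfig)
    forces: ForcesConfig = field(default_factory=ForcesConfig)
    profiles: ProfilesConfig = field(default_factory=ProfilesConfig)
    kinematics: KinematicsConfig = field(default_factory=KinematicsConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    thrust_axis: list | str = field(default_factory=lambda: [0.0, 1.0])  # or "auto"
    stroke_window: list | None = None        # [start, end] frames, None = full
    seed: int = 0
    figures: bool = False

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        return _build(cls, data or {}, "")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})

    def to_dict(self) -> dict:
        return asdict(self)


_SECTIONS = {
    (AnalysisConfig, "paths"): PathsConfig,
    (AnalysisConfig, "fluid"): FluidConfig,
    (AnalysisConfig, "calibration"): CalibrationConfig,
    (AnalysisConfig, "masking"): MaskingConfig,
    (AnalysisConfig, "forces"): ForcesConfig,
    (AnalysisConfig, "profiles"): ProfilesConfig,
    (AnalysisConfig, "kinematics"): KinematicsConfig,
    (AnalysisConfig, "stats"): StatsConfig,
}
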