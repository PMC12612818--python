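"""Typed configuration objects for every pipeline stage.

Each dataclass validates itself on construction and can be built from a
plain mapping (e.g. a parsed YAML section) via :func:`build_config`, which
rejects unknown keys with a message naming the offending key.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Any, Mapping


class ConfigError(ValueError):
    """Raised when a configuration value is missing, unknown or out of bounds."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the synthetic co-culture movie generator.

    The defaults emulate the imaging setup of the study this package
    reproduces: a phase-contrast field observed at sub-second cadence over
    ~1.5 min, containing large fast flagellated protists and far fewer
    small slow rod-shaped bacteria (1:10 bacteria-to-protist count ratio,
    protists at 2.5e5 cells/mL which works out to ~20 cells in a
    ~0.9 x 0.9 mm field of ~100 um depth).

    Speeds are per-cell and log-normal across the population:
    ``*_speed_dist = (median um/s, sigma of log)``.  Shape parameters are
    physical: flagellate ellipse *semi*-axes and bacterial rod full
    (length, width), all in micrometres.
    """

    field_width_px: int = 384
    field_height_px: int = 384
    n_frames: int = 100
    pixel_size_um: float = 1.8
    frame_interval_s: float = 0.09
    n_flagellates: int = 20
    n_bacteria: int = 2
    flagellate_speed_dist: tuple[float, float] = (6.6, 0.35)
    bacteria_speed_dist: tuple[float, float] = (2.0, 0.35)
    flagellate_turn_sd_rad: float = 0.25
    bacteria_turn_sd_rad: float = 0.8
    flagellate_axes_um: tuple[float, float] = (4.5, 2.7)
    bacteria_dims_um: tuple[float, float] = (2.0, 0.8)
    flagellate_intensity: float = 120.0
    bacteria_intensity: float = 60.0
    background_level: float = 20.0
    noise_sd: float = 3.0
    classifier_noise_sd: float = 6.0
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.field_width_px > 0 and self.field_height_px > 0,
                 "field dimensions must be positive")
        _require(self.n_frames > 0, "n_frames must be positive")
        _require(self.pixel_size_um > 0, "pixel_size_um must be > 0")
        _require(self.frame_interval_s > 0, "frame_interval_s must be > 0")
        _require(self.n_flagellates >= 0 and self.n_bacteria >= 0,
                 "cell counts must be >= 0")
        for name in ("flagellate_speed_dist", "bacteria_speed_dist"):
            med, disp = getattr(self, name)
            _require(med >= 0, f"{name}: median speed must be >= 0")
            _require(disp >= 0, f"{name}: dispersion must be >= 0")
        _require(self.flagellate_turn_sd_rad >= 0 and self.bacteria_turn_sd_rad >= 0,
                 "turning-noise SDs must be >= 0")
        _require(min(self.flagellate_axes_um) > 0, "flagellate_axes_um must be > 0")
        _require(min(self.bacteria_dims_um) > 0, "bacteria_dims_um must be > 0")
        _require(self.noise_sd >= 0 and self.classifier_noise_sd >= 0,
                 "noise SDs must be >= 0")
        _require(0 <= self.background_level <= 255, "background_level in [0, 255]")


@dataclass(frozen=True)
class SegmentationParams:
    """Probability-map post-processing chain parameters.

    Defaults are the published operator chain: subtract 50 grey levels,
    Gaussian filter sigma 2.0 px, histogram-minimum global threshold,
    exclude particles with area > 40 px or circularity < 0.25, then 3-D
    Gaussian blur with sigma 1.0 in x, y and frame.
    """

    subtract_value: int = 50
    gaussian_sigma: float = 2.0
    threshold_method: str = "minimum"
    max_area_px: int = 40
    min_circularity: float = 0.25
    temporal_sigma: tuple[float, float, float] = (1.0, 1.0, 1.0)
    connectivity: int = 8
    per_stack_threshold: bool = False
    fallback_threshold: int | None = None

    def __post_init__(self) -> None:
        _require(0 <= self.subtract_value <= 255, "subtract_value must be in [0, 255]")
        _require(self.gaussian_sigma >= 0, "gaussian_sigma must be >= 0")
        _require(self.threshold_method == "minimum",
                 f"unknown threshold_method {self.threshold_method!r}")
        _require(self.max_area_px > 0, "max_area_px must be > 0")
        _require(0 <= self.min_circularity <= 1, "min_circularity must be in [0, 1]")
        _require(all(s >= 0 for s in self.temporal_sigma),
                 "temporal_sigma values must be >= 0")
        _require(self.connectivity in (4, 8), "connectivity must be 4 or 8")
        if self.fallback_threshold is not None:
            _require(0 <= self.fallback_threshold <= 255,
                     "fallback_threshold must be in [0, 255]")


@dataclass(frozen=True)
class LinkingParams:
    """Greedy nearest-neighbour frame-to-frame linking parameters."""

    max_link_dist_px: float = 8.0
    max_gap_frames: int = 0
    min_track_spots: int = 3

    def __post_init__(self) -> None:
        _require(self.max_link_dist_px > 0, "max_link_dist_px must be > 0")
        _require(self.max_gap_frames >= 0, "max_gap_frames must be >= 0")
        _require(self.min_track_spots >= 2, "min_track_spots must be >= 2")


@dataclass(frozen=True)
class Calibration:
    """Spatial and temporal calibration used to convert px/frame to um/s."""

    pixel_size_um: float
    frame_interval_s: float

    def __post_init__(self) -> None:
        _require(self.pixel_size_um > 0, "pixel_size_um must be > 0")
        _require(self.frame_interval_s > 0, "frame_interval_s must be > 0")


def default_link_distance(config: SimulationConfig,
                          expected_max_speed_um_s: float = 25.0) -> float:
    """Linking radius from calibration: 1.5x the expected maximum per-frame step."""
    step = expected_max_speed_um_s * config.frame_interval_s / config.pixel_size_um
    return max(1.5 * step, 2.0)


def build_config(cls: type, raw: Mapping[str, Any] | None, section: str = ""):
    """Instantiate a config dataclass from a mapping, rejecting unknown keys."""
    raw = dict(raw or {})
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = sorted(set(raw) - names)
    if unknown:
        where = f" in section {section!r}" if section else ""
        raise ConfigError(f"unknown configuration key(s){where}: {', '.join(unknown)}")
    # YAML yields lists where the dataclasses expect tuples
    for f in dataclasses.fields(cls):
        if f.name in raw and isinstance(raw[f.name], list):
            raw[f.name] = tuple(raw[f.name])
    missing = [f.name for f in dataclasses.fields(cls)
               if f.default is dataclasses.MISSING
               and f.default_factory is dataclasses.MISSING
               and f.name not in raw]
    if missing:
        where = f" in section {section!r}" if section else ""
        raise ConfigError(f"missing required key(s){where}: {', '.join(missing)}")
    try:
        return cls(**raw)
    except TypeError as exc:  # wrong value type
        raise ConfigError(f"invalid configuration for {section or cls.__name__}: {exc}")
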