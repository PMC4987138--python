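"""Assay configuration: arena geometry, calibration, thresholds, protocol timings.

All distances are millimetres, durations seconds, speeds mm/s, luminances cd/m^2.
Coordinates are dish-centred: x rightward, y upward, pixel centres at integer
pixel coordinates, converted through ``mm_per_pixel``.
"""

from __future__ import annotations

import dataclasses
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Missing or ill-typed configuration key."""


class ValidationError(ValueError):
    """A configuration value violates an invariant."""


@dataclass
class AssayConfig:
    """Parameters of the dot-avoidance assay.

    Defaults are the published protocol: 100 mm dish, 30 Hz video, eight
    animals per dish, 5 mm encounter radius, 24 mm/s avoidance threshold,
    0.25 s response window, 3 min pre-test with background-isoluminant
    ("invisible") dots followed by a 5 min test, 10 mm dots moving at
    2 cm/s, photopic background of 190 cd/m^2.
    """

    dish_diameter: float = 100.0      # mm
    mm_per_pixel: float = 0.5         # calibration (user-supplied for real video)
    frame_rate: float = 30.0          # Hz
    n_animals: int = 8
    encounter_radius: float = 5.0     # mm
    avoidance_delta_v: float = 24.0   # mm/s
    response_window: float = 0.25     # s
    smoothing_sigma: float = 2.0      # frames
    pretest_duration: float = 180.0   # s
    test_duration: float = 300.0      # s
    background_luminance: float = 190.0  # cd/m^2 (photopic); mesopic is 0.65
    dot_luminance: float = 0.0        # cd/m^2 (dark dots)
    dot_diameter: float = 10.0        # mm
    dot_speed: float = 20.0           # mm/s
    size_range: tuple[float, float] = (10.0, 60.0)  # mm^2 blob-area bounds
    seed: int = 0

    def __post_init__(self) -> None:
        self.size_range = tuple(float(v) for v in self.size_range)  # type: ignore[assignment]
        self.validate()

    # -- derived quantities ------------------------------------------------
    @property
    def dish_radius(self) -> float:
        return self.dish_diameter / 2.0

    @property
    def dot_radius(self) -> float:
        return self.dot_diameter / 2.0

    @property
    def response_window_frames(self) -> int:
        """Number of frames after onset inspected by the scorer."""
        return math.ceil(self.response_window * self.frame_rate)

    def validate(self) -> None:
        positive = [
            "dish_diameter", "mm_per_pixel", "frame_rate", "n_animals",
            "encounter_radius", "avoidance_delta_v", "response_window",
            "smoothing_sigma", "pretest_duration", "test_duration",
            "dot_diameter", "dot_speed",
        ]
        for name in positive:
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be strictly positive, got {getattr(self, name)!r}")
        if self.background_luminance <= 0:
            raise ValidationError("background_luminance must be strictly positive")
        if self.dot_luminance < 0:
            raise ValidationError("dot_luminance must be nonnegative")
        if self.encounter_radius >= self.dish_radius:
            raise ValidationError("encounter_radius must be smaller than the dish radius")
        if self.response_window * self.frame_rate < 1:
            raise ValidationError("response_window * frame_rate must cover at least one frame")
        if self.dot_luminance > self.background_luminance:
            raise ValidationError("dot_luminance must not exceed background_luminance (dots are dark or isoluminant)")
        lo, hi = self.size_range
        if not (0 < lo < hi):
            raise ValidationError(f"size_range must satisfy 0 < low < high, got {self.size_range}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["size_range"] = list(self.size_range)
        return d


_FIELD_TYPES = {f.name: f.type for f in dataclasses.fields(AssayConfig)}


def _coerce(name: str, value):
    if name == "size_range":
        if not (isinstance(value, (list, tuple)) and len(value) == 2):
            raise ConfigError(f"key 'size_range' must be a two-element list, got {value!r}")
        return tuple(float(v) for v in value)
    target = {"n_animals": int, "seed": int}.get(name, float)
    if isinstance(value, bool) or not isinstance(value, (int, float)):
        raise ConfigError(f"key {name!r} must be numeric, got {value!r}")
    if target is int and float(value) != int(value):
        raise ConfigError(f"key {name!r} must be an integer, got {value!r}")
    return target(value)


def load_config(path: str | Path) -> AssayConfig:
    """Load a flat key-value (YAML) configuration file.

    Absent keys take the protocol defaults; unknown keys warn but never fail.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path} does not parse as a key-value document")
    kwargs = {}
    for key, value in doc.items():
        if key not in _FIELD_TYPES:
            log.warning("unknown configuration key %r ignored", key)
            continue
        kwargs[key] = _coerce(key, value)
    cfg = AssayConfig(**kwargs)
    log.info("resolved configuration: %s", cfg.to_dict())
    return cfg


def save_config(config: AssayConfig, path: str | Path) -> None:
    """Write the configuration as a flat YAML document (lossless round-trip)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
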