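"""Moving-dot stimulus generation and frame rendering.

Dots follow a ballistic random walk: straight constant-speed runs whose
durations are exponentially distributed, a uniformly random new heading after
each run, and specular reflection at the dish wall. Dots may be rendered dark
against the bright background or flagged invisible (background-isoluminant),
in which case a rendered frame is pixel-identical to an empty arena.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AssayConfig
from .io import frame_shape, mm_to_px


@dataclass
class DotTrajectorySet:
    """Per-frame dot positions with constant per-dot diameter and luminance.

    ``positions`` has shape (n_dots, n_frames, 2) in dish-centred mm.
    """

    positions: np.ndarray
    diameters: np.ndarray      # (n_dots,) mm
    luminances: np.ndarray     # (n_dots,) cd/m^2
    frame_rate: float
    visible: bool = True
    dot_ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[-1] != 2:
            raise ValueError("positions must have shape (n_dots, n_frames, 2)")
        self.diameters = np.broadcast_to(
            np.asarray(self.diameters, dtype=float), (self.n_dots,)).copy()
        self.luminances = np.broadcast_to(
            np.asarray(self.luminances, dtype=float), (self.n_dots,)).copy()
        if self.dot_ids is None:
            self.dot_ids = np.arange(self.n_dots)

    @property
    def n_dots(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def to_frame(self) -> pd.DataFrame:
        """Stimulus log: one row per (frame, dot)."""
        n_d, n_f = self.n_dots, self.n_frames
        return pd.DataFrame({
            "frame": np.tile(np.arange(n_f), n_d),
            "dot_id": np.repeat(self.dot_ids, n_f),
            "x_mm": self.positions[:, :, 0].ravel(),
            "y_mm": self.positions[:, :, 1].ravel(),
            "luminance": np.repeat(self.luminances, n_f),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_rate: float,
                   diameter: float, visible: bool = True) -> "DotTrajectorySet":
        if len(df) == 0:
            return cls(positions=np.empty((0, 0, 2)), diameters=np.empty(0),
                       luminances=np.empty(0), frame_rate=frame_rate, visible=visible)
        ids = np.sort(df["dot_id"].unique())
        n_frames = int(df["frame"].max()) + 1
        pos = np.full((len(ids), n_frames, 2), np.nan)
        lum = np.zeros(len(ids))
        for i, d in enumerate(ids):
            sub = df[df["dot_id"] == d].sort_values("frame")
            pos[i, sub["frame"].to_numpy(), 0] = sub["x_mm"].to_numpy()
            pos[i, sub["frame"].to_numpy(), 1] = sub["y_mm"].to_numpy()
            lum[i] = sub["luminance"].iloc[0]
        return cls(positions=pos, diameters=diameter, luminances=lum,
                   frame_rate=frame_rate, visible=visible, dot_ids=ids)


def _reflect_step(pos: np.ndarray, heading: float, step: float,
                  r_max: float) -> tuple[np.ndarray, float]:
    """Advance one straight step with specular reflection at radius ``r_max``."""
    remaining = step
    pos = pos.copy()
    for _ in range(8):  # multiple bounces in one frame are vanishingly rare
        d = np.array([np.cos(heading), np.sin(heading)])
        nxt = pos + remaining * d
        if nxt @ nxt <= r_max * r_max:
            return nxt, heading
        # solve |pos + t*d| = r_max for the crossing fraction t in (0, remaining]
        b = pos @ d
        c = pos @ pos - r_max * r_max
        t = -b + np.sqrt(b * b - c)
        t = min(max(t, 0.0), remaining)
        hit = pos + t * d
        n = hit / np.linalg.norm(hit)           # outward wall normal
        d_ref = d - 2.0 * (d @ n) * n           # specular reflection
        heading = float(np.arctan2(d_ref[1], d_ref[0]))
        pos = hit
        remaining -= t
        if remaining <= 0:
            return pos, heading
    return pos, heading


def generate_dot_walk(config: AssayConfig, n_dots: int = 5,
                      duration: float | None = None, seed: int | None = None,
                      mean_run_time: float = 1.0,
                      visible: bool = True) -> DotTrajectorySet:
    """Generate ballistic random-walk dot trajectories in the circular arena.

    Each dot moves at ``config.dot_speed`` along straight runs; run durations
    are exponential with mean ``mean_run_time`` seconds, the heading after
    each run is uniform, and the dot reflects specularly off the wall at
    dish radius minus dot radius. Trajectories are independent across dots.
    """
    if duration is None:
        duration = config.test_duration
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n_frames = int(round(duration * config.frame_rate))
    if n_dots <= 0 or n_frames <= 0:
        return DotTrajectorySet(positions=np.empty((max(n_dots, 0), 0, 2)),
                                diameters=config.dot_diameter,
                                luminances=config.dot_luminance,
                                frame_rate=config.frame_rate, visible=visible)
    r_max = config.dish_radius - config.dot_radius
    step = config.dot_speed / config.frame_rate
    dt = 1.0 / config.frame_rate
    pos = np.empty((n_dots, n_frames, 2))
    for i in range(n_dots):
        # uniform start position in the allowed disc
        rr = r_max * np.sqrt(rng.uniform())
        th = rng.uniform(0, 2 * np.pi)
        p = np.array([rr * np.cos(th), rr * np.sin(th)])
        heading = rng.uniform(0, 2 * np.pi)
        run_left = rng.exponential(mean_run_time)
        pos[i, 0] = p
        for t in range(1, n_frames):
            if run_left <= 0:
                heading = rng.uniform(0, 2 * np.pi)
                run_left = rng.exponential(mean_run_time)
            p, heading = _reflect_step(p, heading, step, r_max)
            run_left -= dt
            pos[i, t] = p
    lum = config.background_luminance if not visible else config.dot_luminance
    return DotTrajectorySet(positions=pos, diameters=config.dot_diameter,
                            luminances=lum, frame_rate=config.frame_rate,
                            visible=visible)


# -- rendering -------------------------------------------------------------

def luminance_to_value(luminance: float, config: AssayConfig) -> float:
    """Linear display mapping cd/m^2 -> pixel value with the background at 1.0.

    Only contrast ratios matter downstream; absolute photometry is not modelled.
    """
    return float(np.clip(luminance / config.background_luminance, 0.0, 1.0))


def _paint_disc(frame: np.ndarray, centre_rc: np.ndarray, radius_px: float,
                value: float) -> None:
    """Alpha-composite an anti-aliased filled disc onto ``frame`` in place."""
    h, w = frame.shape
    r0 = max(int(np.floor(centre_rc[0] - radius_px - 1)), 0)
    r1 = min(int(np.ceil(centre_rc[0] + radius_px + 2)), h)
    c0 = max(int(np.floor(centre_rc[1] - radius_px - 1)), 0)
    c1 = min(int(np.ceil(centre_rc[1] + radius_px + 2)), w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    d = np.hypot(rr - centre_rc[0], cc - centre_rc[1])
    alpha = np.clip(radius_px + 0.5 - d, 0.0, 1.0)
    patch = frame[r0:r1, c0:c1]
    patch *= (1.0 - alpha)
    patch += value * alpha

def _paint_ellipse(frame: np.ndarray, centre_rc: np.ndarray, axes_px: tuple[float, float],
                   heading: float, value: float) -> None:
    """Anti-aliased filled ellipse; ``heading`` is the mm-space direction of the
    major axis (x right, y up), converted to image rows/cols internally."""
    a, b = axes_px  # semi-axes in pixels
    h, w = frame.shape
    ext = max(a, b) + 2
    r0 = max(int(np.floor(centre_rc[0] - ext)), 0)
    r1 = min(int(np.ceil(centre_rc[0] + ext + 1)), h)
    c0 = max(int(np.floor(centre_rc[1] - ext)), 0)
    c1 = min(int(np.ceil(centre_rc[1] + ext + 1)), w)
    if r0 >= r1 or c0 >= c1:
        return
    rr, cc = np.mgrid[r0:r1, c0:c1]
    dx = cc - centre_rc[1]
    dy = centre_rc[0] - rr   # image rows grow downward; y grows upward
    u = dx * np.cos(heading) + dy * np.sin(heading)
    v = -dx * np.sin(heading) + dy * np.cos(heading)
    dn = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    alpha = np.clip((1.0 - dn) * min(a, b) + 0.5, 0.0, 1.0)
    patch = frame[r0:r1, c0:c1]
    patch *= (1.0 - alpha)
    patch += value * alpha


def render_frame(dots: DotTrajectorySet | None, config: AssayConfig, t: int = 0,
                 animals: np.ndarray | None = None,
                 body_axes: tuple[float, float] = (9.0, 3.0),
                 animal_luminance: float = 0.0) -> np.ndarray:
    """Render one frame: bright background, dark dots, dark animal ellipses.

    ``animals`` is an (n, 2) array of mm positions or (n, 3) with a heading
    column (radians); ``body_axes`` are full ellipse axes in mm. Invisible
    dots are skipped, so the frame equals an empty-arena render.
    """
    shape = frame_shape(config)
    if dots is not None and dots.n_frames > 0 and not (0 <= t < dots.n_frames):
        raise IndexError(f"frame index {t} out of range [0, {dots.n_frames})")
    frame = np.full(shape, luminance_to_value(config.background_luminance, config),
                    dtype=np.float64)
    if dots is not None and dots.visible and dots.n_frames > 0:
        for i in range(dots.n_dots):
            rc = mm_to_px(dots.positions[i, t], config, shape)
            _paint_disc(frame, rc, dots.diameters[i] / 2.0 / config.mm_per_pixel,
                        luminance_to_value(dots.luminances[i], config))
    if animals is not None and len(animals):
        animals = np.atleast_2d(np.asarray(animals, dtype=float))
        val = luminance_to_value(animal_luminance, config)
        ax = (body_axes[0] / 2.0 / config.mm_per_pixel,
              body_axes[1] / 2.0 / config.mm_per_pixel)
        for row in animals:
            rc = mm_to_px(row[:2], config, shape)
            heading = row[2] if row.shape[0] > 2 else 0.0
            _paint_ellipse(frame, rc, ax, heading, val)
    return frame.astype(np.float32)
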