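"""Link per-frame detections into persistent per-animal tracks.

Exactly ``n_animals`` tracks exist for the whole session (the assay films a
fixed group of animals); no track is created or destroyed mid-session.
Frame-to-frame correspondence is an optimal bipartite assignment minimizing
total squared displacement, gated by a maximum plausible per-frame
displacement. Frames where a track receives no detection are filled in
afterwards by linear interpolation between the nearest assigned positions
(held constant at the ends) and flagged as interpolated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from .config import AssayConfig
from .io import InputError

log = logging.getLogger(__name__)

#: mm/s, upper end of observed swimming speeds; the gate derives from it
MAX_PLAUSIBLE_SPEED = 200.0
GATE_SAFETY_FACTOR = 2.0
_BIG = 1e12


@dataclass
class TrackSet:
    """Per-animal, per-frame positions (mm) with interpolation flags."""

    positions: np.ndarray     # (n_animals, n_frames, 2)
    interpolated: np.ndarray  # (n_animals, n_frames) bool
    frame_rate: float

    @property
    def n_animals(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def to_frame(self) -> pd.DataFrame:
        n_a, n_f = self.positions.shape[:2]
        return pd.DataFrame({
            "frame": np.tile(np.arange(n_f), n_a),
            "animal_id": np.repeat(np.arange(n_a), n_f),
            "x_mm": self.positions[:, :, 0].ravel(),
            "y_mm": self.positions[:, :, 1].ravel(),
            "interpolated": self.interpolated.ravel(),
        })

    @classmethod
    def from_frame(cls, df: pd.DataFrame, frame_rate: float = 30.0) -> "TrackSet":
        ids = np.sort(df["animal_id"].unique())
        n_frames = int(df["frame"].max()) + 1
        pos = np.full((len(ids), n_frames, 2), np.nan)
        interp = np.zeros((len(ids), n_frames), dtype=bool)
        for i, aid in enumerate(ids):
            sub = df[df["animal_id"] == aid]
            f = sub["frame"].to_numpy()
            pos[i, f, 0] = sub["x_mm"].to_numpy()
            pos[i, f, 1] = sub["y_mm"].to_numpy()
            interp[i, f] = sub["interpolated"].to_numpy().astype(bool)
        return cls(positions=pos, interpolated=interp, frame_rate=frame_rate)


def _detection_xy(dets) -> np.ndarray:
    """Accept either Detection objects or raw (k, 2) coordinate arrays."""
    if len(dets) == 0:
        return np.empty((0, 2))
    first = dets[0]
    if hasattr(first, "centroid"):
        return np.array([d.centroid for d in dets], dtype=float)
    return np.atleast_2d(np.asarray(dets, dtype=float))


def _interpolate_track(xy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fill NaN runs linearly; hold at the ends. Returns (filled, was_missing)."""
    missing = np.isnan(xy[:, 0])
    if missing.all():
        return np.zeros_like(xy), missing
    idx = np.flatnonzero(~missing)
    t = np.arange(xy.shape[0])
    out = xy.copy()
    for k in range(2):
        out[:, k] = np.interp(t, idx, xy[idx, k])
    return out, missing


def link_tracks(detections_per_frame, config: AssayConfig,
                gate: float | None = None) -> TrackSet:
    """Assign detections across frames into ``config.n_animals`` tracks.

    ``detections_per_frame`` is a sequence (one entry per frame) of Detection
    lists or (k, 2) mm coordinate arrays. The assignment per frame pair is the
    optimal (Hungarian) matching on squared displacement; matches farther than
    the gate (default ``2 * 200 mm/s / frame_rate``) are rejected and become
    misses. Tracks not yet seeded adopt leftover detections; detections within
    a frame are canonically ordered so the result is independent of their
    input order.
    """
    n_frames = len(detections_per_frame)
    if n_frames == 0:
        raise InputError("no frames to link")
    if gate is None:
        gate = GATE_SAFETY_FACTOR * MAX_PLAUSIBLE_SPEED / config.frame_rate
    n = config.n_animals
    pos = np.full((n, n_frames, 2), np.nan)
    last = np.full((n, 2), np.nan)   # last known position per track
    stale = np.zeros(n)              # frames since the last assignment

    for t in range(n_frames):
        xy = _detection_xy(detections_per_frame[t])
        # canonical order: sort by (x, y) so input order never matters
        if len(xy):
            order = np.lexsort((xy[:, 1], xy[:, 0]))
            xy = xy[order]
        live = np.flatnonzero(~np.isnan(last[:, 0]))
        assigned_det = np.zeros(len(xy), dtype=bool)
        stale += 1
        if live.size and len(xy):
            diff = last[live, None, :] - xy[None, :, :]
            dist = np.sqrt((diff ** 2).sum(-1))
            # a track missed for k frames may have moved k times farther
            track_gate = gate * stale[live, None]
            cost = np.where(dist <= track_gate, dist ** 2, _BIG)
            ri, ci = linear_sum_assignment(cost)
            for r, c in zip(ri, ci):
                if cost[r, c] < _BIG:
                    tr = live[r]
                    pos[tr, t] = xy[c]
                    last[tr] = xy[c]
                    stale[tr] = 0
                    assigned_det[c] = True
        # leftover detections seed tracks that have never been assigned
        free_tracks = np.flatnonzero(np.isnan(last[:, 0]))
        for c in np.flatnonzero(~assigned_det):
            if not free_tracks.size:
                break
            tr, free_tracks = free_tracks[0], free_tracks[1:]
            pos[tr, t] = xy[c]
            last[tr] = xy[c]
            stale[tr] = 0

    interp = np.zeros((n, n_frames), dtype=bool)
    miss_warn = int(config.frame_rate)  # warn on gaps longer than 1 s
    for a in range(n):
        filled, missing = _interpolate_track(pos[a])
        if missing.all():
            log.warning("track %d never received a detection; placed at the origin", a)
        else:
            runs = _run_lengths(missing)
            if runs and max(runs) > miss_warn:
                log.warning("track %d has an interpolated gap of %d frames (> 1 s)",
                            a, max(runs))
        pos[a] = filled
        interp[a] = missing
    return TrackSet(positions=pos, interpolated=interp, frame_rate=config.frame_rate)


def _run_lengths(mask: np.ndarray) -> list[int]:
    runs, count = [], 0
    for v in mask:
        if v:
            count += 1
        elif count:
            runs.append(count)
            count = 0
    if count:
        runs.append(count)
    return runs


def track_video(frames, dots, config: AssayConfig,
                contrast_floor: float | None = None,
                stride: int | None = None,
                keep_detections: bool = False,
                background=None):
    """Full tracking pipeline: background, per-frame detection, linking.

    ``background`` optionally supplies a known BackgroundModel (for example
    from an empty-dish calibration clip), bypassing the temporal-median
    estimate — useful when animals rest long enough to bleed into the median.
    ``dots`` may be None (no stimulus exclusion) or a DotTrajectorySet. Known
    visible dots are excluded two ways: their rendering is painted into the
    per-frame expected background (so an animal swimming over a dot is
    segmented from the part of its body outside the dot), and any residual
    component whose centroid falls inside a dot disc is discarded.
    """
    from .detection import (BackgroundModel, default_contrast_floor,
                            detect_tadpoles, estimate_background)
    from .stimulus import render_frame
    bg = background if background is not None \
        else estimate_background(frames, stride=stride)
    if contrast_floor is None:
        contrast_floor = default_contrast_floor(frames[0], bg)
    per_frame = []
    for t in range(len(frames)):
        dots_mm = None
        bg_t = bg
        if dots is not None and dots.visible and dots.n_frames:
            ti = min(t, dots.n_frames - 1)
            dots_mm = dots.positions[:, ti, :]
            expected = render_frame(dots, config, ti)
            if expected.shape == bg.image.shape:
                bg_t = BackgroundModel(image=np.minimum(bg.image, expected),
                                       method=bg.method + "+stimulus")
        per_frame.append(detect_tadpoles(frames[t], bg_t, dots_mm, config,
                                         contrast_floor=contrast_floor,
                                         frame_index=t))
    tracks = link_tracks(per_frame, config)
    if keep_detections:
        return tracks, per_frame
    return tracks
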