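"""Video input, coordinate transforms, and table/report output.

Videos are held as a :class:`FrameStack`: ordered grayscale frames with
intensities normalized to [0, 1]. Tables go out as CSV with a JSON session
report, in physical units (mm, mm/s).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .config import AssayConfig

log = logging.getLogger(__name__)

#: extra blank pixels around the dish in rendered / expected frames
FRAME_MARGIN_PX = 4


class InputError(ValueError):
    """Unreadable, empty, or inconsistent input data."""


@dataclass
class FrameStack:
    """Ordered grayscale frames, shape (n_frames, height, width), values in [0, 1]."""

    frames: np.ndarray
    frame_rate: float
    mm_per_pixel: float

    def __post_init__(self) -> None:
        if self.frames.ndim != 3:
            raise InputError(f"frames must be 3-D (n, h, w), got shape {self.frames.shape}")

    def __len__(self) -> int:
        return self.frames.shape[0]

    def __getitem__(self, t: int) -> np.ndarray:
        return self.frames[t]

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


# -- coordinate transforms -------------------------------------------------

def frame_shape(config: AssayConfig) -> tuple[int, int]:
    """Pixel dimensions of a rendered frame covering the dish plus a margin."""
    side = int(np.ceil(config.dish_diameter / config.mm_per_pixel)) + 2 * FRAME_MARGIN_PX
    return (side, side)


def mm_to_px(xy_mm: np.ndarray, config: AssayConfig, shape: tuple[int, int]) -> np.ndarray:
    """Dish-centred mm coordinates (x right, y up) -> (row, col) pixel coordinates."""
    xy_mm = np.asarray(xy_mm, dtype=float)
    h, w = shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    out = np.empty_like(xy_mm)
    out[..., 0] = cr - xy_mm[..., 1] / config.mm_per_pixel   # row
    out[..., 1] = cc + xy_mm[..., 0] / config.mm_per_pixel   # col
    return out


def px_to_mm(rc_px: np.ndarray, config: AssayConfig, shape: tuple[int, int]) -> np.ndarray:
    """(row, col) pixel coordinates -> dish-centred mm coordinates."""
    rc_px = np.asarray(rc_px, dtype=float)
    h, w = shape
    cr, cc = (h - 1) / 2.0, (w - 1) / 2.0
    out = np.empty_like(rc_px)
    out[..., 0] = (rc_px[..., 1] - cc) * config.mm_per_pixel  # x
    out[..., 1] = (cr - rc_px[..., 0]) * config.mm_per_pixel  # y
    return out


# -- video input -----------------------------------------------------------

def _to_gray01(arr: np.ndarray) -> np.ndarray:
    arr = np.asarray(arr)
    if arr.ndim == 3 and arr.shape[-1] in (3, 4):
        arr = arr[..., :3].mean(axis=-1)  # unweighted channel mean
    arr = arr.astype(np.float32)
    if arr.max(initial=0.0) > 1.0:
        arr = arr / 255.0
    return np.clip(arr, 0.0, 1.0)


def read_video(path: str | Path, config: AssayConfig) -> FrameStack:
    """Read a video container or a directory of numbered images as a FrameStack.

    Color input is converted to single-channel luminance by an unweighted
    channel mean; 8-bit intensities are scaled to [0, 1]. When the container
    carries no fps metadata the configured frame rate is used with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such video input: {path}")
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".png", ".tif", ".tiff", ".jpg", ".jpeg", ".bmp"})
        if not files:
            raise InputError(f"no image files in directory {path}")
        frames = np.stack([_to_gray01(iio.imread(f)) for f in files])
        fps = None
    else:
        try:
            raw = iio.imread(path, index=None)
        except Exception as exc:  # unreadable container
            raise InputError(f"could not read video {path}: {exc}") from exc
        raw = np.asarray(raw)
        if raw.ndim == 2:
            raw = raw[None]
        frames = np.stack([_to_gray01(f) for f in raw])
        fps = None
        try:
            meta = iio.immeta(path)
            fps = meta.get("fps")
        except Exception:
            pass
    if frames.shape[0] == 0:
        raise InputError(f"zero frames in {path}")
    if fps is None:
        log.warning("no fps metadata in %s; falling back to config.frame_rate=%g",
                    path, config.frame_rate)
        fps = config.frame_rate
    return FrameStack(frames=frames, frame_rate=float(fps),
                      mm_per_pixel=config.mm_per_pixel)


# -- tables ----------------------------------------------------------------

TRACK_COLUMNS = ["frame", "animal_id", "x_mm", "y_mm", "interpolated"]
EVENT_COLUMNS = ["animal_id", "dot_id", "onset_frame", "offset_frame",
                 "min_distance_mm", "baseline_speed", "max_delta_v",
                 "success", "censored"]


def write_tables(tracks, events, result, outdir: str | Path) -> dict[str, Path]:
    """Write track/event CSV tables and a JSON session report into ``outdir``.

    Returns the mapping of table name to written path. ``tracks``, ``events``
    or ``result`` may be None to skip that output.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        probe = outdir / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise IOError(f"output directory {outdir} is not writable: {exc}") from exc

    written: dict[str, Path] = {}
    if tracks is not None:
        p = outdir / "tracks.csv"
        tracks.to_frame().to_csv(p, index=False)
        written["tracks"] = p
    if events is not None:
        p = outdir / "events.csv"
        rows = [e.to_row() for e in events]
        pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(p, index=False)
        written["events"] = p
    if result is not None:
        p = outdir / "session.json"
        with open(p, "w") as fh:
            json.dump(result.to_dict(), fh, indent=2)
        written["session"] = p
    return written


def read_tracks(path: str | Path):
    """Read a track table CSV back into a TrackSet (frame_rate from companion JSON
    if present, else caller supplies it via read_tracks_with_rate)."""
    from .tracking import TrackSet
    df = pd.read_csv(path)
    return TrackSet.from_frame(df)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# -- stimulus log ----------------------------------------------------------

STIMULUS_COLUMNS = ["frame", "dot_id", "x_mm", "y_mm", "luminance"]


def write_stimulus_log(dots, path: str | Path) -> None:
    dots.to_frame().to_csv(path, index=False)


def read_stimulus_log(path: str | Path, config: AssayConfig):
    from .stimulus import DotTrajectorySet
    df = pd.read_csv(path)
    return DotTrajectorySet.from_frame(df, frame_rate=config.frame_rate,
                                       diameter=config.dot_diameter)
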