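"""Per-frame tadpole segmentation by contrast to background.

The background is a per-pixel temporal median over strided frames, so any
object moving enough to occupy a pixel in fewer than half of the sampled
frames is suppressed. Detection thresholds the contrast image
(background - frame), takes connected components, drops components at known
dot positions and components outside the plausible tadpole size range, and
keeps at most the configured number of animals ranked by how close their
area lies to the middle of the size range.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import measure

from .config import AssayConfig
from .io import FrameStack, InputError, px_to_mm

#: mm added to the dot radius when excluding detections near known dots
DOT_EXCLUSION_MARGIN = 1.0
#: absolute lower bound on the contrast floor (guards blank frames)
MIN_CONTRAST_FLOOR = 0.05


class ConsistencyError(ValueError):
    pass


@dataclass
class Detection:
    frame: int
    centroid: tuple[float, float]   # mm
    area: float                     # mm^2
    contrast: float                 # mean background - object intensity
    score: float                    # closeness of area to the size-range midpoint


@dataclass
class BackgroundModel:
    image: np.ndarray
    method: str = "temporal-median"

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float32)


def estimate_background(frames: FrameStack, stride: int | None = None) -> BackgroundModel:
    """Per-pixel temporal median over strided frames."""
    n = len(frames)
    if stride is None:
        stride = max(1, n // 25)
    sampled = frames.frames[::stride]
    if sampled.shape[0] < 3:
        raise InputError(f"need at least 3 sampled frames for a background "
                         f"(got {sampled.shape[0]} at stride {stride})")
    return BackgroundModel(image=np.median(sampled, axis=0))


def default_contrast_floor(frame: np.ndarray, bg: BackgroundModel,
                           fraction: float = 0.2) -> float:
    """Contrast floor from a calibration frame: ``fraction`` of its peak contrast."""
    peak = float(np.max(bg.image - frame, initial=0.0))
    return max(fraction * peak, MIN_CONTRAST_FLOOR)


def detect_tadpoles(frame: np.ndarray, bg: BackgroundModel,
                    dots_mm: np.ndarray | None, config: AssayConfig,
                    contrast_floor: float | None = None,
                    frame_index: int = 0) -> list[Detection]:
    """Detect up to ``config.n_animals`` tadpole candidates in one frame.

    ``dots_mm`` holds the known dot centres for this frame, (k, 2) in mm;
    components whose centroid falls within dot radius + 1 mm of any dot are
    discarded (the stimulus must never be mistaken for an animal).
    """
    if frame.shape != bg.image.shape:
        raise ConsistencyError(f"frame {frame.shape} vs background {bg.image.shape}")
    contrast = bg.image - frame
    if contrast_floor is None:
        contrast_floor = default_contrast_floor(frame, bg)
    mask = contrast > contrast_floor
    labels = measure.label(mask, connectivity=2)
    lo, hi = config.size_range
    mid = 0.5 * (lo + hi)
    px_area = config.mm_per_pixel ** 2
    out: list[Detection] = []
    for rp in measure.regionprops(labels, intensity_image=contrast):
        area = rp.area * px_area
        if not (lo <= area <= hi):
            continue
        xy = px_to_mm(np.array(rp.centroid_weighted), config, frame.shape)
        if np.hypot(*xy) > config.dish_radius:
            continue
        if dots_mm is not None and len(dots_mm):
            d = np.hypot(dots_mm[:, 0] - xy[0], dots_mm[:, 1] - xy[1])
            if np.min(d) <= config.dot_radius + DOT_EXCLUSION_MARGIN:
                continue
        out.append(Detection(frame=frame_index, centroid=(float(xy[0]), float(xy[1])),
                             area=float(area), contrast=float(rp.intensity_mean),
                             score=-abs(area - mid)))
    # deterministic tie-breaking: best score, then larger area, then scan order
    out.sort(key=lambda det: (-det.score, -det.area,
                              det.centroid[1], det.centroid[0]))
    return out[: config.n_animals]
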