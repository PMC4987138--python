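"""Encounter detection and avoidance scoring.

A potential avoidance event (an *encounter*) opens whenever a dot's centre
comes within the encounter radius (default 5 mm) of a tadpole after having
been outside it. The event is scored a *success* when the smoothed swimming
speed changes by at least the avoidance threshold (default 24 mm/s) relative
to the speed at encounter onset, within the response window (default 0.25 s).
The reaction rate is the per-animal fraction of encounters scored successful,
averaged across animals; running the identical code path against
background-isoluminant ("invisible") dots yields the chance-level
false-positive rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .config import AssayConfig
from .kinematics import SpeedSeries, compute_speed, gaussian_smooth
from .stimulus import DotTrajectorySet
from .tracking import TrackSet

#: consecutive frames beyond the radius required to close an open encounter
CLOSE_RUN_FRAMES = 3


class ConsistencyError(ValueError):
    pass


@dataclass
class EncounterEvent:
    animal_id: int
    dot_id: int
    onset_frame: int
    offset_frame: int
    min_distance: float              # mm
    baseline_speed: float = math.nan  # smoothed speed at onset, mm/s
    max_delta_v: float = math.nan     # max |speed - baseline| in window, mm/s
    success: bool = False
    censored: bool = False

    def to_row(self) -> dict:
        return {
            "animal_id": self.animal_id, "dot_id": self.dot_id,
            "onset_frame": self.onset_frame, "offset_frame": self.offset_frame,
            "min_distance_mm": self.min_distance,
            "baseline_speed": self.baseline_speed,
            "max_delta_v": self.max_delta_v,
            "success": self.success, "censored": self.censored,
        }


@dataclass
class SessionResult:
    per_animal: list[dict]
    reaction_rate: float | None       # mean of per-animal rates
    false_positive_rate: float | None
    baseline_speed: float | None      # mm/s, frames with no dot nearby
    escape_speed: float | None        # mm/s, inside successful-event windows
    n_encounters: int
    n_successes: int
    n_censored: int
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "per_animal": self.per_animal,
            "reaction_rate": self.reaction_rate,
            "false_positive_rate": self.false_positive_rate,
            "baseline_speed_mm_s": self.baseline_speed,
            "escape_speed_mm_s": self.escape_speed,
            "n_encounters": self.n_encounters,
            "n_successes": self.n_successes,
            "n_censored": self.n_censored,
            "config": self.config,
        }


def _pair_distances(tracks: TrackSet, dots: DotTrajectorySet) -> np.ndarray:
    """(n_animals, n_dots, n_frames) centre-to-centre distances in mm."""
    diff = tracks.positions[:, None, :, :] - dots.positions[None, :, :, :]
    return np.hypot(diff[..., 0], diff[..., 1])


def detect_encounters(tracks: TrackSet, dots: DotTrajectorySet,
                      config: AssayConfig) -> list[EncounterEvent]:
    """Find all encounters (downward crossings of the encounter radius).

    An event opens at the first frame with distance <= radius after being
    above it, and closes once the distance has exceeded the radius for
    3 consecutive frames *and* the response window has elapsed (whichever is
    later). Overlapping events of one animal with different dots are kept
    separately; re-entry after closure opens a new event.
    """
    if dots.n_frames == 0 or dots.n_dots == 0:
        return []
    if tracks.n_frames != dots.n_frames:
        raise ConsistencyError(
            f"tracks have {tracks.n_frames} frames, dots {dots.n_frames}")
    radius = config.encounter_radius
    window = config.response_window_frames
    dist = _pair_distances(tracks, dots)
    events: list[EncounterEvent] = []
    n_frames = tracks.n_frames
    for a in range(tracks.n_animals):
        for j in range(dots.n_dots):
            d = dist[a, j]
            inside = d <= radius
            open_onset = None
            above_run = 0
            min_d = np.inf
            for t in range(n_frames):
                if open_onset is None:
                    if inside[t] and t > 0 and not inside[t - 1]:
                        open_onset = t
                        above_run = 0
                        min_d = d[t]
                else:
                    min_d = min(min_d, d[t])
                    above_run = above_run + 1 if not inside[t] else 0
                    if above_run >= CLOSE_RUN_FRAMES and t >= open_onset + window:
                        events.append(EncounterEvent(
                            animal_id=a, dot_id=int(dots.dot_ids[j]),
                            onset_frame=open_onset, offset_frame=t,
                            min_distance=float(min_d)))
                        open_onset = None
            if open_onset is not None:
                events.append(EncounterEvent(
                    animal_id=a, dot_id=int(dots.dot_ids[j]),
                    onset_frame=open_onset, offset_frame=n_frames - 1,
                    min_distance=float(min_d)))
    events.sort(key=lambda e: (e.onset_frame, e.animal_id, e.dot_id))
    return events


def score_avoidance(event: EncounterEvent, speeds: SpeedSeries,
                    config: AssayConfig) -> EncounterEvent:
    """Score one encounter against the (smoothed) speed series.

    max_delta_v = max over frames t in (onset, onset + W] of
    |speed(t) - speed(onset)|, W = ceil(response_window * frame_rate);
    success iff max_delta_v >= avoidance_delta_v. Events whose window runs
    past the end of the recording are marked censored and excluded from rates.
    """
    sm = speeds.best()
    window = config.response_window_frames
    onset = event.onset_frame
    end = onset + window
    if end > speeds.n_frames - 1:
        event.censored = True
        event.success = False
        return event
    s = sm[event.animal_id]
    event.baseline_speed = float(s[onset])
    seg = s[onset + 1: end + 1]
    event.max_delta_v = float(np.max(np.abs(seg - s[onset])))
    event.success = event.max_delta_v >= config.avoidance_delta_v
    return event


def score_session(tracks: TrackSet, dots: DotTrajectorySet, config: AssayConfig,
                  speeds: SpeedSeries | None = None
                  ) -> tuple[list[EncounterEvent], SpeedSeries]:
    """Detect and score every encounter; returns the events and the smoothed speeds."""
    if speeds is None:
        speeds = gaussian_smooth(compute_speed(tracks, config), config.smoothing_sigma)
    elif speeds.smoothed is None:
        speeds = gaussian_smooth(speeds, config.smoothing_sigma)
    events = [score_avoidance(e, speeds, config)
              for e in detect_encounters(tracks, dots, config)]
    return events, speeds


def _per_animal_rates(events: list[EncounterEvent], n_animals: int) -> list[dict]:
    rows = []
    for a in range(n_animals):
        mine = [e for e in events if e.animal_id == a and not e.censored]
        n_enc = len(mine)
        n_suc = sum(e.success for e in mine)
        rows.append({"animal_id": a, "n_encounters": n_enc, "n_successes": n_suc,
                     "reaction_rate": (n_suc / n_enc) if n_enc else None})
    return rows


def _mean_rate(per_animal: list[dict]) -> float | None:
    rates = [r["reaction_rate"] for r in per_animal if r["reaction_rate"] is not None]
    return float(np.mean(rates)) if rates else None


def false_positive_rate(tracks: TrackSet, invisible_dots: DotTrajectorySet,
                        config: AssayConfig,
                        speeds: SpeedSeries | None = None
                        ) -> tuple[float | None, list[EncounterEvent]]:
    """Chance-level reaction rate against background-isoluminant dots.

    Runs the identical encounter-detection and scoring code path against the
    virtual (invisible) dot positions. Returns (rate, events); the rate is
    None when no animal had an encounter.
    """
    if invisible_dots.visible:
        raise ConsistencyError("false_positive_rate requires invisible dots")
    events, _ = score_session(tracks, invisible_dots, config, speeds=speeds)
    return _mean_rate(_per_animal_rates(events, tracks.n_animals)), events


def summarize_session(events: list[EncounterEvent], tracks: TrackSet,
                      speeds: SpeedSeries, dots: DotTrajectorySet,
                      config: AssayConfig,
                      fp_rate: float | None = None) -> SessionResult:
    """Per-animal and group reaction rates plus speed summaries.

    Baseline speed averages smoothed speeds over frames where no dot is
    within the encounter radius of the animal; escape speed averages over
    the response windows of successful events.
    """
    per_animal = _per_animal_rates(events, tracks.n_animals)
    sm = speeds.best()
    baseline = escape = None
    if dots.n_dots and dots.n_frames:
        dist = _pair_distances(tracks, dots).min(axis=1)   # (n_animals, n_frames)
        free = dist > config.encounter_radius
        if free.any():
            baseline = float(sm[free].mean())
    else:
        baseline = float(sm.mean())
    esc_samples = []
    window = config.response_window_frames
    for e in events:
        if e.success and not e.censored:
            esc_samples.append(sm[e.animal_id, e.onset_frame: e.onset_frame + window + 1])
    if esc_samples:
        escape = float(np.concatenate(esc_samples).mean())
    live = [e for e in events if not e.censored]
    return SessionResult(
        per_animal=per_animal,
        reaction_rate=_mean_rate(per_animal),
        false_positive_rate=fp_rate,
        baseline_speed=baseline,
        escape_speed=escape,
        n_encounters=len(live),
        n_successes=sum(e.success for e in live),
        n_censored=sum(e.censored for e in events),
        config=config.to_dict(),
    )
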