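"""Synthetic tadpole swimming sessions with ground truth.

Agents swim in the circular dish with the empirical dual power-law speed
marginal (0-200 mm/s, breakpoint 24 mm/s) and temporally persistent speeds
and headings. Speed persistence is a first-order autoregression on a latent
Gaussian variable mapped through the analytic inverse CDF (a Gaussian-copula
autoregression), which preserves the stated marginal exactly while producing
run-like motion. Visible dots trigger programmed escape responses with
probability ``p_avoid``: after a short latency the agent turns directly away
from the dot and its speed jumps by ``dv_escape`` for the escape duration.
Invisible (background-isoluminant) dots never trigger a programmed response.

Every programmed response is recorded, giving ground truth for the scorer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import AssayConfig
from .io import FrameStack
from .speedlaw import DualPowerLaw
from .stimulus import DotTrajectorySet, render_frame

#: consecutive frames outside the radius that close an encounter (the same
#: rule the scorer applies when segmenting events)
ENCOUNTER_CLOSE_FRAMES = 3


class ConsistencyError(ValueError):
    """Simulation inputs disagree (frame counts, frame rates)."""


def _slide_step(pos: np.ndarray, heading: float, step: float,
                r_max: float) -> tuple[np.ndarray, float]:
    """Advance one straight step; slide along the wall at full speed.

    When the step would exit the dish the agent moves straight to the wall
    and covers the remaining path length along the wall circle, leaving with
    a tangential heading. Path length is conserved, so displacement stays
    within a fraction of a percent of the applied speed even at the wall.
    """
    d = np.array([math.cos(heading), math.sin(heading)])
    nxt = pos + step * d
    if nxt @ nxt <= r_max * r_max:
        return nxt, heading
    b = pos @ d
    c = pos @ pos - r_max * r_max
    t_hit = -b + math.sqrt(max(b * b - c, 0.0))
    t_hit = min(max(t_hit, 0.0), step)
    hit = pos + t_hit * d
    rem = step - t_hit
    phi = math.atan2(hit[1], hit[0])
    tang = np.array([-math.sin(phi), math.cos(phi)])
    s = 1.0 if d @ tang >= 0 else -1.0
    new_phi = phi + s * rem / r_max
    out = r_max * np.array([math.cos(new_phi), math.sin(new_phi)])
    new_heading = math.atan2(s * math.cos(new_phi), -s * math.sin(new_phi))
    return out, new_heading


@dataclass
class SwimAgentParams:
    """Agent kinematics and programmed-avoidance parameters.

    Defaults: dual power-law speeds with breakpoint 24 mm/s and exponents
    (0.5, 2.5) on [0, 200] mm/s; speed autocorrelation time 0.5 s; Gaussian
    heading steps of 0.25 rad/frame; 9 x 3 mm body ellipse (~21 mm^2, within
    the default blob-size gate); escape jump 40 mm/s applied 0.1 s after the
    encounter and sustained for 0.5 s.
    """

    speed_law: DualPowerLaw = field(default_factory=DualPowerLaw)
    speed_tau: float = 0.5        # s, autocorrelation time of the latent AR(1)
    turn_sigma: float = 0.25      # rad per frame
    body_axes: tuple[float, float] = (9.0, 3.0)  # mm, full ellipse axes
    p_avoid: float = 0.8
    dv_escape: float = 40.0       # mm/s
    latency: float = 0.1          # s, stimulus-to-escape delay
    escape_duration: float = 0.5  # s
    #: mm; when set, agents steer away from conspecifics and never step
    #: within this distance of one another (useful for producing sessions
    #: without body overlap). None disables mutual avoidance.
    min_separation: float | None = None

    @property
    def body_area(self) -> float:
        return math.pi * self.body_axes[0] * self.body_axes[1] / 4.0


@dataclass
class ProgrammedEvent:
    """One programmed escape: ground truth for the avoidance scorer."""

    animal_id: int
    dot_id: int
    onset_frame: int
    applied_dv: float


@dataclass
class GroundTruth:
    """True per-frame agent state plus the list of programmed escapes."""

    positions: np.ndarray          # (n_animals, n_frames, 2) mm
    headings: np.ndarray           # (n_animals, n_frames) rad
    speeds: np.ndarray             # (n_animals, n_frames) mm/s, applied speeds
    events: list[ProgrammedEvent]
    frame_rate: float
    body_axes: tuple[float, float] = (9.0, 3.0)

    @property
    def n_animals(self) -> int:
        return self.positions.shape[0]

    @property
    def n_frames(self) -> int:
        return self.positions.shape[1]

    def to_tracks(self):
        """True positions as a TrackSet (the ideal tracker output)."""
        from .tracking import TrackSet
        return TrackSet(positions=self.positions.copy(),
                        interpolated=np.zeros(self.positions.shape[:2], dtype=bool),
                        frame_rate=self.frame_rate)

    def to_frame(self) -> pd.DataFrame:
        """Truth table in the track-table schema with a ``true`` flag column."""
        n_a, n_f = self.positions.shape[:2]
        return pd.DataFrame({
            "frame": np.tile(np.arange(n_f), n_a),
            "animal_id": np.repeat(np.arange(n_a), n_f),
            "x_mm": self.positions[:, :, 0].ravel(),
            "y_mm": self.positions[:, :, 1].ravel(),
            "interpolated": False,
            "true": True,
        })


def simulate_swimmers(params: SwimAgentParams, dots: DotTrajectorySet,
                      config: AssayConfig, seed: int | None = None) -> GroundTruth:
    """Simulate ``config.n_animals`` agents against a dot trajectory set."""
    if dots.n_frames > 0 and abs(dots.frame_rate - config.frame_rate) > 1e-9:
        raise ConsistencyError("dots and config disagree on frame_rate")
    n_frames = dots.n_frames
    n_animals = config.n_animals
    rng = np.random.default_rng(config.seed if seed is None else seed)
    fps = config.frame_rate
    dt = 1.0 / fps
    rho = math.exp(-dt / params.speed_tau)
    latency_f = max(1, int(round(params.latency * fps)))
    if latency_f > config.response_window_frames:
        raise ConsistencyError("escape latency exceeds the response window")
    escape_f = max(1, int(round(params.escape_duration * fps)))
    # lookback for the pre-escape peak: long enough that any recent burst
    # still influencing the smoothed speed at onset is seen
    recent_f = max(config.response_window_frames,
                   2 * int(math.ceil(4.0 * config.smoothing_sigma)))
    r_lim = config.dish_radius - params.body_axes[0] / 2.0

    pos = np.empty((n_animals, n_frames, 2))
    head = np.empty((n_animals, n_frames))
    spd = np.empty((n_animals, n_frames))
    events: list[ProgrammedEvent] = []
    from scipy.stats import norm

    sep = params.min_separation
    # initial placement: uniform in the allowed disc, with rejection when a
    # minimum separation is requested
    p_now = np.empty((n_animals, 2))
    for a in range(n_animals):
        for _ in range(1000):
            rr = r_lim * math.sqrt(rng.uniform())
            th = rng.uniform(0, 2 * math.pi)
            cand = np.array([rr * math.cos(th), rr * math.sin(th)])
            if sep is None or a == 0 or np.min(
                    np.hypot(*(p_now[:a] - cand).T)) >= sep:
                p_now[a] = cand
                break
        else:
            p_now[a] = cand
    heading = rng.uniform(0, 2 * math.pi, size=n_animals)
    z = rng.standard_normal(n_animals)
    bspd = np.zeros((n_animals, n_frames))   # sampled (pre-escape) speeds
    # escape state per agent: [-1] means inactive
    esc_start = np.full(n_animals, -1)
    esc_end = np.full(n_animals, -1)
    esc_base = np.zeros(n_animals)
    esc_dot = np.full(n_animals, -1)
    # per (animal, dot) encounter bookkeeping, mirroring the scorer's event
    # segmentation: an encounter opens on a downward crossing of the radius
    # and closes after 3 consecutive frames outside once the response window
    # has elapsed; only a crossing that opens an encounter can startle
    n_dots = max(dots.n_dots, 1)
    inside_prev = np.zeros((n_animals, n_dots), dtype=bool)
    enc_onset = np.full((n_animals, n_dots), -1)
    enc_out = np.zeros((n_animals, n_dots), dtype=int)
    window_f = config.response_window_frames

    for t in range(n_frames):
        pos[:, t] = p_now
        frame_start = p_now.copy()
        for a in range(n_animals):
            z[a] = rho * z[a] + math.sqrt(1.0 - rho * rho) * rng.standard_normal()
            base_speed = float(params.speed_law.ppf(
                np.clip(norm.cdf(z[a]), 1e-9, 1 - 1e-9)))
            bspd[a, t] = base_speed
            p = p_now[a]
            # programmed avoidance: respond (with probability p_avoid) to each
            # encounter the scorer will count
            if dots.visible and dots.n_dots:
                d = np.hypot(dots.positions[:, t, 0] - p[0],
                             dots.positions[:, t, 1] - p[1])
                inside = d <= config.encounter_radius
                new_onsets = []
                for j in range(dots.n_dots):
                    if enc_onset[a, j] < 0:
                        if t > 0 and inside[j] and not inside_prev[a, j]:
                            enc_onset[a, j] = t
                            enc_out[a, j] = 0
                            new_onsets.append(j)
                    else:
                        enc_out[a, j] = enc_out[a, j] + 1 if not inside[j] else 0
                        if (enc_out[a, j] >= ENCOUNTER_CLOSE_FRAMES
                                and t >= enc_onset[a, j] + window_f):
                            enc_onset[a, j] = -1
                inside_prev[a] = inside
                if new_onsets and rng.uniform() < params.p_avoid:
                    j = int(min(new_onsets, key=lambda k: d[k]))
                    esc_start[a] = t + latency_f
                    esc_end[a] = esc_start[a] + escape_f
                    # the startle rides on the recent (~0.25 s) peak of the
                    # applied speed (which includes any burst still decaying
                    # out of the smoothing window), so the jump is always a
                    # jump relative to anything the animal was just doing
                    recent = spd[a, max(0, t - recent_f): t]
                    esc_base[a] = max(float(recent.max()) if recent.size else 0.0,
                                      base_speed)
                    esc_dot[a] = j
                    events.append(ProgrammedEvent(
                        animal_id=a, dot_id=int(dots.dot_ids[j]),
                        onset_frame=t, applied_dv=params.dv_escape))

            escaping = esc_start[a] >= 0 and esc_start[a] - latency_f <= t < esc_end[a]
            if escaping:
                # reaction in progress: speed pinned at the onset value during
                # the latency, then an accelerating burst (the jump dv at
                # burst start, ramping to 2 dv by its end); heading set
                # directly away from the dot at the moment the burst begins
                if t >= esc_start[a]:
                    ramp = 1.0 + (t - esc_start[a]) / escape_f
                    speed = esc_base[a] + params.dv_escape * ramp
                else:
                    speed = esc_base[a]
                if t == esc_start[a]:
                    away = p - dots.positions[esc_dot[a], t]
                    if np.hypot(*away) > 1e-9:
                        heading[a] = math.atan2(away[1], away[0])
            else:
                speed = base_speed
                heading[a] += rng.normal(0.0, params.turn_sigma)
                if sep is not None:
                    others = np.delete(frame_start, a, axis=0)
                    do = np.hypot(*(others - p).T)
                    jn = int(np.argmin(do))
                    if do[jn] < 1.5 * sep:  # steer away from the nearest animal
                        away = p - others[jn]
                        if np.hypot(*away) > 1e-9:
                            heading[a] = math.atan2(away[1], away[0]) \
                                + rng.normal(0.0, 0.3 * params.turn_sigma)

            # advance; at the wall the animal slides along it at full speed
            # (thigmotaxis) rather than bouncing, so displacement-based speed
            # measurements match the applied speed in every frame
            nxt, new_heading = _slide_step(p, heading[a], speed * dt, r_lim)
            if sep is not None:
                others = np.delete(p_now, a, axis=0)
                if np.min(np.hypot(*(others - nxt).T)) < sep:
                    nxt = p          # hold position rather than break separation
                    speed = 0.0
            head[a, t] = heading[a]
            spd[a, t] = speed
            heading[a] = new_heading
            p_now[a] = nxt
    return GroundTruth(positions=pos, headings=head, speeds=spd, events=events,
                       frame_rate=fps, body_axes=params.body_axes)


def render_session(truth: GroundTruth, dots: DotTrajectorySet, config: AssayConfig,
                   noise_std: float = 0.0, seed: int | None = None
                   ) -> tuple[FrameStack, pd.DataFrame, pd.DataFrame]:
    """Render a full synthetic session video with aligned truth tables.

    Returns (frames, stimulus log, truth track table). Optional zero-mean
    Gaussian pixel noise of standard deviation ``noise_std`` is added and the
    result clipped back to [0, 1].
    """
    if truth.n_frames != dots.n_frames:
        raise ConsistencyError(
            f"truth has {truth.n_frames} frames but dots have {dots.n_frames}")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frames = []
    for t in range(truth.n_frames):
        animals = np.column_stack([truth.positions[:, t, :], truth.headings[:, t]])
        fr = render_frame(dots, config, t, animals=animals,
                          body_axes=truth.body_axes)
        if noise_std > 0:
            fr = np.clip(fr + rng.normal(0.0, noise_std, fr.shape), 0.0, 1.0)
        frames.append(fr.astype(np.float32))
    stack = FrameStack(frames=np.stack(frames) if frames else np.empty((0, 1, 1), np.float32),
                       frame_rate=config.frame_rate,
                       mm_per_pixel=config.mm_per_pixel)
    return stack, dots.to_frame(), truth.to_frame()
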