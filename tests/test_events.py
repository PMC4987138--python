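"""Encounter detection, avoidance scoring, and session summaries."""

import numpy as np
import pytest

from dotassay import (AssayConfig, DotTrajectorySet, EncounterEvent, TrackSet,
                      detect_encounters, false_positive_rate, score_avoidance,
                      summarize_session)
from dotassay.events import ConsistencyError, score_session
from dotassay.kinematics import SpeedSeries


def _tracks(pos, fps=30.0):
    pos = np.asarray(pos, dtype=float)
    return TrackSet(positions=pos,
                    interpolated=np.zeros(pos.shape[:2], dtype=bool),
                    frame_rate=fps)


def _dots(pos, cfg, visible=True):
    pos = np.asarray(pos, dtype=float)
    lum = cfg.dot_luminance if visible else cfg.background_luminance
    return DotTrajectorySet(positions=pos, diameters=cfg.dot_diameter,
                            luminances=lum, frame_rate=cfg.frame_rate,
                            visible=visible)


def _speeds(values, fps=30.0):
    v = np.atleast_2d(np.asarray(values, dtype=float))
    return SpeedSeries(raw=v, frame_rate=fps, smoothed=v)


def test_distant_dot_creates_no_encounter(cfg):
    n = 40
    tracks = _tracks(np.zeros((1, n, 2)))
    dpos = np.full((1, n, 2), 30.0)
    assert detect_encounters(tracks, _dots(dpos, cfg), cfg) == []


def test_head_on_pass_gives_one_event_with_min_distance(cfg):
    """A dot passing 4 mm from a stationary animal -> one event, min 4 mm,
    verified against a brute-force distance scan."""
    n = 90
    tracks = _tracks(np.zeros((1, n, 2)))
    x = np.linspace(-40, 40, n)
    dpos = np.stack([np.column_stack([x, np.full(n, 4.0)])])
    dots = _dots(dpos, cfg)
    events = detect_encounters(tracks, dots, cfg)
    assert len(events) == 1
    e = events[0]
    d = np.hypot(x, 4.0)
    assert e.min_distance == pytest.approx(d.min(), abs=1e-9)
    inside = np.flatnonzero(d <= cfg.encounter_radius)
    assert e.onset_frame == inside[0]
    assert e.offset_frame >= inside[-1] + 3


def test_reentry_after_closure_opens_second_event(cfg):
    n = 120
    tracks = _tracks(np.zeros((1, n, 2)))
    # dot approaches, leaves for 20 frames, approaches again
    d = np.full(n, 30.0)
    d[20:30] = 4.0
    d[70:80] = 4.0
    dpos = np.stack([np.column_stack([d, np.zeros(n)])])
    events = detect_encounters(tracks, _dots(dpos, cfg), cfg)
    assert len(events) == 2
    assert events[0].onset_frame == 20
    assert events[1].onset_frame == 70


def test_frame_misalignment_raises(cfg):
    tracks = _tracks(np.zeros((1, 10, 2)))
    dpos = np.zeros((1, 12, 2))
    with pytest.raises(ConsistencyError):
        detect_encounters(tracks, _dots(dpos, cfg), cfg)


def test_exact_threshold_jump_within_window_succeeds(cfg):
    """A speed change of exactly 24 mm/s at 0.2 s after onset is a success."""
    speeds = np.full(60, 10.0)
    speeds[10 + 6:] = 34.0               # +24 at 0.2 s (6 frames) after onset
    e = EncounterEvent(animal_id=0, dot_id=0, onset_frame=10, offset_frame=30,
                       min_distance=4.0)
    scored = score_avoidance(e, _speeds(speeds), cfg)
    assert scored.success
    assert scored.max_delta_v == pytest.approx(24.0)


def test_constant_speed_is_failure(cfg):
    e = EncounterEvent(animal_id=0, dot_id=0, onset_frame=5, offset_frame=20,
                       min_distance=3.0)
    scored = score_avoidance(e, _speeds(np.full(40, 50.0)), cfg)
    assert not scored.success
    assert scored.max_delta_v == 0.0


def test_speed_drop_counts_as_change(cfg):
    speeds = np.full(40, 60.0)
    speeds[12:] = 20.0
    e = EncounterEvent(animal_id=0, dot_id=0, onset_frame=10, offset_frame=25,
                       min_distance=3.0)
    assert score_avoidance(e, _speeds(speeds), cfg).success


def test_threshold_sweep_recovers_configured_threshold(cfg):
    """Sweeping injected jumps in 1 mm/s steps: the smallest success is 24."""
    successes = []
    for jump in range(1, 41):
        speeds = np.full(40, 10.0)
        speeds[14:] = 10.0 + jump
        e = EncounterEvent(animal_id=0, dot_id=0, onset_frame=10,
                           offset_frame=25, min_distance=4.0)
        if score_avoidance(e, _speeds(speeds), cfg).success:
            successes.append(jump)
    assert min(successes) == cfg.avoidance_delta_v == 24


def test_window_end_censoring(cfg):
    e = EncounterEvent(animal_id=0, dot_id=0, onset_frame=35, offset_frame=39,
                       min_distance=4.0)
    scored = score_avoidance(e, _speeds(np.full(40, 10.0)), cfg)
    assert scored.censored and not scored.success


def test_jump_just_outside_window_fails(cfg):
    w = cfg.response_window_frames
    speeds = np.full(60, 10.0)
    speeds[10 + w + 1:] = 60.0
    e = EncounterEvent(animal_id=0, dot_id=0, onset_frame=10, offset_frame=30,
                       min_distance=4.0)
    assert not score_avoidance(e, _speeds(speeds), cfg).success


def test_threshold_monotonicity(cfg, short_session):
    """Raising avoidance_delta_v never increases the number of successes."""
    dots, truth = short_session
    tracks = truth.to_tracks()
    prev = None
    for thr in (10.0, 24.0, 40.0, 80.0):
        c = AssayConfig(avoidance_delta_v=thr, seed=1)
        ev, _ = score_session(tracks, dots, c)
        n_succ = sum(e.success for e in ev if not e.censored)
        if prev is not None:
            assert n_succ <= prev
        prev = n_succ


def test_per_animal_then_average_rate(cfg):
    """2 animals with (2 of 4) and (1 of 1) successes -> rate 0.75."""
    events = []
    for k in range(4):
        events.append(EncounterEvent(animal_id=0, dot_id=0, onset_frame=10 * k,
                                     offset_frame=10 * k + 9, min_distance=4.0,
                                     success=(k < 2)))
    events.append(EncounterEvent(animal_id=1, dot_id=0, onset_frame=5,
                                 offset_frame=14, min_distance=4.0, success=True))
    tracks = _tracks(np.zeros((2, 50, 2)))
    dpos = np.full((1, 50, 2), 30.0)
    speeds = SpeedSeries(raw=np.full((2, 50), 10.0), frame_rate=30.0,
                         smoothed=np.full((2, 50), 10.0))
    res = summarize_session(events, tracks, speeds, _dots(dpos, cfg), cfg)
    assert res.reaction_rate == pytest.approx((0.5 + 1.0) / 2)


def test_no_encounters_reports_missing_rate_but_speeds(cfg):
    tracks = _tracks(np.zeros((2, 50, 2)))
    dpos = np.full((1, 50, 2), 30.0)
    speeds = SpeedSeries(raw=np.full((2, 50), 12.0), frame_rate=30.0,
                         smoothed=np.full((2, 50), 12.0))
    res = summarize_session([], tracks, speeds, _dots(dpos, cfg), cfg)
    assert res.reaction_rate is None
    assert res.baseline_speed == pytest.approx(12.0)


def test_false_positive_requires_invisible_dots(cfg):
    tracks = _tracks(np.zeros((1, 30, 2)))
    dpos = np.full((1, 30, 2), 30.0)
    with pytest.raises(ConsistencyError):
        false_positive_rate(tracks, _dots(dpos, cfg, visible=True), cfg)


def test_frozen_animals_distant_dots_give_missing_rate(cfg):
    tracks = _tracks(np.zeros((2, 60, 2)))
    dpos = np.full((1, 60, 2), 35.0)
    rate, events = false_positive_rate(tracks, _dots(dpos, cfg, visible=False), cfg)
    assert rate is None
    assert events == []


def test_scorer_matches_exhaustive_oracle_on_500_frame_session(cfg):
    """Event sets and success flags match an independent frame-by-frame
    reference exactly on a 500-frame simulated session."""
    from oracles import oracle_events

    from dotassay import SwimAgentParams, generate_dot_walk, simulate_swimmers
    dots = generate_dot_walk(cfg, n_dots=5, duration=500 / 30.0, seed=21)
    truth = simulate_swimmers(SwimAgentParams(p_avoid=0.5), dots, cfg, seed=22)
    tracks = truth.to_tracks()
    events, speeds = score_session(tracks, dots, cfg)
    ref = oracle_events(tracks, dots, cfg, speeds.best())
    assert len(events) == len(ref)
    for e, r in zip(events, ref):
        assert (e.animal_id, e.dot_id, e.onset_frame, e.offset_frame) == \
            (r["animal"], r["dot"], r["onset"], r["offset"])
        assert e.min_distance == pytest.approx(r["min_d"], abs=1e-9)
        assert e.censored == r["censored"]
        assert e.success == r["success"]
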