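"""Synthetic swimmer generator: speed law, programmed avoidance, rendering."""

import numpy as np
import pytest
from scipy.stats import ks_2samp

from dotassay import (AssayConfig, DualPowerLaw, SwimAgentParams,
                      generate_dot_walk, render_session, simulate_swimmers,
                      track_video)
from dotassay.swim_sim import ConsistencyError


def test_p_avoid_zero_programs_no_events(cfg, short_session):
    dots, _ = short_session
    truth = simulate_swimmers(SwimAgentParams(p_avoid=0.0), dots, cfg, seed=4)
    assert truth.events == []


def test_sampled_speeds_stay_in_range(cfg):
    """10^5 agent-frames of sampled speeds all lie in [0, 200] mm/s."""
    dots = generate_dot_walk(cfg, n_dots=0, duration=500.0, seed=2)
    dots.positions = np.empty((0, 15000, 2))  # dotless arena, same duration
    truth = simulate_swimmers(SwimAgentParams(), dots, cfg, seed=5)
    assert truth.speeds.size >= 1e5
    assert truth.speeds.min() >= 0.0
    assert truth.speeds.max() <= 200.0


def test_speed_marginal_matches_independent_sampler(cfg):
    """Copula-correlated speeds match direct inverse-CDF sampling (two-sample)."""
    dots = generate_dot_walk(cfg, n_dots=5, duration=120.0, seed=2)
    truth = simulate_swimmers(SwimAgentParams(p_avoid=0.0), dots, cfg, seed=6)
    law = DualPowerLaw()
    ref = law.ppf(np.random.default_rng(7).uniform(1e-9, 1 - 1e-9, truth.speeds.size))
    # thin the autocorrelated series so the KS test sees near-independent draws
    sample = truth.speeds.ravel()[:: 37]
    stat = ks_2samp(sample, ref).pvalue
    assert stat > 0.01


def test_dual_power_law_analytic_properties():
    law = DualPowerLaw(c=24.0, alpha_low=0.5, alpha_high=2.5, s_max=200.0)
    # CDF at the breakpoint equals the configured mass split
    assert law.cdf(np.array([24.0]))[0] == pytest.approx(law.mass_low, abs=1e-12)
    # ppf inverts cdf across the domain
    q = np.linspace(0.001, 0.999, 101)
    np.testing.assert_allclose(law.cdf(law.ppf(q)), q, atol=1e-10)
    # sampled quantiles converge to analytic quantiles as n grows
    rng = np.random.default_rng(0)
    errs = []
    for n in (1_000, 10_000, 100_000):
        s = law.rvs(n, rng)
        emp = np.quantile(s, [0.25, 0.5, 0.9])
        errs.append(np.abs(emp - law.ppf(np.array([0.25, 0.5, 0.9]))).max())
    assert errs[-1] < errs[0]
    assert errs[-1] < 1.0


def test_programmed_events_satisfy_encounter_precondition(cfg, short_session):
    """At every programmed onset the dot is within the encounter radius."""
    dots, truth = short_session
    ids = list(dots.dot_ids)
    for ev in truth.events:
        j = ids.index(ev.dot_id)
        d = np.linalg.norm(truth.positions[ev.animal_id, ev.onset_frame]
                           - dots.positions[j, ev.onset_frame])
        assert d <= cfg.encounter_radius + 1e-9


def test_invisible_dots_never_trigger(cfg):
    inv = generate_dot_walk(cfg, n_dots=5, duration=30.0, seed=8, visible=False)
    truth = simulate_swimmers(SwimAgentParams(p_avoid=1.0), inv, cfg, seed=9)
    assert truth.events == []


def test_mismatched_frame_rate_raises(cfg):
    dots = generate_dot_walk(cfg, n_dots=1, duration=1.0, seed=0)
    other = AssayConfig(frame_rate=25.0, seed=1)
    with pytest.raises(ConsistencyError):
        simulate_swimmers(SwimAgentParams(), dots, other, seed=0)


def test_min_separation_is_enforced(cfg):
    dots = generate_dot_walk(cfg, n_dots=2, duration=20.0, seed=2)
    truth = simulate_swimmers(SwimAgentParams(min_separation=20.0), dots, cfg, seed=3)
    n = truth.n_animals
    for i in range(n):
        for j in range(i + 1, n):
            d = np.linalg.norm(truth.positions[i] - truth.positions[j], axis=-1)
            assert d.min() >= 20.0 - 1e-9


def test_blank_arena_when_nothing_to_render(cfg):
    dots = generate_dot_walk(cfg, n_dots=0, duration=0.5, seed=0)
    dots.positions = np.empty((0, 15, 2))
    empty_cfg = AssayConfig(n_animals=1, seed=1)
    truth = simulate_swimmers(SwimAgentParams(), dots, empty_cfg, seed=1)
    truth.positions = truth.positions[:0]
    truth.headings = truth.headings[:0]
    truth.speeds = truth.speeds[:0]
    stack, _, _ = render_session(truth, dots, empty_cfg)
    assert np.unique(stack.frames).size == 1     # uniform background


def test_rendered_blob_count_equals_animals_when_separated(cfg):
    """With 8 separated animals and no noise, each frame segments into 8 blobs."""
    from skimage import measure
    dots = generate_dot_walk(cfg, n_dots=0, duration=2.0, seed=4)
    dots.positions = np.empty((0, 60, 2))
    truth = simulate_swimmers(SwimAgentParams(min_separation=15.0), dots, cfg, seed=5)
    stack, _, _ = render_session(truth, dots, cfg)
    for t in range(0, len(stack), 10):
        labels = measure.label(stack[t] < 0.5)
        assert labels.max() == cfg.n_animals


def test_truth_round_trips_through_rendered_video(cfg):
    """Detection recovers isolated animals from the rendered video within
    0.5 mm of their true positions (known clean background)."""
    from scipy.optimize import linear_sum_assignment

    from dotassay.detection import BackgroundModel
    from dotassay.stimulus import render_frame
    dots = generate_dot_walk(cfg, n_dots=0, duration=5.0, seed=6)
    dots.positions = np.empty((0, 150, 2))
    truth = simulate_swimmers(SwimAgentParams(min_separation=20.0), dots, cfg, seed=7)
    stack, _, _ = render_session(truth, dots, cfg)
    bg = BackgroundModel(image=render_frame(None, cfg))
    tracks = track_video(stack, None, cfg, background=bg)
    assert not tracks.interpolated.any()
    n = cfg.n_animals
    cost = np.array([[np.linalg.norm(tracks.positions[i] - truth.positions[j],
                                     axis=-1).mean() for j in range(n)]
                     for i in range(n)])
    ri, ci = linear_sum_assignment(cost)
    err = np.array([np.linalg.norm(tracks.positions[i] - truth.positions[j], axis=-1)
                    for i, j in zip(ri, ci)])
    assert np.quantile(err, 0.99) <= 0.5
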