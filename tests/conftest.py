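import numpy as np
import pytest

from dotassay import AssayConfig, SwimAgentParams, generate_dot_walk, simulate_swimmers


@pytest.fixture()
def cfg() -> AssayConfig:
    return AssayConfig(seed=1)


@pytest.fixture(scope="session")
def cfg_session() -> AssayConfig:
    return AssayConfig(seed=1)


@pytest.fixture(scope="session")
def short_session(cfg_session):
    """A 10 s simulated session (no rendering): dots + ground truth."""
    dots = generate_dot_walk(cfg_session, n_dots=5, duration=10.0, seed=2)
    truth = simulate_swimmers(SwimAgentParams(), dots, cfg_session, seed=3)
    return dots, truth
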