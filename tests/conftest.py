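"""Shared fixtures: canonical stimuli and a session-scoped synthetic plume."""

import numpy as np
import pytest

from flynav import (
    PlumeEnvironment,
    PlumeGenParams,
    StimulusSpec,
    make_stimulus,
    make_synthetic_plume,
)

SAMPLE_RATE = 50.0


@pytest.fixture(scope="session")
def square_pulse_spec():
    return StimulusSpec("square_pulse", concentration=1.0, onset=10.0, duration=10.0)


@pytest.fixture(scope="session")
def square_pulse(square_pulse_spec):
    return make_stimulus(square_pulse_spec, SAMPLE_RATE)


@pytest.fixture(scope="session")
def sweep_up():
    return make_stimulus(StimulusSpec("freq_sweep_up", onset=10.0, duration=20.0), SAMPLE_RATE)


@pytest.fixture(scope="session")
def sweep_down():
    return make_stimulus(StimulusSpec("freq_sweep_down", onset=10.0, duration=20.0), SAMPLE_RATE)


@pytest.fixture(scope="session")
def plume_movie():
    """A short but otherwise default-parameter synthetic plume recording."""
    return make_synthetic_plume(PlumeGenParams(duration=40.0, seed=0))


@pytest.fixture(scope="session")
def plume_env(plume_movie):
    return PlumeEnvironment(plume_movie, duration=120.0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
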