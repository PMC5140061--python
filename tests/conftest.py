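"""Shared fixtures: small organs, presets and simulation budgets."""

import numpy as np
import pytest

from nutkin.drivers import DEFAULTS
from nutkin.io import RunConfig
from nutkin.simulate import run_simulation

OMEGA = DEFAULTS["omega"]  # rad/s, the driving rotation rate of the presets
PERIOD = 2.0 * np.pi / OMEGA  # s
DELTA_EDOT = DEFAULTS["delta_edot"]
RADIUS = DEFAULTS["radius"]
LENGTH = DEFAULTS["length"]


@pytest.fixture(scope="session")
def circle_sim():
    """Uniform-rotation drive, no growth: the canonical circular pattern."""
    return run_simulation(
        RunConfig(preset=4, driver_overrides={"edot": 0.0}, t_end=5 * PERIOD)
    )


@pytest.fixture(scope="session")
def rate_mod_sim():
    """Rate-modulated rotation (ellipse mechanism i)."""
    return run_simulation(RunConfig(preset=0))


@pytest.fixture(scope="session")
def amp_mod_sim():
    """Amplitude-modulated drive (ellipse mechanism ii)."""
    return run_simulation(RunConfig(preset=1))


@pytest.fixture()
def rng():
    return np.random.default_rng(20160)
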