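"""Shared fixtures: small, fast scenario variants for unit tests."""

import numpy as np
import pytest

import localft as lf


@pytest.fixture(scope="session")
def small_active_spec():
    return lf.make_scenario("active", {"box_lengths": (8.0, 8.0),
                                       "n_fluid": 32})


@pytest.fixture(scope="session")
def small_channel_spec():
    return lf.make_scenario("channel", {"box_lengths": (12.0, 10.0),
                                        "width": 7.0, "amplitude": 1.5,
                                        "n_fluid": 24})


@pytest.fixture(scope="session")
def small_obstacle_spec():
    return lf.make_scenario("obstacle", {"box_lengths": (14.0, 14.0),
                                         "radius": 2.5, "n_fluid": 60})


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_state(spec, seed=0):
    """Deterministic lattice state for a spec."""
    from localft.dynamics import build_initial_state
    return build_initial_state(spec, np.random.default_rng(seed))
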