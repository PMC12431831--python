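"""Shared fixtures: one simulated two-rod phantom study per session."""

from types import SimpleNamespace

import numpy as np
import pytest

from rmar import make_phantom, run_rmar, simulate_series
from rmar.phantom import default_fixtures
from rmar.spectral import AttenuationTable


@pytest.fixture(scope="session")
def table() -> AttenuationTable:
    return AttenuationTable.default()


@pytest.fixture(scope="session")
def rod_study():
    """Default two-rod solid-water phantom, simulated once (seed 1)."""
    fx = default_fixtures()["rods"]
    phantom = make_phantom(fx.spec)
    sim, truth = simulate_series(phantom, seed=1)
    return SimpleNamespace(fixture=fx, phantom=phantom, sim=sim, truth=truth)


@pytest.fixture(scope="session")
def rod_result(rod_study):
    """rMAR applied to the session rod study."""
    return run_rmar(rod_study.sim)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
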