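import numpy as np
import pytest

from kymoslide.kymosynth import (
    OpticsParams,
    SimulationParams,
    render_kymograph,
    simulate_pair,
)


@pytest.fixture(scope="session")
def basic_params() -> SimulationParams:
    """A small, fast-stalling event with growing end-tags."""
    return SimulationParams(ml1=8000.0, ml2=6000.0, s0=4000.0, duration=150.0)


@pytest.fixture(scope="session")
def saturated_params() -> SimulationParams:
    """Pre-formed, saturated end-tags: the roadblock-identity regime."""
    return SimulationParams(
        ml1=8000.0, ml2=7000.0, s0=2500.0, endtag_fraction=0.3,
        endtags_preformed=True, duration=200.0,
    )


@pytest.fixture(scope="session")
def bright_optics() -> OpticsParams:
    return OpticsParams()


@pytest.fixture(scope="session")
def noiseless_event(saturated_params, bright_optics):
    """(trajectory, noiseless kymograph) of the saturated event."""
    traj = simulate_pair(saturated_params)
    kymo = render_kymograph(traj, bright_optics, noise=False)
    return traj, kymo


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


# keep hypothesis stateless: derandomized examples, no on-disk example DB
from hypothesis import settings

settings.register_profile("ci", database=None, derandomize=True, deadline=None)
settings.load_profile("ci")
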