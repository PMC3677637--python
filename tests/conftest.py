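import numpy as np
import pytest

import osmoadapt as oa
from osmoadapt.simulate import StressProtocol, presstress_equilibrate, simulate


@pytest.fixture(scope="session")
def params():
    return oa.reference_parameters()


@pytest.fixture(scope="session")
def eq_state(params):
    """Wild-type pre-stress fixed point."""
    return presstress_equilibrate(params)


@pytest.fixture(scope="session")
def wt_traj(params):
    """Reference wild-type stress response, 0-180 min, 1-min grid."""
    return simulate(params, "WT")


@pytest.fixture(scope="session")
def hog1_traj(params):
    return simulate(params, "hog1D")


@pytest.fixture(scope="session")
def gpd1_traj(params):
    return simulate(params, "gpd1D")


@pytest.fixture(scope="session")
def fps1_traj(params):
    return simulate(params, "FPS1-D1")


@pytest.fixture(scope="session")
def protocol_240():
    return StressProtocol(t_end=240.0,
                          t_grid=np.arange(0.0, 241.0, 1.0))


def perturbed_state(eq_state, rng, rel=0.3):
    """A random valid state in the neighbourhood of the fixed point."""
    x = eq_state * rng.uniform(1 - rel, 1 + rel, size=eq_state.shape)
    x[oa.STATE_NAMES.index("Fps1o")] = rng.uniform(0.05, 0.95)
    return np.maximum(x, 0.0)
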