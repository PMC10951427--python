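import numpy as np
import pytest

from statescope.ensemble_io import Ensemble
from statescope.superposition import superpose_ensemble
from statescope.synthetic_data import (
    TwoStateSpec,
    make_endpoint_pair,
    make_toy_domain,
    make_two_state_ensemble,
    toy_layout,
)


@pytest.fixture(scope="session")
def toy_frame():
    return make_toy_domain(64)


@pytest.fixture(scope="session")
def layout():
    return toy_layout(64)


@pytest.fixture(scope="session")
def endpoints():
    alpha, beta, lay = make_endpoint_pair()
    return alpha, beta, lay


@pytest.fixture(scope="session")
def two_state(endpoints):
    """Small two-state ensemble (40 frames) plus its generating labels."""
    alpha, beta, lay = endpoints
    ens, labels = make_two_state_ensemble(
        TwoStateSpec(alpha, beta, n_frames=40, seed=77))
    return ens, labels, lay


@pytest.fixture(scope="session")
def fitted_two_state(two_state):
    ens, labels, lay = two_state
    fitted = superpose_ensemble(ens, ens.frames[0], lay.core_range)
    return fitted, labels, lay


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
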