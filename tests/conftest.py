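import numpy as np
import pytest

from ceimerge import RiskThresholds, SimParams, TrackGeometry, make_thresholds


@pytest.fixture(scope="session")
def geometry():
    return TrackGeometry()


@pytest.fixture(scope="session")
def params():
    return SimParams()


@pytest.fixture(scope="session")
def quiet_params():
    """All noise disabled: fully deterministic simulations."""
    return SimParams(beta=0.0, sigma_n=0.0)


@pytest.fixture(scope="session")
def pair3():
    """The driver pair with the strongest threshold asymmetry."""
    return make_thresholds(3, "left"), make_thresholds(3, "right")


@pytest.fixture(scope="session")
def passive_pair():
    """Two drivers that tolerate near-certain collision risk (no incentives)."""
    th = RiskThresholds(0.3, 0.99)
    return th, th


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
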