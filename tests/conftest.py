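import numpy as np
import pytest

from exposim.geometry import (
    URBAN_OZONE_CORRELATION,
    DistanceModel,
    GridLayout,
    build_covariance,
)


@pytest.fixture(scope="session")
def layout():
    return GridLayout()


@pytest.fixture(scope="session")
def dm():
    return DistanceModel()


@pytest.fixture(scope="session")
def urban_cm():
    return URBAN_OZONE_CORRELATION


@pytest.fixture(scope="session")
def urban_cov(layout, dm, urban_cm):
    return build_covariance(layout, dm, urban_cm, 25.28**2)


@pytest.fixture
def rng():
    return np.random.default_rng(20130613)
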