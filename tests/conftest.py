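import numpy as np
import pytest

import scaleshort as ss


@pytest.fixture(scope="session")
def ref_params() -> dict:
    """Reference GPCM calibration of the 12-item scale."""
    return dict(ss.REFERENCE_ITEM_PARAMS)


@pytest.fixture(scope="session")
def fixture404() -> ss.Fixture:
    """Default-profile synthetic study (404 persons, seed 7)."""
    return ss.make_fixture(ss.SimulationProfile(seed=7))


@pytest.fixture(scope="session")
def fit404(fixture404) -> ss.GpcmFit:
    """Pooled single-group GPCM fit of the default fixture."""
    return ss.fit_gpcm(fixture404.matrix, se=False)


@pytest.fixture(scope="session")
def small_fixture() -> ss.Fixture:
    """A quicker 150-person fixture for estimation-path tests."""
    return ss.make_fixture(ss.SimulationProfile(n_persons=150, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
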