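import numpy as np
import pytest

from aurorab.params import OneSiteParams


@pytest.fixture(scope="session")
def ref_params() -> OneSiteParams:
    """Reference one-site constant set (commercial chemosensor)."""
    return OneSiteParams.defaults()


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20231104)
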