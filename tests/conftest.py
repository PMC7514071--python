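import numpy as np
import pytest

from impactsize import ImpactConfig
from impactsize.synthetic import make_dataset4


@pytest.fixture(scope="session")
def dataset4():
    """One fixed 20-variable benchmark matrix shared across tests."""
    return make_dataset4(seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)


@pytest.fixture
def default_config():
    return ImpactConfig()
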