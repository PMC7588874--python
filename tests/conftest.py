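import numpy as np
import pytest

from rdnaquant.models import CohortConfig
from rdnaquant.synthetic_data import default_unit_model


@pytest.fixture(scope="session")
def unit():
    return default_unit_model()


@pytest.fixture(scope="session")
def unit_b2():
    return default_unit_model(include_bamhi2=True)


@pytest.fixture
def small_config():
    """A fast cohort for pipeline-level tests."""
    return CohortConfig(n_mice=3, cells_per_mouse=40, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
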