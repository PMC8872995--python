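import numpy as np
import pytest

from crpconn.parcellation import default_parcellation
from crpconn.synth import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def meta():
    return default_parcellation()


@pytest.fixture(scope="session")
def cohort():
    """Full-size study cohort (46 HC, 50 loCRP, 33 hiCRP)."""
    return generate_cohort(CohortConfig(), seed=11)


@pytest.fixture(scope="session")
def tiny_config():
    """Small cohort/panel configuration for fast end-to-end tests."""
    return CohortConfig(n_hc=6, n_locrp=6, n_hicrp=6, t_points=64)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
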