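import numpy as np
import pytest

from mtgs.datamodel import GenotypeMatrix, PhenotypeMatrix, PriorConfig
from mtgs.simulator import fast_config, generate_dataset


@pytest.fixture
def toy_data():
    """Small deterministic two-trait dataset with one strong SNP signal."""
    rng = np.random.default_rng(123)
    n = 40
    U = rng.integers(-1, 2, size=(n, 5)).astype(np.int8)
    sigma_e = np.array([[1.0, 0.3], [0.3, 1.0]])
    g1 = np.array([0.9, 0.6])
    y = (np.array([0.5, -0.2]) + U[:, [0]] * g1
         + rng.multivariate_normal(np.zeros(2), sigma_e, size=n))
    return GenotypeMatrix(U), PhenotypeMatrix(y)


@pytest.fixture(scope="session")
def fast_dataset():
    """One miniature simulated replicate shared across tests."""
    return generate_dataset("data1", fast_config(seed=3))


@pytest.fixture
def shrinkage_priors():
    return PriorConfig(pi_mode="fixed_zero")
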