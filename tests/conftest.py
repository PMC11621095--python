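import numpy as np
import pytest

import fcnet


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small cohort for fast end-to-end tests: 12 regions, 3 modules."""
    return fcnet.CohortSpec(
        n_patients=4,
        n_controls=4,
        n_regions=12,
        n_modules=3,
        n_volumes=120,
        seed=99,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return fcnet.generate_cohort(tiny_spec)


def random_binary_network(rng, n, p=0.3):
    """ER graph as a BinaryNetwork (helper shared across test modules)."""
    a = (rng.random((n, n)) < p).astype(np.uint8)
    a = np.triu(a, 1)
    a = a + a.T
    return fcnet.BinaryNetwork(a, sparsity=max(a.sum() / (n * (n - 1)), 1e-6))
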