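import numpy as np
import pytest

from sigmixture import MixParameters, MutationCatalog


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_params():
    """L=2 clusters, K=2 signatures, M=2 categories with degenerate emissions."""
    return MixParameters(
        w=np.array([0.5, 0.5]),
        pi=np.array([[1.0, 0.0], [0.0, 1.0]]),
        e=np.array([[1.0, 0.0], [0.0, 1.0]]),
    )


@pytest.fixture
def small_catalog(rng):
    """8 samples over 6 categories with moderate counts, one all-zero sample."""
    counts = rng.integers(0, 12, size=(8, 6))
    counts[3] = 0
    return MutationCatalog(counts)


def random_params(rng, L, K, M):
    return MixParameters(
        w=rng.dirichlet(np.ones(L)),
        pi=rng.dirichlet(np.ones(K), size=L),
        e=rng.dirichlet(np.ones(M), size=K),
    )


def random_catalog(rng, N, M, max_count=10):
    return MutationCatalog(rng.integers(0, max_count, size=(N, M)))
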