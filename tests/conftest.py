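import numpy as np
import pytest
from hypothesis import settings, HealthCheck

from gwsn import GWSNParams, WeightedNetwork

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def triangle():
    return WeightedNetwork.from_edges(3, [(0, 1, 1.0), (1, 2, 1.0), (0, 2, 1.0)])


@pytest.fixture
def star_k14():
    return WeightedNetwork.from_edges(5, [(0, i, 1.0) for i in range(1, 5)])


@pytest.fixture
def path3():
    return WeightedNetwork.from_edges(3, [(0, 1, 1.0), (1, 2, 1.0)])


@pytest.fixture
def k4():
    return WeightedNetwork.from_edges(
        4, [(i, j, 1.0) for i in range(4) for j in range(i + 1, 4)])


def random_weighted_network(rng, n_max=30):
    """A small random weighted graph for oracle cross-checks."""
    n = int(rng.integers(3, n_max + 1))
    p = rng.uniform(0.1, 0.6)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < p:
                edges.append((i, j, float(rng.uniform(0.5, 5.0))))
    if len(edges) < 2:  # keep percolation and correlations defined
        edges = [(0, 1, 1.0), (1, 2, 2.0)]
    return WeightedNetwork.from_edges(n, edges)


@pytest.fixture
def sparse_params():
    """A small, quickly-equilibrating parameter set for smoke runs."""
    return GWSNParams(N=120, F=2, q=2, alpha=0.0, p_r=2e-3, p_delta=0.02,
                      w_r=1.0, p_nd=2e-3, p_ld=1e-4, A=1e-3)
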