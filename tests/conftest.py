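import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import isingscape as isc

settings.register_profile(
    "ci",
    deadline=None,
    derandomize=True,
    max_examples=40,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_independent_net():
    """Two independent nodes with zero thresholds: all microstates equal."""
    return isc.IsingNetwork(
        labels=("a", "b"), thresholds=np.zeros(2), weights=np.zeros((2, 2))
    )


@pytest.fixture
def toy_coupled_net():
    """Two nodes, zero thresholds, one edge of weight ln 2."""
    w = np.array([[0.0, np.log(2)], [np.log(2), 0.0]])
    return isc.IsingNetwork(labels=("a", "b"), thresholds=np.zeros(2), weights=w)


@pytest.fixture
def make_random_net():
    """Factory for seeded random networks of a given size."""

    def _make(n_nodes, seed, **kwargs):
        return isc.random_network(n_nodes, seed, **kwargs)

    return _make


def poisson_binomial_pmf(probs):
    """Distribution of a sum of independent Bernoulli variables.

    Dynamic-programming convolution; serves as the closed-form oracle
    for landscapes of networks without edges.
    """
    pmf = np.array([1.0])
    for p in probs:
        pmf = np.convolve(pmf, [1.0 - p, p])
    return pmf
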