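import numpy as np
import pytest

from connrepro import SyntheticConfig, generate_cohort


def random_weighted_graph(n, density, rng, distinct=True):
    """Symmetric non-negative random weight matrix with zero diagonal.

    Weights are drawn continuous (distinct with probability one) so that
    MST / shortest-path tie-breaking never matters in oracle comparisons.
    """
    W = np.zeros((n, n))
    iu, ju = np.triu_indices(n, k=1)
    present = rng.random(iu.size) < density
    w = rng.uniform(0.1, 1.0, size=iu.size)
    W[iu[present], ju[present]] = w[present]
    return W + W.T


@pytest.fixture(scope="session")
def small_cohort():
    """A 5-participant, 20-node cohort with moderate retest noise."""
    config = SyntheticConfig(
        n_participants=5, n_nodes=20, density=0.4, retest_correlation=0.9,
        dropout_rate=0.2, seed=42,
    )
    return generate_cohort(config)


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Zero-noise limit: identical scans, no dropout."""
    config = SyntheticConfig(
        n_participants=4, n_nodes=16, density=0.4, retest_correlation=1.0,
        dropout_rate=0.0, seed=7,
    )
    return generate_cohort(config)
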