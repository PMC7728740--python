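import numpy as np
import pytest

from gwpred import simulate_genotypes, simulate_trait


@pytest.fixture(scope="session")
def small_panel():
    """120 samples x 80 unlinked markers."""
    return simulate_genotypes(120, 80, seed=11)


@pytest.fixture(scope="session")
def small_trait(small_panel):
    return simulate_trait(small_panel, n_qtl=5, h2a=0.5, seed=12)


@pytest.fixture(scope="session")
def sparse_panel():
    """Mid-sized panel with a sparse 10-QTL trait, for signal-recovery checks."""
    G = simulate_genotypes(300, 500, seed=21)
    y, truth = simulate_trait(G, n_qtl=10, h2a=0.5, seed=22)
    return G, y, truth


def rng(seed=0):
    return np.random.default_rng(seed)
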