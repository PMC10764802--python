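import numpy as np
import pytest
import scipy.sparse as sp

from sclsc import ExpressionMatrix, SimConfig, simulate_counts


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def small_counts(rng):
    """20 cells x 12 genes random sparse count matrix, no labels."""
    dense = rng.poisson(2.0, size=(20, 12))
    return ExpressionMatrix(
        values=sp.csr_matrix(dense),
        cell_ids=[f"c{i}" for i in range(20)],
        gene_ids=[f"g{j}" for j in range(12)],
    )


@pytest.fixture(scope="session")
def two_group_sim():
    """Well-separated 2-group simulation reused by several training tests."""
    cfg = SimConfig(
        n_cells=400,
        n_genes=200,
        group_probs=(0.5, 0.5),
        de_prob=0.3,
        de_fac_loc=1.0,
        seed=7,
    )
    return simulate_counts(cfg)
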