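import numpy as np
import pytest
import scipy.sparse as sp

from dropcell import CountMatrix, SimConfig, generate_synthetic_input, simulate_sim_ia


def make_matrix(dense, gene_ids=None, barcode_ids=None, symbols=None):
    dense = np.asarray(dense)
    g, b = dense.shape
    return CountMatrix(
        gene_ids or [f"g{i}" for i in range(g)],
        barcode_ids or [f"b{j}" for j in range(b)],
        sp.csc_matrix(dense),
        gene_symbols=symbols,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def small_input():
    """Modest synthetic droplet experiment shared across tests."""
    return generate_synthetic_input(
        n_genes=800, n_cell_types=3, n_cells=700, n_ambient=4000, seed=123
    )


@pytest.fixture(scope="session")
def small_sim(small_input):
    return simulate_sim_ia(small_input, SimConfig(n_per_group=200, seed=9))


@pytest.fixture
def random_matrix(rng):
    dense = rng.poisson(1.0, size=(40, 30))
    dense[:, 0] += 5  # make sure no all-zero barcode
    dense[0, :] += 1
    return make_matrix(dense)
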