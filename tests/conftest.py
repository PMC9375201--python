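import numpy as np
import pytest

import mcgrain as mg


@pytest.fixture(scope="session")
def blob_data():
    """Well-separated 5-blob log-expression dataset (small, fast)."""
    values, labels, gene_ids, cell_ids = mg.simulate_blobs(
        n_cells=600, n_genes=120, n_types=5, n_informative=20, separation=5.0, seed=7
    )
    expr = mg.ExpressionMatrix(values, gene_ids, cell_ids)
    return expr, labels


@pytest.fixture(scope="session")
def blob_partition(blob_data):
    expr, labels = blob_data
    part, emb, graph = mg.make_metacells(expr, gamma=10, n_hvg=120)
    return part, emb, graph


@pytest.fixture(scope="session")
def counts_data():
    """Negative-binomial counts with spiked markers and dropout."""
    return mg.simulate_counts(
        n_cells=500, n_genes=200, n_types=4, de_frac=0.05, effect_lfc=2.0,
        dropout_rate=0.3, seed=11,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
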