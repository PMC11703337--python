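import networkx as nx
import numpy as np
import pytest

from msclust import ScenarioSpec, simulate_dataset
from msclust.similarity import ExpressionMatrix, pearson_similarity


@pytest.fixture(scope="session")
def three_block_dataset():
    """Three well-separated Gaussian blocks of 30 cells each."""
    spec = ScenarioSpec(
        scenario="I",
        inner_sizes=(30, 30, 30),
        rho_in=0.8,
        sigma=0.5,
        n_features=300,
        seed=7,
    )
    return simulate_dataset(spec)


@pytest.fixture(scope="session")
def three_block_expr(three_block_dataset):
    ds = three_block_dataset
    gene_ids = [f"g{i}" for i in range(ds.data.shape[0])]
    return ExpressionMatrix(ds.data.T, list(ds.sample_ids), gene_ids)


@pytest.fixture(scope="session")
def three_block_sim(three_block_expr):
    return pearson_similarity(three_block_expr)


@pytest.fixture()
def two_cliques():
    """Two disconnected 6-cliques on nodes 0-5 and 6-11."""
    g = nx.Graph()
    g.add_edges_from(nx.complete_graph(range(6)).edges())
    g.add_edges_from(nx.complete_graph(range(6, 12)).edges())
    return g


def random_similarity(n, seed):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n, n))
    s = (a + a.T) / 2
    np.fill_diagonal(s, s.max() + 1)
    return s
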