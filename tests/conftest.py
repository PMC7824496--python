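import networkx as nx
import numpy as np
import pytest

from mnbdr import simulate_benchmark, simulate_ppi


@pytest.fixture(scope="session")
def default_synthetic():
    """One default-regime synthetic benchmark shared across tests."""
    graph, truth = simulate_ppi(seed=11)
    diseases, drugs, standard = simulate_benchmark(truth, seed=12)
    return graph, truth, diseases, drugs, standard


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def clique(n: int, prefix: str = "v") -> nx.Graph:
    g = nx.complete_graph(n)
    return nx.relabel_nodes(g, {i: f"{prefix}{i}" for i in g.nodes})
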