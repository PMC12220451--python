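import networkx as nx
import numpy as np
import pytest

from repowalk import (
    HeterogeneousNetwork,
    SyntheticConfig,
    TypedEdge,
    generate,
)


def ppi_network(g: nx.Graph, prefix: str = "T") -> HeterogeneousNetwork:
    """Wrap an arbitrary networkx graph as a target-target network."""
    net = HeterogeneousNetwork()
    relabel = {n: f"{prefix}{n:03d}" if isinstance(n, int) else str(n) for n in g.nodes}
    for u, v in g.edges:
        net.add_edge(TypedEdge(relabel[u], relabel[v], "target-target"))
    for n in g.nodes:
        net.add_node(relabel[n], "target")
    return net


def random_ppi(n: int, p: float, seed: int) -> HeterogeneousNetwork:
    return ppi_network(nx.gnp_random_graph(n, p, seed=seed))


@pytest.fixture(scope="session")
def synthetic_default():
    """One default-config synthetic dataset shared across tests."""
    return generate(SyntheticConfig(seed=11))


@pytest.fixture()
def five_node_net():
    """Small fixture where all second-order transitions can be checked
    by hand: square a-b-c-d with diagonal a-c and pendant e on a."""
    net = HeterogeneousNetwork()
    for u, v in [("Ta", "Tb"), ("Tb", "Tc"), ("Tc", "Td"), ("Td", "Ta"),
                 ("Ta", "Tc"), ("Ta", "Te")]:
        net.add_edge(TypedEdge(u, v, "target-target"))
    return net


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
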