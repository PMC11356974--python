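import networkx as nx
import numpy as np
import pandas as pd
import pytest

from emnet import SimParams, simulate_dataset


@pytest.fixture
def tiny_table() -> pd.DataFrame:
    return pd.DataFrame([[3, 0], [1, 2]], index=["s1", "s2"],
                        columns=["t1", "t2"])


@pytest.fixture(scope="session")
def default_dataset():
    return simulate_dataset(SimParams(seed=0))


@pytest.fixture(scope="session")
def small_sim_params() -> SimParams:
    """Generator settings for replicated Monte-Carlo tests (defaults)."""
    return SimParams(seed=0)


@pytest.fixture
def five_node_graph() -> nx.Graph:
    """Hand-enumerable network: square a-b-c-d-a plus pendant e on a."""
    g = nx.Graph()
    for u, v in [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "e")]:
        g.add_edge(u, v, rho=0.9, p_value=1e-5, sign=1)
    return g


def three_clique_bridge_graph(rng: np.random.Generator) -> tuple[nx.Graph, str]:
    """Three cliques (8, 6, 5 nodes) plus one bridge with two random
    attachments per clique; the bridge's participation coefficient is
    1 - 3 (2/6)^2 = 2/3 regardless of its module assignment."""
    g = nx.Graph()
    cliques = []
    start = 0
    for size in (8, 6, 5):
        nodes = [f"n{j:02d}" for j in range(start, start + size)]
        cliques.append(nodes)
        g.add_edges_from((a, b) for i, a in enumerate(nodes)
                         for b in nodes[i + 1:])
        start += size
    bridge = "bridge"
    for clique in cliques:
        for u in rng.choice(clique, size=2, replace=False):
            g.add_edge(bridge, u)
    return g, bridge
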