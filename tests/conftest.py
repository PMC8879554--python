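import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mitonet.io_formats import Interactome, SpotIntensityTable


@pytest.fixture
def toy_table() -> SpotIntensityTable:
    """2 measured spots + reference, 2 groups × 2 gels."""
    df = pd.DataFrame(
        {
            "g1": [10.0, 40.0, 100.0],
            "g2": [30.0, 60.0, 200.0],
            "g3": [20.0, 10.0, 100.0],
            "g4": [44.0, 12.0, 400.0],
        },
        index=["S1", "S2", "ALB"],
    )
    groups = {"g1": "A", "g2": "A", "g3": "B", "g4": "B"}
    return SpotIntensityTable(df, groups, "ALB")


def two_triangles() -> Interactome:
    g = nx.Graph()
    for a, b in [("a", "b"), ("b", "c"), ("a", "c"), ("x", "y"), ("y", "z"), ("x", "z")]:
        g.add_edge(a, b, weight=1.0)
    return Interactome(g)


@pytest.fixture
def triangles() -> Interactome:
    return two_triangles()


def random_weighted_graph(rng: np.random.Generator, n_max: int = 7) -> nx.Graph:
    """A small random connected weighted graph (for oracle comparisons)."""
    n = int(rng.integers(2, n_max + 1))
    while True:
        p = float(rng.uniform(0.3, 0.9))
        g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
        if nx.is_connected(g):
            break
    for u, v in g.edges:
        g[u][v]["weight"] = float(rng.uniform(0.2, 1.0))
    return g
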