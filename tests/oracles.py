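"""Independent reference implementations used only to check mitonet.

These deliberately share no code with the package: the MCL reference is a
plain dense-matrix loop with no pruning and a much stricter tolerance, the
hypergeometric oracle literally enumerates draws, and BH is done by hand.
"""

from __future__ import annotations

import itertools
from math import comb

import networkx as nx
import numpy as np


def mcl_reference(
    graph: nx.Graph,
    inflation: float,
    expansion: int = 2,
    tol: float = 1e-12,
    structure: float = 1e-5,
    max_iter: int = 10000,
) -> frozenset:
    """Dense, pruning-free Markov clustering; returns a set of frozensets."""
    nodes = sorted(graph.nodes, key=str)
    a = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    loops = a.max(axis=0)
    loops[loops == 0] = 1.0
    np.fill_diagonal(a, loops)
    m = a / a.sum(axis=0)
    for _ in range(max_iter):
        new = np.linalg.matrix_power(m, expansion) ** inflation
        new = new / new.sum(axis=0)
        done = np.abs(new - m).max() < tol
        m = new
        if done:
            break
    support = m > structure
    support = support | support.T
    comps = nx.connected_components(nx.from_numpy_array(support))
    return frozenset(frozenset(nodes[i] for i in comp) for comp in comps)


def hypergeom_enumerate(k: int, K: int, n: int, N: int) -> float:
    """P[X >= k] by exhaustive enumeration of all size-n draws from N items."""
    annotated = set(range(K))
    total = comb(N, n)
    hits = sum(
        1
        for draw in itertools.combinations(range(N), n)
        if len(annotated.intersection(draw)) >= k
    )
    return hits / total


def hypergeom_tail_counts(K: int, n: int, N: int) -> dict[int, float]:
    """P[X >= k] for every k at once, via one enumeration pass."""
    annotated = set(range(K))
    counts = np.zeros(min(n, K) + 1)
    for draw in itertools.combinations(range(N), n):
        counts[len(annotated.intersection(draw))] += 1
    total = comb(N, n)
    tail = np.cumsum(counts[::-1])[::-1] / total
    return {k: float(tail[k]) for k in range(len(counts))}


def bh_by_hand(p: list[float]) -> list[float]:
    """Benjamini–Hochberg step-up, written the long way."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * m / rank_from_top)
        adjusted[i] = running
    return adjusted
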