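"""PPI network construction, edge-enrichment testing and Markov clustering.

The differential proteins are projected onto a background interactome,
their internal connectivity is tested against same-sized random node sets
(a permutation analogue of the STRING expected-edges test), and the induced
network is partitioned with a from-scratch Markov Cluster (MCL) algorithm:
alternating expansion (matrix power) and inflation (entrywise power with
column renormalization) of a column-stochastic transition matrix until the
matrix reaches its attractor structure.  The inflation parameter controls
granularity; 1.4 — the conventional "coarse clusters" setting — is the
default.
"""

from __future__ import annotations

import warnings
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .io_formats import Interactome, ValidationError

__all__ = [
    "MCLParams",
    "ClusterPartition",
    "PPIEnrichment",
    "induce_network",
    "ppi_enrichment",
    "mcl",
    "modularity",
]


@dataclass(frozen=True)
class MCLParams:
    """Markov clustering parameters.

    inflation
        Entrywise power r > 1 applied after each expansion; larger values
        give finer clusters.  Default 1.4.
    expansion
        Matrix power e >= 2 (integer) simulating random-walk flow.
    pruning_threshold
        Entries below this are zeroed after inflation (with column
        renormalization) to keep iterates sparse in effect.
    max_iterations, convergence_epsilon
        Iteration stops when the max entrywise change drops below epsilon
        or after max_iterations (then ``converged`` is False).
    self_loop_weight
        ``"max"`` adds a self-loop equal to the column's maximum edge
        weight (the standard stabilization; isolated nodes get 1.0), or a
        positive float for a fixed loop weight.
    """

    inflation: float = 1.4
    expansion: int = 2
    pruning_threshold: float = 1e-5
    max_iterations: int = 200
    convergence_epsilon: float = 1e-8
    self_loop_weight: float | str = "max"

    def __post_init__(self):
        if not self.inflation > 1:
            raise ValidationError(f"inflation must be > 1, got {self.inflation}")
        if int(self.expansion) != self.expansion or self.expansion < 2:
            raise ValidationError(
                f"expansion must be an integer >= 2, got {self.expansion}"
            )
        if not self.pruning_threshold > 0:
            raise ValidationError("pruning_threshold must be > 0")
        if not self.convergence_epsilon > 0:
            raise ValidationError("convergence_epsilon must be > 0")
        if isinstance(self.self_loop_weight, str):
            if self.self_loop_weight != "max":
                raise ValidationError(
                    f"unknown self_loop_weight policy {self.self_loop_weight!r}"
                )
        elif not self.self_loop_weight > 0:
            raise ValidationError("self_loop_weight must be > 0")


@dataclass(frozen=True)
class ClusterPartition:
    """Node→cluster assignment; ids are dense ints ordered by cluster size.

    Cluster 0 is the largest; ties in size are ordered by smallest member
    id (string order) so the labeling is invariant to node input order.
    """

    node_to_cluster: Mapping
    clusters: tuple[frozenset, ...]
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self):
        covered: set = set()
        for c in self.clusters:
            if covered & set(c):
                raise ValidationError("clusters overlap; not a partition")
            covered |= set(c)
        if covered != set(self.node_to_cluster):
            raise ValidationError("node_to_cluster and clusters disagree")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters]


@dataclass(frozen=True)
class PPIEnrichment:
    """Permutation test of internal edge count vs same-sized random sets."""

    observed_edges: int
    null_mean: float
    p_value: float
    n_permutations: int

    def __post_init__(self):
        lower = 1.0 / (self.n_permutations + 1)
        if not (lower <= self.p_value <= 1.0):
            raise ValidationError(
                f"p-value {self.p_value} outside [{lower}, 1]"
            )


def induce_network(background: Interactome, node_set: Iterable) -> tuple[Interactome, list]:
    """Subgraph of the background induced on ``node_set``.

    Nodes absent from the background are retained as isolates and returned
    as the second element so callers can report them.
    """
    node_set = set(node_set)
    if not node_set:
        raise ValidationError("node_set is empty")
    present = [n for n in node_set if background.graph.has_node(n)]
    missing = sorted(node_set - set(present), key=str)
    if not present:
        warnings.warn("node_set is disjoint from the background interactome")
    g = nx.Graph(background.graph.subgraph(present))
    g.add_nodes_from(missing)
    return Interactome(g), missing


def _degree_bins(degrees: np.ndarray, n_bins: int = 10) -> np.ndarray:
    """Assign nodes to degree-quantile bins (for the degree-matched null)."""
    edges = np.quantile(degrees, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(edges, degrees, side="left")


def ppi_enrichment(
    background: Interactome,
    node_set: Iterable,
    n_permutations: int = 1000,
    seed=0,
    degree_matched: bool = False,
) -> PPIEnrichment:
    """Test whether ``node_set`` has more internal edges than random sets.

    The null resamples node sets of the same size uniformly from the
    background (or matched on degree deciles when ``degree_matched``); the
    p-value is ``(1 + #{null >= observed}) / (n_permutations + 1)``.
    """
    if n_permutations < 100:
        raise ValidationError(
            f"n_permutations must be >= 100, got {n_permutations}"
        )
    nodes = list(background.graph.nodes)
    n = len(nodes)
    node_set = set(node_set)
    if len(node_set) > n:
        raise ValidationError(
            f"node_set ({len(node_set)}) larger than background ({n})"
        )
    index = {node: i for i, node in enumerate(nodes)}
    sample = np.array(sorted((index[x] for x in node_set if x in index)), dtype=int)
    m = len(sample)

    adj = nx.to_numpy_array(background.graph, nodelist=nodes, weight=None) > 0
    observed = int(adj[np.ix_(sample, sample)].sum() // 2) if m else 0

    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations, dtype=int)
    if degree_matched and m:
        degrees = adj.sum(axis=1)
        bins = _degree_bins(degrees)
        by_bin = {b: np.flatnonzero(bins == b) for b in np.unique(bins)}
        need = {b: int((bins[sample] == b).sum()) for b in np.unique(bins[sample])}
        for i in range(n_permutations):
            pick = np.concatenate(
                [rng.choice(by_bin[b], size=k, replace=False) for b, k in need.items()]
            )
            null[i] = adj[np.ix_(pick, pick)].sum() // 2
    else:
        for i in range(n_permutations):
            pick = rng.choice(n, size=m, replace=False)
            null[i] = adj[np.ix_(pick, pick)].sum() // 2
    p = (1 + int((null >= observed).sum())) / (n_permutations + 1)
    return PPIEnrichment(
        observed_edges=observed,
        null_mean=float(null.mean()),
        p_value=p,
        n_permutations=n_permutations,
    )


def _extract_clusters(limit: np.ndarray, threshold: float) -> list[list[int]]:
    """Clusters = connected components of the limit matrix's support."""
    support = (limit > threshold)
    support = support | support.T
    n = limit.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps: list[list[int]] = []
    for start in range(n):
        if seen[start]:
            continue
        stack = [start]
        seen[start] = True
        comp = []
        while stack:
            i = stack.pop()
            comp.append(i)
            for j in np.flatnonzero(support[i]):
                if not seen[j]:
                    seen[j] = True
                    stack.append(int(j))
        comps.append(comp)
    return comps


def mcl(network: Interactome, params: MCLParams | None = None) -> ClusterPartition:
    """Markov clustering of a weighted network.  Fully deterministic.

    Self-loops are added per ``params.self_loop_weight``, the adjacency is
    column-normalized, and expansion/inflation/pruning iterate until the
    matrix stops changing.  Clusters are the connected components of the
    limit matrix's nonzero structure; isolated nodes become singletons.
    Non-convergence within ``max_iterations`` is reported via the
    ``converged`` flag and a warning, never silently.
    """
    if params is None:
        params = MCLParams()
    nodes = list(network.graph.nodes)
    if not nodes:
        raise ValidationError("network is empty")
    n = len(nodes)
    a = nx.to_numpy_array(network.graph, nodelist=nodes, weight="weight")
    if isinstance(params.self_loop_weight, str):  # "max" policy
        loops = a.max(axis=0)
        loops[loops == 0] = 1.0
    else:
        loops = np.full(n, float(params.self_loop_weight))
    np.fill_diagonal(a, loops)
    m = a / a.sum(axis=0)

    converged = False
    iterations = 0
    for iterations in range(1, params.max_iterations + 1):
        new = np.linalg.matrix_power(m, int(params.expansion))
        new **= params.inflation
        new[new < params.pruning_threshold] = 0.0
        colsum = new.sum(axis=0)
        dead = colsum == 0  # pruning emptied the column: pin to self
        if dead.any():
            new[np.flatnonzero(dead), np.flatnonzero(dead)] = 1.0
            colsum = new.sum(axis=0)
        new /= colsum
        change = float(np.abs(new - m).max())
        m = new
        if change < params.convergence_epsilon:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"MCL did not converge within {params.max_iterations} iterations"
        )

    comps = _extract_clusters(m, params.pruning_threshold)
    named = [frozenset(nodes[i] for i in comp) for comp in comps]
    named.sort(key=lambda c: (-len(c), min(str(x) for x in c)))
    node_to_cluster = {}
    for cid, cluster in enumerate(named):
        for node in cluster:
            node_to_cluster[node] = cid
    return ClusterPartition(
        node_to_cluster=node_to_cluster,
        clusters=tuple(named),
        converged=converged,
        n_iterations=iterations,
    )


def modularity(network: Interactome, partition) -> float:
    """Weighted Newman modularity of a partition, in [-0.5, 1]."""
    if isinstance(partition, ClusterPartition):
        mapping = partition.node_to_cluster
    else:
        mapping = partition
    nodes = set(network.graph.nodes)
    uncovered = nodes - set(mapping)
    if uncovered:
        raise ValidationError(
            f"partition does not cover nodes: {sorted(uncovered, key=str)}"
        )
    if network.graph.number_of_edges() == 0:
        raise ValidationError("modularity undefined for an edgeless network")
    groups: dict = {}
    for node in nodes:
        groups.setdefault(mapping[node], set()).add(node)
    return float(
        nx.algorithms.community.modularity(
            network.graph, list(groups.values()), weight="weight"
        )
    )
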