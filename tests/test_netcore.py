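"""Network induction, PPI edge enrichment, MCL, modularity."""

import networkx as nx
import numpy as np
import pytest

from conftest import random_weighted_graph, two_triangles
from mitonet.io_formats import Interactome, ValidationError
from mitonet.netcore import (
    MCLParams,
    induce_network,
    mcl,
    modularity,
    ppi_enrichment,
)
from oracles import mcl_reference


class TestInduceNetwork:
    def test_two_of_three_triangle_nodes_leave_one_edge(self):
        bg = Interactome.from_edges(
            [("a", "b", 0.5), ("b", "c", 0.5), ("a", "c", 0.5)]
        )
        net, missing = induce_network(bg, {"a", "b"})
        assert net.n_edges == 1 and missing == []

    def test_disjoint_node_set_all_isolates(self):
        bg = Interactome.from_edges([("a", "b", 0.5)])
        with pytest.warns(UserWarning, match="disjoint"):
            net, missing = induce_network(bg, {"p", "q"})
        assert net.n_edges == 0 and net.n_nodes == 2
        assert missing == ["p", "q"]

    def test_degree_equals_within_subgraph_degree(self):
        bg = Interactome.from_edges(
            [("a", "b", 0.5), ("b", "c", 0.5), ("c", "d", 0.5), ("a", "c", 0.5)]
        )
        net, _ = induce_network(bg, {"a", "b", "c"})
        assert dict(net.graph.degree) == {"a": 2, "b": 2, "c": 2}


class TestPPIEnrichment:
    def test_zero_observed_edges_gives_p_one(self):
        bg = Interactome.from_edges(
            [("a", "b", 0.5)], nodes=[f"n{i}" for i in range(20)]
        )
        enr = ppi_enrichment(bg, {"n1", "n2", "n3"}, n_permutations=100, seed=0)
        assert enr.observed_edges == 0 and enr.p_value == 1.0

    def test_whole_background_gives_p_one(self):
        g = nx.gnp_random_graph(12, 0.4, seed=1)
        for u, v in g.edges:
            g[u][v]["weight"] = 0.5
        bg = Interactome(g)
        enr = ppi_enrichment(bg, set(g.nodes), n_permutations=100, seed=0)
        assert enr.p_value == 1.0

    def test_planted_clique_is_detected(self):
        g = nx.gnp_random_graph(100, 0.02, seed=3)
        for u, v in g.edges:
            g[u][v]["weight"] = 0.8
        for i in range(8):
            for j in range(i + 1, 8):
                g.add_edge(i, j, weight=0.9)
        enr = ppi_enrichment(Interactome(nx.Graph(g)), set(range(8)),
                             n_permutations=1000, seed=5)
        assert enr.p_value <= 0.01
        assert enr.observed_edges >= 28

    def test_determinism_and_degree_matched_variant(self):
        g = nx.gnp_random_graph(50, 0.1, seed=9)
        for u, v in g.edges:
            g[u][v]["weight"] = 0.5
        bg = Interactome(g)
        a = ppi_enrichment(bg, set(range(10)), n_permutations=200, seed=1)
        b = ppi_enrichment(bg, set(range(10)), n_permutations=200, seed=1)
        assert a == b
        dm = ppi_enrichment(
            bg, set(range(10)), n_permutations=200, seed=1, degree_matched=True
        )
        assert dm.n_permutations == 200

    def test_node_set_larger_than_background_rejected(self):
        bg = Interactome.from_edges([("a", "b", 0.5)])
        with pytest.raises(ValidationError, match="larger"):
            ppi_enrichment(bg, {"a", "b", "c"}, n_permutations=100)


class TestMCL:
    def test_disjoint_triangles_stay_separate(self, triangles):
        part = mcl(triangles)
        assert set(map(frozenset, part.clusters)) == {
            frozenset("abc"),
            frozenset("xyz"),
        }

    def test_single_edge_single_cluster(self):
        net = Interactome.from_edges([("A", "B", 0.9)])
        part = mcl(net)
        assert part.clusters == (frozenset({"A", "B"}),)

    def test_isolates_become_singletons(self):
        net = Interactome.from_edges([("A", "B", 0.9)], nodes=["A", "B", "C"])
        part = mcl(net)
        assert frozenset({"C"}) in part.clusters

    def test_matches_independent_reference_on_small_graphs(self):
        rng = np.random.default_rng(123)
        for _ in range(60):
            g = random_weighted_graph(rng)
            for inflation in (1.4, 2.0):
                mine = frozenset(
                    mcl(Interactome(nx.Graph(g)), MCLParams(inflation=inflation)).clusters
                )
                assert mine == mcl_reference(g, inflation)

    def test_node_permutation_invariance(self):
        rng = np.random.default_rng(7)
        g = random_weighted_graph(rng, n_max=7)
        base = frozenset(mcl(Interactome(nx.Graph(g))).clusters)
        perm = list(g.nodes)
        rng.shuffle(perm)
        relabeled = nx.relabel_nodes(g, dict(zip(g.nodes, perm)))
        h = nx.Graph()
        h.add_nodes_from(sorted(relabeled.nodes))
        h.add_weighted_edges_from(
            (u, v, d["weight"]) for u, v, d in relabeled.edges(data=True)
        )
        inverse = {b: a for a, b in zip(g.nodes, perm)}
        back = frozenset(
            frozenset(inverse[n] for n in cluster)
            for cluster in mcl(Interactome(h)).clusters
        )
        assert back == base

    def test_clusters_never_span_components(self):
        rng = np.random.default_rng(21)
        g1 = random_weighted_graph(rng, n_max=5)
        g2 = nx.relabel_nodes(random_weighted_graph(rng, n_max=5), lambda n: f"b{n}")
        combined = Interactome(nx.compose(nx.Graph(g1), nx.Graph(g2)))
        part = mcl(combined)
        comp_of = {}
        for cid, comp in enumerate(nx.connected_components(combined.graph)):
            for n in comp:
                comp_of[n] = cid
        for cluster in part.clusters:
            assert len({comp_of[n] for n in cluster}) == 1

    def test_cluster_ids_ordered_by_size(self, triangles):
        g = triangles.graph.copy()
        g.add_edge("c", "d", weight=1.0)
        g.add_edge("d", "e", weight=0.2)
        part = mcl(Interactome(g))
        sizes = part.sizes()
        assert sizes == sorted(sizes, reverse=True)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValidationError):
            MCLParams(inflation=1.0)
        with pytest.raises(ValidationError):
            MCLParams(expansion=1)

    def test_planted_partition_recovery_when_blocks_are_separable(self):
        # near-disconnected blocks: MCL at inflation 1.4 must recover them
        from sklearn.metrics import adjusted_rand_score

        from mitonet.synthetic_data import NetworkSimConfig, simulate_interactome

        hits = 0
        for seed in range(10):
            inter, labels = simulate_interactome(
                NetworkSimConfig(
                    n_clusters=4,
                    cluster_sizes=(10, 10, 10, 10),
                    p_within=0.5,
                    p_between=0.002,
                    seed=seed,
                )
            )
            part = mcl(inter)
            nodes = list(labels)
            ari = adjusted_rand_score(
                [labels[n] for n in nodes],
                [part.node_to_cluster[n] for n in nodes],
            )
            hits += ari >= 0.9
        assert hits >= 9


class TestModularity:
    def test_two_triangles_closed_form(self, triangles):
        part = {n: 0 for n in "abc"} | {n: 1 for n in "xyz"}
        assert modularity(triangles, part) == pytest.approx(0.5)

    def test_single_cluster_is_zero(self, triangles):
        part = {n: 0 for n in "abcxyz"}
        assert modularity(triangles, part) == pytest.approx(0.0)

    def test_random_partition_of_er_graph_is_small(self):
        rng = np.random.default_rng(2)
        values = []
        for seed in range(50):
            g = nx.gnp_random_graph(30, 0.3, seed=seed)
            for u, v in g.edges:
                g[u][v]["weight"] = 1.0
            part = {n: int(rng.integers(0, 3)) for n in g.nodes}
            values.append(modularity(Interactome(g), part))
        assert max(abs(v) for v in values) < 0.2

    def test_uncovered_node_rejected(self, triangles):
        with pytest.raises(ValidationError, match="cover"):
            modularity(triangles, {n: 0 for n in "abc"})
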