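"""Generators: determinism, planted ground truth, degenerate configs."""

import numpy as np
import pandas as pd
import pytest

from mitonet.diffexp import logfc, normalize
from mitonet.io_formats import ValidationError
from mitonet.synthetic_data import (
    NetworkSimConfig,
    RegulatorySimConfig,
    SimulationConfig,
    StudyParams,
    simulate_annotations,
    simulate_interactome,
    simulate_linkset,
    simulate_spot_table,
    simulate_study,
)


class TestSpotTableGenerator:
    def test_zero_noise_zero_scale_constant_across_gels(self):
        cfg = SimulationConfig(n_spots=5, noise_sd=0.0, gel_scale_sd=0.0, seed=3)
        table, _ = simulate_spot_table(cfg)
        assert (table.intensities.nunique(axis=1) == 1).all()

    def test_planted_effect_appears_as_group_ratio(self):
        cfg = SimulationConfig(
            n_spots=4,
            noise_sd=0.0,
            gel_scale_sd=0.0,
            planted_effects={"S0002": {"PostC": 1.0}},
            seed=1,
        )
        table, truth = simulate_spot_table(cfg)
        norm = normalize(table)
        assert logfc(norm, "S0002", "PostC", "sham") == pytest.approx(1.0)
        assert truth.loc["S0002", "PostC"] == 1.0

    def test_gel_scale_cancels_exactly_under_normalization(self):
        # noise-free but heavy per-gel scaling: the reference ratio is exact
        cfg = SimulationConfig(
            n_spots=6,
            noise_sd=0.0,
            gel_scale_sd=2.0,
            planted_effects={"S0001": {"I/R": -0.8, "PostC": 1.3}},
            seed=9,
        )
        table, truth = simulate_spot_table(cfg)
        norm = normalize(table)
        for group in ("I/R", "PostC"):
            expected = truth.loc["S0001", group]
            assert logfc(norm, "S0001", group, "sham") == pytest.approx(
                expected, abs=1e-12
            )

    def test_seed_determinism(self):
        cfg = SimulationConfig(n_spots=10, seed=5)
        t1, e1 = simulate_spot_table(cfg)
        t2, e2 = simulate_spot_table(cfg)
        pd.testing.assert_frame_equal(t1.intensities, t2.intensities)
        pd.testing.assert_frame_equal(e1, e2)

    def test_invalid_config_names_field(self):
        with pytest.raises(ValidationError, match="n_gels_per_group"):
            SimulationConfig(n_gels_per_group=1)
        with pytest.raises(ValidationError, match="noise_sd"):
            SimulationConfig(noise_sd=-0.1)
        with pytest.raises(ValidationError, match="reference"):
            SimulationConfig(planted_effects={"ALB": {"PostC": 1.0}})

    def test_intensities_strictly_positive(self):
        table, _ = simulate_spot_table(SimulationConfig(n_spots=20, seed=0))
        assert (table.intensities.to_numpy() > 0).all()


class TestInteractomeGenerator:
    def test_degenerate_probabilities_two_triangles(self):
        cfg = NetworkSimConfig(
            n_clusters=2, cluster_sizes=(3, 3), p_within=1.0, p_between=0.0, seed=0
        )
        inter, labels = simulate_interactome(cfg)
        assert inter.n_edges == 6
        for u, v in inter.graph.edges:
            assert labels[u] == labels[v]

    def test_all_zero_probabilities_edgeless(self):
        cfg = NetworkSimConfig(
            n_clusters=2, cluster_sizes=(4, 4), p_within=0.0, p_between=0.0
        )
        inter, _ = simulate_interactome(cfg)
        assert inter.n_edges == 0 and inter.n_nodes == 8

    def test_within_edge_count_matches_binomial_expectation(self):
        # 4 clusters of 10 at p_within=0.5: E[within] = 4*C(10,2)*0.5 = 90
        counts = []
        for seed in range(200):
            cfg = NetworkSimConfig(
                n_clusters=4,
                cluster_sizes=(10, 10, 10, 10),
                p_within=0.5,
                p_between=0.0,
                seed=seed,
            )
            inter, _ = simulate_interactome(cfg)
            counts.append(inter.n_edges)
        assert abs(np.mean(counts) - 90) <= 5

    def test_inconsistent_cluster_sizes_rejected(self):
        with pytest.raises(ValidationError, match="cluster_sizes"):
            NetworkSimConfig(n_clusters=3, cluster_sizes=(5, 5))

    def test_seed_determinism_and_score_range(self):
        cfg = NetworkSimConfig(n_clusters=2, cluster_sizes=(6, 6), seed=11)
        i1, _ = simulate_interactome(cfg)
        i2, _ = simulate_interactome(cfg)
        assert sorted(i1.graph.edges(data="weight")) == sorted(
            i2.graph.edges(data="weight")
        )
        for _, _, w in i1.graph.edges(data="weight"):
            assert 0.4 <= w <= 0.999


class TestAnnotationGenerator:
    def test_terms_equal_clusters_without_decoys(self):
        clusters = [["A", "B"], ["C", "D", "E"], ["F"]]
        coll = simulate_annotations(clusters, n_decoy_terms=0)
        assert len(coll) == 3
        assert sorted(coll.members("CL02")) == ["C", "D", "E"]

    def test_decoy_terms_within_universe(self):
        clusters = [["A", "B", "C"]]
        universe = [f"N{i}" for i in range(40)] + ["A", "B", "C"]
        coll = simulate_annotations(clusters, n_decoy_terms=10, seed=2, universe=universe)
        assert len(coll) == 11
        for term in coll:
            assert coll.members(term) <= set(universe)

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValidationError):
            simulate_annotations([["A"], []])


class TestLinksetGenerator:
    IR = {"A": -0.6, "B": 0.9, "C": 0.1, "D": -1.2}
    POSTC = {"A": 0.7, "B": 0.8, "C": -0.9, "D": 1.1}
    # opposite under (IR, POSTC): A (−0.6 vs +0.7) and D (−1.2 vs +1.1)

    def test_zero_opposite_tfs_gives_empty_truth(self):
        cfg = RegulatorySimConfig(n_tfs=3, targets_per_tf=2, n_opposite_tfs=0, seed=0)
        linkset, planted = simulate_linkset(
            cfg, ["A", "B", "C", "D"], (self.IR, self.POSTC)
        )
        assert planted == []
        assert len(linkset.tfs) == 3

    def test_planted_tf_targets_all_opposite(self):
        cfg = RegulatorySimConfig(n_tfs=4, targets_per_tf=2, n_opposite_tfs=2, seed=1)
        linkset, planted = simulate_linkset(
            cfg, ["A", "B", "C", "D"], (self.IR, self.POSTC)
        )
        assert planted == ["TF01", "TF02"]
        for tf, target in linkset.pairs:
            if tf in planted:
                assert target in {"A", "D"}
            else:
                assert target in {"B", "C"}

    def test_impossible_plant_raises(self):
        same_sign = {"A": 0.9, "B": 0.8}
        with pytest.raises(ValidationError, match="opposite"):
            simulate_linkset(
                RegulatorySimConfig(n_tfs=2, n_opposite_tfs=1),
                ["A", "B"],
                (same_sign, same_sign),
            )

    def test_single_target_definition_instance(self):
        ir, postc = {"X": -0.6}, {"X": 0.7}
        cfg = RegulatorySimConfig(n_tfs=1, targets_per_tf=1, n_opposite_tfs=1)
        linkset, planted = simulate_linkset(cfg, ["X"], (ir, postc))
        assert planted == ["TF01"] and linkset.pairs == [("TF01", "X")]


class TestStudy:
    def test_study_ground_truth_is_consistent(self):
        study = simulate_study(seed=4, params=StudyParams(n_spots=80, cluster_sizes=(5, 5, 4)))
        assert len(study.planted_differential) == 14
        # every planted spot is differential (|true logFC| >= 1) in some contrast
        for spot in study.planted_differential:
            effects = study.true_effects.loc[spot]
            assert effects.abs().max() >= 1.0
        # opposite pool spots flip sign between the two screen contrasts
        ir = study.true_contrast("I/R", "Isch")
        postc = study.true_contrast("PostC", "Isch")
        n_opp_nodes = sum(
            1
            for s in study.planted_differential
            if ir[s] * postc[s] < 0 and abs(ir[s]) > 0.5 and abs(postc[s]) > 0.5
        )
        assert n_opp_nodes == 2 * study.params.n_opposite_tfs
        assert len(study.planted_opposite_tfs) == study.params.n_opposite_tfs

    def test_study_determinism(self):
        s1 = simulate_study(seed=7, params=StudyParams(n_spots=60, cluster_sizes=(4, 4, 4)))
        s2 = simulate_study(seed=7, params=StudyParams(n_spots=60, cluster_sizes=(4, 4, 4)))
        pd.testing.assert_frame_equal(s1.table.intensities, s2.table.intensities)
        assert sorted(s1.interactome.graph.edges(data="weight")) == sorted(
            s2.interactome.graph.edges(data="weight")
        )
        assert s1.linkset.edges == s2.linkset.edges
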