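"""Pattern pipeline: aggregation, reconstruction training, projections."""

import numpy as np
import pytest
from scipy.spatial.distance import pdist
from scipy.linalg import orthogonal_procrustes

from hginjury.cohort import SimulationConfig, generate_cohort, hypergraph_from_groups
from hginjury.hypergraph import Hypergraph
from hginjury.pattern import (
    TrainSettings,
    aggregate_hyperedge,
    aggregation_matrix,
    compactness_stats,
    embed_cohort,
    project_2d,
    reconstruction_loss,
    structure_report,
    train_pattern_model,
)


class TestAggregation:
    def test_mean_of_two_rows(self):
        Z = np.array([[1.0, 3.0], [3.0, 5.0]])
        assert np.allclose(aggregate_hyperedge(Z, (0, 1)), [2.0, 4.0])

    def test_singleton_returns_row(self):
        Z = np.array([[1.0, 2.0], [9.0, 9.0]])
        assert np.allclose(aggregate_hyperedge(Z, (0,)), Z[0])

    def test_weighted_mean(self):
        Z = np.array([[0.0, 0.0], [4.0, 8.0]])
        out = aggregate_hyperedge(
            Z, (0, 1), method="weighted_mean", weights=np.array([1.0, 3.0])
        )
        assert np.allclose(out, [3.0, 6.0])

    def test_empty_hyperedge_rejected(self):
        with pytest.raises(ValueError):
            aggregate_hyperedge(np.zeros((2, 2)), ())

    def test_matrix_form_matches_per_edge_aggregation(self, rng):
        g = Hypergraph(5, ((0, 1, 2), (2, 3), (4,)))
        Z = rng.normal(size=(5, 3))
        M = aggregation_matrix(g)
        for j, e in enumerate(g.hyperedges):
            assert np.allclose((M @ Z)[j], aggregate_hyperedge(Z, e))


class TestReconstructionLoss:
    def test_perfect_reconstruction(self):
        A = np.arange(6.0).reshape(3, 2)
        assert reconstruction_loss(A, A) == 0.0

    def test_unit_displacement(self):
        assert reconstruction_loss(np.array([[1.0, 0.0]]), np.zeros((1, 2))) == 1.0

    def test_hand_sum_of_squares(self):
        A = np.array([[1.0, 1.0], [2.0, 0.0]])
        assert reconstruction_loss(A, np.zeros_like(A)) == 6.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            reconstruction_loss(np.zeros((2, 2)), np.zeros((3, 2)))


class TestTrainPatternModel:
    def test_training_loss_decreases(self):
        cohort = generate_cohort(SimulationConfig(seed=5))
        g = hypergraph_from_groups(cohort)
        _, trace = train_pattern_model(cohort, g, TrainSettings(seed=5))
        assert trace["train_loss"][-1] <= trace["train_loss"][0]

    def test_fixed_seed_identical_trace(self):
        cohort = generate_cohort(SimulationConfig(seed=5))
        g = hypergraph_from_groups(cohort)
        _, t1 = train_pattern_model(cohort, g, TrainSettings(seed=9))
        _, t2 = train_pattern_model(cohort, g, TrainSettings(seed=9))
        assert t1["train_loss"] == t2["train_loss"]
        assert t1["val_loss"] == t2["val_loss"]

    def test_small_instance_is_overfittable(self):
        """On a tiny cohort the joint model drives train loss below 1e-3."""
        cohort = generate_cohort(
            SimulationConfig(n_athletes=6, n_features=3, seed=2, group_size_range=(2, 3))
        )
        g = hypergraph_from_groups(cohort)
        settings = TrainSettings(
            seed=2, learning_rate=3e-3, max_epochs=6000, patience=6000
        )
        _, trace = train_pattern_model(cohort, g, settings, hgnn_widths=(6, 3))
        assert trace["train_loss"][-1] < 1e-3

    def test_early_stopping_respects_patience(self):
        cohort = generate_cohort(SimulationConfig(seed=5))
        g = hypergraph_from_groups(cohort)
        settings = TrainSettings(seed=5, max_epochs=100, patience=5)
        _, trace = train_pattern_model(cohort, g, settings)
        best_epoch = int(np.argmin(trace["val_loss"]))
        assert len(trace["epoch"]) <= max(best_epoch + 5 + 1, 100)

    def test_mismatched_hypergraph_rejected(self):
        cohort = generate_cohort(SimulationConfig(seed=5))
        g = Hypergraph(4, ((0, 1), (2, 3)))
        with pytest.raises(ValueError):
            train_pattern_model(cohort, g)


class TestProject2d:
    def test_recovers_planted_plane(self, rng):
        coords = rng.normal(size=(30, 2))
        Z = np.hstack([coords, np.zeros((30, 1))])  # third dim carries nothing
        out = project_2d(Z)
        R, _ = orthogonal_procrustes(out, coords - coords.mean(axis=0))
        err = np.linalg.norm(out @ R - (coords - coords.mean(axis=0)))
        assert err < 1e-6

    def test_output_centered_and_variance_ordered(self, rng):
        Z = rng.normal(size=(40, 6)) * np.array([5, 3, 1, 1, 1, 1])
        out = project_2d(Z)
        assert np.allclose(out.mean(axis=0), 0, atol=1e-10)
        assert out[:, 0].var() >= out[:, 1].var()

    def test_too_few_rows_rejected(self):
        with pytest.raises(ValueError):
            project_2d(np.zeros((2, 5)))


class TestCompactnessStats:
    def test_separated_point_masses_have_silhouette_near_one(self):
        coords = np.vstack([np.zeros((5, 2)), np.full((5, 2), 10.0)])
        labels = np.array([0] * 5 + [1] * 5)
        out = compactness_stats(coords, labels)
        assert out["silhouette"] == pytest.approx(1.0, abs=1e-9)
        assert out["mean_within_distance"][0] == 0.0

    def test_singleton_group_reported_missing(self):
        coords = np.array([[0.0, 0.0], [1.0, 0.0], [5.0, 5.0]])
        out = compactness_stats(coords, np.array(["a", "a", "b"]))
        assert out["mean_within_distance"]["b"] is None

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            compactness_stats(np.zeros((4, 2)), np.zeros(4))

    def test_random_labels_on_one_blob_score_near_zero(self):
        sils = []
        for seed in range(20):
            r = np.random.default_rng(seed)
            coords = r.normal(size=(60, 2))
            labels = r.integers(0, 2, size=60)
            sils.append(compactness_stats(coords, labels)["silhouette"])
        assert abs(np.mean(sils)) < 0.1


class TestStructureReport:
    def test_disjoint_singletons(self):
        g = Hypergraph(4, ((0,), (1,), (2,), (3,)))
        rep = structure_report(g, g)["pre"]
        assert rep["n_components"] == 4
        assert rep["n_isolated_vertices"] == 0

    def test_single_covering_edge(self):
        g = Hypergraph(4, ((0, 1, 2, 3),))
        rep = structure_report(g, g)["post"]
        assert rep["n_components"] == 1
        assert rep["n_isolated_vertices"] == 0
        assert rep["mean_hyperedge_overlap"] == 0.0  # no second edge to overlap

    def test_shared_vertex_between_two_edges(self):
        g = Hypergraph(5, ((0, 1, 2), (2, 3, 4)))
        rep = structure_report(g, g)["pre"]
        assert rep["mean_hyperedge_overlap"] == 1.0
        assert rep["n_components"] == 1

    def test_vertex_count_mismatch_rejected(self):
        with pytest.raises(ValueError):
            structure_report(Hypergraph(3, ((0, 1),)), Hypergraph(4, ((0, 1),)))


def test_trained_embedding_shows_maft_compaction():
    """Spot check of the visual contrast: tighter MAFT cluster in 2-D."""
    cohort = generate_cohort(SimulationConfig(seed=1))
    g = hypergraph_from_groups(cohort)
    model, _ = train_pattern_model(cohort, g, TrainSettings(seed=1))
    coords = project_2d(embed_cohort(cohort, g, model))
    d_maft = pdist(coords[cohort.regime == "maft"]).mean()
    d_trad = pdist(coords[cohort.regime == "traditional"]).mean()
    assert d_maft < d_trad
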