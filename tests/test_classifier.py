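"""Regularised hypergraph classifier: objective terms, training, evaluation."""

import numpy as np
import pytest

from hginjury.classifier import (
    DEFAULT_CLASSIFIER_SETTINGS,
    METRIC_NAMES,
    RegularizerConfig,
    UNREGULARIZED,
    ablation_grid,
    bce_with_logits,
    cross_validate,
    omega,
    penalty_scale,
    predict_proba,
    total_objective,
    train_classifier,
)
from hginjury.cohort import SimulationConfig, generate_cohort
from hginjury.hypergraph import Hypergraph, build_knn_hypergraph, laplacian, smoothness
from hginjury.pattern import TrainSettings

FAST = TrainSettings(optimizer="sgd", learning_rate=0.01, max_epochs=60, patience=60)


def small_cohort(seed=0, n=30, d=12, sep=2.0):
    return generate_cohort(
        SimulationConfig(
            n_athletes=n, n_features=d, class_separation=sep, seed=seed,
            site_rates=((0.5,) * 9, (0.5,) * 9),
        )
    )


class TestOmega:
    def test_zero_embedding(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert omega(np.zeros((2, 3)), A, RegularizerConfig()) == 0.0

    def test_constant_rows_without_decay(self):
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        X = np.ones((2, 3))
        cfg = RegularizerConfig(beta=0.0)
        assert omega(X, A, cfg) == pytest.approx(0.0, abs=1e-12)

    def test_two_vertex_hand_value(self):
        A = np.array([[0.0, 0.5], [0.5, 0.0]])
        X = np.array([[0.0], [1.0]])
        cfg = RegularizerConfig(lam=1.0, alpha=1.0, beta=1.0)
        # alpha: (0.5 + 0.5) * 1; beta: 0 + 1
        assert omega(X, A, cfg) == pytest.approx(2.0)

    def test_negative_adjacency_rejected(self):
        with pytest.raises(ValueError):
            omega(np.zeros((2, 1)), np.array([[0.0, -1.0], [-1.0, 0.0]]),
                  RegularizerConfig())

    def test_quadratic_homogeneity(self, rng):
        A = rng.uniform(0, 1, size=(5, 5))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 0)
        X = rng.normal(size=(5, 3))
        cfg = RegularizerConfig()
        assert omega(2.0 * X, A, cfg) == pytest.approx(4.0 * omega(X, A, cfg))

    def test_alpha_zero_reduces_to_weight_decay(self, rng):
        A = np.ones((3, 3)) - np.eye(3)
        X = rng.normal(size=(3, 2))
        cfg = RegularizerConfig(alpha=0.0, beta=0.7)
        assert omega(X, A, cfg) == pytest.approx(0.7 * float((X**2).sum()))

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            RegularizerConfig(lam=-0.1)


class TestTotalObjective:
    def test_regularizer_off_equals_cross_entropy(self, rng):
        # singleton hyperedges: clique expansion (hence L) is identically zero
        g = Hypergraph(4, ((0,), (1,), (2,), (3,)))
        bundle = laplacian(g)
        logits = rng.normal(size=(4, 2))
        y = (rng.random((4, 2)) < 0.5).astype(float)
        X = rng.normal(size=(4, 3))
        obj = total_objective(logits, y, X, bundle, RegularizerConfig(lam=0.0))
        assert obj == pytest.approx(bce_with_logits(logits, y))

    def test_perfect_logits_and_zero_embedding_reach_floor(self):
        g = Hypergraph(2, ((0, 1),))
        bundle = laplacian(g)
        y = np.array([[1.0, 0.0], [0.0, 1.0]])
        logits = np.where(y == 1, 40.0, -40.0)
        obj = total_objective(logits, y, np.zeros((2, 3)), bundle, RegularizerConfig())
        assert obj == pytest.approx(0.0, abs=1e-12)

    def test_decomposes_into_term_oracles_at_study_defaults(self, rng):
        """Objective = CE + c*smoothness + c*lambda*Omega with the published
        defaults lambda=0.2, alpha=0.03, beta=0.005."""
        X_feat = rng.normal(size=(7, 4))
        g = build_knn_hypergraph(X_feat, 2)
        bundle = laplacian(g)
        X = rng.normal(size=(7, 3))
        logits = rng.normal(size=(7, 2))
        y = (rng.random((7, 2)) < 0.5).astype(float)
        cfg = RegularizerConfig()
        assert (cfg.lam, cfg.alpha, cfg.beta) == (0.2, 0.03, 0.005)
        c = penalty_scale(X, bundle)
        expected = (
            bce_with_logits(logits, y)
            + c * smoothness(X, bundle)
            + c * cfg.lam * omega(X, bundle.adjacency, cfg)
        )
        assert total_objective(logits, y, X, bundle, cfg) == pytest.approx(
            expected, rel=1e-12
        )

    def test_non_finite_inputs_rejected(self):
        g = Hypergraph(2, ((0, 1),))
        bundle = laplacian(g)
        with pytest.raises(ValueError):
            total_objective(
                np.array([[np.inf]]), np.array([[1.0]]), np.zeros((2, 1)),
                bundle, RegularizerConfig(),
            )


class TestTrainClassifier:
    def test_fixed_seed_identical_parameters(self):
        cohort = small_cohort()
        m1 = train_classifier(cohort, settings=FAST)
        m2 = train_classifier(cohort, settings=FAST)
        for a, b in zip(m1.hgnn_stack + [m1.head], m2.hgnn_stack + [m2.head]):
            assert np.array_equal(a.weight, b.weight)
            assert np.array_equal(a.bias, b.bias)

    def test_single_class_sites_skipped_with_warning(self, caplog):
        cohort = small_cohort(seed=4)
        labels = cohort.injury_labels.copy()
        labels[:, 0] = 0  # no positives at the first site
        object.__setattr__(cohort, "injury_labels", labels)
        with caplog.at_level("WARNING"):
            model = train_classifier(cohort, settings=FAST)
        assert not model.trained_sites[0]
        assert any("single-class" in r.message for r in caplog.records)

    def test_predictions_cover_all_athletes_and_sites(self):
        cohort = small_cohort()
        model = train_classifier(cohort, settings=FAST)
        probs = predict_proba(model, cohort.features)
        assert probs.shape == cohort.injury_labels.shape
        assert ((probs >= 0) & (probs <= 1)).all()

    def test_strong_separation_is_learnable(self):
        cohort = small_cohort(seed=1, n=60, d=24, sep=6.0)
        mask = np.zeros(60, dtype=bool)
        mask[:45] = True
        model = train_classifier(
            cohort, train_mask=mask, settings=DEFAULT_CLASSIFIER_SETTINGS
        )
        pred = (predict_proba(model, cohort.features)[~mask] > 0.5).astype(int)
        acc = (pred == cohort.injury_labels[~mask]).mean()
        assert acc > 0.85


class TestCrossValidate:
    def test_metric_table_layout(self):
        cohort = small_cohort()
        df = cross_validate(cohort, "rhgnn", folds=2, seed=0, settings=FAST)
        for m in METRIC_NAMES:
            assert f"{m}_mean" in df.columns
            assert f"{m}_std" in df.columns
            assert "±" in df[m].iloc[0]
        assert 0.0 <= df["acc_mean"].iloc[0] <= 1.0
        assert len(df.attrs["folds"]) == 2

    @pytest.mark.parametrize("method", ["mlp", "svm"])
    def test_baselines_run(self, method):
        cohort = small_cohort()
        df = cross_validate(cohort, method, folds=2, seed=0)
        assert 0.0 <= df["acc_mean"].iloc[0] <= 1.0

    def test_ceiling_case_all_methods_near_perfect(self):
        # few label patterns + huge separation: every method should saturate
        cohort = generate_cohort(
            SimulationConfig(
                n_athletes=60, n_features=24, n_sites=2, class_separation=8.0,
                seed=2, site_rates=((0.5, 0.5), (0.5, 0.5)),
            )
        )
        for method in ("rhgnn", "mlp", "svm"):
            df = cross_validate(cohort, method, folds=3, seed=2,
                                settings=DEFAULT_CLASSIFIER_SETTINGS)
            assert df["acc_mean"].iloc[0] > 0.95, method

    def test_too_few_folds_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(small_cohort(), folds=1)

    def test_unregularized_config_is_pure_hgnn(self):
        assert UNREGULARIZED.lam == 0.0
        assert not UNREGULARIZED.include_smoothness


class TestAblationGrid:
    def test_grid_rows_and_order(self):
        cohort = small_cohort(n=24, d=8)
        df = ablation_grid(cohort, folds=2, seed=0,
                           settings=TrainSettings(optimizer="sgd",
                                                  learning_rate=0.01,
                                                  max_epochs=8, patience=8))
        assert list(df["method"]) == [
            "rHGNN (full)",
            "λ=0.01", "λ=0.1", "λ=1.0",
            "α=0.001", "α=0.01", "α=0.1",
            "β=0.0001", "β=0.001", "β=0.01",
        ]
        assert df[["acc_mean", "acc_std"]].notna().all().all()
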