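"""Label rules, cross-validation, grid search and confusion metrics."""

import numpy as np
import pandas as pd
import pytest
import sklearn.metrics

from mesn import (
    ConfigurationError,
    DegenerateFoldError,
    ESNConfig,
    GridSpec,
    InvalidSplitError,
    TopologyConfig,
    binarize_labels,
    confusion_metrics,
    evaluate_config,
    grid_search,
    kfold_indices,
    leak_rate_sweep,
)

SMALL_TOPO = TopologyConfig(n=100, modules=4, p_intra=0.2, p_inter=0.05, seed=0)
FAST_ESN = ESNConfig(alpha=0.25, ridge_lambda=1e-6)


def ratings_frame(valence, arousal):
    return pd.DataFrame({"valence": valence, "arousal": arousal})


class TestBinarizeLabels:
    def test_valence_boundary_is_low(self):
        lab = binarize_labels(ratings_frame([5.0, 5.01, 9.0, 1.0], [5] * 4), "valence")
        assert np.array_equal(lab.labels, [0, 1, 1, 0])
        assert lab.included.all()

    def test_arousal_rule(self):
        lab = binarize_labels(ratings_frame([5] * 3, [4.9, 5.0, 6.0]), "arousal")
        assert np.array_equal(lab.labels, [0, 0, 1])

    @pytest.mark.parametrize(
        "valence,arousal,expected",
        [
            (2.0, 6.0, 1),   # stress: v <= 3 and a >= 5
            (3.0, 5.0, 1),   # stress boundary
            (5.0, 2.0, 0),   # calm: 4 <= v <= 6 and a < 4
            (4.0, 3.99, 0),  # calm boundary
            (7.0, 4.5, -1),  # matches neither rule
            (3.5, 6.0, -1),  # between stress and calm valence ranges
            (5.0, 4.0, -1),  # calm needs a < 4
        ],
    )
    def test_stress_calm_rules(self, valence, arousal, expected):
        lab = binarize_labels(ratings_frame([valence], [arousal]), "stress_calm")
        assert lab.labels[0] == expected
        assert lab.included[0] == (expected != -1)

    def test_out_of_range_ratings_rejected(self):
        with pytest.raises(ConfigurationError):
            binarize_labels(ratings_frame([0.5], [5.0]), "valence")

    def test_unknown_task_rejected(self):
        with pytest.raises(ConfigurationError):
            binarize_labels(ratings_frame([5.0], [5.0]), "dominance")


class TestKFold:
    def test_balanced_cover_disjoint(self):
        assignment = kfold_indices(10, 5, seed=0)
        sizes = np.bincount(assignment, minlength=5)
        assert np.array_equal(sizes, [2] * 5)

    def test_uneven_sizes_differ_by_at_most_one(self):
        sizes = np.bincount(kfold_indices(13, 5, seed=1), minlength=5)
        assert sizes.sum() == 13 and sizes.max() - sizes.min() <= 1

    def test_deterministic(self):
        assert np.array_equal(kfold_indices(20, 5, seed=2), kfold_indices(20, 5, seed=2))

    def test_too_few_samples(self):
        with pytest.raises(InvalidSplitError):
            kfold_indices(3, 5)


class TestEvaluateConfig:
    def test_separable_clusters_classified(self, separable_dataset):
        feats, labels = separable_dataset
        result = evaluate_config(feats, labels, SMALL_TOPO, FAST_ESN, repeats=1, seed=0)
        assert result.mean_accuracy > 0.95
        assert len(result.per_repeat) == 1
        assert set(result.fold_table.columns) == {"repeat", "fold", "accuracy"}

    def test_shuffled_labels_at_chance(self, separable_dataset):
        feats, labels = separable_dataset
        shuffled = np.random.default_rng(0).permutation(labels)
        result = evaluate_config(feats, shuffled, SMALL_TOPO, FAST_ESN, repeats=1, seed=0)
        # binomial 4-sigma band around 0.5 at n=300
        assert abs(result.mean_accuracy - 0.5) < 4 * np.sqrt(0.25 / len(labels))

    def test_deterministic_given_seed(self, separable_dataset):
        feats, labels = separable_dataset
        a = evaluate_config(feats, labels, SMALL_TOPO, FAST_ESN, repeats=2, seed=3)
        b = evaluate_config(feats, labels, SMALL_TOPO, FAST_ESN, repeats=2, seed=3)
        assert a.mean_accuracy == b.mean_accuracy
        assert np.array_equal(a.per_repeat, b.per_repeat)

    def test_single_class_dataset_degenerate(self, separable_dataset):
        feats, _ = separable_dataset
        with pytest.raises(DegenerateFoldError):
            evaluate_config(
                feats, np.zeros(len(feats), dtype=int), SMALL_TOPO, FAST_ESN,
                repeats=1, seed=0,
            )


class TestGridSearch:
    def test_default_grid_enumerates_240_triples(self):
        grid = GridSpec()
        triples = list(grid.triples())
        assert grid.n_triples == 240 and len(triples) == 240
        assert all(p2 <= p1 + 1e-12 for p1, _, p2 in triples)

    def test_loop_order_is_p1_then_m_then_p2(self):
        grid = GridSpec(p1_values=(0.1, 0.2), m_values=(1, 2), p2_fractions=(0.5, 1.0))
        assert list(grid.triples()) == [
            (0.1, 1, 0.05), (0.1, 1, 0.1), (0.1, 2, 0.05), (0.1, 2, 0.1),
            (0.2, 1, 0.1), (0.2, 1, 0.2), (0.2, 2, 0.1), (0.2, 2, 0.2),
        ]

    def test_single_triple_grid_returns_it(self):
        grid = GridSpec(p1_values=(0.1,), m_values=(3,), p2_fractions=(0.5,))
        result = grid_search(None, None, grid, evaluator=lambda m, p1, p2: 0.7)
        assert (result.best_m, result.best_p1, result.best_p2) == (3, 0.1, 0.05)

    def test_planted_optimum_found(self):
        grid = GridSpec()

        def oracle(m, p1, p2):
            hit = m == 6 and p1 == 0.05 and abs(p2 - 0.02) < 1e-12
            return 1.0 if hit else 0.5

        result = grid_search(None, None, grid, evaluator=oracle)
        assert (result.best_m, result.best_p1) == (6, 0.05)
        assert result.best_p2 == pytest.approx(0.02, abs=1e-12)
        assert result.best_accuracy == 1.0
        assert len(result.table) == 240

    def test_ties_resolve_to_first_in_loop_order(self):
        grid = GridSpec(p1_values=(0.1, 0.2), m_values=(1, 2), p2_fractions=(1.0,))
        result = grid_search(None, None, grid, evaluator=lambda m, p1, p2: 0.6)
        assert (result.best_p1, result.best_m) == (0.1, 1)

    def test_empty_grid_rejected(self):
        with pytest.raises(ConfigurationError):
            GridSpec(p1_values=())

    def test_cross_validated_path_runs(self, separable_dataset):
        feats, labels = separable_dataset
        grid = GridSpec(p1_values=(0.2,), m_values=(1, 4), p2_fractions=(1.0,),
                        cv_repeats=1)
        result = grid_search(feats, labels, grid, esn=FAST_ESN, n=100, seed=0)
        assert len(result.table) == 2
        assert result.best_accuracy > 0.9


class TestLeakRateSweep:
    def test_returns_best_alpha_and_table(self, separable_dataset):
        feats, labels = separable_dataset
        best, table = leak_rate_sweep(
            feats, labels, SMALL_TOPO, FAST_ESN, alphas=(0.1, 0.3),
            repeats=1, seed=0,
        )
        assert best in (0.1, 0.3)
        assert list(table["alpha"]) == [0.1, 0.3]


class TestConfusionMetrics:
    def test_perfect_prediction(self):
        y = np.array([0, 1, 1, 0, 1])
        report = confusion_metrics(y, y)
        for value in (report.precision, report.sensitivity, report.specificity,
                      report.accuracy, report.f1):
            assert value == 1.0

    def test_hand_computed_balanced_table(self):
        # TP=40, FP=10, FN=10, TN=40 -> every metric 0.8
        y_true = np.array([1] * 50 + [0] * 50)
        y_pred = np.array([1] * 40 + [0] * 10 + [1] * 10 + [0] * 40)
        report = confusion_metrics(y_true, y_pred)
        assert np.array_equal(report.confusion, [[40, 10], [10, 40]])
        for value in (report.precision, report.sensitivity, report.specificity,
                      report.accuracy, report.f1):
            assert value == pytest.approx(0.8)

    def test_all_positive_predictions(self):
        y_true = np.array([0, 0, 1, 1])
        report = confusion_metrics(y_true, np.ones(4, dtype=int))
        assert report.sensitivity == 1.0
        assert report.specificity == 0.0

    def test_undefined_ratios_flagged_not_raised(self):
        report = confusion_metrics(np.zeros(4, dtype=int), np.zeros(4, dtype=int))
        assert np.isnan(report.precision)
        assert "precision" in report.undefined

    def test_accuracy_equals_direct_agreement(self, rng):
        y_true = rng.integers(0, 2, size=200)
        y_pred = rng.integers(0, 2, size=200)
        report = confusion_metrics(y_true, y_pred)
        assert report.accuracy == np.mean(y_true == y_pred)

    def test_agrees_with_sklearn_oracle(self, rng):
        y_true = rng.integers(0, 2, size=500)
        y_pred = (y_true + (rng.random(500) < 0.3)) % 2
        report = confusion_metrics(y_true, y_pred)
        assert report.precision == pytest.approx(
            sklearn.metrics.precision_score(y_true, y_pred)
        )
        assert report.sensitivity == pytest.approx(
            sklearn.metrics.recall_score(y_true, y_pred)
        )
        assert report.f1 == pytest.approx(sklearn.metrics.f1_score(y_true, y_pred))
        assert np.array_equal(
            report.confusion, sklearn.metrics.confusion_matrix(y_true, y_pred)
        )
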