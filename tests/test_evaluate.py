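"""Metrics, stratified folds, CV harness, and the weighted-average baseline."""

import numpy as np
import pytest

from fuzzyfuse import (
    ProbabilityMatrix,
    compute_metrics,
    cross_validate_ensemble,
    stratified_folds,
    weighted_average_baseline,
)

from conftest import random_probability_matrix


class TestMetrics:
    def test_hand_tallied_example(self):
        m = compute_metrics([1, 1, 0, 0, 0], [1, 0, 0, 0, 1])
        assert m.accuracy == pytest.approx(0.6)
        assert m.sensitivity == pytest.approx(0.5)
        assert m.precision == pytest.approx(0.5)
        assert m.f1 == pytest.approx(0.5)
        assert m.specificity == pytest.approx(2 / 3)
        assert m.balanced_accuracy == pytest.approx(7 / 12)
        assert (m.counts.tp, m.counts.fp, m.counts.tn, m.counts.fn) == (1, 1, 2, 1)

    def test_perfect_prediction(self):
        m = compute_metrics([0, 1, 1, 0], [0, 1, 1, 0])
        assert all(
            v == 1.0
            for v in (m.accuracy, m.sensitivity, m.specificity, m.precision, m.f1,
                      m.balanced_accuracy)
        )

    def test_all_majority_on_imbalanced_cohort(self):
        y = np.concatenate([np.zeros(1489, dtype=int), np.ones(491, dtype=int)])
        m = compute_metrics(y, np.zeros_like(y))
        assert m.sensitivity == 0.0
        assert m.specificity == 1.0
        assert m.balanced_accuracy == pytest.approx(0.5)
        assert m.accuracy == pytest.approx(1489 / 1980)

    def test_metric_identities_on_random_tables(self, rng):
        for _ in range(50):
            y = rng.integers(0, 2, size=60)
            yp = rng.integers(0, 2, size=60)
            m = compute_metrics(y, yp)
            assert m.balanced_accuracy == pytest.approx(
                (m.sensitivity + m.specificity) / 2, abs=1e-12
            )
            if m.precision + m.sensitivity > 0:
                assert m.f1 == pytest.approx(
                    2 * m.precision * m.sensitivity / (m.precision + m.sensitivity),
                    abs=1e-12,
                )

    def test_nonbinary_labels_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            compute_metrics([0, 2], [0, 1])

    def test_zero_denominator_reports_zero_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="fuzzyfuse.evaluate"):
            m = compute_metrics([0, 0], [0, 0])
        assert m.sensitivity == 0.0 and m.precision == 0.0
        assert any("undefined" in r.message for r in caplog.records)


class TestStratifiedFolds:
    def test_imbalanced_cohort_fold_counts(self):
        y = np.concatenate([np.zeros(1489, dtype=int), np.ones(491, dtype=int)])
        fa = stratified_folds(y, k=10, seed=7)
        zero_counts = np.bincount(fa.fold_index[y == 0], minlength=10)
        one_counts = np.bincount(fa.fold_index[y == 1], minlength=10)
        assert set(zero_counts.tolist()) <= {148, 149}
        assert set(one_counts.tolist()) <= {49, 50}

    def test_small_balanced_case(self):
        fa = stratified_folds([0, 0, 1, 1], k=2, seed=0)
        for fold in (0, 1):
            idx = fa.test_indices(fold)
            assert len(idx) == 2

    def test_deterministic_given_seed(self):
        y = np.tile([0, 0, 0, 1], 30)
        a = stratified_folds(y, k=4, seed=3)
        b = stratified_folds(y, k=4, seed=3)
        np.testing.assert_array_equal(a.fold_index, b.fold_index)
        c = stratified_folds(y, k=4, seed=4)
        assert not np.array_equal(a.fold_index, c.fold_index)

    def test_folds_partition_sample_set(self, rng):
        y = rng.integers(0, 2, size=200)
        fa = stratified_folds(y, k=5, seed=1)
        all_idx = np.concatenate([fa.test_indices(f) for f in range(5)])
        assert sorted(all_idx.tolist()) == list(range(200))

    def test_class_rarer_than_k_rejected(self):
        with pytest.raises(ValueError, match="fewer than"):
            stratified_folds([0] * 20 + [1] * 3, k=5, seed=0)


class TestCrossValidation:
    def test_one_hot_scores_give_perfect_mean_accuracy(self, rng):
        y = np.tile([0, 1], 30)
        values = np.eye(2)[y]
        tables = [
            ProbabilityMatrix([f"S{i}" for i in range(60)], values, ["0", "1"])
            for _ in range(3)
        ]
        folds = stratified_folds(y, k=5, seed=0)
        per_fold, mean = cross_validate_ensemble(tables, y, folds)
        assert mean.accuracy == 1.0
        assert len(per_fold) == 5

    def test_manifest_accuracy_policy_matches_explicit(self, rng):
        y = rng.integers(0, 2, size=100)
        tables = [random_probability_matrix(rng, 100, 2) for _ in range(2)]
        folds = stratified_folds(y, k=4, seed=2)
        _, mean_fixed = cross_validate_ensemble(tables, y, folds, accuracies=[0.7, 0.8])
        _, mean_fixed2 = cross_validate_ensemble(tables, y, folds, accuracies=[0.7, 0.8])
        assert mean_fixed.accuracy == mean_fixed2.accuracy

    def test_sample_count_mismatch_rejected(self, rng):
        y = rng.integers(0, 2, size=30)
        tables = [random_probability_matrix(rng, 40, 2)]
        folds = stratified_folds(y, k=2, seed=0)
        with pytest.raises(ValueError, match="same samples"):
            cross_validate_ensemble(tables, y, folds)


class TestWeightedBaseline:
    def test_equal_weights_average(self):
        t1 = ProbabilityMatrix(["a"], np.array([[0.6, 0.4]]), ["0", "1"])
        t2 = ProbabilityMatrix(["a"], np.array([[0.8, 0.2]]), ["0", "1"])
        assert weighted_average_baseline([t1, t2], [1, 1])[0] == 0

    def test_degenerate_weight_selects_single_classifier(self, rng):
        tables = [random_probability_matrix(rng, 50, 3) for _ in range(2)]
        labels = weighted_average_baseline(tables, [1.0, 0.0])
        np.testing.assert_array_equal(labels, np.argmax(tables[0].values, axis=1))

    def test_all_zero_weights_rejected(self, rng):
        with pytest.raises(ValueError, match="zero"):
            weighted_average_baseline([random_probability_matrix(rng, 5, 2)], [0.0])

    def test_disagreement_rate_with_fuzzy_ensemble_is_reported(self, rng):
        from fuzzyfuse import ensemble_predict, simulate_cohort, SimulationConfig

        cohort = simulate_cohort(SimulationConfig(n_samples=400, seed=9))
        acc = cohort.realized_accuracies
        rec, _ = ensemble_predict(cohort.score_tables, acc)
        baseline = weighted_average_baseline(cohort.score_tables, acc)
        disagreement = float(np.mean(rec.labels != baseline))
        assert 0.0 <= disagreement <= 1.0
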