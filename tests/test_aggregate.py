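"""Choquet aggregation and the deviation-priority decision rule."""

import math

import numpy as np
import pytest

from fuzzyfuse import (
    AggregatedScores,
    DensityVector,
    ProbabilityMatrix,
    aggregate_per_class,
    build_lambda_measure,
    choquet_integral,
    decide_labels,
    densities_from_accuracies,
    ensemble_predict,
    transform_scores,
)

from conftest import brute_force_choquet, random_probability_matrix


def _measure(g):
    return build_lambda_measure(DensityVector(np.array(g, dtype=float)))


class TestChoquetIntegral:
    def test_idempotent_on_constant_values(self, rng):
        for _ in range(10):
            g = rng.uniform(0.05, 0.5, size=4)
            m = _measure(g)
            v = rng.uniform()
            assert choquet_integral(np.full(4, v), m) == pytest.approx(v, abs=1e-12)

    def test_additive_case_is_weighted_mean(self):
        m = _measure([0.5, 0.5])
        assert choquet_integral(np.array([0.3, 0.1]), m) == pytest.approx(0.2, abs=1e-12)

    def test_nonadditive_hand_example(self):
        # g = [0.2, 0.3] gives lambda = 25/3 and g({0,1}) = 1; sorting
        # descending pairs 0.9 with {1} and the drop to 0.4 with the full set:
        # 0.4 * 1 + (0.9 - 0.4) * 0.3 = 0.55
        m = _measure([0.2, 0.3])
        assert choquet_integral(np.array([0.4, 0.9]), m) == pytest.approx(0.55, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(300):
            C = int(rng.integers(1, 6))
            g = rng.uniform(0.05, 0.6, size=C)
            if C == 1:
                g = np.array([1.0])
            m = _measure(g)
            v = rng.uniform(size=C)
            expected = brute_force_choquet(list(v), list(g), m.lam)
            assert choquet_integral(v, m) == pytest.approx(expected, abs=1e-12)

    def test_tied_values_use_lowest_index_first(self):
        # with distinct densities, tie order changes nothing for the value
        # itself (equal values telescope), but the implementation must not
        # crash or depend on sort instability
        m = _measure([0.2, 0.3])
        v = np.array([0.4, 0.4])
        assert choquet_integral(v, m) == pytest.approx(0.4, abs=1e-12)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="values for a measure"):
            choquet_integral(np.array([0.1, 0.2, 0.3]), _measure([0.5, 0.5]))


class TestAggregatePerClass:
    def test_single_classifier_identity(self, rng):
        table = random_probability_matrix(rng, 20, 2)
        t = transform_scores(table)
        agg = aggregate_per_class([t], _measure([1.0]))
        np.testing.assert_allclose(agg.deviation_agg, t.deviation, atol=1e-15)
        np.testing.assert_allclose(agg.support_agg, t.support, atol=1e-15)

    def test_two_classifier_worked_example(self):
        p1 = ProbabilityMatrix(["a"], np.array([[0.9, 0.1]]), ["0", "1"])
        p2 = ProbabilityMatrix(["a"], np.array([[0.4, 0.6]]), ["0", "1"])
        agg = aggregate_per_class(
            [transform_scores(p1), transform_scores(p2)], _measure([0.5, 0.5])
        )
        # additive measure: aggregates are plain means of the transforms
        d = lambda p: 1 - math.exp(-((p - 1) ** 2) / 2)
        s = lambda p: 1 - math.tanh((p - 1) ** 2 / 2)
        np.testing.assert_allclose(
            agg.deviation_agg[0],
            [(d(0.9) + d(0.4)) / 2, (d(0.1) + d(0.6)) / 2],
            atol=1e-12,
        )
        np.testing.assert_allclose(
            agg.support_agg[0],
            [(s(0.9) + s(0.4)) / 2, (s(0.1) + s(0.6)) / 2],
            atol=1e-12,
        )
        np.testing.assert_allclose(
            agg.deviation_agg[0], [0.08485865, 0.20495342], atol=1e-8
        )
        np.testing.assert_allclose(
            agg.support_agg[0], [0.90845959, 0.76797561], atol=1e-8
        )

    def test_identical_classifiers_collapse_to_single(self, rng):
        table = random_probability_matrix(rng, 15, 3)
        t = transform_scores(table)
        agg = aggregate_per_class([t] * 4, _measure([0.25] * 4))
        np.testing.assert_allclose(agg.deviation_agg, t.deviation, atol=1e-12)
        np.testing.assert_allclose(agg.support_agg, t.support, atol=1e-12)

    def test_additive_collapse_to_weighted_mean(self, rng):
        tables = [random_probability_matrix(rng, 30, 2) for _ in range(4)]
        # force identical sample ids across classifiers
        tables = [
            ProbabilityMatrix([f"S{i}" for i in range(30)], t.values, t.class_labels)
            for t in tables
        ]
        dv = densities_from_accuracies(rng.uniform(0.6, 0.9, size=4))
        m = build_lambda_measure(dv)
        assert m.lam == 0.0
        transformed = [transform_scores(t) for t in tables]
        agg = aggregate_per_class(transformed, m)
        dev_mean = sum(g * t.deviation for g, t in zip(dv.densities, transformed))
        sup_mean = sum(g * t.support for g, t in zip(dv.densities, transformed))
        np.testing.assert_allclose(agg.deviation_agg, dev_mean, atol=1e-12)
        np.testing.assert_allclose(agg.support_agg, sup_mean, atol=1e-12)


class TestDecisionRule:
    def test_agreeing_pathways(self):
        agg = AggregatedScores(np.array([[0.1, 0.3]]), np.array([[0.9, 0.6]]))
        rec = decide_labels(agg)
        assert rec.labels[0] == 0 and rec.agreed[0]

    def test_clash_resolved_by_deviation(self):
        agg = AggregatedScores(np.array([[0.20, 0.25]]), np.array([[0.70, 0.80]]))
        rec = decide_labels(agg)
        assert rec.labels[0] == 0
        assert not rec.agreed[0]
        assert rec.support_choice[0] == 1

    def test_ties_break_to_lowest_index(self):
        agg = AggregatedScores(np.array([[0.2, 0.2]]), np.array([[0.8, 0.8]]))
        assert decide_labels(agg).labels[0] == 0

    def test_label_always_equals_deviation_argmin(self, rng):
        dev = rng.uniform(0, 0.39, size=(2000, 4))
        sup = rng.uniform(0.54, 1.0, size=(2000, 4))
        rec = decide_labels(AggregatedScores(dev, sup))
        np.testing.assert_array_equal(rec.labels, np.argmin(dev, axis=1))


class TestEnsemblePredict:
    def test_worked_example_end_to_end(self):
        p1 = ProbabilityMatrix(["a"], np.array([[0.9, 0.1]]), ["0", "1"])
        p2 = ProbabilityMatrix(["a"], np.array([[0.4, 0.6]]), ["0", "1"])
        rec, agg = ensemble_predict([p1, p2], [0.8, 0.8])
        assert rec.labels[0] == 0
        assert rec.agreed[0]

    def test_single_classifier_reduces_to_argmax(self, rng):
        table = random_probability_matrix(rng, 500, 3)
        rec, _ = ensemble_predict([table], [0.9])
        np.testing.assert_array_equal(rec.labels, np.argmax(table.values, axis=1))

    def test_identical_copies_match_argmax_labels(self, rng):
        table = random_probability_matrix(rng, 100, 2)
        rec, _ = ensemble_predict([table] * 4, [0.7, 0.75, 0.8, 0.85])
        np.testing.assert_array_equal(rec.labels, np.argmax(table.values, axis=1))

    def test_mismatched_accuracy_count_rejected(self, rng):
        table = random_probability_matrix(rng, 5, 2)
        with pytest.raises(ValueError):
            ensemble_predict([table], [0.8, 0.9])
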