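"""Choquet aggregation of transformed scores and the final decision rule.

For each sample and class, the per-classifier deviation (and, separately,
support) scores are aggregated with a discrete Choquet integral: sort the C
scores in descending order, and sum the successive differences weighted by
the fuzzy measure of the nested subset of classifiers attaining at least
that level,

    Agg = sum_k (v_(k) - v_(k+1)) * g({top-k classifiers}),   v_(C+1) = 0.

With accuracy-normalised densities the measure is additive (lambda = 0) and
the integral collapses to the density-weighted mean.  The final label is the
class minimising aggregated deviation; the class maximising aggregated
support is recorded as well, and an ``agreed`` flag marks whether the two
pathways coincide.  On a clash, deviation wins — so the label always equals
argmin of the aggregated deviations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fuzzy_measure import (
    DensityVector,
    LambdaMeasure,
    build_lambda_measure,
    densities_from_accuracies,
    nested_subset_measures,
)
from .transform import (
    DEVIATION_MAX,
    SUPPORT_MIN,
    ProbabilityMatrix,
    TransformedScores,
    check_alignment,
    multiplicative_relevance,
    transform_scores,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AggregatedScores:
    """Choquet-aggregated deviation and support vectors per sample.

    Each row of ``deviation_agg`` lies in [0, 1 - e^{-1/2}] and each row of
    ``support_agg`` in [1 - tanh(1/2), 1]: the Choquet integral of values in
    an interval stays in that interval.
    """

    deviation_agg: np.ndarray  # shape (n_samples, n_classes)
    support_agg: np.ndarray  # shape (n_samples, n_classes)
    sample_ids: tuple = ()
    class_labels: tuple = ()

    def __post_init__(self):
        d = np.asarray(self.deviation_agg, dtype=float)
        s = np.asarray(self.support_agg, dtype=float)
        if d.shape != s.shape:
            raise ValueError("aggregated deviation and support shapes differ")
        eps = 1e-9
        if (d < -eps).any() or (d > DEVIATION_MAX + eps).any():
            raise ValueError("aggregated deviation outside its transform range")
        if (s < SUPPORT_MIN - eps).any() or (s > 1.0 + eps).any():
            raise ValueError("aggregated support outside its transform range")
        object.__setattr__(self, "deviation_agg", d)
        object.__setattr__(self, "support_agg", s)


@dataclass(frozen=True)
class DecisionRecord:
    """Per-sample decisions: final labels plus both pathway choices.

    ``labels`` always equals ``deviation_choice``: when the pathways agree
    they coincide, and on a clash the deviation pathway is preferred.
    """

    labels: np.ndarray  # final class index per sample
    deviation_choice: np.ndarray  # argmin of aggregated deviation
    support_choice: np.ndarray  # argmax of aggregated support
    agreed: np.ndarray  # boolean, pathways named the same class
    diagnostics: np.ndarray | None = None  # optional multiplicative relevance R_n

    @property
    def agreement_rate(self) -> float:
        return float(np.mean(self.agreed))


def _sorted_descending(values_2plus: np.ndarray) -> np.ndarray:
    """Indices ordering the last axis descending, ties to the lowest index."""
    # stable sort on negated values keeps the original (ascending-index) order
    # among ties
    return np.argsort(-values_2plus, axis=-1, kind="stable")


def choquet_integral(values: Sequence[float] | np.ndarray, measure: LambdaMeasure) -> float | np.ndarray:
    """Discrete Choquet integral of per-classifier values against a measure.

    ``values`` may be a length-C vector or any array whose last axis has
    length C; the integral is taken along that axis.  Values are sorted
    descending (ties broken by ascending classifier index) and the sorted
    differences are weighted by the measures of the nested top-k subsets.
    """
    v = np.asarray(values, dtype=float)
    C = measure.n_classifiers
    if v.shape[-1] != C:
        raise ValueError(
            f"got {v.shape[-1]} values for a measure over {C} classifiers"
        )
    if not np.isfinite(v).all():
        raise ValueError("values must be finite")
    order = _sorted_descending(v)
    v_sorted = np.take_along_axis(v, order, axis=-1)
    g_nested = nested_subset_measures(measure, order)
    v_next = np.concatenate(
        [v_sorted[..., 1:], np.zeros(v_sorted.shape[:-1] + (1,))], axis=-1
    )
    result = np.sum((v_sorted - v_next) * g_nested, axis=-1)
    return float(result) if result.ndim == 0 else result


def aggregate_per_class(
    transformed: Sequence[TransformedScores], measure: LambdaMeasure
) -> AggregatedScores:
    """Choquet-aggregate deviation and support independently per sample/class."""
    check_alignment(transformed)
    if len(transformed) != measure.n_classifiers:
        raise ValueError(
            f"{len(transformed)} score tables for a measure over "
            f"{measure.n_classifiers} classifiers"
        )
    # stack to (n_samples, n_classes, C) so the integral runs along classifiers
    dev = np.stack([t.deviation for t in transformed], axis=-1)
    sup = np.stack([t.support for t in transformed], axis=-1)
    first = transformed[0]
    return AggregatedScores(
        deviation_agg=choquet_integral(dev, measure),
        support_agg=choquet_integral(sup, measure),
        sample_ids=first.sample_ids,
        class_labels=first.class_labels,
    )


def decide_labels(agg: AggregatedScores, diagnostics: np.ndarray | None = None) -> DecisionRecord:
    """Apply the deviation-priority decision rule to aggregated scores.

    argmin over aggregated deviations and argmax over aggregated supports
    (ties to the lowest class index in both); the final label is the
    deviation choice, so a clash is always resolved in deviation's favour.
    """
    if not (np.isfinite(agg.deviation_agg).all() and np.isfinite(agg.support_agg).all()):
        raise ValueError("aggregated scores must be finite")
    dev_choice = np.argmin(agg.deviation_agg, axis=-1)
    sup_choice = np.argmax(agg.support_agg, axis=-1)
    agreed = dev_choice == sup_choice
    return DecisionRecord(
        labels=dev_choice.copy(),
        deviation_choice=dev_choice,
        support_choice=sup_choice,
        agreed=agreed,
        diagnostics=diagnostics,
    )


def ensemble_predict(
    score_tables: Sequence[ProbabilityMatrix],
    accuracies: Sequence[float],
    with_diagnostics: bool = False,
) -> tuple[DecisionRecord, AggregatedScores]:
    """Full fusion pipeline: transforms, fuzzy measure, Choquet, decision.

    Parameters
    ----------
    score_tables : sequence of ProbabilityMatrix
        One aligned probability table per base classifier.
    accuracies : sequence of float
        One accuracy per classifier, in (0, 1]; turned into normalised fuzzy
        densities.
    with_diagnostics : bool
        Also compute the multiplicative deviation-support relevance per class.

    Returns
    -------
    (DecisionRecord, AggregatedScores)
        Deterministic given the inputs.
    """
    check_alignment(score_tables)
    densities = densities_from_accuracies(np.asarray(accuracies, dtype=float))
    if len(score_tables) != len(densities):
        raise ValueError(
            f"{len(score_tables)} score tables but {len(densities)} accuracies"
        )
    measure = build_lambda_measure(densities)
    logger.info(
        "fuzzy densities %s, solved lambda %.6g",
        np.array2string(densities.densities, precision=6),
        measure.lam,
    )
    transformed = [transform_scores(t) for t in score_tables]
    agg = aggregate_per_class(transformed, measure)
    diag = multiplicative_relevance(transformed) if with_diagnostics else None
    record = decide_labels(agg, diagnostics=diag)
    logger.info("deviation/support agreement rate %.4f", record.agreement_rate)
    return record, agg
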