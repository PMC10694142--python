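"""Deviation and support transforms of classifier probability scores.

A classifier that is sure of a class emits a probability near 1 for it.  Two
non-linear maps quantify that confidence from opposite directions:

* support  ``S(p) = 1 - tanh((p - 1)^2 / 2)`` — a reward, largest (1) at
  ``p = 1`` and smallest (``1 - tanh(1/2) ≈ 0.5379``) at ``p = 0``;
* deviation ``D(p) = 1 - exp(-(p - 1)^2 / 2)`` — a penalty, zero at ``p = 1``
  and largest (``1 - e^{-1/2} ≈ 0.3935``) at ``p = 0``.

Both are strictly monotone on [0, 1], and the deviation range lies entirely
below the support range; their product is therefore dominated by the
deviation term, which motivates preferring deviation when the two aggregated
pathways disagree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Tolerance on |row sum - 1| below which a probability row is silently
#: renormalised; larger violations are hard errors.
ROW_SUM_TOL = 1e-6

#: Extremes of the two transforms over the probability domain [0, 1].
DEVIATION_MAX = 1.0 - np.exp(-0.5)  # ≈ 0.3934693, attained at p = 0
SUPPORT_MIN = 1.0 - np.tanh(0.5)  # ≈ 0.5378828, attained at p = 0


class ValidationError(ValueError):
    """Raised when an input violates a probability-table contract."""


class AlignmentError(ValueError):
    """Raised when per-classifier tables disagree on samples or classes."""


@dataclass(frozen=True)
class ProbabilityMatrix:
    """Per-sample class-probability scores of one classifier.

    Parameters
    ----------
    sample_ids : sequence of str
        Unique sample identifiers, one per row.
    values : ndarray, shape (n_samples, n_classes)
        Probabilities in [0, 1]; each row sums to 1.
    class_labels : sequence of str
        Ordered class names, one per column.
    """

    sample_ids: tuple
    values: np.ndarray
    class_labels: tuple

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "class_labels", tuple(str(c) for c in self.class_labels))
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValidationError(f"values must be 2-D, got shape {values.shape}")
        n, k = values.shape
        if len(self.sample_ids) != n:
            raise ValidationError(f"{len(self.sample_ids)} sample_ids for {n} rows")
        if len(self.class_labels) != k:
            raise ValidationError(f"{len(self.class_labels)} class labels for {k} columns")
        if k < 2:
            raise ValidationError("at least two classes are required")
        if len(set(self.sample_ids)) != n:
            raise ValidationError("sample_ids are not unique")
        self._check_entries(values)
        values = _renormalize_rows(values, self.sample_ids)
        values.setflags(write=False)
        object.__setattr__(self, "values", values)

    def _check_entries(self, values: np.ndarray) -> None:
        bad = ~np.isfinite(values) | (values < 0.0) | (values > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"probability out of [0, 1] or non-finite for sample "
                f"{self.sample_ids[i]!r}, class {self.class_labels[j]!r}: {values[i, j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_classes(self) -> int:
        return self.values.shape[1]


def _renormalize_rows(values: np.ndarray, sample_ids: Sequence[str]) -> np.ndarray:
    sums = values.sum(axis=1)
    err = np.abs(sums - 1.0)
    worst = int(np.argmax(err))
    if err[worst] > ROW_SUM_TOL:
        raise ValidationError(
            f"row for sample {sample_ids[worst]!r} sums to {sums[worst]:.9g} "
            f"(|sum - 1| = {err[worst]:.3g} exceeds tolerance {ROW_SUM_TOL:g})"
        )
    if (err > 0).any():
        if err[worst] > 1e-12:  # don't warn about bare float-epsilon drift
            logger.warning(
                "renormalizing %d probability row(s) with |sum - 1| <= %g (worst %.3g)",
                int((err > 0).sum()), ROW_SUM_TOL, err[worst],
            )
        values = values / sums[:, None]
    return values


@dataclass(frozen=True)
class TransformedScores:
    """Deviation and support matrices derived from one probability table."""

    deviation: np.ndarray
    support: np.ndarray
    sample_ids: tuple = field(default=())
    class_labels: tuple = field(default=())

    def __post_init__(self):
        d = np.asarray(self.deviation, dtype=float)
        s = np.asarray(self.support, dtype=float)
        if d.shape != s.shape:
            raise ValidationError("deviation and support shapes differ")
        object.__setattr__(self, "deviation", d)
        object.__setattr__(self, "support", s)


def _as_prob_array(probs) -> np.ndarray:
    if isinstance(probs, ProbabilityMatrix):
        return probs.values
    arr = np.asarray(probs, dtype=float)
    if not np.isfinite(arr).all() or (arr < 0).any() or (arr > 1).any():
        raise ValidationError("probabilities must be finite and in [0, 1]")
    return arr


def support_scores(probs) -> np.ndarray:
    """Reward ``S = 1 - tanh((P - 1)^2 / 2)``, elementwise.

    Strictly increasing in P; range [1 - tanh(1/2), 1] on [0, 1].
    """
    p = _as_prob_array(probs)
    return 1.0 - np.tanh((p - 1.0) ** 2 / 2.0)


def deviation_scores(probs) -> np.ndarray:
    """Penalty ``D = 1 - exp(-(P - 1)^2 / 2)``, elementwise.

    Strictly decreasing in P; range [0, 1 - e^{-1/2}] on [0, 1].
    """
    p = _as_prob_array(probs)
    return 1.0 - np.exp(-((p - 1.0) ** 2) / 2.0)


def transform_scores(probs: ProbabilityMatrix) -> TransformedScores:
    """Apply both transforms to one probability table."""
    ids = probs.sample_ids if isinstance(probs, ProbabilityMatrix) else ()
    labels = probs.class_labels if isinstance(probs, ProbabilityMatrix) else ()
    return TransformedScores(
        deviation=deviation_scores(probs),
        support=support_scores(probs),
        sample_ids=ids,
        class_labels=labels,
    )


def check_alignment(items: Sequence) -> None:
    """Verify that all tables agree on sample ids and class labels.

    Tables without identifier metadata (plain arrays) are only checked for
    shape compatibility.
    """
    if not items:
        raise AlignmentError("at least one classifier table is required")
    shapes = set()
    ids = set()
    labels = set()
    for item in items:
        if isinstance(item, ProbabilityMatrix):
            shapes.add(item.values.shape)
            ids.add(item.sample_ids)
            labels.add(item.class_labels)
        elif isinstance(item, TransformedScores):
            shapes.add(item.deviation.shape)
            if item.sample_ids:
                ids.add(item.sample_ids)
            if item.class_labels:
                labels.add(item.class_labels)
        else:
            shapes.add(np.asarray(item).shape)
    if len(shapes) > 1:
        raise AlignmentError(f"classifier tables have mismatched shapes: {sorted(shapes)}")
    if len(ids) > 1:
        raise AlignmentError("classifier tables disagree on sample identifiers")
    if len(labels) > 1:
        raise AlignmentError("classifier tables disagree on class labels")


def multiplicative_relevance(transformed: Sequence[TransformedScores]) -> np.ndarray:
    """Diagnostic relevance ``R_n = sum_c D^c_n * S^c_n`` per sample and class.

    Because the deviation range sits wholly below the support range, each
    product term is dominated by its deviation factor.  The result is
    reported for inspection only and never drives the decision rule.
    """
    check_alignment(transformed)
    return np.sum([t.deviation * t.support for t in transformed], axis=0)
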