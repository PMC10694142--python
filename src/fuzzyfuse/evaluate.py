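"""Metrics, stratified cross-validation harness, and the weighted baseline.

The evaluation setting is imbalanced binary survival classification: label 1
(short-term survivor, below the 5-year cutoff) is the positive minority
class and label 0 (long-term survivor) the majority.  Metrics follow the
standard confusion-matrix definitions — sensitivity tp/(tp+fn), specificity
tn/(tn+fp), precision tp/(tp+fp), F1 as the harmonic mean of precision and
sensitivity, balanced accuracy as the mean of sensitivity and specificity.
Ratios with a zero denominator are reported as 0 with a logged warning so
that per-fold averages remain well defined.

The cross-validation harness mirrors the usual late-fusion protocol: base
classifiers are assumed to have produced out-of-fold probability scores for
every sample; each fold's test samples are fused with densities derived
either from accuracies supplied by the caller or from each classifier's
accuracy on that fold's training portion (the default, which never touches
test labels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import confusion_matrix

from .aggregate import ensemble_predict
from .transform import ProbabilityMatrix, check_alignment

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    """Binary confusion counts with label 1 as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass(frozen=True)
class MetricsReport:
    """Standard binary classification metrics, each in [0, 1]."""

    accuracy: float
    sensitivity: float
    specificity: float
    precision: float
    f1: float
    balanced_accuracy: float
    counts: ConfusionCounts | None = None

    def as_dict(self) -> dict:
        out = {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "precision": self.precision,
            "f1": self.f1,
            "balanced_accuracy": self.balanced_accuracy,
        }
        if self.counts is not None:
            out["confusion"] = {
                "tp": self.counts.tp, "fp": self.counts.fp,
                "tn": self.counts.tn, "fn": self.counts.fn,
            }
        return out


@dataclass(frozen=True)
class FoldAssignment:
    """Stratified fold index per sample."""

    fold_index: np.ndarray
    k: int
    seed: int

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_index != fold)


def _safe_ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s undefined (zero denominator); reporting 0", name)
        return 0.0
    return num / den


def compute_metrics(y_true: Sequence[int], y_pred: Sequence[int]) -> MetricsReport:
    """Confusion-matrix metrics for binary labels in {0, 1}, positive = 1."""
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    if yt.shape != yp.shape or yt.ndim != 1:
        raise ValueError("label vectors must be 1-D and of equal length")
    if not (np.isin(yt, (0, 1)).all() and np.isin(yp, (0, 1)).all()):
        raise ValueError("binary metrics require labels in {0, 1}")
    tn, fp, fn, tp = confusion_matrix(yt, yp, labels=[0, 1]).ravel()
    counts = ConfusionCounts(tp=int(tp), fp=int(fp), tn=int(tn), fn=int(fn))
    sn = _safe_ratio(tp, tp + fn, "sensitivity")
    sp = _safe_ratio(tn, tn + fp, "specificity")
    prec = _safe_ratio(tp, tp + fp, "precision")
    ac = _safe_ratio(tp + tn, counts.total, "accuracy")
    f1 = _safe_ratio(2 * prec * sn, prec + sn, "f1")
    return MetricsReport(
        accuracy=ac, sensitivity=sn, specificity=sp, precision=prec,
        f1=f1, balanced_accuracy=(sn + sp) / 2.0, counts=counts,
    )


def stratified_folds(labels: Sequence[int], k: int, seed: int) -> FoldAssignment:
    """Shuffled-within-class round-robin assignment into k stratified folds.

    Each class's members are shuffled with the seeded generator and dealt
    round-robin across folds, so per-fold class counts deviate from exact
    proportionality by at most one sample.  Deterministic given the seed.
    """
    y = np.asarray(labels)
    if y.ndim != 1:
        raise ValueError("labels must be a 1-D vector")
    if k < 2:
        raise ValueError("k must be at least 2")
    rng = np.random.default_rng(seed)
    fold_index = np.full(y.shape[0], -1, dtype=int)
    for cls in np.unique(y):
        members = np.flatnonzero(y == cls)
        if members.size < k:
            raise ValueError(
                f"class {cls!r} has {members.size} members, fewer than k={k} folds"
            )
        rng.shuffle(members)
        fold_index[members] = np.arange(members.size) % k
    return FoldAssignment(fold_index=fold_index, k=k, seed=seed)


def _oof_accuracy(table: ProbabilityMatrix, labels: np.ndarray, train_idx: np.ndarray) -> float:
    """Classifier accuracy on the training portion (argmax prediction)."""
    pred = np.argmax(table.values[train_idx], axis=1)
    return float(np.mean(pred == labels[train_idx]))


def cross_validate_ensemble(
    score_tables: Sequence[ProbabilityMatrix],
    labels: Sequence[int],
    folds: FoldAssignment,
    accuracies: Sequence[float] | None = None,
) -> tuple[list[MetricsReport], MetricsReport]:
    """Fuse each test fold and average metrics across folds.

    Parameters
    ----------
    score_tables : sequence of ProbabilityMatrix
        Out-of-fold probability tables covering every sample, one per base
        classifier.
    labels : sequence of int
        True class per sample, aligned with the tables' row order.
    folds : FoldAssignment
        Stratified fold assignment over the same samples.
    accuracies : sequence of float, optional
        Fixed per-classifier accuracies for the fuzzy densities (the
        "manifest" policy).  When omitted, each fold uses accuracies
        computed on its training portion ("out-of-fold" policy).

    Returns
    -------
    (per-fold reports, unweighted mean report)
    """
    check_alignment(score_tables)
    y = np.asarray(labels, dtype=int)
    n = score_tables[0].n_samples
    if y.shape[0] != n or folds.fold_index.shape[0] != n:
        raise ValueError("labels, folds and score tables must cover the same samples")
    per_fold: list[MetricsReport] = []
    for fold in range(folds.k):
        test_idx = folds.test_indices(fold)
        train_idx = folds.train_indices(fold)
        if accuracies is not None:
            acc = np.asarray(accuracies, dtype=float)
        else:
            acc = np.array([_oof_accuracy(t, y, train_idx) for t in score_tables])
        fold_tables = [
            ProbabilityMatrix(
                sample_ids=[t.sample_ids[i] for i in test_idx],
                values=t.values[test_idx],
                class_labels=t.class_labels,
            )
            for t in score_tables
        ]
        record, _ = ensemble_predict(fold_tables, acc)
        per_fold.append(compute_metrics(y[test_idx], record.labels))
    mean = MetricsReport(
        accuracy=float(np.mean([m.accuracy for m in per_fold])),
        sensitivity=float(np.mean([m.sensitivity for m in per_fold])),
        specificity=float(np.mean([m.specificity for m in per_fold])),
        precision=float(np.mean([m.precision for m in per_fold])),
        f1=float(np.mean([m.f1 for m in per_fold])),
        balanced_accuracy=float(np.mean([m.balanced_accuracy for m in per_fold])),
    )
    return per_fold, mean


def weighted_average_baseline(
    score_tables: Sequence[ProbabilityMatrix], weights: Sequence[float]
) -> np.ndarray:
    """Classic late-fusion baseline: argmax of the weighted mean probability.

    Weights must be non-negative with a positive sum; they are renormalised
    to sum to one.  Ties go to the lowest class index.
    """
    check_alignment(score_tables)
    w = np.asarray(weights, dtype=float)
    if w.ndim != 1 or w.shape[0] != len(score_tables):
        raise ValueError("one weight per score table is required")
    if (w < 0).any() or not np.isfinite(w).all():
        raise ValueError("weights must be finite and non-negative")
    if w.sum() == 0:
        raise ValueError("weights must not all be zero")
    w = w / w.sum()
    fused = np.tensordot(w, np.stack([t.values for t in score_tables]), axes=(0, 0))
    return np.argmax(fused, axis=1)
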