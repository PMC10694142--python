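"""Sugeno lambda fuzzy measures over classifier subsets.

A fuzzy measure g assigns a weight in [0, 1] to every subset of classifiers,
with g(empty) = 0, g(all) = 1, and monotonicity under set inclusion.  The
Sugeno lambda family builds the whole measure from per-classifier densities
g_i via

    g(A ∪ {j}) = g(A) + g_j + lambda * g(A) * g_j,

where lambda is the root of ``1 + lambda = prod_i (1 + g_i * lambda)`` in
(-1, inf) that makes the full set measure exactly 1.  Densities here are the
base classifiers' accuracies normalised to sum to one, in which case the
unique measure-consistent root is lambda = 0 and the measure is additive;
unnormalised densities yield a genuinely non-additive measure (lambda > 0
when the densities sum below 1, lambda in (-1, 0) when above).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import optimize

__all__ = [
    "DensityVector",
    "LambdaMeasure",
    "densities_from_accuracies",
    "solve_lambda",
    "build_lambda_measure",
    "measure_of_subset",
]

_SUM_TOL = 1e-12
_RESIDUAL_TOL = 1e-12


@dataclass(frozen=True)
class DensityVector:
    """Per-classifier fuzzy densities g_i with their source accuracies."""

    densities: np.ndarray
    source_accuracies: np.ndarray | None = None

    def __post_init__(self):
        g = np.asarray(self.densities, dtype=float)
        if g.ndim != 1 or g.size < 1:
            raise ValueError("densities must be a non-empty 1-D vector")
        if not np.isfinite(g).all() or (g < 0).any():
            raise ValueError("densities must be finite and non-negative")
        g.setflags(write=False)
        object.__setattr__(self, "densities", g)
        if self.source_accuracies is not None:
            acc = np.asarray(self.source_accuracies, dtype=float)
            acc.setflags(write=False)
            object.__setattr__(self, "source_accuracies", acc)

    def __len__(self) -> int:
        return self.densities.size


@dataclass(frozen=True)
class LambdaMeasure:
    """A solved Sugeno lambda measure: densities plus the scalar lambda.

    Subset values are evaluated lazily through :func:`measure_of_subset`
    (the Choquet integral only ever needs the C nested subsets per sample,
    not the full 2^C lattice).
    """

    densities: DensityVector
    lam: float

    def __call__(self, subset: Iterable[int]) -> float:
        return measure_of_subset(self, subset)

    @property
    def n_classifiers(self) -> int:
        return len(self.densities)


def densities_from_accuracies(accuracies: Sequence[float]) -> DensityVector:
    """Accuracy-proportional densities ``g_i = acc_i / sum(acc)``.

    The normalisation makes the densities sum to one, so the lambda measure
    built from them is additive (lambda = 0).
    """
    acc = np.asarray(accuracies, dtype=float)
    if acc.ndim != 1 or acc.size < 1:
        raise ValueError("accuracies must be a non-empty 1-D vector")
    if not np.isfinite(acc).all() or (acc <= 0).any() or (acc > 1).any():
        raise ValueError("accuracies must be finite and in (0, 1]")
    return DensityVector(densities=acc / acc.sum(), source_accuracies=acc)


def _deflated_coeffs(g: np.ndarray) -> np.ndarray:
    """Coefficients (ascending powers) of h(x) = (prod(1 + g_i x) - 1 - x) / x.

    x = 0 is always a root of the normalisation equation; dividing it out
    leaves a polynomial whose value at 0 is sum(g) - 1 exactly, so the
    non-zero root can be bracketed without catastrophic cancellation.
    """
    c = np.array([1.0])
    for gi in g:
        c = np.convolve(c, np.array([1.0, gi]))  # multiply by (1 + g_i x)
    h = c[1:].copy()
    h[0] -= 1.0  # h_0 = e_1 - 1
    return h


def solve_lambda(densities: DensityVector | Sequence[float]) -> float:
    """Solve ``1 + lambda = prod_i (1 + g_i * lambda)`` on (-1, inf).

    lambda = 0 is a root for any densities; it is the measure-consistent one
    exactly when the densities sum to 1, which is when it is returned.
    Otherwise the unique non-zero root — positive when sum(g) < 1, in
    (-1, 0) when sum(g) > 1 — is found by bracketed refinement of the
    deflated polynomial (the normalisation equation with the trivial root
    divided out).
    """
    if not isinstance(densities, DensityVector):
        densities = DensityVector(np.asarray(densities, dtype=float))
    g = densities.densities
    total = g.sum()
    if abs(total - 1.0) <= _SUM_TOL:
        return 0.0
    if g.size == 1:
        raise ValueError(
            f"a single classifier must carry density 1 (got {g[0]:.6g}); "
            "no lambda can normalise the measure"
        )
    h = _deflated_coeffs(g)
    poly = np.polynomial.Polynomial(h)
    if total < 1.0:
        # h(0) = sum(g) - 1 < 0 and h -> +inf (leading coefficient > 0)
        lo, hi = 0.0, 1.0
        while poly(hi) < 0.0:
            hi *= 2.0
            if hi > 1e12:
                raise ArithmeticError(
                    f"failed to bracket positive lambda root for densities {g!r}"
                )
    else:
        # h(0) = sum(g) - 1 > 0 and h(-1) = (prod(1 - g_i) - 0) / (-1) < 0
        # whenever all g_i < 1; clip the endpoint just inside the domain
        lo, hi = -1.0 + 1e-12, 0.0
        if poly(lo) >= 0.0:
            raise ArithmeticError(
                f"failed to bracket lambda root in (-1, 0) for densities {g!r}"
            )
    lam = float(optimize.brentq(poly, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200))
    residual = np.prod(1.0 + g * lam) - (1.0 + lam)
    if abs(residual) > max(_RESIDUAL_TOL, 1e-12 * abs(lam) * g.size):
        raise ArithmeticError(
            f"lambda root residual {residual:.3g} exceeds tolerance (lambda={lam!r})"
        )
    return lam


def build_lambda_measure(densities: DensityVector | Sequence[float]) -> LambdaMeasure:
    """Convenience constructor: solve lambda and wrap into a LambdaMeasure."""
    if not isinstance(densities, DensityVector):
        densities = DensityVector(np.asarray(densities, dtype=float))
    return LambdaMeasure(densities=densities, lam=solve_lambda(densities))


def measure_of_subset(measure: LambdaMeasure, subset: Iterable[int]) -> float:
    """Evaluate g(A) for a subset A of classifier indices (0-based).

    The empty set maps to 0 exactly and singletons to their density; larger
    subsets are built by left-folding the pairwise combination rule
    ``g(A ∪ {j}) = g(A) + g_j + lambda g(A) g_j``, which is order-independent.
    """
    g = measure.densities.densities
    lam = measure.lam
    idx = list(subset)
    if len(set(idx)) != len(idx):
        raise ValueError(f"subset contains repeated indices: {idx}")
    for i in idx:
        if not 0 <= i < g.size:
            raise IndexError(f"classifier index {i} out of range [0, {g.size})")
    value = 0.0
    for i in idx:
        value = value + g[i] + lam * value * g[i]
    assert value >= -1e-12, f"fuzzy measure went negative: {value!r}"
    return float(value)


def nested_subset_measures(measure: LambdaMeasure, order: np.ndarray) -> np.ndarray:
    """Measures of the nested prefixes of ``order`` along its last axis.

    ``order`` holds 0-based classifier indices; the result's entry k is
    g({order[..., 0], ..., order[..., k]}).  Computed with the closed form
    ``g(A) = (prod_{i in A}(1 + lambda g_i) - 1) / lambda`` (cumulative sum
    when lambda = 0), vectorised over any leading axes.
    """
    g_sorted = measure.densities.densities[order]
    if measure.lam == 0.0:
        return np.cumsum(g_sorted, axis=-1)
    cp = np.cumprod(1.0 + measure.lam * g_sorted, axis=-1)
    return (cp - 1.0) / measure.lam
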