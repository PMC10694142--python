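"""Synthetic imbalanced cohorts with controllable classifier quality.

The generator emulates the late-fusion setting the package targets: C base
classifiers of differing quality emit probability vectors over N classes for
every sample of an imbalanced cohort.  Defaults mirror a realistic survival
study: 1980 samples with class prior 1489:491 (about 75:25 in favour of the
long-term-survivor majority class) scored by four classifiers.

Mechanism: each sample carries a latent evidence magnitude ``w``
(exponential, mean 1) — a property of the sample itself, so easy samples
look easy to every classifier and hard ones hard.  Classifier c draws its
probability row from a Dirichlet whose concentration is proportional to the
class prior, boosted on the true class by ``quality_c * w``; a
``miscalibration`` temperature then re-scales the row.  The Dirichlet
sampling noise is classifier-specific, so at ``correlation = 0`` the
classifiers are conditionally independent given the sample, correlated only
through the shared difficulty ``w``.  The ``correlation`` coefficient
couples the sampling noise itself through a Gaussian copula (comonotone in
the limit) without changing any classifier's marginal score distribution.
With quality 0 the rows concentrate near the prior, so every classifier
degenerates to majority guessing and its accuracy approaches the largest
prior; with large quality, accuracy approaches 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import stats

from .transform import ProbabilityMatrix

#: Base Dirichlet concentration mass; large enough that quality = 0 rows sit
#: tightly around the prior (majority guessing), small enough to leave
#: sample-to-sample variability.
_BASE_CONCENTRATION = 20.0



@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort generator.

    Parameters
    ----------
    n_samples : int
        Cohort size.
    class_prior : tuple of float
        Class probabilities, summing to 1.  Default is the 1489:491
        imbalance of a 1980-patient survival cohort.
    quality : tuple of float
        Per-classifier concentration boost on the true class, >= 0; higher
        means more accurate.  Length defines the number of classifiers.
    miscalibration : tuple of float
        Per-classifier temperature > 0 applied to the probability rows
        (1 = calibrated, > 1 flattens, < 1 sharpens).
    correlation : float
        Shared-noise mixing coefficient in [0, 1); higher couples the
        classifiers' sampling noise and makes their mistakes more
        correlated, beyond the correlation already induced by shared
        sample difficulty.
    seed : int
        Generator seed; the cohort is fully reproducible from it.
    """

    n_samples: int = 1980
    class_prior: tuple = (1489 / 1980, 491 / 1980)
    quality: tuple = (0.145, 0.15, 0.34, 0.35)
    miscalibration: tuple = (1.0, 1.0, 1.0, 1.0)
    correlation: float = 0.0
    seed: int = 0

    def __post_init__(self):
        prior = np.asarray(self.class_prior, dtype=float)
        if prior.ndim != 1 or prior.size < 2 or (prior <= 0).any() or abs(prior.sum() - 1) > 1e-9:
            raise ValueError("class_prior must be a positive vector summing to 1")
        q = np.asarray(self.quality, dtype=float)
        if q.size < 1 or (q < 0).any():
            raise ValueError("quality must be a non-empty vector of non-negatives")
        t = np.asarray(self.miscalibration, dtype=float)
        if t.shape != q.shape or (t <= 0).any():
            raise ValueError("miscalibration must be positive, one per classifier")
        if not 0.0 <= self.correlation < 1.0:
            raise ValueError("correlation must lie in [0, 1)")
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")

    @property
    def n_classifiers(self) -> int:
        return len(self.quality)

    @property
    def n_classes(self) -> int:
        return len(self.class_prior)


@dataclass(frozen=True)
class SyntheticCohort:
    """Labels, per-classifier score tables, and realised accuracies."""

    labels: np.ndarray
    score_tables: list  # list[ProbabilityMatrix]
    realized_accuracies: np.ndarray
    config: SimulationConfig = field(compare=False, default=None)


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Draw one synthetic cohort from the configured mechanism."""
    rng = np.random.default_rng(config.seed)
    prior = np.asarray(config.class_prior, dtype=float)
    n, N, C = config.n_samples, config.n_classes, config.n_classifiers
    labels = rng.choice(N, size=n, p=prior)
    onehot = np.eye(N)[labels]  # (n, N)
    evidence = rng.exponential(1.0, size=n)  # per-sample difficulty, shared
    sample_ids = [f"S{i:05d}" for i in range(n)]
    class_labels = [str(j) for j in range(N)]

    rho = config.correlation
    shared_z = rng.standard_normal((n, N))
    tables = []
    accs = np.empty(C)
    for c in range(C):
        boost = config.quality[c] * evidence[:, None] * onehot
        alpha = _BASE_CONCENTRATION * (prior[None, :] + boost)
        # per-row Dirichlet via Gamma draws; a Gaussian copula couples the
        # classifiers' draws without altering any marginal
        z = rho * shared_z + np.sqrt(1.0 - rho**2) * rng.standard_normal((n, N))
        gam = stats.gamma.ppf(stats.norm.cdf(z), a=alpha)
        rows = gam / gam.sum(axis=1, keepdims=True)
        log_rows = np.log(np.clip(rows, 1e-300, None))
        log_rows = log_rows / config.miscalibration[c]
        log_rows -= log_rows.max(axis=1, keepdims=True)
        probs = np.exp(log_rows)
        probs /= probs.sum(axis=1, keepdims=True)
        tables.append(
            ProbabilityMatrix(sample_ids=sample_ids, values=probs, class_labels=class_labels)
        )
        accs[c] = float(np.mean(np.argmax(probs, axis=1) == labels))
    return SyntheticCohort(
        labels=labels, score_tables=tables, realized_accuracies=accs, config=config
    )


def make_fixture_bundle(config: SimulationConfig, out_dir: str | Path) -> Path:
    """Write a cohort as score files, a labels file, and an ensemble manifest.

    Returns the manifest path.  The files round-trip bit-identically through
    the package's readers.
    """
    from .io import write_labels, write_score_table  # deferred: io imports transform

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(config)
    entries = []
    for c, table in enumerate(cohort.score_tables):
        path = out_dir / f"classifier_{c}.csv"
        write_score_table(table, path)
        entries.append(
            {
                "id": f"classifier_{c}",
                "scores": path.name,
                "accuracy": float(cohort.realized_accuracies[c]),
            }
        )
    labels_path = out_dir / "labels.csv"
    write_labels(cohort.score_tables[0].sample_ids, cohort.labels, labels_path)
    manifest = {
        "classifiers": entries,
        "labels": labels_path.name,
        "positive_class": "1",
        "options": {"accuracy_policy": "manifest"},
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n", encoding="utf-8")
    return manifest_path


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy a configuration with a different seed."""
    return replace(config, seed=seed)
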