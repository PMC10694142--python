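import numpy as np
import pytest

from fuzzyfuse import ProbabilityMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


def random_probability_matrix(rng, n_samples, n_classes, prefix="S"):
    """Valid random probability table (Dirichlet rows)."""
    values = rng.dirichlet(np.ones(n_classes), size=n_samples)
    return ProbabilityMatrix(
        sample_ids=[f"{prefix}{i}" for i in range(n_samples)],
        values=values,
        class_labels=[str(j) for j in range(n_classes)],
    )


def brute_force_choquet(values, densities, lam):
    """Independent sorted-difference Choquet oracle with closed-form subset measures."""
    C = len(values)
    order = sorted(range(C), key=lambda i: (-values[i], i))

    def g(subset):
        if not subset:
            return 0.0
        if lam == 0.0:
            return float(sum(densities[i] for i in subset))
        prod = 1.0
        for i in subset:
            prod *= 1.0 + lam * densities[i]
        return (prod - 1.0) / lam

    total = 0.0
    for k in range(C):
        v_k = values[order[k]]
        v_next = values[order[k + 1]] if k + 1 < C else 0.0
        total += (v_k - v_next) * g(order[: k + 1])
    return total
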