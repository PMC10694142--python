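"""Decision-level fusion of probabilistic classifiers with fuzzy integrals.

``fuzzyfuse`` combines the class-probability outputs of several base
classifiers into a single prediction.  Each probability is first mapped to a
*deviation* score (a penalty that grows as the probability falls away from 1)
and a *support* score (a reward that grows as the probability approaches 1).
Per class, the scores of all classifiers are then aggregated with a Choquet
integral against a Sugeno lambda fuzzy measure whose densities are the
classifiers' accuracies, normalised to sum to one.  The final label is the
class with the smallest aggregated deviation; the support pathway is computed
and reported alongside, and disagreements between the two are resolved in
favour of deviation.

The package also ships a confusion-matrix metrics module, a stratified
cross-validation harness, a weighted-average-ensemble baseline, a synthetic
cohort simulator for testing at realistic scale, and delimited-text I/O with
a small command-line interface.
"""

from .transform import (
    ProbabilityMatrix,
    TransformedScores,
    support_scores,
    deviation_scores,
    transform_scores,
    multiplicative_relevance,
)
from .fuzzy_measure import (
    DensityVector,
    LambdaMeasure,
    densities_from_accuracies,
    solve_lambda,
    build_lambda_measure,
    measure_of_subset,
)
from .aggregate import (
    AggregatedScores,
    DecisionRecord,
    choquet_integral,
    aggregate_per_class,
    decide_labels,
    ensemble_predict,
)
from .evaluate import (
    ConfusionCounts,
    MetricsReport,
    FoldAssignment,
    compute_metrics,
    stratified_folds,
    cross_validate_ensemble,
    weighted_average_baseline,
)
from .simulate import SimulationConfig, SyntheticCohort, simulate_cohort, make_fixture_bundle
from .io import EnsembleManifest, read_score_table, write_score_table, read_labels, write_labels, read_manifest

__version__ = "0.1.0"

__all__ = [
    "ProbabilityMatrix",
    "TransformedScores",
    "support_scores",
    "deviation_scores",
    "transform_scores",
    "multiplicative_relevance",
    "DensityVector",
    "LambdaMeasure",
    "densities_from_accuracies",
    "solve_lambda",
    "build_lambda_measure",
    "measure_of_subset",
    "AggregatedScores",
    "DecisionRecord",
    "choquet_integral",
    "aggregate_per_class",
    "decide_labels",
    "ensemble_predict",
    "ConfusionCounts",
    "MetricsReport",
    "FoldAssignment",
    "compute_metrics",
    "stratified_folds",
    "cross_validate_ensemble",
    "weighted_average_baseline",
    "SimulationConfig",
    "SyntheticCohort",
    "simulate_cohort",
    "make_fixture_bundle",
    "EnsembleManifest",
    "read_score_table",
    "write_score_table",
    "read_labels",
    "write_labels",
    "read_manifest",
]
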