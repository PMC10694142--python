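"""Building a Sugeno lambda fuzzy measure from classifier accuracies.

Densities are accuracies normalised to sum to one, which makes the measure
additive (lambda = 0).  The script also builds a measure from unnormalised
densities to show a genuinely non-additive case where the whole is more
than the sum of its parts.
"""

from fuzzyfuse import (
    DensityVector,
    build_lambda_measure,
    densities_from_accuracies,
    measure_of_subset,
)

accuracies = [0.7727, 0.7717, 0.8182, 0.8187]
measure = build_lambda_measure(densities_from_accuracies(accuracies))
print("accuracy-proportional densities:",
      [round(float(g), 6) for g in measure.densities.densities])
print(f"solved lambda: {measure.lam}")
print(f"g(empty set)     = {measure_of_subset(measure, [])}")
print(f"g({{classifier 3}}) = {measure_of_subset(measure, [3]):.6f}")
print(f"g({{2, 3}})        = {measure_of_subset(measure, [2, 3]):.6f}")
print(f"g(all four)      = {measure_of_subset(measure, range(4)):.6f}")

print()
print("unnormalised densities [0.2, 0.3] force a non-zero lambda:")
nonadd = build_lambda_measure(DensityVector([0.2, 0.3]))
print(f"lambda = {nonadd.lam:.6f}  (positive because the densities sum below 1)")
print(f"g({{0}}) + g({{1}}) = {0.2 + 0.3}  but  g({{0, 1}}) = "
      f"{measure_of_subset(nonadd, [0, 1]):.6f}")
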