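# Methods

## The fusion model

`fuzzyfuse` performs decision-level (late) fusion of C base classifiers
that each emit a probability vector P over N classes for every sample.
The motivating application is imbalanced binary survival classification —
long-term (label 0, majority) versus short-term (label 1, minority)
survivors at a 5-year cutoff — but every component is written for general
N ≥ 2 and C ≥ 1.

Fusion proceeds in four steps.

**1. Deviation and support transforms.**  Each probability is mapped to a
penalty and a reward:

    D(p) = 1 − exp(−(p − 1)² / 2)        (deviation)
    S(p) = 1 − tanh((p − 1)² / 2)        (support)

Both are strictly monotone on [0, 1].  Deviation spans [0, 1 − e^{−1/2}]
≈ [0, 0.3935] and support [1 − tanh(1/2), 1] ≈ [0.5379, 1]; the deviation
range sits entirely below the support range, so the per-class product
D·S (exposed as the *multiplicative relevance* diagnostic, R_n = Σ_c
D^c_n S^c_n) is steered by the deviation factor.  That asymmetry is the
rationale for resolving disagreements between the two aggregation
pathways in deviation's favour.

**2. Fuzzy densities and the Sugeno λ-measure.**  Classifier i receives a
density g_i = acc_i / Σ_j acc_j, its accuracy normalised over the
ensemble.  A subset A of classifiers is weighted by the Sugeno λ-measure
generated from the densities via the pairwise rule
g(A ∪ {j}) = g(A) + g_j + λ g(A) g_j, with λ the root of
1 + λ = Π_i (1 + g_i λ) in (−1, ∞).  λ = 0 solves this equation for any
densities; it is the measure-consistent root exactly when Σ g_i = 1, and
the solver returns it only then (the standard λ-measure convention).
Otherwise the unique non-zero root is returned: positive when Σ g_i < 1,
in (−1, 0) when Σ g_i > 1.  Because accuracy normalisation forces
Σ g_i = 1, the measure built from accuracies is always additive; the
non-additive branch is fully implemented and exercised with unnormalised
densities.

*Numerics.*  The normalisation equation always has the trivial root
λ = 0, which makes naive bracketing around zero numerically hopeless
(catastrophic cancellation).  The solver divides that root out
analytically — expanding Π(1 + g_i λ) into elementary symmetric
polynomial coefficients leaves h(λ) = (Σg − 1) + e₂λ + e₃λ² + … — and
Brent-refines h on [0, hi] or [−1 + 1e−12, 0].  The residual of the
original equation is checked to 1e−12 after refinement.

**3. Choquet aggregation.**  Per sample and class, the C deviation scores
(and separately the C support scores) are aggregated with the discrete
Choquet integral: sort values descending (ties broken by ascending
classifier index, for determinism), then sum successive differences
weighted by the measure of the nested top-k subsets:

    Agg = Σ_k (v_(k) − v_(k+1)) · g({σ(1) … σ(k)}),   v_(C+1) = 0.

The printed telescoped form of the aggregation is a Choquet integral only
when the value index order coincides with the descending sort, so the
implementation sorts explicitly.  Only the C nested subsets per sample
are evaluated (lazily, via the closed form
g(A) = (Π_{i∈A}(1 + λ g_i) − 1)/λ, cumulative sums when λ = 0), never the
full 2^C lattice; a full-lattice brute-force evaluator exists in the test
suite as the independent oracle.  When λ = 0 the integral collapses to
the density-weighted mean — the regime the accuracy-normalised
construction always lands in.

**4. Decision rule.**  The final label is argmin over classes of the
aggregated deviation; argmax of aggregated support is computed alongside,
and an `agreed` flag records whether the two pathways coincide.  On a
clash the deviation choice wins, so the label identically equals the
deviation argmin — the support pathway is a first-class reported output
(its agreement rate is logged) but cannot alter a label.  Ties in argmin
and argmax break to the lowest class index.  With a single classifier,
monotonicity of the transforms makes the rule collapse to argmax of the
raw probabilities.

## Evaluation harness

Metrics use the standard confusion-matrix definitions with label 1 as the
positive class: Sn = tp/(tp+fn), Sp = tn/(tn+fp), Prec = tp/(tp+fp),
Ac = (tp+tn)/total, F1 the harmonic mean of precision and sensitivity,
Bal-Ac = (Sn+Sp)/2.  Zero-denominator ratios are reported as 0 with a
logged warning rather than NaN so that per-fold averages stay defined.

Stratified k-fold assignment shuffles each class with a seeded generator
and deals members round-robin across folds; per-fold class counts
therefore deviate from exact proportionality by at most one sample (a
1489:491 cohort at k = 10 yields per-fold counts {148, 149} × {49, 50}),
and assignments are deterministic given the seed.

The cross-validation harness assumes base classifiers have produced
out-of-fold scores for every sample (the usual late-fusion protocol);
each test fold is fused with densities from either caller-supplied
accuracies ("manifest" policy) or accuracies recomputed on the fold's
training portion ("out-of-fold" policy, the harness default when no
accuracies are given — chosen so test labels never leak into the
densities).  Fold metrics are averaged unweighted.

The weighted-average baseline labels each sample by argmax of
Σ_c w_c P^c, with non-negative weights renormalised to sum to one.

## The synthetic cohort generator

The generator emulates the study conditions the package targets: 1980
samples with class prior 1489:491 (≈ 0.752 : 0.248) scored by four
classifiers of unequal quality.  Default quality knobs (0.145, 0.15,
0.34, 0.35) were calibrated so realized accuracies match the accuracy
levels of published multi-modal survival base classifiers (≈ 0.772,
0.772, 0.818, 0.819).

Per sample: a label is drawn from the prior and a latent evidence
magnitude w ~ Exponential(1) is attached to the sample itself — easy
samples look easy to every classifier.  Classifier c draws its
probability row from a Dirichlet with concentration
a₀ · (prior + quality_c · w · onehot(label)), a₀ = 20, via Gamma draws;
a `miscalibration` temperature then rescales the row in log space
(1 = calibrated).  The Dirichlet noise is classifier-specific, so at
`correlation = 0` classifiers are conditionally independent given the
sample, correlated only through shared difficulty.  The `correlation`
coefficient ρ couples the Gamma draws through a Gaussian copula
(z = ρ z_shared + √(1−ρ²) z_own mapped through each classifier's Gamma
quantile function), which leaves every marginal score distribution
exactly unchanged — accuracies do not drift with ρ — while making
correctness indicators increasingly correlated.

Limit behaviour: quality 0 concentrates rows at the prior, so the
classifier degenerates to majority guessing and its accuracy approaches
the largest prior; large quality drives accuracy to 1; expected accuracy
is non-decreasing in quality.

**What the generator does not emulate.**  Scores are generated directly
at the probability level; there are no feature blocks, no training
dynamics, and no model-specific bias structure.  In particular the
synthetic classifiers reach realistic *accuracies* with a more
specificity-heavy operating point (Sp ≈ 1, Sn ≈ 0.1–0.3) than trained
clinical classifiers typically show: an accuracy-matched real base
classifier trades some specificity for substantially higher sensitivity.
Passing tests on synthetic cohorts therefore demonstrate the fusion
machinery's correctness and its noise-averaging benefit over the weakest
base classifier, not clinical-grade sensitivity.  A design in which
classifiers were conditionally independent given the *label alone* was
considered and rejected: at these accuracy levels such classifiers hold
their edge in private, marginal detections whose conditional mean score
sits below the decision boundary, and every mean-type fusion rule
(Choquet with λ = 0, weighted averaging, majority vote) then provably
collapses to majority guessing — shared sample difficulty is both the
realistic and the useful regime for studying fusion.

## Numerical conventions

- Probability rows must lie in [0, 1] and sum to 1 within 1e−6; rows
  within tolerance are renormalised (warning logged above 1e−12 drift),
  larger violations are hard errors.
- λ-solver: residual tolerance 1e−12; full-set measure asserted to 1
  within 1e−9.
- Sort and argmin/argmax ties: lowest index, everywhere.
- Score tables serialise with 10 significant digits.
- Library tests compare floats at absolute tolerance 1e−9 unless a
  tighter oracle (1e−12) is available.

## Problem sizes used in the test suite

Property checks run at 10⁴-point transform grids, 10⁵ random decision
vectors, 1000 random Choquet instances at C ≤ 5, and 20 simulated
paper-scale cohorts (1980 × 4) under 10-fold cross-validation; the whole
suite completes in a few seconds on one CPU.
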