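# Methods

This note documents the statistical model behind `hetsens`, the defaults
and the reasoning for them, the numerical choices, and the limits of what
the synthetic-data tests demonstrate.

## Model and procedures

### Matched designs and the sharp null

The unit of inference is a matched set: one treated unit and
n<sub>i</sub> − 1 controls with similar observed covariates.  Fisher's
sharp null asserts identical potential outcomes under treatment and
control for every unit in a stated collection of sets; subgroup nulls
restrict that collection.  All tests in the package are randomization
tests conditional on the matched structure, so they need no outcome
model.

### Weighted M-statistics

For scale s (the λ-quantile of pooled within-set |treated − control|
outcome differences, λ = 1/2 by default) and a trimming ramp
ψ(y) = sign(y)·min(max(|y| − inner, 0), outer − inner), each member gets
the score q<sub>ij</sub> = Σ<sub>l</sub> ψ((R<sub>ij</sub> − R<sub>il</sub>)/s),
and the statistic sums the treated members' scores with nonnegative set
weights w<sub>i</sub>.  With the identity ψ (inner = 0, outer = ∞) and
constant weights this is the permutational t-statistic up to scaling;
p-values are invariant to any positive rescaling of ψ or of the weights,
so the un-normalized ramp is used.  Inner/outer trimming (e.g. 0 and 3,
or 1.5 and 2.6) buys robustness against long-tailed outcomes.  A
U-statistic weighting (parameters m, m̲, m̄) is available behind
`ScoreConfig.weight_scheme`: set i's weight is the probability that its
magnitude rank falls in positions m̲..m̄ within a random size-m subset of
sets containing it (a hypergeometric sum).  Constant weights are the
default and the only scheme the package's own benchmarks rely on; the
weighting is isolated so an alternative construction can be swapped in
without touching any other module.

### The Γ sensitivity model and worst-case moments

Two units in the same set may differ in their odds of treatment by at
most Γ ≥ 1 given observed covariates and a hidden covariate u.  For the
upper-tailed test, the adverse u-configuration within a set of size n
puts probability Γ/(aΓ + n − a) on each of the a largest q-values and
1/(aΓ + n − a) on the rest; a is chosen per set to maximize the null mean
(the separable construction).  Ties in the mean are resolved toward the
larger second moment — the conservative choice, since a larger variance
makes the reference distribution heavier-tailed.  Summing per-set means
and variances gives θ<sub>Γ</sub> and σ<sub>Γ</sub>², and the p-value is
1 − Φ((T − θ<sub>Γ</sub>)/σ<sub>Γ</sub>).  Lower-tailed tests negate the
scores; two-sided tests either double the smaller one-sided p-value
(tree-based pipeline) or run both tails at α/2 (submax pipelines).  An
exact enumeration oracle over all binary u-configurations
(`exact_worstcase_tail`, feasible to 14 members) backs the unit tests.
The scale s and the weights are computed once per matched sample, not per
subgroup, so that subgroup statistics remain comparable.

### Matching

Distances are squared Mahalanobis distances on covariate ranks (average
ranks for ties; categorical covariates expanded to one indicator per
level).  Ranks make the distance invariant to monotone transforms and
robust to outliers; the rank covariance is regularized by adding
10⁻⁶·trace/p to the diagonal when singular, and zero-variance columns are
dropped with a warning.  A soft propensity caliper adds
penalty·(gap − w)/w beyond width w (default w = 0.2 SD of the estimated
scores, a common convention); soft rather than hard so feasibility is
never destroyed.  Almost-exact matching adds a dominant penalty
(1000 × the largest finite base distance) per disagreeing key, which
makes exact agreement strictly preferred whenever feasible.

Assignment is a minimum-cost flow (networkx) with costs integerized at a
relative resolution of 10⁻⁶; pair matching and variable-ratio matching
share the network.  Near-fine balance is implemented with category-slot
nodes on the joint (interaction) categories of the balance keys: each
control routes through its category, categories have free slots sized to
the treated marginal (times the maximum matching ratio), and overflow
pays a penalty (default 10 × the largest finite distance).  Balancing the
interaction implies balancing each marginal.  With a control ratio range
(min, max) the cost-minimal solution uses min controls per treated unit
unless `total_controls` fixes the overall number of controls; the fixed
total is enforced by a saturated bypass arc, which does not affect which
controls are chosen.  Balance is reported as standardized mean
differences with the pooled SD always taken from the *before*-matching
groups, so before/after values share a scale; in variable-ratio samples
each set contributes equally (controls weighted 1/(n<sub>i</sub> − 1)).

Propensity scores come from a main-effects logistic fit on the imputed,
rank-reduced design (collinear one-hot columns removed by pivoted QR);
perfect separation or non-convergence falls back to a ridge-penalized
fit with a logged warning.

### Missing data

Each covariate with missing entries gains a binary indicator (1 = was
missing) and its gaps are filled with the mean of the observed entries.
Categorical covariates are filled with the modal level (ties broken by
sorted order): a mean is undefined for unordered categories, so the
modal fill is this package's choice where the convention only covers
numeric covariates.  Matching on the filled covariate plus the indicator
balances observed values and the missingness pattern; the missing values
themselves may remain unbalanced.

### Subgroup discovery

Within-pair differences Y<sub>i</sub> are defined for pairs exactly
matched on the candidate modifiers; |Y<sub>i</sub>| is invariant to which
member was treated under the sharp null, so fitting a regression tree to
|Y| does not bias the subsequent randomization inference.  The tree is a
least-squares CART (scikit-learn) with the conventional
recursive-partitioning controls: minimum 20 records to split, minimum
leaf size 7, maximum depth 30, and complexity parameter cp = 0.01
enforced as a minimum impurity decrease of cp·Var(|Y|) — i.e. a split
must reduce the residual sum of squares by 1% of the root sum of squares.
Determinism comes from a fixed random state; in the measure-zero event of
an exactly tied split gain the library's internal order decides, which
may differ from a lexicographic rule.  After the tree is fit, inexactly
matched pairs are re-paired so both members share a leaf: the pooled
treated and control units from inexact pairs are optimally re-assigned
within identical leaf profiles, and unmatchable units are dropped
(logged).  The number of exactly matched pairs never decreases.

### Closed testing

For G subgroup nulls, every nonempty intersection is tested and a
hypothesis is rejected familywise-validly iff every intersection
containing it is rejected.  The tree-based pipeline tests intersections
with the truncated product of the member subgroups' p-values: W is the
product of p-values ≤ α̃ (default 0.05; empty product = 1), and its null
distribution under independent uniforms has the closed form obtained by
conditioning on how many p-values fall below the threshold.  The
independence premise holds here because subgroups are disjoint
collections of matched sets and, under the sharp null, set contributions
are independent across sets.  W = 1 has probability (1 − α̃)^G, so its
p-value is exactly 1; products that underflow double precision are
treated as p = 0.

The submax family instead forms, per comparison k, the studentized
deviate D<sub>Γk</sub> = (Σ T − θ<sub>Γk</sub>)/σ<sub>Γk</sub> over the
comparison's member sets, where membership is at the set level: a set
joins a modifier comparison only if all its members share that modifier's
value, and always joins the overall comparison.  The deviate vector is
asymptotically normal with correlation
ρ(k,k′) = Σ<sub>shared sets</sub> w²·var / (σ<sub>k</sub>σ<sub>k′</sub>),
computed from the sets in both comparisons — which subsumes the
partition-based formula and handles partial membership.  H<sub>J</sub> is
rejected when max<sub>k∈J</sub> D<sub>Γk</sub> ≥ κ from the |J|-dim
correlation submatrix.  Two exact shortcuts keep the 2^K lattice cheap:
nothing is rejected unless the full family rejects, and since
κ<sub>J</sub> ≤ κ<sub>full</sub> for any subfamily, any subset whose max
deviate clears κ<sub>full</sub> is rejected without recomputing κ.
Beyond 15 comparisons the exhaustive lattice is not enumerated and
singleton rejections use the conservative rule D<sub>k</sub> ≥
κ<sub>full</sub> (never anti-conservative).

### Critical values

κ<sub>Γ,α</sub> is the 1−α quantile of the maximum of a zero-mean
unit-variance normal vector with correlation ρ<sub>Γ</sub>.  Rectangle
probabilities use Genz's separation-of-variables representation
integrated with a scrambled Sobol' rule at a fixed seed (8192 points),
giving deterministic values accurate to ~10⁻⁵ for the dimensions that
occur in practice; κ is found by bracketed root search between the
univariate quantile (perfect dependence) and the independence quantile,
to 10⁻⁵ on κ.  Rank-deficient correlation matrices (possible with nested
comparisons) are repaired by eigenvalue clipping before the Cholesky
factor is taken.

### Sensitivity values and amplification

Worst-case p-values are nondecreasing in Γ, so each hypothesis has a
unique grid crossing: the sensitivity value is the first grid Γ at which
the test stops rejecting (grid default 1.00–3.00 by 0.01; "∞" means
rejection holds through the grid maximum).  Amplification reinterprets Γ
as any pair (Λ, Δ) with Γ = (ΛΔ+1)/(Λ+Δ): Λ multiplies the odds of
treatment, Δ the odds of a higher outcome.  The map is symmetric,
strictly increasing in each argument, and Δ = (ΓΛ−1)/(Λ−Γ) round-trips to
machine precision; reported tables round Γ to 2 decimals and Λ, Δ to 1.

## Simulation design

One replicate draws I matched pairs.  Each pair shares a vector of p
Bernoulli(1/2) covariates; the first log₂(G) of them define G subgroups
with additive effects β (e.g. β = (1.2, 0, 0, 0.4) for G = 4: a strong, a
small, and two null subgroups).  Control responses are standard normal,
treated responses add the subgroup effect, and the treated position is
randomized within the pair — so every pair is exactly matched by
construction and the matching step is bypassed; the matching machinery is
exercised separately on the observational fixture generator.  Covariates
beyond the designated modifiers are pure noise: they influence neither
treatment nor outcome, matching the displayed data-generating process.
The statistic configuration for simulations is the permutational-t form
(identity ψ, λ = 1/2, constant weights).  Per-replicate seeds are the
master seed plus the replicate index.

Five variants are compared.  Hypothesis labeling for power follows the
benchmark convention: a tested hypothesis is a false null iff its
subpopulation contains any set from a subgroup with β ≠ 0; F1 =
2TP/(2TP+FP+FN) and TPR = TP/(TP+FN), with undefined denominators
reported as 0 and flagged.  For the tree-based variant the tested
hypotheses are the leaf nulls plus, when the tree has more than one leaf,
the global intersection (with a single leaf the two coincide and one
hypothesis is tested).  A covariate counts as an identified modifier for
the submax family when a subpopulation it defines is rejected, and for
the tree-based variant when the tree splits on it and a leaf below that
split is rejected.

Two behaviors of this design are worth knowing before reading results.
First, the first-split signal for CART sits close to the cp = 0.01
boundary in the large-effect setting (expected relative SSE gain ≈ 0.01
at I = 600), so the tree selects a true modifier in roughly half the
replicates and tests only the overall hypothesis otherwise; this is
inherent to the design plus the conventional tree controls, not a bug,
and it is why tree-seeded subpopulation recovery rates plateau near the
split rate.  Second, every hypothesis the "worst" benchmark tests still
contains affected sets, so it cannot make false positives and its
power-F1 can be high; its defining property is that its modifier-F1 and
TPR are identically zero.

## What the synthetic data do and do not show

The generator (and the observational fixture, with its ~1:3
treated:control ratio, ~30 mixed-type covariates and sparse missingness)
emulates the *structure* of a cognitive-aging cohort: paired designs,
binary modifiers, additive effects, Gaussian noise.  It does not emulate
correlated covariates, non-Gaussian or heteroscedastic outcomes,
treatment-probability models, informative missingness, or real hidden
confounding.  Passing tests therefore demonstrate correctness of the
procedures (error control, oracle agreement, monotonicity) under the
stated design — not performance guarantees on any particular real
cohort.

## Numerical choices and degenerate inputs

- Scale s = 0 (all outcomes tied within sets): `scale_s` raises and
  advises the identity fallback s = 1, which `scores_from_outcomes`
  applies with a warning.
- σ<sub>Γ</sub> = 0: the p-value degenerates to 1 or 0 with a warning.
- Quantiles interpolate linearly between order statistics.
- Flow costs are rounded to integer units of 10⁻⁶ × the largest finite
  distance; distances beyond that resolution tie.
- Closed testing over more than 20 subgroup hypotheses is refused (the
  submax route is suggested); the submax lattice is enumerated to K = 15.
- Tree routing of unseen/NaN modifier values raises, naming the rows.

## Known limitations

- The worst-case null is the separable (per-set) approximation with a
  normal reference; exact tail probabilities are available only through
  the enumeration oracle at toy sizes.  The approximation is tested to be
  within 0.08 of the exact tail at three pairs and within 0.05 of the
  permutation p-value at I ≥ 50.
- Near-fine balance is a penalty device, not a hard constraint; residual
  category deviations are reported by `evaluate_fine_balance`.
- Variable-ratio matching optimizes the total distance for a given
  control budget; it does not optimize the budget itself.
- Full matching, matching with replacement, cardinality matching, and
  design-sensitivity calculations are out of scope.
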