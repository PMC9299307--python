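# Methods

## Model and scope

`interactkit` fits fixed-effects factorial linear models to long-format
between-subjects data: one categorical level per factor per observation,
optional numeric covariates, one numeric response,

y = Xβ + ε,  ε ~ iid N(0, σ²),

estimated by ordinary least squares. Independence across observations is
*assumed, not checked*: all inference (EMM intervals, the CI-overlap rule,
the simulation) presumes between-subjects designs. Repeated-measures and
mixed models are out of scope, as are type-II decompositions and GLMs.

### Coding and type-III tests

Factors are coded with sum-to-zero (deviation) contrasts: a k-level factor
contributes k−1 columns; interaction columns are products of parent columns;
covariates are centred at their grand mean so that the intercept is the
grand-mean prediction. Under treatment (dummy) coding, the "drop this
effect's columns" operation silently tests different hypotheses, which is
why the coding is not configurable.

Type-III sums of squares are computed by full-vs-reduced refits
(SS = RSS_reduced − RSS_full) rather than hypothesis-matrix algebra. The two
are algebraically identical; the refit route is trivially cross-checkable
against an independent OLS solver, and the test suite does exactly that on
random unbalanced designs (relative tolerance 1e-8). Under balance, type III
coincides with the sequential decomposition, which is also asserted.
F-tests use the upper tail of F(df_effect, df_error); no one-sided variant
is offered.

### Estimated marginal means

EMMs average model predictions over an equally weighted reference grid:
every level combination of the factors not in the requested grid counts the
same, and covariates sit at their grand mean. Equal weights (not observed
frequencies) are the point — they are what removes allocation imbalance from
the cell summaries. SEs propagate through SE² = g′ Cov(β̂) g and intervals
use the central t quantile at the model's error df, the same error term the
ANOVA uses, keeping the table and the plot-ready export internally
consistent with the omnibus test.

### CI-overlap rule

Two cells are flagged as credibly different when their CIs overlap by less
than a threshold fraction (default 0.25) of the full CI length. When the two
intervals differ in length (unbalanced designs), the denominator is the
*mean* of the two full lengths — consistent with the equal-length case and
symmetric in the pair. For equal-SE independent means at large df, the 0.25
boundary maps onto a two-sided difference p ≈ 0.037 (t ≈ 1.5·t_crit/√2),
which is what makes the rule roughly comparable with a per-pair α of 0.05.
Both zero-length intervals are defined to overlap fully iff they are the
same point.

### Observed-means post-hoc tests

`pairwise_observed` runs an independent two-sample pooled-variance t-test per
unordered cell pair, each using *only* that pair's raw data (df = n₁+n₂−2).
This deliberately reproduces the common flawed practice rather than the
model-based contrast; the EMM-based contrast with the whole-model error term
lives in `emm_contrasts`, and the difference between the two error terms is
the toolkit's central teaching point. Welch's variant is available behind a
flag. Corrections implemented: Bonferroni (min(1, m·p)), Šidák (1−(1−p)^m),
Holm (step-down), none. Tukey/Scheffé/Dunnett and FDR procedures are
deliberately not implemented. Degenerate pairs (zero variance, equal means)
report t = 0, p = 1 rather than NaN.

## False-positive-risk simulation

`make_null_means` builds additive true cell means μ_ij = α_i + β_j with
adjacent row/column effects spaced by δ, so every interaction contrast is
exactly zero while main effects of average size δ may be present. This is
the only reading under which "the null is true" coexists with nonzero mean
differences: the null at stake is the *interaction* null, and conditioning
on a significant interaction is what makes the follow-ups' flags false
positives.

Each replicate: draw iid normal data (sd σ, default 1), fit the full
factorial model, keep the replicate iff the type-III interaction p < α
(default 0.05). On retained replicates both procedures run on all C(k, 2)
cell pairs; the primary outputs are per-comparison frequencies (flags over
total pairs examined), with familywise variants reported alongside.
Replicate RNG streams are spawned from the master seed (`SeedSequence`), so
results are independent of execution order; degenerate draws (zero residual
variance) are redrawn with a counted retry. Monte-Carlo SEs are binomial.
With zero retained replicates the rates are reported as NaN with a warning,
never as 0.

Reference configuration and defaults: designs 2×2/2×3/3×3, σ = 1,
n ∈ {5, 10, 20, 30, 50, 100}, δ ∈ {0, 0.1, 0.25, 0.5}, α = 0.05, overlap
threshold 0.25, Bonferroni correction, 5000 replicates. The desk-scale grid
used by the test suite ({2×2, 3×3} × n {5, 20, 100} × δ {0, 0.25} at 600
replicates) keeps the full sweep under a minute; the full grid sits behind
`--full`.

**A calibration finding.** It is often asserted that the observed-means
Bonferroni post-hoc path carries a *higher* false-positive risk than the
EMM CI-overlap rule. Under the definitions above the test suite measures
the opposite ordering in every grid cell (e.g. 2×2, n = 20, δ = 0:
per-comparison rates ≈ 0.08 post-hoc vs ≈ 0.21 overlap), and the analytic
threshold comparison explains why it cannot be otherwise: with six pairwise
comparisons, Bonferroni flags a pair only at a raw p below 0.05/6 ≈ 0.0083,
while the 25%-overlap rule flags at roughly p < 0.037 *uncorrected*. Both
procedures see the same (conditioning-inflated) mean differences and
comparable error estimates, so the more liberal per-pair threshold flags
more often. The corresponding acceptance test is intentionally left failing
rather than redefined; orderings consistent with the common assertion appear
only under materially different definitions (e.g. uncorrected post-hoc
tests, or overlap applied to main-effect marginal means, which are
orthogonal to the interaction conditioning).

## Synthetic-data generators

* `generate_example1`: balanced 2×2, n = 50/cell, true cell means
  (0.624, 0.589, 0.755, 0.651), residual sd √(50·mean(SE²)) ≈ 0.0545 implied
  by the published observed SEs at n = 50. Across seeds the true interaction
  contrast (0.069) is detected at α = 0.05 in well over 90% of draws.
* `generate_example2`: 2×2×2 with a dichotomous working-memory factor,
  n = 50 per group × stimulus cell split imbalance : (1−imbalance)
  (default 0.7) between working-memory levels, direction reversed between
  control and lesion cells; working-memory main effect ±wm_effect/2
  (default 1.2) with no interactions in the truth; σ = 0.9. The imbalance
  makes observed cell means diverge from the EMMs monotonically in the
  imbalance parameter; imbalance = 0.5 restores the identity. The base
  group × stimulus means (1.281, 0.981, 2.274, 1.086) and effect sizes were
  chosen once to reproduce the published summary *structure* (strong
  third-factor main effect, weak surviving interaction), not any particular
  dataset row-for-row.
* `generate_null`: wraps `make_null_means` with iid normal noise for the
  simulation.

What the generators do *not* emulate: non-normal errors, heteroscedasticity,
dependence between observations, missingness mechanisms, and the exact
random draws behind any published dataset (those RNG states are unknown).
Passing tests therefore demonstrate correctness of the machinery and of the
structural claims (identities, orderings, calibrations), not agreement with
any specific published F statistic.

## Informative hypotheses

Hypotheses are parsed from strings over cell labels (factor levels joined by
`:`), supporting `+`/`-` arithmetic, parentheses, single-sense chains
(`a < b < c` → adjacent-pair constraints) and comma groups
(`(a, b) > (c, d)` → all cross pairs, nothing within a group). Only strict
inequalities are supported; equality and about-equality constraints are not
(v1 limitation).

* **Fit** is estimated on draws from a multivariate-normal approximation to
  the cell-mean posterior: mean = EMMs, covariance = G Cov(β̂) G′. Residual
  variance uncertainty is neglected — a deliberate simplification that is
  accurate at moderate cell sizes (the worked examples use n = 50/cell); a
  t-posterior refinement is a natural extension point.
* **Complexity** is estimated on draws from an exchangeable standard normal
  over the cell means. For pure inequality constraints this reference is
  location/scale-free, so complexity depends only on constraint geometry:
  1/2 for a single inequality, 1/k! for a full ordering — properties the
  test suite checks combinatorially.
* Bayes factors vs the unconstrained hypothesis are bf = f/c (Hu: exactly
  1); PMPs normalise bf over the compared set with equal prior model
  weights, so adding Hu never changes the other hypotheses' PMP ratios.
  The complement Bayes factor is (f/c)/((1−f)/(1−c)), reported as `inf`
  with a warning when f reaches 1 at the given draw count.
* Defaults: 100,000 draws; the seed is mandatory in the CLI. Fit and
  complexity use shared draw sets across hypotheses (their MC errors are
  therefore correlated; the reported per-hypothesis SEs are binomial, and
  the PMP SEs use a delta method that treats the Bayes factors as
  independent — an approximation stated as such). A complexity estimated as
  0 raises with advice to increase draws rather than returning an infinite
  Bayes factor.

## Numerical choices and degenerate inputs

* OLS via `numpy.linalg.lstsq` with an explicit rank check; (X′X)⁻¹ is
  formed only after the full-rank check (p is small: the largest supported
  designs have a few dozen columns). Noise-free data give MSE = 0 and are
  handled: F = ∞ (p = 0) for nonzero SS, F = 0 (p = 1) otherwise.
* Empty cells with interactions requested raise a rank-deficiency error
  naming the cell; additive models remain estimable.
* Cells with n = 1 report observed SE as NaN (undefined), never 0; model
  fitting requires at least one cell with replication (df_error > 0).
* Missing values are dropped listwise with a logged count; non-numeric text
  in numeric columns is an error naming the row (silent coercion would mask
  data-entry bugs).
* Posterior draws use a Cholesky factor with a tiny trace-scaled jitter
  fallback for near-singular covariances.
* Factor level order is first appearance (or an explicit override) and only
  affects labels, never estimates; the test suite asserts invariance of
  type-III SS to relabeling and record order.

## Known limitations

* Between-subjects only; the interface has no repeated-measures escape
  hatch by design.
* The overlap rule's p ≈ 0.037 calibration holds for comparable interval
  lengths; with severely unequal SEs the mean-length denominator is a
  convention, not an exact test.
* The normal cell-mean posterior understates tail uncertainty at very small
  n (single-digit cells).
* Per-comparison false-positive frequencies treat pairs within a replicate
  as exchangeable counts; dependence between pairs of the same replicate is
  reflected in the familywise variants, not in the binomial SEs.
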