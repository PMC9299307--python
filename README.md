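# interactkit

A statistics toolkit for interpreting **interaction effects in factorial
designs**. It is written for experimentalists — the motivating setting is a
2 (group: lesion/control) × 2 (stimulus: fearful/neutral) between-subjects
study of arousal — who have obtained a significant interaction in an ANOVA
and must decide what to do next.

The common practice is to follow up with pairwise t-tests computed on the
observed cell means and errors. That practice is statistically incoherent:
each such test uses an error term disconnected from the model that produced
the interaction, and the many comparisons require multiplicity corrections
that trade false positives for false negatives. `interactkit` implements
both the criticised path and the model-based alternatives, so the difference
can be demonstrated, quantified, and used.

## What it computes

* **Type-III factorial ANOVA** under sum-to-zero (deviation) coding. For the
  model *y = Xβ + ε*, each effect's sum of squares is
  SS = RSS(model without the effect's columns) − RSS(full model), tested with
  F = (SS/df) / MSE against F(df, df_error). Sum-to-zero coding is mandatory:
  type-III hypotheses are only the intended "each effect net of all others"
  under a coding whose columns are centred over levels.
* **Estimated marginal means (EMMs)**: model predictions averaged over an
  equally weighted reference grid (covariates at their grand mean), with
  SE² = g′ Cov(β̂) g and t confidence intervals at the model's error df. In a
  balanced, covariate-free design EMMs equal the observed cell means exactly,
  but the EMM standard errors are the pooled √(MSE/n), not the per-cell
  observed SEs — the estimated *errors* always differ.
* **The CI-overlap rule**: two independent means are treated as credibly
  different when their 95% CIs overlap by less than 25% of the (mean) full
  interval length; for equal-SE means at large df this corresponds to a
  two-sided p ≈ 0.037.
* **Observed-means post-hoc pairwise t-tests** with Bonferroni, Šidák or
  Holm corrections — the classical path, kept for contrast, plus model-based
  EMM contrasts (arbitrary zero-sum contrast vectors, so planned and
  one-vs-rest comparisons are covered).
* **A false-positive-risk Monte-Carlo experiment**: data are simulated with
  purely additive true cell means (interaction null true, main-effect spacing
  δ ∈ {0, 0.1, 0.25, 0.5}, sd 1, n per cell 5–100, designs 2×2/2×3/3×3);
  whenever the interaction is nonetheless significant, both follow-up
  procedures run on all cell pairs and their per-comparison flag rates are
  recorded.
* **Bayesian informative hypotheses**: research expectations written as
  inequality constraints among cell means, e.g.
  `H1: (μ_cf − μ_cn) > (μ_lf − μ_ln)`. Each hypothesis gets a fit *f*
  (posterior probability of the constraints), a complexity *c* (probability
  under an exchangeable reference — 1/k! for a full ordering), a Bayes factor
  *f/c* against the unconstrained hypothesis Hu, and posterior model
  probabilities that sum to 1.

## Worked example

No downloads are needed: the `demo` subcommand regenerates synthetic
datasets with the worked examples' ground-truth structure.

```sh
interactkit demo example1 --seed 42 --out ex1.csv
interactkit anova --input ex1.csv --factors group,stimulus --response arousal --format csv
```

```
effect,ss,df,F,p
group,0.28126909451879,1,121.48208794726564,2.7102038300723923e-22
stimulus,0.486709367253389,1,210.21317773497617,7.576794100880739e-33
group:stimulus,0.03018137028369039,1,13.035544788328416,0.00038815029947942734
Residual,0.4538014077401581,196,,
```

Both main effects and the group × stimulus interaction are significant
(F(1, 196) = 13.04, p < 0.001 for the interaction in this draw). The EMMs
with 95% CIs describe the interaction without further testing:

```sh
interactkit emm --input ex1.csv --factors group,stimulus --response arousal --format csv
```

```
group,stimulus,emm,se,ci_low,ci_high,level,df
control,neutral,0.6289749743666375,0.0068048707626180895,0.6155548082275956,0.6423951405056795,0.95,196
control,fearful,0.7522057896368397,0.0068048707626180895,0.7387856234977977,0.7656259557758817,0.95,196
lesion,neutral,0.5785412584354424,0.0068048707626180895,0.5651210922964004,0.5919614245744843,0.95,196
lesion,fearful,0.6526344137827784,0.0068048707626180895,0.6392142476437365,0.6660545799218204,0.95,196
```

All four SEs are identical (√(MSE/50)) and every pair of intervals is well
separated: the control group sits above the lesion group for *both* stimulus
types, so the difference is not specific to fearful stimuli — a conclusion
the observed-means post-hoc path (`interactkit posthoc …`) obscures.

Competing explanations can be compared directly:

```sh
interactkit pmp --input ex1.csv --factors group,stimulus --response arousal --seed 1 --format csv \
  --hypothesis "H1: (control:fearful-control:neutral)>(lesion:fearful-lesion:neutral)" \
  --hypothesis "H2: (lesion:fearful,control:fearful)>(lesion:neutral,control:neutral)" \
  --hypothesis "H3: lesion:neutral<lesion:fearful<control:neutral<control:fearful"
```

```
hypothesis,fit,complexity,bf_u,pmp,...
H1,0.99986,0.50017,1.9990403262890617,0.2444188515482948,...
H2,0.99282,0.16523,6.008715124372088,0.7346741487232654,...
H3,0.00718,0.04199,0.17099309359371279,0.02090699972843967,...
```

H2 — "fearful stimuli raise arousal regardless of group" — wins (PMP 0.73):
although H1's interaction-shaped constraint is almost certainly true in the
posterior (fit 0.9999), it is also easy to satisfy by chance (complexity
0.5), while H2 is four constraints satisfied nearly as surely but much more
specific (complexity ≈ 1/6).

The false-positive-risk experiment runs with

```sh
interactkit simulate --design 2x2 --n 20 --delta 0 --reps 2000 --seed 1 --format csv
```

which reports the interaction's significance rate (≈ 0.05 under the additive
null) and the per-comparison flag rates of both follow-up procedures on the
retained replicates.

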