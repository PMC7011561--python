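# Methods

## The problem

Exploratory subgroup analysis of a randomised controlled trial (RCT) asks
whether the treatment effect varies systematically across patients —
treatment effect heterogeneity (TEH). Two flavours matter clinically:

* **crossover TEH** — the optimal treatment switches for some patient
  stratum ("a subgroup"): these patients would do better off the standard
  of care;
* **non-crossover TEH** — one arm is optimal everywhere but its benefit
  varies in magnitude.

Flexible ML learners are attractive discovery tools but have no countable
degrees of freedom, so classical interaction tests do not apply and naive
refitting inflates the false positive rate. This package implements two
omnibus tests that let an arbitrary learner search for heterogeneity while
keeping the type I error at a user-chosen level alpha. Both are
non-constructive by design: they report a p value for a global null, not
an estimate of the subgroup.

## Repeated splitting and cross-prediction

Each iteration draws a random partition of the trial into two halves with
treated/untreated counts balanced within arms (counts differ by at most 1
per arm and overall). A model trained on one half scores the subjects of
the other half, and vice versa, so every prediction is strictly
out-of-sample; an assertion enforces this bookkeeping on every split.

The 50/50 ratio is fixed in the headline API because the standard error of
the cross-predictions scales as 1/(sqrt(n1) + sqrt(n2)), which is minimised
at n1 = n2 = n/2. `split_ratio_experiment` reproduces this empirically
(unequal ratios are available only there). Because the RMSE gap between
ratios is on the order of 2%, the experiment uses a paired design: each
replicate draws one trial and evaluates every ratio on it, so the
comparison is not diluted by between-trial variation.

## The crossover (subgroup) test

Within a split, the individual treatment effect (ITE) for a held-out
subject is the difference in predicted event probability under forced
treatment assignments,

    ite_i = Pr(Y=1 | X_i, T=1) - Pr(Y=1 | X_i, T=0),

from a single model with T as a feature (a counterfactual toggle; this
pools information across arms). With outcome 1 an adverse event, ite < 0
predicts benefit from the experimental arm; ties (ite = 0) go to standard
of care, so a null learner never nominates anyone. The subjects predicted
to benefit form the held-out subgroup (size n_s). Randomisation guarantees
that about half of them actually received each arm, so a one-sided
two-sample test — default: Fisher exact on the 2x2 table of received arm
by event, alternative "experimental arm better" — is valid within the
subgroup. Under the global null its p value is uniform (conservative).
n_s/n averaged over splits estimates the subgroup prevalence; rarer
subgroups give smaller n_s and hence less power.

Degenerate splits (empty subgroup, subgroup inside a single received arm,
no outcome variation, or a training half that cannot support a fit) are
assigned p = 1 rather than discarded — discarding would bias the
aggregate toward small values.

## The added-benefit (stacking) test

Whether an ML model is worth its opacity is itself a testable hypothesis.
Using the same partitions, both the baseline logistic GLM and the ML model
are fitted to each half; every subject receives an out-of-sample GLM
linear predictor z_glm and an out-of-sample ML log-odds z_ml, both
evaluated at the subject's actual treatment (risk prediction, not a
counterfactual). ML probabilities are clipped to [eps, 1-eps], eps = 0.001
by default, before the log-odds transform since forests can emit exact 0/1.
A second-stage logistic regression of Y on (z_glm, z_ml) over the full
trial then tests theta_ml = 0 with a 1-df likelihood-ratio (deviance
ANOVA) test.

Numerical choices:

* an **intercept** is included in the stacked model by default.
  Out-of-sample predictors can be miscalibrated in level, and forcing the
  fit through the origin can manufacture spurious significance; the
  intercept-free variant is available via `include_intercept=False`.
* **separation**: if the unpenalised fit diverges (detected as non-finite
  or >1e3 coefficients — stacked covariates live on the log-odds scale,
  so genuine coefficients are O(1)), both nested models are refitted with
  an identical small ridge penalty (1e-3) and the penalised LRT is
  reported with a flag. Identical penalties keep the statistic
  conservative.
* exact collinearity of z_ml with the null design short-circuits to
  LRT = 0, p = 1 (no added information).

## Aggregating K dependent p values

The K split p values are individually valid but dependent. With
Q_gamma({p_i}) = min(1, Quantile_gamma({p_i / gamma})), two merging rules
give a single valid p value:

* **fixed gamma** (prespecified): p_agg = Q_gamma; gamma = 0.5 gives
  min(1, median of the doubled p values);
* **adaptive**: p_agg = min over gamma in [alpha, 1] of
  min(1, (1 - ln alpha) * Q_gamma), where (1 - ln alpha) pays for the
  search.

Quantile convention: inverse ECDF (smallest order statistic whose ECDF
reaches gamma); conventions differ materially at small K, so this is fixed
and documented. The gamma minimisation is exact, not gridded: Q_gamma is
piecewise in gamma with breakpoints at j/K and decreasing within each
piece, so scanning j = ceil(alpha K)..K attains the continuum minimum.

The adaptive rejection event has a geometric reading used by the ECDF
diagnostic: p_agg <= alpha iff the empirical CDF of the p values touches
or crosses above the segment {(gamma alpha/(1 - ln alpha), gamma)}. This
equivalence is a tested property.

K should be large enough that p_agg stabilises (default K = 1000;
stabilisation is typically visible by K ≈ 200 and is checked with the
traceplot, which recomputes the aggregate on each prefix of the p-value
sequence).

Seeding: one master seed; split k uses seed master_seed + k, recorded in
every result and report.

The two tests are distinct prespecified analyses and are reported
separately without a cross-test multiplicity correction. Post-hoc
exploratory numbers computed after a rejection (e.g. ITE scatter plots)
carry no formal error control and should be labelled qualitative.

## The synthetic generator

`generate_trial` draws d independent N(0,1) covariates, a fair-coin
treatment independent of X, and a Bernoulli outcome with

    logit Pr(Y=1) = b0 + X·beta + T·treat_main
                    + T·1[x1 > z_{1-prev}]·teh_magnitude.

The step interaction in the first covariate is the simplest structure
realising both crossover (treat_main and treat_main + teh_magnitude of
opposite signs) and non-crossover TEH; a `smooth_crossover` preset
replaces the step with a cubic smoothstep ramp for a graded effect. The
intercept b0 is calibrated by 64-node Gauss–Hermite quadrature so the
standard-of-care arm has a target event rate (default 0.2, a typical
severe-disease mortality scale). Defaults: n = 500, d = 5, beta =
(0.5, -0.5, 0.3, 0.3, 0), prevalence 0.3, crossover preset treat_main =
+0.5 with interaction -2.0 (net -1.5 inside the subgroup). Ground truth
(per-subject true ITE, subgroup membership) is returned with every draw.

What the generator does *not* emulate: correlated or skewed covariates,
measurement error, missing data (the pipeline requires complete cases and
fails loudly), non-compliance, clustered recruitment, or survival
endpoints. Passing tests therefore demonstrate the procedure's validity
and power under clean, independently recruited data — the same assumption
the testing theory itself makes — not robustness to real-data pathologies.

## Problem sizes used by the test suite and acceptance script

Monte-Carlo studies run at desk scale, chosen as the smallest sizes at
which the checks are meaningful: type I error of the full pipelines at
n = 300, K = 20 splits, 50 replicates (100-tree forests); power at
n = 1000, K = 15, 25 replicates, effect magnitudes -2.0 and -3.5;
split-ratio experiment at n = 400 with 30 paired replicates (80 in the
reproduction script, where the argmin over ratios is reported and needs
the extra precision). Rejection-rate
bounds always use the binomial 3-standard-error band at the replicate
count actually run. Aggregation-level checks (closed forms, validity on
iid uniforms, boundary equivalence) run at K = 1000 with hundreds of
replicates since they are cheap.

## Known limitations

* Binary outcomes only; survival endpoints and continuous scores are out
  of scope (the test-statistic registry accepts user statistics with the
  same 2x2 contract, but the data model enforces Y in {0,1}).
* Two-arm parallel designs with independent recruitment only; paired or
  cluster-randomised designs would need a different splitting scheme.
* The tests are omnibus: a rejection says a benefitting subgroup (or
  added predictive signal) exists, not where it is or how large the
  effect is; confidence intervals for subgroup effects are deliberately
  not produced.
* Power falls with subgroup prevalence and with the number of irrelevant
  covariates fed to the learner ("no free power"): judicious prespecified
  covariate selection matters.
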