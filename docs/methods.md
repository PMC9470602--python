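# Methods

## Model

`multitraj` implements a finite-mixture ("group-based") multi-trajectory
model. A cohort of *n* subjects is measured on *K* bounded symptom
composites at *T* shared assessment ages. Latent group membership is
multinomial with logits `θ` (first logit anchored at 0). Conditional on
group *j*, phenotype *k* follows a polynomial mean trajectory in centered
age `c = age − 11` with residual SD `σ_k` shared across groups (the
standard identification choice for this model family; per-group SDs are
available via `sigma_shared=False`). Ages are used on their natural scale,
so the unequal final gap (13 → 15) is handled without assumptions about
wave spacing. Centering at 11 keeps the design matrix well conditioned
over ages 7–15 and makes intercepts interpretable as mid-trajectory
levels.

**Emission.** Sum-scores have hard floors and ceilings and empirical
minima typically sit exactly at the floor, so the emission is a censored
(tobit) normal on the scale bounds: interior scores get the normal
density, boundary scores the corresponding tail mass. Setting bounds to
±∞ recovers the plain normal exactly (unit-tested to 1e-12), so an
uncensored analysis is a configuration, not a separate code path.

**Distal outcomes.** Outcomes measured after the trajectory window enter
the same likelihood with group-specific means and a shared-across-groups
SD per outcome, and are maximised *jointly* with the trajectory
parameters (one-step estimation). The joint fit is warm-started from the
trajectory-only fit, with outcome means initialised at posterior-weighted
group means; the maximised joint log-likelihood is therefore never below
the joint likelihood of the warm start (asserted on every fit). Outcome
missingness is treated as ignorable given group: only observed outcomes
contribute. Heavily skewed outcomes (e.g. count-like violence scores) are
still modelled as normal to match the reporting convention of group means
with SEs; a `log1p`-style lognormal generator option exists for
robustness experiments but is off by default.

## Estimation

EM with log-sum-exp stabilised E-steps. M-steps:

* membership logits — closed form from mean responsibilities;
* trajectory coefficients — responsibility-weighted censored-normal
  polynomial regression per group × phenotype, maximised by L-BFGS with
  analytic gradients, warm-started at the current value and reverted if
  the inner optimiser fails to improve (so EM is monotone by
  construction; monotonicity is asserted at 1e-8 throughout the suite);
* residual SDs — one-dimensional L-BFGS on `log σ` given all coefficients
  (an ECM scheme);
* outcome means/SDs — exact closed forms.

Convergence is declared when the log-likelihood changes by less than
`tol` (default 1e-6); the iteration cap is 500 by default. If a group's
expected share falls below 1/n, the fit restarts from a fresh random
partition (counted and reported on the model object).

**Starts.** Initialisation uses one quantile-stratified start (subjects
ranked by overall standardised severity), several k-means starts on
standardised phenotype-wave profiles, and random partitions, each run for
a short EM burst (`short_iter`, default 15) with the best continued to
convergence. K-means starts are what make the six-group fit reliable;
random partitions alone occasionally select a basin in which two
similarly shaped groups exchange members for hundreds of iterations.
Default `n_starts=8` (half k-means); the simulation studies in the test
suite pass `n_starts=6` for the six-group design and fewer for the
well-separated small designs.

**Standard errors.** SEs for the group outcome means come from the
inverse empirical observed-information matrix — the outer product of
per-subject analytic score vectors of the full joint likelihood
(membership logits, trajectory coefficients, log residual SDs, outcome
means, log outcome SDs) evaluated at the MLE. A singular information
matrix (e.g. an empty group) flags SEs unavailable rather than failing.

**Model selection.** BIC = −2 logL + k log n, minimised. (The equivalent
maximise-2·(logL − ½·k·log n) convention orders models identically.) The
selection table also reports each candidate's smallest group share and
flags models with groups below a configurable share threshold (default
5%) — the "practical consideration" that small groups undermine
downstream group comparisons.

**Label alignment.** Mixture labels are arbitrary, so fits are aligned
across imputations (and to the generating configuration in synthetic
runs) by minimising the summed squared distance between model-predicted
trajectory curves over all phenotypes and ages. The objective decomposes
over matched pairs, so the exact optimum over all J! permutations is
obtained by linear assignment (verified in tests against exhaustive
enumeration). The alignment report carries per-group maximum curve
discrepancies as the "same groups across imputations" audit.

## Missing data

**Imputation** is fully conditional specification (chained equations) on
wave-level composites plus outcome scores — one column per
phenotype × age and per outcome. Continuous variables use predictive mean
matching: Bayesian-draw linear regression on all other variables
(type-1 matching: observed predictions from the posterior mean, missing
predictions from a posterior draw), with each missing cell receiving the
observed value of one of `k_donors = 5` nearest-prediction donors chosen
uniformly. PMM guarantees imputations stay in the observed support —
important for bounded scores. Nominal variables use a multinomial-logit
draw. Defaults: `M = 3` datasets, `n_iter = 10` sweeps, independent
streams spawned from one master seed. Perfectly collinear predictors fall
back to a ridge-penalised solve with a warning.

**Pooling** follows the standard combining rules: pooled estimate `q̄`,
total variance `T = Ū + (1 + 1/M)·B` with `B` the between-imputation
sample variance (denominator M−1). Intervals use the normal quantile
`z₀.₉₇₅ = 1.959964` rather than a small-M t quantile: this reproduces the
reported worked-example interval rows exactly at printed precision (a few
rows deviate by ±0.01, consistent with rounding of the printed means/SEs,
which is the tolerance the worked-example tests use). Group proportions
are pooled on the probability (softmax) scale. Pairwise comparisons use
the CI-overlap screen: strictly disjoint 95% intervals count as
significant, shared endpoints as overlap, no multiplicity correction.
Non-overlap is a conservative screen (per-pair type-I error well below
5%); the null-calibration test asserts the per-pair flag rate stays
below 0.05.

## Synthetic cohort generator

The generator emulates the study design the analysis assumes: n = 1620
subjects; ages 7, 8, 9, 10, 11, 12, 13, 15; three bounded composites
(ADHD 7–35, internalising 7–35, externalising 17–85); six latent groups
with shares (0.325, 0.279, 0.106, 0.135, 0.120, 0.034) — the printed
shares renormalised to sum to one; twelve age-20 outcomes whose
group-specific generating means follow the reported group-mean profiles
with marginal descriptive SDs as residual SDs and observed fractions
matching the reported outcome Ns.

Latent scores are polynomial means plus normal noise, *clamped* to the
scale bounds — exactly the floor/ceiling mechanism the censored-normal
emission models. The default trajectory coefficient sets are **synthetic
package defaults**, chosen once to reproduce the qualitative group
profiles (flat-low; mild and maturing out; stably elevated internalising
only; multimorbid late onset; multimorbid remitting; multimorbid with
rapidly remitting externalising but persistent ADHD/internalising), with
residual SDs (4.0, 3.5, 5.0) giving Table-like marginal spreads. They are
not estimates from any dataset and should not be read as such.

**Missingness** deletes whole phenotype-wave observations with
probability `logistic(α_kt + γ·z_prev)` where `z_prev` is the subject's
most recent still-observed earlier-wave score of the same phenotype
(standardised; 0 if none) — a MAR mechanism by construction, since the
probability uses only values that remain observed. The intercepts are
calibrated by root-finding so the marginal per-wave deletion rates hit
the per-wave targets implied by the reported observed counts
(`1 − N_kt/1620`, e.g. ≈0.41 for externalising at age 12). The default
dependence strength γ = 0.3 makes attrition mildly symptom-related
without dominating the marginal calibration. Default missingness is
intermittent; a monotone-dropout mode (once missing, always missing;
requires non-decreasing targets) is available because the real attrition
pattern is unknown. Outcome missingness is completely at random at the
configured observed fractions.

**What the generator does not emulate:** item-level responses (the
pipeline models composites; imputation therefore operates at composite
level, whereas an item-level imputation model would use more
information), auxiliary covariates in the imputation model, outcome skew
(outcomes are generated normal by default), and any dependence of
missingness on unobserved values. Passing tests therefore demonstrate
correctness of the estimation machinery under the model's own
assumptions — not robustness to item-level measurement error, MNAR
attrition or heavy outcome skew.

## Problem sizes used in the test suite and acceptance script

Simulation studies are sized to be decisive yet desk-scale, as the
package's own choice of experiment size:

* six-group recovery: 20 replicates at the full design size (n = 1620,
  MAR on), `n_starts=6`, `tol=1e-5`, iteration cap 200;
* BIC selection: 20 replicates each for the one- and three-group
  single-phenotype designs (n = 600);
* end-to-end pooled-CI calibration: 20 replicates at n = 400 with four
  outcomes, M = 3, five chained-equation sweeps;
* the acceptance script repeats these with 5–10 replicates per study and
  reports the replicate counts in its output (`"n"` fields).

## Known limitations

* All subjects share one assessment-age grid; per-subject age jitter is
  not modelled.
* No within-group random effects (this is the classic "group-based"
  approximation, not a growth mixture model), no covariates on group
  membership, no classification-error-corrected three-step estimators.
* The outcome-mean SEs use the OPG information estimator; for very small
  groups these can be optimistic relative to a full Hessian.
* The CI-overlap screen is conservative; it is reproduced because it is
  the reporting convention being modelled, not because it is the most
  powerful comparison.
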