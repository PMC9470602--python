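# multitraj

Group-based **multi-trajectory modelling** of bounded mental-health symptom
scales across childhood and adolescence, with **distal (young-adult)
outcomes** estimated jointly in one step, **chained-equation multiple
imputation** of missing data, and **Rubin's-rules pooling** with a
CI-overlap significance screen.

The package is aimed at developmental/psychiatric epidemiologists who work
with longitudinal cohort panels of symptom sum-scores (e.g. teacher-rated
ADHD, internalising and externalising composites measured yearly) and want
to (a) summarise heterogeneity in joint symptom development as a small
number of latent trajectory groups, and (b) compare those groups on
outcomes measured after the trajectory window, under realistic
missing-at-random attrition.

## Model

Each subject *i* belongs to one of *J* latent groups with probabilities
`π_j = softmax(θ)`. Within group *j*, phenotype *k* at age *t* follows a
polynomial mean trajectory on centered age (`c = age − 11`):

```
y*_ikt = β_jk0 + β_jk1·c + β_jk2·c² + ε,   ε ~ N(0, σ_k²)
```

Observed sum-scores are bounded, so the emission is a **censored (tobit)
normal** on the scale bounds `[S_min, S_max]`: interior values get the
normal density, values at the floor/ceiling get the corresponding tail
mass. The subject likelihood mixes over groups:

```
L_i = Σ_j π_j · Π_{k,t observed} f_cens(y_ikt | x_t'β_jk, σ_k)
```

Distal outcomes `z_io` enter the same likelihood with group-specific means
`m_jo` and outcome SDs `s_o` (one-step joint estimation, warm-started from
the trajectory-only fit so the groups do not move when outcomes are added —
checked by `trajectory_stability_check`). Fitting is by EM with
responsibility-weighted censored-normal regression M-steps; model choice
uses BIC (`−2·logL + k·log n`, minimised) plus a small-group flag.

With missing data, the analysis runs per imputed dataset (chained equations
with predictive mean matching, `M = 3` by default), group labels are
aligned across imputations by trajectory-curve matching, and each group
mean is pooled as `T = Ū + (1 + 1/M)·B` with 95% CIs `q̄ ± 1.959964·√T`.
Non-overlapping CIs are read as significant group differences (no
multiplicity correction).

## Worked example

```python
import multitraj as mt

# the default six-group cohort design: n=1620, ages 7..13 and 15, three
# bounded phenotypes, calibrated per-wave MAR missingness, 12 outcomes
cfg = mt.default_cohort_config()
panel, outcomes, truth = mt.generate_cohort(cfg, seed=1)
damaged = mt.apply_mar_missingness(panel, cfg, seed=2)

model = mt.fit_multitrajectory(damaged, J=6, n_starts=6, seed=7)
print(round(model.loglik, 1), [float(round(p, 3)) for p in model.pi])
```

```
-77760.7 [0.032, 0.102, 0.32, 0.124, 0.138, 0.283]
```

The fitted group shares (order arbitrary) recover the generating shares
(0.325, 0.279, 0.106, 0.135, 0.120, 0.034) to within about one percentage
point; posterior modal assignment agrees with the true group for 97.8% of
subjects here. CI arithmetic and the overlap screen work directly on pooled
summaries:

```python
lo, hi = mt.ci_from_pooled(12.43, 0.41)      # -> (11.63, 13.23)
sig = mt.compare_groups_ci([(9.44, 10.45), (11.63, 13.23)])
print((round(lo, 2), round(hi, 2)), bool(sig[0, 1]))
```

```
(11.63, 13.23) True
```

i.e. a group with pooled mean 12.43 (SE 0.41) is declared significantly
different from one whose interval ends at 10.45.

The full pipeline (simulate → impute → fit → joint distal fit → align →
pool → report) runs from the shell:

```bash
multitraj run --seed 1 --out-dir results/run1
```

writing `pooled_outcomes.csv` (outcome × group: mean, SE, CI),
`significance.csv` (pairwise CI-overlap decisions),
`predicted_trajectories.csv` (group × phenotype × age) and a reproducible
`manifest.json`.

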