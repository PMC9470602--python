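"""End-to-end pipeline driver.

Stage order mirrors the analysis design: simulate a cohort → apply MAR
damage → chained-equation imputation (M datasets) → multi-trajectory fit per
imputation (all warm started from the same trajectory-only fit) → one-step
joint distal fit per imputation → cross-imputation label alignment → Rubin
pooling → report tables. All randomness flows from one master seed; every
artifact written is recorded (with digest) in the run manifest.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import CohortConfig
from .distal import fit_joint, trajectory_stability_check
from .impute import chained_impute
from .io import (RunManifest, save_joint_model, save_model, write_outcomes,
                 write_panel, write_truth)
from .mixture import fit_multitrajectory, posterior_assignments
from .panel import PanelData
from .pooling import (align_group_labels, pool_group_proportions,
                      pool_outcome_table, significance_table)
from .simulate import apply_mar_missingness, generate_cohort


@dataclass
class AnalysisConfig:
    """Analysis-stage settings (model fitting, imputation, pooling)."""

    J: int | None = None          # trajectory groups; default = generating J
    order: int = 2                # polynomial order on centered age
    M: int = 3                    # imputations
    n_iter: int = 10              # chained-equation sweeps
    k_donors: int = 5             # PMM donor pool
    n_starts: int = 4             # random EM starts for the initial fit
    tol: float = 1e-6
    max_iter: int = 300
    ci_level: float = 0.95
    stability_tol: float = 1.0    # score units

    @classmethod
    def from_dict(cls, d: dict | None) -> "AnalysisConfig":
        return cls(**(d or {}))


def panel_to_wide(panel: PanelData) -> pd.DataFrame:
    """One row per subject, one column per phenotype-age composite."""
    n, K, T = panel.scores.shape
    cols = {f"{s.name}_{age:g}": panel.scores[:, k, t]
            for k, s in enumerate(panel.scales)
            for t, age in enumerate(panel.ages)}
    return pd.DataFrame(cols, index=pd.Index(panel.subject_ids, name="subject_id"))


def wide_to_panel(df: pd.DataFrame, template: PanelData) -> PanelData:
    scores = np.empty_like(template.scores)
    for k, s in enumerate(template.scales):
        for t, age in enumerate(template.ages):
            scores[:, k, t] = df[f"{s.name}_{age:g}"].to_numpy(dtype=float)
    return PanelData(template.subject_ids.copy(), template.ages.copy(),
                     list(template.scales), scores)


def _spawn_seeds(master_seed: int, names) -> dict:
    ss = np.random.SeedSequence(master_seed)
    return {name: int(child.generate_state(1)[0] % (2 ** 31))
            for name, child in zip(names, ss.spawn(len(names)))}


def run_pipeline(config: CohortConfig, seed: int, out_dir,
                 analysis: AnalysisConfig | None = None) -> RunManifest:
    """Run the full synthetic-cohort analysis and write all stage outputs.

    Returns the manifest. Outputs under ``out_dir``: the damaged panel,
    outcomes and truth tables, fitted models per imputation, the pooled
    outcome table (mean/SE/CI per outcome x group), the pairwise
    CI-overlap significance table, and predicted-trajectory tables.
    """
    analysis = analysis or AnalysisConfig()
    if analysis.M < 2:
        raise ValueError("M must be >= 2 (Rubin pooling is undefined for M=1)")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    J = analysis.J or config.n_groups
    seeds = _spawn_seeds(seed, ["simulate", "mar", "impute", "fit"])
    manifest = RunManifest(config=config.to_dict(), master_seed=seed,
                           stage_seeds=seeds, package_version=__version__)
    timings = {}

    def stage(name):
        timings[name] = time.perf_counter()

    def done(name):
        timings[name] = round(time.perf_counter() - timings[name], 3)

    # --- simulate -------------------------------------------------------
    stage("simulate")
    panel, outcomes, truth = generate_cohort(config, seeds["simulate"])
    damaged = apply_mar_missingness(panel, config, seeds["mar"])
    write_panel(damaged, out_dir / "panel.csv")
    write_outcomes(outcomes, out_dir / "outcomes.csv")
    write_truth(truth.labels, panel.subject_ids, out_dir / "truth.csv")
    config.to_yaml(out_dir / "config.yaml")
    done("simulate")

    # --- impute ---------------------------------------------------------
    stage("impute")
    wide = panel_to_wide(damaged).join(outcomes)
    imps = chained_impute(wide, M=analysis.M, n_iter=analysis.n_iter,
                          k_donors=analysis.k_donors, seed=seeds["impute"])
    panel_cols = panel_to_wide(damaged).columns
    outcome_cols = list(outcomes.columns)
    panels = [wide_to_panel(d[panel_cols], damaged) for d in imps]
    outcome_sets = [d[outcome_cols] for d in imps]
    done("impute")

    # --- fit trajectories (shared start values) -------------------------
    stage("fit")
    start = fit_multitrajectory(panels[0], J, order=analysis.order,
                                n_starts=analysis.n_starts, seed=seeds["fit"],
                                tol=analysis.tol, max_iter=analysis.max_iter)
    traj_models = [fit_multitrajectory(p, J, order=analysis.order, init=start,
                                       tol=analysis.tol,
                                       max_iter=analysis.max_iter)
                   for p in panels]
    for m, model in enumerate(traj_models):
        save_model(model, out_dir / f"trajectory_model_imp{m + 1}.json")
    done("fit")

    # --- joint distal fit ----------------------------------------------
    stage("fit_distal")
    joint_models = []
    stability = []
    for m, (p, z, tm) in enumerate(zip(panels, outcome_sets, traj_models)):
        jm = fit_joint(p, z, J, start=tm, tol=analysis.tol,
                       max_iter=analysis.max_iter)
        joint_models.append(jm)
        rep = trajectory_stability_check(tm, jm, tol=analysis.stability_tol)
        stability.append({"imputation": m + 1,
                          "max_abs_diff": rep.max_abs_diff,
                          "passed": rep.passed})
        save_joint_model(jm, out_dir / f"joint_model_imp{m + 1}.json")
    pd.DataFrame(stability).to_csv(out_dir / "stability_check.csv", index=False)
    done("fit_distal")

    # --- align + pool + report ------------------------------------------
    stage("pool")
    align_rep = align_group_labels(joint_models, reference=0)
    aligned = [m.relabelled(p) for m, p in
               zip(joint_models, align_rep.permutations)]
    if J == config.n_groups:
        # name fitted groups by matching their curves to the configured shapes
        from .mixture import design_matrix
        from .pooling import _curve_permutation
        mu_truth = np.stack([g.coeffs @ design_matrix(
            config.ages, g.coeffs.shape[1] - 1).T for g in config.groups])
        perm = _curve_permutation(mu_truth, aligned[0].base.predicted_means(config.ages))
        aligned = [m.relabelled(perm) for m in aligned]
        group_names = [g.name for g in config.groups]
    else:
        group_names = [f"group_{j + 1}" for j in range(J)]
    pooled = pool_outcome_table(aligned, group_names=group_names,
                                level=analysis.ci_level, align=False)
    pooled.to_csv(out_dir / "pooled_outcomes.csv", index=False)
    sig = significance_table(pooled)
    sig.to_csv(out_dir / "significance.csv", index=False)
    props = pool_group_proportions(aligned, align=False)
    pd.DataFrame({"group": group_names, "share": props}).to_csv(
        out_dir / "pooled_group_shares.csv", index=False)

    # predicted-trajectory table per group x phenotype x age (reference fit)
    ref = aligned[0].base
    mu = ref.predicted_means()
    rows = []
    for j in range(J):
        for k, s in enumerate(ref.scales):
            for t, age in enumerate(ref.ages):
                rows.append({"group": group_names[j], "phenotype": s.name,
                             "age": age, "predicted_mean": mu[j, k, t]})
    pd.DataFrame(rows).to_csv(out_dir / "predicted_trajectories.csv", index=False)

    assign = posterior_assignments(panels[0], aligned[0].base)
    pd.DataFrame({"group": group_names, "app": assign.app,
                  "modal_count": assign.group_counts}).to_csv(
        out_dir / "assignment_diagnostics.csv", index=False)
    done("pool")

    for f in sorted(out_dir.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest.record_artifact(out_dir, f)
    manifest.timings = timings
    manifest.to_json(out_dir / "manifest.json")
    return manifest
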