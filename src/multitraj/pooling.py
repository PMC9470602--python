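"""Rubin's-rules pooling, confidence intervals, CI-overlap comparison and
cross-imputation group-label alignment.

Pooling combines M per-imputation estimates ``q_m`` with squared standard
errors ``u_m`` into ``qbar = mean(q_m)`` with total variance
``T = ubar + (1 + 1/M) * B`` where ``ubar = mean(u_m)`` and ``B`` is the
between-imputation sample variance. 95% intervals use the normal quantile
z = 1.959964. Non-overlapping intervals are read as a significant group
difference; a shared endpoint counts as overlap, and no multiplicity
correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import norm


@dataclass
class PooledEstimate:
    """A parameter pooled across imputations by Rubin's rules."""

    qbar: float    # pooled point estimate
    ubar: float    # mean within-imputation variance
    b: float       # between-imputation variance (ddof=1)
    t_var: float   # total variance ubar + (1 + 1/M) * b
    se: float
    ci_lo: float
    ci_hi: float
    m: int


def pool_rubin(estimates, variances, level: float = 0.95) -> PooledEstimate:
    """Pool one parameter's per-imputation estimates and squared SEs."""
    q = np.asarray(estimates, dtype=float)
    u = np.asarray(variances, dtype=float)
    if q.shape != u.shape or q.ndim != 1:
        raise ValueError("estimates and variances must be 1-D and equal length")
    m = len(q)
    if m < 2:
        raise ValueError("Rubin pooling requires M >= 2 imputations")
    if np.any(u < 0):
        raise ValueError("variances must be non-negative")
    qbar = float(q.mean())
    ubar = float(u.mean())
    b = float(q.var(ddof=1))
    t_var = ubar + (1.0 + 1.0 / m) * b
    se = float(np.sqrt(t_var))
    lo, hi = ci_from_pooled(qbar, se, level)
    return PooledEstimate(qbar=qbar, ubar=ubar, b=b, t_var=t_var, se=se,
                          ci_lo=lo, ci_hi=hi, m=m)


def ci_from_pooled(qbar: float, se: float, level: float = 0.95) -> tuple[float, float]:
    """Normal-quantile interval ``qbar +/- z * se`` (z = 1.959964 at 95%)."""
    if not 0 < level < 1:
        raise ValueError("level must be in (0, 1)")
    if se < 0:
        raise ValueError("se must be non-negative")
    z = norm.ppf(0.5 * (1.0 + level))
    return float(qbar - z * se), float(qbar + z * se)


def compare_groups_ci(intervals) -> np.ndarray:
    """Pairwise CI-overlap significance screen.

    ``intervals`` is a sequence of (lo, hi) per group. Pair (a, b) is
    declared significant iff the intervals are disjoint with strict
    inequality — a shared endpoint counts as overlap. Returns a symmetric
    boolean matrix with a False diagonal.
    """
    iv = np.asarray(intervals, dtype=float)
    if iv.ndim != 2 or iv.shape[1] != 2:
        raise ValueError("intervals must be (G, 2)")
    if np.any(iv[:, 0] > iv[:, 1]):
        raise ValueError("interval lower bound exceeds upper bound")
    lo, hi = iv[:, 0], iv[:, 1]
    sig = (hi[:, None] < lo[None, :]) | (hi[None, :] < lo[:, None])
    np.fill_diagonal(sig, False)
    return sig


# ---------------------------------------------------------------------------
# Label alignment across imputations
# ---------------------------------------------------------------------------

def _curve_permutation(mu_ref: np.ndarray, mu_other: np.ndarray) -> np.ndarray:
    """Permutation ``perm`` minimising ``sum_j ||mu_ref[j] - mu_other[perm[j]]||^2``.

    The summed-squared-curve-distance objective decomposes over matched
    pairs, so the exact optimum over all J! permutations is the solution of
    a linear assignment problem.
    """
    J = mu_ref.shape[0]
    cost = np.empty((J, J))
    for a in range(J):
        cost[a] = ((mu_ref[a][None] - mu_other) ** 2).sum(axis=(1, 2))
    _, col = linear_sum_assignment(cost)
    return col


@dataclass
class AlignmentReport:
    """Label permutations and post-alignment curve discrepancies."""

    permutations: list[np.ndarray]    # one per model; identity for reference
    group_discrepancy: np.ndarray     # (n_models, J) max |curve diff| per group
    reference: int

    @property
    def max_discrepancy(self) -> float:
        return float(np.nanmax(self.group_discrepancy))


def align_group_labels(models, reference: int = 0) -> AlignmentReport:
    """Match group labels across fitted models by trajectory-curve distance.

    Each model's groups are matched to the reference model's by minimising
    the summed squared distance between model-predicted trajectory curves
    (all phenotypes, all ages). The report also carries each group's maximum
    post-alignment curve discrepancy — the "same groups across imputations"
    audit.
    """
    bases = [m.base if hasattr(m, "base") else m for m in models]
    J = bases[reference].n_groups
    if any(b.n_groups != J for b in bases):
        raise ValueError("models have differing group counts")
    ages = bases[reference].ages
    mu_ref = bases[reference].predicted_means()
    perms, disc = [], []
    for b in bases:
        mu = b.predicted_means(ages)
        perm = _curve_permutation(mu_ref, mu)
        perms.append(perm)
        disc.append(np.abs(mu_ref - mu[perm]).max(axis=(1, 2)))
    return AlignmentReport(permutations=perms,
                           group_discrepancy=np.array(disc),
                           reference=reference)


# ---------------------------------------------------------------------------
# Pooled reporting
# ---------------------------------------------------------------------------

def pool_outcome_table(joint_models, group_names=None, level: float = 0.95,
                       align: bool = True) -> pd.DataFrame:
    """Pool group outcome means across per-imputation joint fits.

    Returns a long table with one row per outcome x group: pooled mean, SE
    (between-imputation-variance adjusted) and CI bounds. Models are label-
    aligned to the first before pooling unless ``align=False``.
    """
    if len(joint_models) < 2:
        raise ValueError("pooling requires M >= 2 fitted models")
    models = list(joint_models)
    if align:
        rep = align_group_labels(models, reference=0)
        models = [m.relabelled(p) for m, p in zip(models, rep.permutations)]
    names = models[0].outcome_names
    J = models[0].n_groups
    if group_names is None:
        group_names = [f"group_{j + 1}" for j in range(J)]
    rows = []
    for o, oname in enumerate(names):
        for j in range(J):
            est = [m.outcome_means[j, o] for m in models]
            var = [m.outcome_se[j, o] ** 2 if m.outcome_se is not None else np.nan
                   for m in models]
            pe = pool_rubin(est, var, level=level)
            rows.append({"outcome": oname, "group": group_names[j],
                         "mean": pe.qbar, "se": pe.se,
                         "ci_lo": pe.ci_lo, "ci_hi": pe.ci_hi,
                         "ubar": pe.ubar, "b": pe.b})
    return pd.DataFrame(rows)


def significance_table(pooled: pd.DataFrame) -> pd.DataFrame:
    """Pairwise CI-overlap decisions per outcome, long format."""
    rows = []
    for oname, sub in pooled.groupby("outcome", sort=False):
        sub = sub.reset_index(drop=True)
        sig = compare_groups_ci(sub[["ci_lo", "ci_hi"]].to_numpy())
        G = len(sub)
        for a in range(G):
            for b in range(a + 1, G):
                rows.append({"outcome": oname,
                             "group_a": sub.loc[a, "group"],
                             "group_b": sub.loc[b, "group"],
                             "significant": bool(sig[a, b])})
    return pd.DataFrame(rows)


def pool_group_proportions(models, align: bool = True) -> np.ndarray:
    """Pooled group shares: softmax outputs averaged across aligned fits."""
    ms = list(models)
    if align:
        rep = align_group_labels(ms, reference=0)
        ms = [m.relabelled(p) for m, p in zip(ms, rep.permutations)]
    bases = [m.base if hasattr(m, "base") else m for m in ms]
    return np.mean([b.pi for b in bases], axis=0)
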