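"""One-step joint estimation of trajectory groups and distal outcome means.

The joint model appends, to each latent group's likelihood contribution, a
normal density for every observed distal outcome with a group-specific mean
and an outcome-specific SD (shared across groups by default). Trajectory
parameters and outcome means are maximised together in a single EM, warm
started from a trajectory-only fit so the groups that emerge with outcomes
attached are the groups established without them — a property checked
explicitly by :func:`trajectory_stability_check`.

Standard errors of the group outcome means come from the inverse of the
empirical observed-information matrix (outer product of per-subject analytic
scores of the full joint likelihood at the MLE).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .censnorm import _loglik_and_grads
from .mixture import (MultiTrajModel, _e_step, _emission_matrix, _m_step,
                      _sig_jk, _GroupCollapse, design_matrix)
from .panel import PanelData

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


@dataclass
class JointModel:
    """Trajectory mixture extended with per-group distal-outcome means."""

    base: MultiTrajModel
    outcome_names: list[str]
    outcome_means: np.ndarray        # (J, O)
    outcome_sd: np.ndarray           # (O,) shared across groups
    outcome_se: np.ndarray | None = None   # (J, O), NaN where unavailable
    se_available: bool = True
    loglik: float = np.nan
    loglik_start: float = np.nan     # joint loglik evaluated at the warm start
    loglik_trace: list = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return self.base.n_groups

    @property
    def n_outcomes(self) -> int:
        return len(self.outcome_names)

    def relabelled(self, perm) -> "JointModel":
        perm = np.asarray(perm)
        return JointModel(
            base=self.base.relabelled(perm), outcome_names=list(self.outcome_names),
            outcome_means=self.outcome_means[perm], outcome_sd=self.outcome_sd.copy(),
            outcome_se=None if self.outcome_se is None else self.outcome_se[perm],
            se_available=self.se_available, loglik=self.loglik,
            loglik_start=self.loglik_start, loglik_trace=list(self.loglik_trace))


def _align_outcomes(panel: PanelData, outcomes: pd.DataFrame) -> np.ndarray:
    """Outcome matrix (n, O) aligned to the panel's subject order."""
    Z = outcomes.reindex(panel.subject_ids)
    return Z.to_numpy(dtype=float)


def _outcome_ll_matrix(Z, means, sd):
    """Per-subject per-group outcome log-likelihood, (n, J); missing skip."""
    obs = np.isfinite(Z)
    resid = (Z[:, None, :] - means[None]) / sd[None, None, :]
    ll = -np.log(sd)[None, None, :] - 0.5 * resid ** 2 - _LOG_SQRT_2PI
    return np.where(obs[:, None, :], ll, 0.0).sum(axis=2)


def joint_subject_loglik(panel: PanelData, outcomes: pd.DataFrame,
                         model: JointModel) -> np.ndarray:
    """Per-subject joint log-likelihood, (n,): trajectory terms plus normal
    terms for each observed outcome, mixed over groups."""
    panel.require_nonempty_subjects()
    base = model.base
    lo, hi = base.bounds()
    L = _emission_matrix(panel.scores, base.predicted_means(),
                         base.sigma_jk(), lo, hi)
    Z = _align_outcomes(panel, outcomes)
    L = L + _outcome_ll_matrix(Z, model.outcome_means, model.outcome_sd)
    return logsumexp(np.log(base.pi)[None, :] + L, axis=1)


def joint_posteriors(panel: PanelData, outcomes: pd.DataFrame | None,
                     model: JointModel) -> np.ndarray:
    """Posterior group probabilities; with ``outcomes=None`` the outcome
    information is removed and the result equals the trajectory-only
    posterior."""
    base = model.base
    lo, hi = base.bounds()
    L = _emission_matrix(panel.scores, base.predicted_means(),
                         base.sigma_jk(), lo, hi)
    if outcomes is not None:
        Z = _align_outcomes(panel, outcomes)
        L = L + _outcome_ll_matrix(Z, model.outcome_means, model.outcome_sd)
    logw = np.log(base.pi)[None, :] + L
    return np.exp(logw - logsumexp(logw, axis=1, keepdims=True))


def fit_joint(panel: PanelData, outcomes: pd.DataFrame, J: int,
              start: MultiTrajModel, seed: int | None = None,
              tol: float = 1e-6, max_iter: int = 500,
              compute_se: bool = True) -> JointModel:
    """Joint one-step fit, warm started at a trajectory-only model.

    Outcome means are initialised at posterior-weighted group means under
    the warm start; EM then updates trajectory and outcome parameters
    together. The maximised joint log-likelihood is always at least the
    joint log-likelihood of the warm start itself.
    """
    if start.n_groups != J:
        raise ValueError("warm start has a different number of groups")
    panel.require_nonempty_subjects()
    Y = panel.scores
    n, K, T = Y.shape
    X = design_matrix(panel.ages, start.order)
    lo, hi = start.bounds()
    Z = _align_outcomes(panel, outcomes)
    names = list(outcomes.columns)
    O = Z.shape[1]
    obs = np.isfinite(Z)
    Z0 = np.where(obs, Z, 0.0)

    theta = start.theta.copy()
    coeffs = start.coeffs.copy()
    sigma = start.sigma.copy()

    # initial outcome means: posterior-weighted group means under the start
    L0 = _emission_matrix(Y, coeffs @ X.T, _sig_jk(sigma, J, K), lo, hi)
    logw = np.log(start.pi)[None, :] + L0
    r0 = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
    denom = r0.T @ obs                                   # (J, O)
    means = np.where(denom > 0, (r0.T @ Z0) / np.maximum(denom, 1e-12),
                     np.nanmean(np.where(obs, Z, np.nan), axis=0)[None, :])
    resid2 = (Z[:, None, :] - means[None]) ** 2
    sd = np.sqrt(np.nansum(np.where(obs[:, None, :], r0[:, :, None] * resid2, 0.0),
                           axis=(0, 1)) / np.maximum(obs.sum(axis=0), 1))
    sd = np.clip(sd, 1e-3, None)

    def joint_estep(theta, coeffs, sigma, means, sd):
        L = _emission_matrix(Y, coeffs @ X.T, _sig_jk(sigma, J, K), lo, hi)
        L = L + _outcome_ll_matrix(Z, means, sd)
        logpi = theta - logsumexp(theta)
        logw = logpi[None, :] + L
        tot = logsumexp(logw, axis=1)
        return np.exp(logw - tot[:, None]), float(tot.sum())

    loglik_start = joint_estep(theta, coeffs, sigma, means, sd)[1]

    trace = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        resp, ll = joint_estep(theta, coeffs, sigma, means, sd)
        trace.append(ll)
        if ll < prev - 1e-8:
            warnings.warn(f"joint EM log-likelihood decreased by {prev - ll:.3e}")
        if abs(ll - prev) < tol:
            converged = True
            break
        prev = ll
        try:
            theta, coeffs, sigma = _m_step(Y, X, resp, coeffs, sigma,
                                           start.sigma_shared, lo, hi, 1.0 / n)
        except _GroupCollapse:
            warnings.warn("a group collapsed during the joint fit; "
                          "returning best-so-far parameters")
            break
        # closed-form outcome updates
        denom = resp.T @ obs
        new_means = np.where(denom > 0, (resp.T @ Z0) / np.maximum(denom, 1e-12),
                             means)
        resid2 = (Z[:, None, :] - new_means[None]) ** 2
        ssq = np.where(obs[:, None, :], resp[:, :, None] * resid2, 0.0).sum(axis=(0, 1))
        sd = np.clip(np.sqrt(ssq / np.maximum(obs.sum(axis=0), 1)), 1e-6, None)
        means = new_means
    else:
        _, ll = joint_estep(theta, coeffs, sigma, means, sd)
        trace.append(ll)
        warnings.warn(f"joint EM did not converge within {max_iter} iterations")

    base = MultiTrajModel(
        theta=theta - theta[0], coeffs=coeffs, sigma=sigma,
        scales=list(panel.scales), ages=panel.ages.copy(), order=start.order,
        sigma_shared=start.sigma_shared, loglik=np.nan, converged=converged,
        n_iter=len(trace), loglik_trace=[])
    model = JointModel(base=base, outcome_names=names, outcome_means=means,
                       outcome_sd=sd, loglik=trace[-1],
                       loglik_start=loglik_start, loglik_trace=trace)
    if compute_se:
        _attach_outcome_se(model, panel, Z, obs, X)
    return model


def _attach_outcome_se(model: JointModel, panel: PanelData, Z, obs, X) -> None:
    """Empirical observed-information SEs for all free parameters; the
    outcome-mean block is stored on the model. Singular information (e.g. a
    group with no expected membership) flags SEs unavailable."""
    base = model.base
    Y = panel.scores
    n, K, T = Y.shape
    J, O = model.outcome_means.shape
    P = base.coeffs.shape[2]

    # full joint posteriors
    L = _emission_matrix(Y, base.predicted_means(), base.sigma_jk(),
                         *base.bounds())
    L = L + _outcome_ll_matrix(Z, model.outcome_means, model.outcome_sd)
    logw = np.log(base.pi)[None, :] + L
    resp = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))

    lo, hi = base.bounds()
    sig = base.sigma_jk()
    mu = base.predicted_means()
    _, dmu, dls = _loglik_and_grads(
        Y[:, None, :, :], mu[None], sig[None, :, :, None],
        lo[None, None, :, None], hi[None, None, :, None])
    mask = np.isfinite(Y[:, None])
    dmu = np.where(mask, dmu, 0.0)
    dls = np.where(mask, dls, 0.0)

    blocks = []
    # membership logits (first fixed at 0)
    blocks.append(resp[:, 1:] - base.pi[None, 1:])
    # trajectory coefficients: resp_ij * sum_t dmu X_tp
    s_beta = np.einsum("ijkt,tp->ijkp", dmu, X) * resp[:, :, None, None]
    blocks.append(s_beta.reshape(n, J * K * P))
    # log residual SDs
    if base.sigma_shared:
        blocks.append(np.einsum("ij,ijkt->ik", resp, dls))
    else:
        blocks.append((resp[:, :, None] * dls.sum(axis=3)).reshape(n, J * K))
    # outcome means and log outcome SDs
    sd = model.outcome_sd
    zres = np.where(obs[:, None, :], Z[:, None, :] - model.outcome_means[None], 0.0)
    s_mean = resp[:, :, None] * zres / sd[None, None, :] ** 2
    blocks.append(s_mean.reshape(n, J * O))
    s_lsd = (resp[:, :, None] * np.where(obs[:, None, :],
                                         (zres / sd[None, None, :]) ** 2 - 1.0,
                                         0.0)).sum(axis=1)
    blocks.append(s_lsd)

    S = np.concatenate(blocks, axis=1)
    info = S.T @ S
    mean_start = (J - 1) + J * K * P + (K if base.sigma_shared else J * K)
    try:
        cov = np.linalg.inv(info)
        diag = np.diag(cov)
        if np.any(diag < 0):
            raise np.linalg.LinAlgError("negative variance")
        se = np.sqrt(diag[mean_start:mean_start + J * O]).reshape(J, O)
        model.outcome_se = se
        model.se_available = True
    except np.linalg.LinAlgError:
        warnings.warn("observed information matrix is singular; outcome-mean "
                      "SEs unavailable")
        model.outcome_se = np.full((J, O), np.nan)
        model.se_available = False


@dataclass
class StabilityReport:
    """Trajectory agreement before vs after appending distal outcomes."""

    max_abs_diff: float
    per_group: np.ndarray     # (J,) max abs predicted-mean difference
    permutation: np.ndarray   # label map applied to `after`
    tol: float

    @property
    def passed(self) -> bool:
        return bool(self.max_abs_diff < self.tol)


def trajectory_stability_check(before: MultiTrajModel, after: JointModel | MultiTrajModel,
                               tol: float = 1.0) -> StabilityReport:
    """Check that the joint fit reproduces the warm-start trajectory groups.

    Groups of ``after`` are matched to ``before`` by predicted-curve
    distance (label-invariant); the report gives the maximum absolute
    difference in model-predicted scores over groups x phenotypes x ages.
    """
    from .pooling import _curve_permutation

    after_base = after.base if isinstance(after, JointModel) else after
    if after_base.n_groups != before.n_groups:
        raise ValueError("group counts differ")
    mu_b = before.predicted_means()
    mu_a = after_base.predicted_means(before.ages)
    perm = _curve_permutation(mu_b, mu_a)
    diff = np.abs(mu_b - mu_a[perm])
    return StabilityReport(max_abs_diff=float(diff.max()),
                           per_group=diff.max(axis=(1, 2)),
                           permutation=perm, tol=tol)
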