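"""Group-based multi-trajectory finite mixture model.

Each latent group ``j`` is defined by polynomial mean trajectories (on
centered age, ``c = age - 11``) for every phenotype ``k``, with a
censored-normal emission at the scale bounds and residual SD shared across
groups within a phenotype (per-group SDs behind a flag). Group membership
probabilities are parameterised as a multinomial logit with the first logit
fixed at 0.

Fitting is by EM: the E-step computes posterior responsibilities with
log-sum-exp stability; the M-step updates the logits in closed form and the
trajectory coefficients / residual scales by responsibility-weighted
censored-normal regression (L-BFGS inner maximisation, warm-started, with a
revert-on-non-improvement safeguard so EM never decreases the
log-likelihood). Multiple short-run starts (random partitions plus one
quantile-stratified start) precede a full run from the best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import logsumexp

from .censnorm import _loglik_and_grads
from .config import AGE_CENTER, ScaleSpec
from .panel import PanelData


# ---------------------------------------------------------------------------
# Small pure functions
# ---------------------------------------------------------------------------

def trajectory_mean(coeffs, age, center: float = AGE_CENTER):
    """Polynomial trajectory mean at ``age``; coeffs ``(..., P)`` low-to-high
    order on centered age ``c = age - center``."""
    coeffs = np.asarray(coeffs, dtype=float)
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("non-finite trajectory coefficients")
    c = np.asarray(age, dtype=float) - center
    scalar_age = c.ndim == 0
    powers = np.atleast_1d(c)[:, None] ** np.arange(coeffs.shape[-1])  # (T, P)
    out = coeffs @ powers.T                                            # (..., T)
    if scalar_age:
        out = out[..., 0]
        if out.ndim == 0:
            return float(out)
    return out


def design_matrix(ages, order: int, center: float = AGE_CENTER) -> np.ndarray:
    """(T, order+1) polynomial design on centered age."""
    c = np.asarray(ages, dtype=float) - center
    return c[:, None] ** np.arange(order + 1)


def group_membership_probs(theta) -> np.ndarray:
    """Softmax of membership logits; invariant to adding a constant."""
    theta = np.asarray(theta, dtype=float)
    if not np.all(np.isfinite(theta)):
        raise ValueError("non-finite logits")
    w = theta - theta.max()
    e = np.exp(w)
    return e / e.sum()


# ---------------------------------------------------------------------------
# Model container
# ---------------------------------------------------------------------------

@dataclass
class MultiTrajModel:
    """Fitted (or candidate) multi-trajectory mixture parameters."""

    theta: np.ndarray            # (J,) membership logits, theta[0] == 0
    coeffs: np.ndarray           # (J, K, P) polynomial coefficients
    sigma: np.ndarray            # (K,) shared, or (J, K) per-group residual SD
    scales: list[ScaleSpec]
    ages: np.ndarray             # (T,) assessment ages
    order: int = 2
    sigma_shared: bool = True
    loglik: float = np.nan
    converged: bool = False
    n_iter: int = 0
    n_restarts: int = 0
    loglik_trace: list = field(default_factory=list)

    def __post_init__(self):
        self.theta = np.asarray(self.theta, dtype=float)
        self.coeffs = np.asarray(self.coeffs, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)

    @property
    def n_groups(self) -> int:
        return self.coeffs.shape[0]

    @property
    def n_phenotypes(self) -> int:
        return self.coeffs.shape[1]

    @property
    def pi(self) -> np.ndarray:
        return group_membership_probs(self.theta)

    @property
    def n_params(self) -> int:
        J, K, P = self.coeffs.shape
        n_sig = K if self.sigma_shared else J * K
        return (J - 1) + J * K * P + n_sig

    def sigma_jk(self) -> np.ndarray:
        """Residual SD as a (J, K) array regardless of sharing."""
        if self.sigma.ndim == 1:
            return np.broadcast_to(self.sigma, (self.n_groups, self.n_phenotypes))
        return self.sigma

    def predicted_means(self, ages=None) -> np.ndarray:
        """Model-predicted trajectory means, (J, K, T)."""
        ages = self.ages if ages is None else np.asarray(ages, float)
        X = design_matrix(ages, self.order)
        return self.coeffs @ X.T

    def bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.array([s.lo for s in self.scales])
        hi = np.array([s.hi for s in self.scales])
        return lo, hi

    def relabelled(self, perm) -> "MultiTrajModel":
        """Return a copy with groups reordered so new group ``j`` is old
        group ``perm[j]``; logits re-anchored at the new first group."""
        perm = np.asarray(perm)
        theta = self.theta[perm]
        return MultiTrajModel(
            theta=theta - theta[0], coeffs=self.coeffs[perm],
            sigma=self.sigma if self.sigma.ndim == 1 else self.sigma[perm],
            scales=list(self.scales), ages=self.ages.copy(), order=self.order,
            sigma_shared=self.sigma_shared, loglik=self.loglik,
            converged=self.converged, n_iter=self.n_iter,
            n_restarts=self.n_restarts, loglik_trace=list(self.loglik_trace))


@dataclass
class PosteriorAssignment:
    """Posterior membership probabilities and modal-assignment diagnostics."""

    probs: np.ndarray       # (n, J), rows sum to 1
    modal: np.ndarray       # (n,) argmax group, lowest index on ties
    app: np.ndarray         # (J,) average posterior probability among modal members

    @property
    def group_counts(self) -> np.ndarray:
        J = self.probs.shape[1]
        return np.bincount(self.modal, minlength=J)


# ---------------------------------------------------------------------------
# Likelihood machinery
# ---------------------------------------------------------------------------

def _sig_jk(sigma, J, K):
    return np.broadcast_to(sigma, (J, K)) if sigma.ndim == 1 else sigma


def _emission_matrix(Y, mu, sigma_jk, lo, hi):
    """Per-subject per-group emission log-likelihood, (n, J).

    Y (n, K, T); mu (J, K, T); sigma_jk (J, K); lo, hi (K,).
    Missing cells contribute zero.
    """
    ll, _, _ = _loglik_and_grads(
        Y[:, None, :, :], mu[None], sigma_jk[None, :, :, None],
        lo[None, None, :, None], hi[None, None, :, None], grads=False)
    return np.where(np.isfinite(Y[:, None]), ll, 0.0).sum(axis=(2, 3))


def subject_loglik(panel: PanelData, model: MultiTrajModel) -> np.ndarray:
    """Per-subject mixture log-likelihood contributions, (n,).

    ``log sum_j pi_j exp(sum of censored-normal terms over observed cells)``,
    computed with log-sum-exp. Subjects with zero observations are rejected
    (:class:`~multitraj.panel.EmptySubjectError`).
    """
    panel.require_nonempty_subjects()
    lo, hi = model.bounds()
    mu = model.predicted_means()
    L = _emission_matrix(panel.scores, mu, model.sigma_jk(), lo, hi)
    logpi = np.log(model.pi)
    return logsumexp(logpi[None, :] + L, axis=1)


def posterior_assignments(panel: PanelData, model: MultiTrajModel) -> PosteriorAssignment:
    """Bayes-rule posterior group probabilities under a fitted model."""
    lo, hi = model.bounds()
    mu = model.predicted_means()
    L = _emission_matrix(panel.scores, mu, model.sigma_jk(), lo, hi)
    logw = np.log(model.pi)[None, :] + L
    probs = np.exp(logw - logsumexp(logw, axis=1, keepdims=True))
    modal = probs.argmax(axis=1)    # argmax takes the lowest index on ties
    J = probs.shape[1]
    app = np.full(J, np.nan)
    for j in range(J):
        sel = modal == j
        if sel.any():
            app[j] = probs[sel, j].mean()
    return PosteriorAssignment(probs=probs, modal=modal, app=app)


def bic(model: MultiTrajModel, n: int) -> float:
    """Bayesian information criterion, ``-2 logL + k log(n)``; lower is better."""
    return -2.0 * model.loglik + model.n_params * np.log(n)


# ---------------------------------------------------------------------------
# EM fitting
# ---------------------------------------------------------------------------

class _GroupCollapse(RuntimeError):
    pass


def _e_step(Y, X, theta, coeffs, sigma_jk, lo, hi):
    mu = coeffs @ X.T
    L = _emission_matrix(Y, mu, sigma_jk, lo, hi)
    logpi = theta - logsumexp(theta)
    logw = logpi[None, :] + L
    tot = logsumexp(logw, axis=1)
    resp = np.exp(logw - tot[:, None])
    return resp, float(tot.sum())


def _update_beta(yk, mask, w, X, beta0, sig, lo_k, hi_k, maxiter=40):
    """Responsibility-weighted censored-normal polynomial regression."""

    def nll(beta):
        mu_t = X @ beta
        ll, dmu, _ = _loglik_and_grads(yk, mu_t[None, :], sig, lo_k, hi_k)
        ll = np.where(mask, ll, 0.0)
        dmu = np.where(mask, dmu, 0.0)
        f = -float(w @ ll.sum(axis=1))
        g = -((w @ dmu) @ X)
        return f, g

    f0, _ = nll(beta0)
    res = minimize(nll, beta0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter})
    return (res.x, float(res.fun)) if res.fun <= f0 else (beta0, f0)


def _update_logsigma(yk, mask, resp, mu_groups, ls0, lo_k, hi_k, maxiter=25):
    """1-D update of a (log) residual SD given all group trajectory means.

    ``resp`` is (n, J') for the groups sharing this SD; ``mu_groups`` (J', T).
    """

    def nll(ls):
        s = float(np.exp(ls[0]))
        ll, _, dls = _loglik_and_grads(
            yk[:, None, :], mu_groups[None], s, lo_k, hi_k)
        m = mask[:, None, :]
        f = -float((resp * np.where(m, ll, 0.0).sum(axis=2)).sum())
        g = -float((resp * np.where(m, dls, 0.0).sum(axis=2)).sum())
        return f, np.array([g])

    f0, _ = nll(np.array([ls0]))
    res = minimize(nll, np.array([ls0]), jac=True, method="L-BFGS-B",
                   bounds=[(ls0 - 3.0, ls0 + 3.0)], options={"maxiter": maxiter})
    return (float(res.x[0]), float(res.fun)) if res.fun <= f0 else (ls0, f0)


def _m_step(Y, X, resp, coeffs, sigma, sigma_shared, lo, hi, n_floor):
    n, K, T = Y.shape
    J = resp.shape[1]
    pi = resp.mean(axis=0)
    if np.any(pi < n_floor):
        raise _GroupCollapse(f"group share fell below 1/n (pi={pi.round(4)})")
    theta = np.log(pi) - np.log(pi[0])

    coeffs = coeffs.copy()
    sigma = sigma.copy()
    sig_jk = np.broadcast_to(sigma, (J, K)).copy() if sigma.ndim == 1 else sigma
    for k in range(K):
        yk = Y[:, k, :]
        mask = np.isfinite(yk)
        for j in range(J):
            coeffs[j, k], _ = _update_beta(
                yk, mask, resp[:, j], X, coeffs[j, k], sig_jk[j, k], lo[k], hi[k])
        mu_groups = coeffs[:, k] @ X.T
        if sigma_shared:
            ls, _ = _update_logsigma(yk, mask, resp, mu_groups,
                                     float(np.log(sigma[k])), lo[k], hi[k])
            sigma[k] = np.exp(ls)
        else:
            for j in range(J):
                ls, _ = _update_logsigma(yk, mask, resp[:, [j]], mu_groups[[j]],
                                         float(np.log(sigma[j, k])), lo[k], hi[k])
                sigma[j, k] = np.exp(ls)
    return theta, coeffs, sigma


def _params_from_resp(Y, X, resp, sigma_shared):
    """Closed-form WLS initial parameters from soft assignments (censoring
    ignored — good enough to start EM)."""
    n, K, T = Y.shape
    J = resp.shape[1]
    P = X.shape[1]
    coeffs = np.zeros((J, K, P))
    sig = np.zeros((J, K))
    for k in range(K):
        yk = Y[:, k, :]
        mask = np.isfinite(yk)
        y0 = np.where(mask, yk, 0.0)
        for j in range(J):
            w = resp[:, j][:, None] * mask            # (n, T)
            XtWX = X.T @ np.diag(w.sum(axis=0)) @ X
            XtWy = X.T @ (w * y0).sum(axis=0)
            beta = np.linalg.solve(XtWX + 1e-8 * np.eye(P), XtWy)
            coeffs[j, k] = beta
            res2 = np.where(mask, (yk - (X @ beta)[None, :]) ** 2, 0.0)
            sig[j, k] = np.sqrt((resp[:, j][:, None] * res2).sum() / max(w.sum(), 1e-9))
    sig = np.clip(sig, 1e-2, None)
    pi = np.clip(resp.mean(axis=0), 1e-6, None)
    theta = np.log(pi) - np.log(pi[0])
    if sigma_shared:
        w = resp.mean(axis=0)
        sig_k = np.sqrt((w[:, None] * sig ** 2).sum(axis=0) / w.sum())
        return theta, coeffs, sig_k
    return theta, coeffs, sig


def _run_em(Y, X, theta, coeffs, sigma, lo, hi, sigma_shared,
            tol, max_iter):
    n = Y.shape[0]
    J, K = coeffs.shape[0], Y.shape[1]
    n_floor = 1.0 / n
    trace = []
    prev = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        resp, ll = _e_step(Y, X, theta, coeffs, _sig_jk(sigma, J, K), lo, hi)
        trace.append(ll)
        if ll < prev - 1e-8:
            warnings.warn(f"EM log-likelihood decreased by {prev - ll:.3e}")
        if abs(ll - prev) < tol:
            converged = True
            break
        prev = ll
        theta, coeffs, sigma = _m_step(Y, X, resp, coeffs, sigma,
                                       sigma_shared, lo, hi, n_floor)
    else:
        # one final E-step so the stored loglik matches the final parameters
        _, ll = _e_step(Y, X, theta, coeffs, _sig_jk(sigma, J, K), lo, hi)
        trace.append(ll)
    return theta, coeffs, sigma, trace, converged, it


def _feature_matrix(Y):
    """Per-subject standardised phenotype-wave profile; NaN -> 0 (mean)."""
    n, K, T = Y.shape
    F = Y.reshape(n, K * T).copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        m = np.nanmean(F, axis=0)
        s = np.nanstd(F, axis=0)
    s[~np.isfinite(s) | (s == 0)] = 1.0
    m[~np.isfinite(m)] = 0.0
    F = (F - m) / s
    return np.nan_to_num(F)


def _kmeans_start(Y, J, rng, n_iter=25):
    """Hard k-means partition of subject profiles as an EM start."""
    F = _feature_matrix(Y)
    n = F.shape[0]
    centers = F[rng.choice(n, size=J, replace=False)]
    labels = np.zeros(n, dtype=int)
    for _ in range(n_iter):
        d = ((F[:, None, :] - centers[None]) ** 2).sum(axis=2)
        new_labels = d.argmin(axis=1)
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for j in range(J):
            sel = labels == j
            if sel.any():
                centers[j] = F[sel].mean(axis=0)
            else:
                centers[j] = F[rng.integers(n)]
    resp = np.zeros((n, J))
    resp[np.arange(n), labels] = 1.0
    return resp


def _quantile_start(Y, J, rng):
    """Stratify subjects into J blocks by overall standardised severity."""
    n, K, T = Y.shape
    zs = np.empty((n, K))
    for k in range(K):
        yk = Y[:, k, :]
        m, s = np.nanmean(yk), np.nanstd(yk)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            zs[:, k] = (np.nanmean(yk, axis=1) - m) / (s if s > 0 else 1.0)
    zs = np.nan_to_num(zs)
    score = zs.mean(axis=1) + 1e-9 * rng.standard_normal(n)
    ranks = np.argsort(np.argsort(score))
    labels = np.minimum((ranks * J) // n, J - 1)
    resp = np.zeros((n, J))
    resp[np.arange(n), labels] = 1.0
    return resp


def fit_multitrajectory(panel: PanelData, J: int, order: int = 2,
                        n_starts: int = 8, seed: int | None = None,
                        tol: float = 1e-6, max_iter: int = 500,
                        init: MultiTrajModel | None = None,
                        sigma_shared: bool = True,
                        short_iter: int = 15,
                        max_restarts: int = 10) -> MultiTrajModel:
    """Maximum-likelihood fit of the J-group multi-trajectory model.

    Strategy: ``n_starts`` random-partition starts plus one
    quantile-stratified start are each run for ``short_iter`` EM iterations;
    the best continues to convergence (change in log-likelihood < ``tol``,
    up to ``max_iter`` iterations). A warm start (``init``) skips the
    multi-start phase. Collapsed groups (share below 1/n) trigger a restart
    from a fresh random partition, counted in ``n_restarts``.
    """
    if J < 1:
        raise ValueError("J must be >= 1")
    panel.require_nonempty_subjects()
    rng = np.random.default_rng(seed)
    Y = panel.scores
    n, K, T = Y.shape
    X = design_matrix(panel.ages, order)
    lo = np.array([s.lo for s in panel.scales])
    hi = np.array([s.hi for s in panel.scales])

    def one_hot(labels):
        r = np.zeros((n, J))
        r[np.arange(n), labels] = 1.0
        return r

    n_restarts = 0

    def short_run(resp):
        nonlocal n_restarts
        theta, coeffs, sigma = _params_from_resp(Y, X, resp, sigma_shared)
        return _run_em(Y, X, theta, coeffs, sigma, lo, hi, sigma_shared,
                       tol, short_iter)

    candidates = []
    if init is not None:
        if init.n_groups != J:
            raise ValueError("warm start has a different number of groups")
        sigma0 = init.sigma.copy()
        candidates.append((init.theta.copy(), init.coeffs.copy(), sigma0, [-np.inf]))
    else:
        starts = [_quantile_start(Y, J, rng)]
        if J > 1:
            n_km = max(1, n_starts // 2)
            starts += [_kmeans_start(Y, J, rng) for _ in range(n_km)]
            starts += [one_hot(rng.integers(0, J, size=n))
                       for _ in range(n_starts - n_km)]
        else:
            starts += [one_hot(rng.integers(0, J, size=n))
                       for _ in range(n_starts)]
        for resp in starts:
            tries = 0
            while True:
                try:
                    th, cf, sg, tr, _, _ = short_run(resp)
                    candidates.append((th, cf, sg, tr))
                    break
                except _GroupCollapse:
                    n_restarts += 1
                    tries += 1
                    if tries > max_restarts:
                        break
                    resp = one_hot(rng.integers(0, J, size=n))
        if not candidates:
            raise RuntimeError("all EM starts collapsed; reduce J")

    best = max(candidates, key=lambda c: c[3][-1])
    theta, coeffs, sigma = best[0], best[1], best[2]

    tries = 0
    while True:
        try:
            theta, coeffs, sigma, trace, converged, n_iter = _run_em(
                Y, X, theta, coeffs, sigma, lo, hi, sigma_shared, tol, max_iter)
            break
        except _GroupCollapse:
            n_restarts += 1
            tries += 1
            if tries > max_restarts:
                raise RuntimeError("EM could not maintain J non-empty groups")
            th0, cf0, sg0 = _params_from_resp(Y, X, one_hot(rng.integers(0, J, size=n)),
                                              sigma_shared)
            theta, coeffs, sigma = th0, cf0, sg0
    if not converged:
        warnings.warn(f"EM did not converge within {len(trace)} iterations; "
                      "returning best-so-far parameters")

    return MultiTrajModel(
        theta=theta - theta[0], coeffs=coeffs, sigma=sigma,
        scales=list(panel.scales), ages=panel.ages.copy(), order=order,
        sigma_shared=sigma_shared, loglik=trace[-1], converged=converged,
        n_iter=len(trace), n_restarts=n_restarts, loglik_trace=trace)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------

def select_model(panel: PanelData, J_range, order: int = 2,
                 seed: int | None = None, min_share: float = 0.05,
                 **fit_kwargs):
    """Fit a range of group counts and choose the minimum-BIC model.

    Returns ``(table, chosen_J, models)`` where ``table`` is a pandas
    DataFrame with one row per J (loglik, n_params, bic, smallest group
    share and a small-group flag). Models whose smallest share falls below
    ``min_share`` are flagged but not excluded — the flag is the "practical
    consideration" hook for the analyst.
    """
    import pandas as pd

    J_range = list(J_range)
    if not J_range:
        raise ValueError("J_range must be non-empty")
    ss = np.random.SeedSequence(seed)
    rows, models = [], {}
    for J, child in zip(J_range, ss.spawn(len(J_range))):
        sub_seed = int(child.generate_state(1)[0] % (2 ** 31))
        try:
            m = fit_multitrajectory(panel, J, order=order, seed=sub_seed, **fit_kwargs)
        except Exception as exc:  # recorded, not fatal
            rows.append({"J": J, "loglik": np.nan, "n_params": np.nan,
                         "bic": np.nan, "min_share": np.nan,
                         "small_group_flag": False, "error": str(exc)})
            continue
        models[J] = m
        share = m.pi.min()
        rows.append({"J": J, "loglik": m.loglik, "n_params": m.n_params,
                     "bic": bic(m, panel.n_subjects), "min_share": share,
                     "small_group_flag": bool(share < min_share), "error": ""})
    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["bic"])
    if ok.empty:
        raise RuntimeError("every candidate model failed to fit")
    chosen_J = int(ok.loc[ok["bic"].idxmin(), "J"])
    return table, chosen_J, models
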