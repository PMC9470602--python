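"""Multiple imputation by chained equations (fully conditional specification).

Continuous variables are imputed by predictive mean matching (PMM): a
Bayesian-draw linear regression of the variable on all other variables, with
each missing value receiving the *observed* value of one of the ``k_donors``
candidates whose predicted means lie nearest the missing case's prediction
(chosen uniformly at random). Nominal variables are imputed by a
multinomial-logit draw. The chained system sweeps every incomplete variable
``n_iter`` times per imputed dataset, and the ``M`` datasets are generated
from independently spawned streams of a single master seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class ImputationSet:
    """M completed datasets sharing identical observed cells."""

    M: int
    completed: list[pd.DataFrame]
    seed: int | None
    trace: pd.DataFrame   # per (dataset, iteration, variable) imputed-value mean

    def __iter__(self):
        return iter(self.completed)


def _bayes_regression_draw(Xo, yo, rng, ridge_scale: float = 1e-5):
    """mice-style Bayesian linear regression draw with ridge fallback.

    Returns ``(beta_hat, beta_star)``; ``beta_hat`` for the observed
    predictions (type-1 matching), ``beta_star`` a posterior draw for the
    missing predictions.
    """
    n, p = Xo.shape
    S = Xo.T @ Xo
    if np.linalg.matrix_rank(S) < p:
        warnings.warn("collinear predictors in chained imputation; "
                      "applying ridge penalty")
        S = S + ridge_scale * np.trace(S) / p * np.eye(p)
    else:
        S = S + 1e-10 * np.trace(S) / p * np.eye(p)
    Sinv = np.linalg.inv(S)
    beta_hat = Sinv @ (Xo.T @ yo)
    resid = yo - Xo @ beta_hat
    df = max(n - p, 1)
    sigma2_star = float(resid @ resid) / max(rng.chisquare(df), 1e-12)
    cov = sigma2_star * Sinv
    try:
        chol = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        chol = np.linalg.cholesky(cov + 1e-10 * np.trace(cov) / p * np.eye(p))
    beta_star = beta_hat + chol @ rng.standard_normal(p)
    return beta_hat, beta_star


def _pmm_draw(y, X, mis, rng, k_donors):
    """Predictive-mean-matched values for the missing entries of ``y``."""
    obs = ~mis
    Xo, yo, Xm = X[obs], y[obs], X[mis]
    beta_hat, beta_star = _bayes_regression_draw(Xo, yo, rng)
    eta_o = Xo @ beta_hat
    eta_m = Xm @ beta_star
    k = min(k_donors, len(yo))
    d = np.abs(eta_o[None, :] - eta_m[:, None])
    donors = np.argpartition(d, k - 1, axis=1)[:, :k]
    pick = donors[np.arange(len(eta_m)), rng.integers(0, k, size=len(eta_m))]
    return yo[pick]


def _polytomous_draw(y, X, mis, rng):
    """Multinomial-logit draw for a nominal variable."""
    from sklearn.linear_model import LogisticRegression

    obs = ~mis
    classes, y_codes = np.unique(y[obs], return_inverse=True)
    if len(classes) == 1:
        return np.repeat(classes[0], mis.sum())
    clf = LogisticRegression(max_iter=500)
    clf.fit(X[obs], y_codes)
    probs = clf.predict_proba(X[mis])
    cum = probs.cumsum(axis=1)
    u = rng.random(len(cum))
    picked = (u[:, None] < cum).argmax(axis=1)
    return classes[picked]


def chained_impute(data: pd.DataFrame, M: int = 3, n_iter: int = 10,
                   k_donors: int = 5, seed: int | None = None,
                   categorical: tuple[str, ...] = ()) -> ImputationSet:
    """Run chained-equation imputation and return ``M`` completed datasets.

    Every incomplete variable is regressed on all other variables (current
    working values). Continuous targets use PMM, so imputed values are
    always members of the variable's observed support; columns listed in
    ``categorical`` use a multinomial-logit draw.
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    df = data.copy()
    miss = df.isna()
    for col in df.columns:
        n_obs = int((~miss[col]).sum())
        if n_obs < k_donors:
            raise ValueError(f"variable {col!r} has only {n_obs} observed values "
                             f"(need >= k_donors={k_donors})")
    incomplete = [c for c in df.columns if miss[c].any()]

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(M)
    completed, trace_rows = [], []

    for m, child in enumerate(children):
        rng = np.random.default_rng(child)
        work = df.copy()
        # initial fill: random draws from each variable's observed values
        for col in incomplete:
            obs_vals = df.loc[~miss[col], col].to_numpy()
            work.loc[miss[col], col] = rng.choice(obs_vals, size=miss[col].sum())
        for it in range(n_iter if incomplete else 0):
            for col in incomplete:
                others = [c for c in df.columns if c != col]
                X = _encode(work[others], [c for c in categorical if c != col])
                X = np.column_stack([np.ones(len(X)), X])
                mis = miss[col].to_numpy()
                y = work[col].to_numpy()
                if col in categorical:
                    work.loc[mis, col] = _polytomous_draw(y, X, mis, rng)
                else:
                    work.loc[mis, col] = _pmm_draw(y.astype(float), X, mis, rng,
                                                   k_donors)
                trace_rows.append({"dataset": m, "iteration": it, "variable": col,
                                   "imputed_mean": float(pd.to_numeric(
                                       work.loc[mis, col], errors="coerce").mean())})
        completed.append(work)

    trace = pd.DataFrame(trace_rows,
                         columns=["dataset", "iteration", "variable", "imputed_mean"])
    return ImputationSet(M=M, completed=completed, seed=seed, trace=trace)


def _encode(df: pd.DataFrame, categorical) -> np.ndarray:
    """Numeric design matrix; nominal predictors are dummy-coded."""
    if categorical:
        df = pd.get_dummies(df, columns=list(categorical), drop_first=True)
    return df.to_numpy(dtype=float)
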