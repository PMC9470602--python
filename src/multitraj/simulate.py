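"""Synthetic cohort generation with known ground truth.

Generates longitudinal panels with the structure the analysis pipeline
assumes: subjects drawn into latent groups, group-specific polynomial mean
trajectories on centered age with normal residuals, observed scores clamped
to the scale bounds (so floor/ceiling mass appears exactly where the
censored-normal emission expects it), group-linked distal outcomes, and a
missing-at-random deletion mechanism calibrated to per-wave target rates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .config import AGE_CENTER, CohortConfig
from .panel import PanelData


@dataclass
class SyntheticTruth:
    """Ground truth attached to a generated cohort."""

    labels: np.ndarray        # (n,) true group index per subject
    config: CohortConfig


def _poly_means(coeffs: np.ndarray, ages: np.ndarray) -> np.ndarray:
    """Evaluate polynomial trajectories at ``ages``; coeffs (..., P)."""
    c = np.asarray(ages, dtype=float) - AGE_CENTER
    powers = c[..., None] ** np.arange(coeffs.shape[-1])   # (T, P)
    return coeffs @ powers.T                                # (..., T)


def generate_cohort(config: CohortConfig, seed: int | None = None
                    ) -> tuple[PanelData, pd.DataFrame, SyntheticTruth]:
    """Draw a complete cohort (no missingness) from ``config``.

    Returns the panel, a wide outcomes table (index subject_id, one column
    per outcome, NaN where unobserved) and the generating truth. Outcome
    missingness is applied here (completely at random per outcome at rate
    ``1 - observed_fraction``); panel missingness is a separate step, see
    :func:`apply_mar_missingness`.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    n, J = config.n_subjects, config.n_groups
    ages = config.ages
    K, T = len(config.scales), len(ages)

    labels = rng.choice(J, size=n, p=config.proportions)
    scores = np.empty((n, K, T))
    for j, g in enumerate(config.groups):
        idx = labels == j
        mu = _poly_means(g.coeffs, ages)                    # (K, T)
        eps = rng.standard_normal((idx.sum(), K, T)) * g.sigma[:, None]
        scores[idx] = mu[None] + eps
    for k, s in enumerate(config.scales):
        np.clip(scores[:, k, :], s.lo, s.hi, out=scores[:, k, :])

    subject_ids = np.arange(1, n + 1)
    panel = PanelData(subject_ids, ages.copy(), list(config.scales), scores)

    out = {}
    for o in config.outcomes:
        mu = o.group_means[labels]
        if config.lognormal_outcomes:
            # lognormal with matched mean and SD, for skew-robustness runs
            s2 = np.log1p((o.sd / mu) ** 2)
            z = np.exp(np.log(mu) - 0.5 * s2 + rng.standard_normal(n) * np.sqrt(s2))
        else:
            z = mu + o.sd * rng.standard_normal(n)
        if o.observed_fraction < 1:
            z[rng.random(n) >= o.observed_fraction] = np.nan
        out[o.name] = z
    outcomes = pd.DataFrame(out, index=pd.Index(subject_ids, name="subject_id"))

    return panel, outcomes, SyntheticTruth(labels=labels, config=config)


def _calibrate_alpha(z: np.ndarray, gamma: float, target: float) -> float:
    """Solve ``mean(expit(alpha + gamma * z)) == target`` for alpha."""
    if target <= 0:
        return -np.inf
    if gamma == 0 or np.allclose(z, 0):
        return float(logit(target))

    def f(a):
        return expit(a + gamma * z).mean() - target

    lo, hi = -30.0, 30.0
    return float(brentq(f, lo, hi, xtol=1e-10))


def apply_mar_missingness(panel: PanelData, config: CohortConfig,
                          seed: int | None = None) -> PanelData:
    """Delete phenotype-wave observations under a calibrated MAR mechanism.

    Waves are processed in age order. At wave ``t`` the deletion probability
    for subject ``i``, phenotype ``k`` is
    ``logistic(alpha_{k,t} + gamma * z_{i,k,<t})`` where ``z`` is the
    standardised most recent still-observed earlier-wave score of the same
    phenotype (0 when none exists). Probabilities therefore depend only on
    values that remain observed — the mechanism is MAR by construction.
    ``alpha`` is calibrated per phenotype-wave so the marginal deletion rate
    matches the configured target.
    """
    spec = config.missingness
    if spec is None:
        return panel.copy()
    if np.any(spec.target_rates >= 1):
        raise ValueError("missingness target rate >= 1 requested")
    if seed is None:
        seed = config.seed + 1
    rng = np.random.default_rng(seed)

    out = panel.copy()
    n, K, T = out.scores.shape
    rates = spec.target_rates
    if spec.monotone and np.any(np.diff(rates, axis=1) < -1e-12):
        raise ValueError("monotone dropout requires non-decreasing target rates")

    for k in range(K):
        yk = out.scores[:, k, :]
        dropped = np.zeros(n, dtype=bool)
        for t in range(T):
            target = rates[k, t]
            # predictor from data still observed at earlier waves only
            z = np.zeros(n)
            if t > 0:
                prior = yk[:, :t]
                has = np.isfinite(prior)
                any_prior = has.any(axis=1)
                if any_prior.any():
                    last_idx = t - 1 - np.argmax(has[:, ::-1], axis=1)
                    vals = prior[np.arange(n), last_idx]
                    mu_p = np.nanmean(prior)
                    sd_p = np.nanstd(prior)
                    sd_p = sd_p if sd_p > 0 else 1.0
                    z[any_prior] = (vals[any_prior] - mu_p) / sd_p
            if spec.monotone:
                # incremental hazard among subjects not yet dropped
                already = dropped.mean()
                incr = max(0.0, (target - already) / max(1e-12, 1.0 - already))
                if incr > 0:
                    alpha = _calibrate_alpha(z[~dropped], spec.gamma, incr)
                    p = expit(alpha + spec.gamma * z)
                    new = (~dropped) & (rng.random(n) < p)
                    dropped |= new
                yk[dropped, t] = np.nan
            else:
                if target <= 0:
                    continue
                alpha = _calibrate_alpha(z, spec.gamma, target)
                p = expit(alpha + spec.gamma * z)
                delete = rng.random(n) < p
                yk[delete, t] = np.nan
    return out
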