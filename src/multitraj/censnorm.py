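"""Censored (tobit) normal log-density and its derivatives.

Bounded symptom sum-scores pile probability mass at the scale floor and
ceiling. The emission density used throughout the mixture model is a normal
censored at the scale bounds ``[lo, hi]``:

* ``lo < y < hi``  — normal density ``phi((y - mu) / sigma) / sigma``
* ``y == lo``      — point mass ``Phi((lo - mu) / sigma)``
* ``y == hi``      — point mass ``1 - Phi((hi - mu) / sigma)``

With ``lo = -inf`` and ``hi = +inf`` this reduces exactly to the plain
normal density, which is how an uncensored emission is requested.

All functions broadcast over numpy arrays (including the bounds) and are
written against ``scipy.special.log_ndtr`` for tail stability.
"""

from __future__ import annotations

import numpy as np
from scipy.special import log_ndtr

_LOG_SQRT_2PI = 0.5 * np.log(2.0 * np.pi)


def censored_normal_loglik(y, mu, sigma, lo, hi):
    """Elementwise log-density of the censored normal.

    Parameters
    ----------
    y : array_like
        Observed scores, all within ``[lo, hi]``. NaN entries yield NaN.
    mu, sigma : array_like
        Latent normal mean and SD (``sigma > 0``); broadcast against ``y``.
    lo, hi : array_like
        Censoring bounds; may be ``-inf`` / ``+inf`` for an uncensored tail.

    Raises
    ------
    ValueError
        If any finite ``y`` lies outside ``[lo, hi]`` or ``sigma <= 0``.
    """
    y = np.asarray(y, dtype=float)
    if np.any(np.asarray(sigma, dtype=float) <= 0):
        raise ValueError("sigma must be strictly positive")
    yb, lob, hib = np.broadcast_arrays(y, np.asarray(lo, float), np.asarray(hi, float))
    finite = np.isfinite(yb)
    if np.any((yb[finite] < lob[finite]) | (yb[finite] > hib[finite])):
        raise ValueError("scores outside censoring bounds")
    ll, _, _ = _loglik_and_grads(y, mu, sigma, lo, hi, grads=False)
    return ll


def _loglik_and_grads(y, mu, sigma, lo, hi, grads: bool = True):
    """Return ``(loglik, d loglik/d mu, d loglik/d log sigma)`` elementwise.

    With ``grads=False`` the derivative slots are ``None`` (cheaper).
    NaN observations propagate NaN in all outputs; callers mask them.
    """
    y, mu, sigma, lo, hi = np.broadcast_arrays(
        np.asarray(y, float), np.asarray(mu, float), np.asarray(sigma, float),
        np.asarray(lo, float), np.asarray(hi, float))
    scalar = y.ndim == 0
    if scalar:
        y, mu, sigma, lo, hi = (np.atleast_1d(a) for a in (y, mu, sigma, lo, hi))
    left = (y <= lo) & np.isfinite(lo)
    right = (y >= hi) & np.isfinite(hi)

    z = (y - mu) / sigma
    ll = -np.log(sigma) - 0.5 * z * z - _LOG_SQRT_2PI
    dmu = z / sigma if grads else None
    dls = z * z - 1.0 if grads else None

    if left.any():
        a = (lo[left] - mu[left]) / sigma[left]
        la = log_ndtr(a)
        ll[left] = la
        if grads:
            # inverse Mills ratio phi(a)/Phi(a), stable in the far tail
            imr = np.exp(-0.5 * a * a - _LOG_SQRT_2PI - la)
            dmu[left] = -imr / sigma[left]
            dls[left] = -a * imr
    if right.any():
        b = (mu[right] - hi[right]) / sigma[right]
        lb = log_ndtr(b)
        ll[right] = lb
        if grads:
            imr = np.exp(-0.5 * b * b - _LOG_SQRT_2PI - lb)
            dmu[right] = imr / sigma[right]
            dls[right] = -b * imr
    if scalar:
        ll = ll[0]
        dmu = dmu[0] if grads else None
        dls = dls[0] if grads else None
    return ll, dmu, dls
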