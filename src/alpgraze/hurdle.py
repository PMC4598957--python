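"""Weighted zero-inflated negative-binomial hurdle likelihood.

Cell counts ``y_i`` follow a hurdle model: with probability ``pi`` a cell is
a structural zero; otherwise the count is drawn from a zero-truncated
negative binomial with mean ``mu_i`` and over-dispersion (size) ``kappa``,

    Pr(y_i) = pi * 1[y_i = 0] + (1 - pi) * NB(mu_i, kappa | y > 0).

The NB is parameterised by mean and size, variance ``mu + mu^2 / kappa``;
large ``kappa`` recovers a (truncated) Poisson.  Each observation carries a
gap-correction weight ``w_i`` that enters the likelihood as a frequency
weight (power of the per-cell probability).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def nb_logpmf(y, mu, kappa):
    """Negative-binomial log-pmf, mean/size parameterisation."""
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    lk = np.log(kappa)
    lkm = np.log(kappa + mu)
    return (
        gammaln(y + kappa)
        - gammaln(kappa)
        - gammaln(y + 1.0)
        + kappa * (lk - lkm)
        + y * (np.log(mu) - lkm)
    )


def nb_logp0(mu, kappa):
    """log NB(0; mu, kappa) = kappa * log(kappa / (kappa + mu))."""
    mu = np.asarray(mu, dtype=float)
    return kappa * (np.log(kappa) - np.log(kappa + mu))


def truncated_nb_logpmf(y, mu, kappa):
    """Zero-truncated NB log-pmf for y >= 1."""
    y = np.asarray(y)
    if np.any(y < 1):
        raise ValueError("zero-truncated pmf requires y >= 1")
    logp0 = nb_logp0(mu, kappa)
    # log(1 - p0), stable also when p0 is close to 1
    log1m_p0 = np.where(logp0 > -1e-8, np.log(-np.expm1(np.minimum(logp0, -1e-300))), np.log1p(-np.exp(logp0)))
    return nb_logpmf(y, mu, kappa) - log1m_p0


def zinb_hurdle_loglik(y, w, mu, kappa, pi) -> float:
    """Weighted hurdle ZINB log-likelihood ``sum_i w_i log Pr(y_i)``.

    Zeros contribute ``log pi``; positive counts contribute
    ``log(1 - pi)`` plus the zero-truncated NB log-pmf.
    """
    y = np.asarray(y)
    if not np.issubdtype(y.dtype, np.integer):
        yf = np.asarray(y, dtype=float)
        if not np.allclose(yf, np.round(yf)):
            raise ValueError("counts must be integers")
        y = np.round(yf).astype(int)
    if np.any(y < 0):
        raise ValueError("counts must be non-negative")
    w = np.broadcast_to(np.asarray(w, dtype=float), y.shape)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    if np.any(w <= 0) or np.any(mu <= 0) or kappa <= 0 or not (0.0 < pi < 1.0):
        raise ValueError("require w > 0, mu > 0, kappa > 0, pi in (0, 1)")
    zero = y == 0
    ll = 0.0
    if zero.any():
        ll += float(np.sum(w[zero]) * np.log(pi))
    if (~zero).any():
        ll += float(
            np.sum(
                w[~zero]
                * (np.log1p(-pi) + truncated_nb_logpmf(y[~zero], mu[~zero], kappa))
            )
        )
    return ll


def truncated_nb_mean(mu, kappa):
    """Mean of the zero-truncated NB: mu / (1 - P(0))."""
    p0 = np.exp(nb_logp0(mu, kappa))
    return mu / (1.0 - p0)


def truncated_nb_eta_derivs(y, eta, kappa, w):
    """Log-likelihood, gradient and curvature of the weighted truncated-NB
    terms with respect to the linear predictor ``eta = log(mu)``.

    Returns ``(loglik, grad, curv)`` where ``curv`` is the *negative* second
    derivative, floored at a small positive value so Newton steps on the
    latent field stay well posed.
    """
    eta = np.asarray(eta, dtype=float)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    mu = np.exp(np.clip(eta, -40.0, 40.0))
    km = kappa + mu
    logp0 = kappa * (np.log(kappa) - np.log(km))
    p0 = np.exp(np.minimum(logp0, -1e-300))
    one_m_p0 = -np.expm1(np.minimum(logp0, -1e-12))

    ll = float(np.sum(w * (nb_logpmf(y, mu, kappa) - np.log(one_m_p0))))

    a = kappa * mu / km
    # NB core derivatives wrt eta
    g_nb = y - (kappa + y) * mu / km
    h_nb = -(kappa + y) * kappa * mu / km**2  # second derivative (<= 0)
    # truncation term T = -log(1 - p0); dT = dp0 / (1 - p0)
    dp0 = -p0 * a
    da = a * kappa / km
    d2p0 = p0 * a * a - p0 * da
    g_T = dp0 / one_m_p0
    h_T = (d2p0 * one_m_p0 + dp0 * dp0) / one_m_p0**2

    grad = w * (g_nb + g_T)
    curv = -w * (h_nb + h_T)
    curv = np.maximum(curv, 1e-8 * w)
    return ll, grad, curv
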