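"""Random-walk Metropolis oracle for the positive-part posterior.

Samples the exact posterior of the (non-spatial) truncated-NB latent
Gaussian model — fixed effects beta, iid cell effects eps, and
hyperparameters (log tau_eps, log kappa) with the same priors as the
Laplace fitter — so the two inference routes can be compared on a small
instance.  Adaptive joint proposals; used only as a test oracle.
"""

from __future__ import annotations

import numpy as np

from alpgraze.hurdle import truncated_nb_eta_derivs


def log_posterior(params, y, w, X, beta_prec, tau_eps_prior, kappa_prior):
    p = X.shape[1]
    n = len(y)
    beta = params[:p]
    eps = params[p : p + n]
    lt, lk = params[p + n], params[p + n + 1]
    if abs(lt) > 20 or abs(lk) > 20:
        return -np.inf
    tau_eps, kappa = np.exp(lt), np.exp(lk)
    eta = X @ beta + eps
    ll, _, _ = truncated_nb_eta_derivs(y, eta, kappa, w)
    lp = ll
    lp += -0.5 * beta_prec * float(beta @ beta)
    lp += 0.5 * n * lt - 0.5 * tau_eps * float(eps @ eps)
    a, b = tau_eps_prior
    lp += a * lt - b * tau_eps
    a, b = kappa_prior
    lp += a * lk - b * kappa
    return lp


def run_mcmc(
    y,
    w,
    X,
    n_iter: int = 200_000,
    burn: int = 60_000,
    seed: int = 0,
    beta_prec: float = 1e-3,
    tau_eps_prior=(0.5, 0.00149),
    kappa_prior=(1.0, 0.01),
):
    """Adaptive random-walk Metropolis; returns posterior draws of beta and
    batch-means Monte-Carlo standard errors."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    n = len(y)
    d = p + n + 2
    x = np.zeros(d)
    x[0] = np.log(max(y.mean(), 1.0))
    x[p + n] = np.log(10.0)
    x[p + n + 1] = np.log(2.0)
    lp = log_posterior(x, y, w, X, beta_prec, tau_eps_prior, kappa_prior)

    scale = 2.38 / np.sqrt(d)
    cov = np.eye(d) * 0.01
    chol = np.linalg.cholesky(cov)
    samples = np.empty((n_iter - burn, p))
    acc = 0
    mean_est = x.copy()
    cov_est = np.eye(d) * 0.01
    for it in range(n_iter):
        prop = x + scale * (chol @ rng.standard_normal(d))
        lpp = log_posterior(prop, y, w, X, beta_prec, tau_eps_prior, kappa_prior)
        if np.log(rng.uniform()) < lpp - lp:
            x, lp = prop, lpp
            acc += 1
        # adapt during burn-in from the running sample covariance
        g = 1.0 / (it + 2)
        dx = x - mean_est
        mean_est += g * dx
        cov_est = (1 - g) * (cov_est + g * np.outer(dx, dx))
        if it < burn:
            if (it + 1) % 2000 == 0:
                chol = np.linalg.cholesky(cov_est + 1e-9 * np.eye(d))
                rate = acc / (it + 1)
                scale *= np.exp((rate - 0.234))
        else:
            samples[it - burn] = x[:p]
    draws = samples
    nb = 50
    bs = len(draws) // nb
    bm = draws[: nb * bs].reshape(nb, bs, p).mean(axis=1)
    mcse = bm.std(axis=0, ddof=1) / np.sqrt(nb)
    return {
        "beta_mean": draws.mean(axis=0),
        "beta_sd": draws.std(axis=0),
        "mcse": mcse,
        "accept_rate": acc / n_iter,
        "draws": draws,
    }
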