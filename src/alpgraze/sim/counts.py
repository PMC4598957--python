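"""Direct simulation of grid-cell counts from the hurdle activity model.

Generates data straight from the statistical model (covariates -> linear
predictor -> latent fields -> hurdle ZINB counts) with known ground truth,
which is what parameter-recovery and coverage experiments need: unlike the
track simulator there is no behavioural layer in between.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import nbinom

from ..gmrf import PrecisionStructure, sample_constrained
from ..hurdle import nb_logp0


@dataclass
class SimulatedCounts:
    """Counts plus every latent quantity used to generate them."""

    y: np.ndarray
    eta: np.ndarray
    f_s: np.ndarray | None
    f_z: np.ndarray | None
    eps: np.ndarray
    beta_true: np.ndarray
    kappa_true: float
    pi_true: float
    tau_s_true: float | None
    tau_z_true: float | None
    tau_eps_true: float
    meta: dict = field(default_factory=dict)


def sample_truncated_nb(mu, kappa, rng):
    """Zero-truncated NB draws via inverse-CDF restricted to (P(0), 1]."""
    mu = np.asarray(mu, dtype=float)
    p = kappa / (kappa + mu)
    p0 = np.exp(nb_logp0(mu, kappa))
    u = p0 + (1.0 - p0) * rng.uniform(size=mu.shape)
    y = nbinom.ppf(np.clip(u, None, 1.0 - 1e-14), kappa, p).astype(int)
    return np.maximum(y, 1)


def simulate_cell_counts(
    X,
    beta,
    *,
    kappa: float,
    pi: float,
    tau_eps: float,
    spatial: PrecisionStructure | None = None,
    tau_s: float | None = None,
    elev_struct: PrecisionStructure | None = None,
    elev_bin_idx=None,
    tau_z: float | None = None,
    seed: int = 0,
) -> SimulatedCounts:
    """Draw hurdle-ZINB counts from the full latent Gaussian model.

    ``log mu = X beta + f_s + f_z[bin] + eps`` with the intrinsic fields
    drawn from their constrained (scaled) GMRF priors; with probability
    ``pi`` a cell emits a structural zero, otherwise a zero-truncated
    NB(mu, kappa) draw.
    """
    X = np.asarray(X, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if X.shape[1] != beta.size:
        raise ValueError("design matrix and beta dimensions differ")
    if not (0.0 <= pi <= 1.0):
        raise ValueError("pi must lie in [0, 1]")
    if kappa <= 0 or tau_eps <= 0:
        raise ValueError("kappa and precisions must be positive")
    n = X.shape[0]
    rng = np.random.default_rng(seed)

    eta = X @ beta
    f_s = f_z = None
    if spatial is not None:
        if tau_s is None or tau_s <= 0:
            raise ValueError("tau_s required with a spatial structure")
        if spatial.n != n:
            raise ValueError("spatial structure size does not match X")
        f_s = sample_constrained(spatial, tau_s, rng)
        eta = eta + f_s
    if elev_struct is not None:
        if tau_z is None or tau_z <= 0:
            raise ValueError("tau_z required with an elevation structure")
        f_z = sample_constrained(elev_struct, tau_z, rng)
        eta = eta + f_z[np.asarray(elev_bin_idx)]
    eps = rng.normal(0.0, 1.0 / np.sqrt(tau_eps), size=n)
    eta = eta + eps
    mu = np.exp(np.clip(eta, -30, 30))

    y = np.zeros(n, dtype=int)
    occupied = rng.uniform(size=n) >= pi
    if occupied.any():
        y[occupied] = sample_truncated_nb(mu[occupied], kappa, rng)

    return SimulatedCounts(
        y=y,
        eta=eta,
        f_s=f_s,
        f_z=f_z,
        eps=eps,
        beta_true=beta.copy(),
        kappa_true=float(kappa),
        pi_true=float(pi),
        tau_s_true=tau_s,
        tau_z_true=tau_z,
        tau_eps_true=float(tau_eps),
        meta={"seed": seed, "n": n},
    )
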