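"""Bayesian inference for the spatial hurdle activity model.

The positive part of the hurdle is a latent Gaussian count model

    log(mu_i) = beta'x_i + f(s_i) + f(z_i) + eps_i,

with a planar RW2 field ``f(s)`` over the lattice, an RW1 effect ``f(z)`` of
elevation, and an unstructured error ``eps``, each governed by a single
precision (tau_s, tau_z, tau_eps) with Gamma priors; the zero-truncated NB
observation model adds the over-dispersion parameter ``kappa``.  The zero
part is a single Bernoulli probability ``pi`` with a conjugate Beta(1, 1)
prior, estimated from the zero/positive split.

Inference follows the nested-Laplace strategy for latent Gaussian models:
for each hyperparameter configuration ``theta = (log tau_s, log tau_z,
log tau_eps, log kappa)`` the latent field is replaced by its Gaussian
approximation at the conditional mode (Newton iterations with the exact
likelihood gradient/curvature); the marginal posterior of ``theta`` is a
Laplace approximation explored on an adaptive star grid around its mode
(5 points per dimension spanning +-3 posterior SDs); fixed-effect marginals
are mixtures of the conditional Gaussians over that grid.  Sum-to-zero and
linear-trend constraints on the intrinsic fields are imposed by
conditioning (kriging correction), never by soft penalties.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.optimize import brentq, minimize
from scipy.sparse.linalg import splu
from scipy.stats import norm

from .hurdle import truncated_nb_eta_derivs
from .gmrf import PrecisionStructure, build_rw1_precision, build_rw2d_precision, scale_precision

log = logging.getLogger(__name__)

_JITTER_REL = 1e-6


@dataclass(frozen=True)
class GammaPrior:
    """Gamma(shape a, rate b) prior for a precision (or for kappa)."""

    a: float
    b: float

    def logpdf_log(self, theta: float) -> float:
        """Log density of theta = log(x) for x ~ Gamma(a, b), incl. Jacobian."""
        return self.a * theta - self.b * np.exp(theta)


@dataclass
class ModelSpec:
    """Likelihood and prior configuration of one activity regression.

    ``prior_tau_s``/``prior_tau_z`` are the Gamma priors on the scaled
    spatial and elevation precisions (default the study's reference choice
    a=1, b=0.00025, i.e. marginal-SD upper limit U = 0.5 at tail 0.001);
    ``prior_tau_eps`` is Gamma(0.5, 0.00149) for the unstructured error.
    """

    prior_tau_s: GammaPrior = GammaPrior(1.0, 0.00025)
    prior_tau_z: GammaPrior = GammaPrior(1.0, 0.00025)
    prior_tau_eps: GammaPrior = GammaPrior(0.5, 0.00149)
    prior_kappa: GammaPrior = GammaPrior(1.0, 0.01)
    include_spatial: bool = True
    include_elevation: bool = True
    include_iid: bool = True
    elevation_bin_width: float = 25.0
    beta_precision: float = 1e-3  # fixed effects ~ N(0, 1000)
    int_strategy: str = "grid"  # "grid" (adaptive axis walk) or "eb" (mode only)
    grid_step: float = 1.0  # step size along each axis, in posterior SDs
    grid_max_steps: int = 6
    grid_logdrop: float = 4.0  # stop a walk once log-density falls this far
    max_newton_iter: int = 50
    theta_init: dict = field(default_factory=dict)

    def prior_sd_upper_limits(self) -> dict:
        from .gmrf import prior_sd_upper_limit

        return {
            "tau_s": prior_sd_upper_limit(self.prior_tau_s.a, self.prior_tau_s.b),
            "tau_z": prior_sd_upper_limit(self.prior_tau_z.a, self.prior_tau_z.b),
        }


@dataclass
class PosteriorSummary:
    """Posterior summaries of one fitted activity regression."""

    effects: pd.DataFrame  # per covariate: mean, sd, q025, q975, significant
    intercept: pd.Series
    hypers: pd.DataFrame  # kappa, tau_s, tau_z, tau_eps: mean, sd
    pi_mean: float
    pi_sd: float
    fitted_mu: np.ndarray  # exp of posterior-mean linear predictor per cell
    theta_mode: dict
    theta_sd: dict
    log_marginal: float
    meta: dict = field(default_factory=dict)


def significance(summary: PosteriorSummary) -> dict:
    """Classify each effect by its 95 % credibility interval.

    ``positive`` if the 2.5 % quantile exceeds 0, ``negative`` if the 97.5 %
    quantile is below 0, else ``none``.
    """
    out = {}
    for name, row in summary.effects.iterrows():
        if row["q025"] > 0:
            out[name] = "positive"
        elif row["q975"] < 0:
            out[name] = "negative"
        else:
            out[name] = "none"
    return out


def _sig_label(q025: float, q975: float) -> str:
    if q025 > 0:
        return "positive"
    if q975 < 0:
        return "negative"
    return "none"


class _LatentModel:
    """Pre-assembled sparse structures for one positive-part fit."""

    def __init__(self, y, w, X, names, spec: ModelSpec, spatial: PrecisionStructure | None, elev_struct: PrecisionStructure | None, elev_bin_idx):
        y = np.asarray(y)
        w = np.asarray(w, dtype=float)
        X = np.asarray(X, dtype=float)
        pos = y > 0
        if not pos.any():
            raise ValueError("no positive counts: the hurdle's positive part cannot be fitted")
        self.n_cells = len(y)
        self.pos = pos
        self.y = y[pos].astype(float)
        self.w = w[pos]
        self.p = X.shape[1]
        self.names = list(names)
        self.spec = spec

        blocks = [("beta", self.p)]
        Bcols = [X[pos]]
        Ball_cols = [X]  # linear predictor over all cells (without eps)
        self.hyper_names: list[str] = []
        prior_blocks = []  # (kind, matrix-or-size, theta-name)
        prior_blocks.append(("fixed", self.p, None))

        self.A_blocks = []  # (block offset, A matrix, theta name, M0 = A Qj^-1 A')
        offset = self.p
        self.structs = {}
        if spec.include_spatial:
            if spatial is None:
                raise ValueError("spatial structure required when include_spatial")
            n_s = spatial.n
            if n_s != self.n_cells:
                raise ValueError("spatial structure does not match cell count")
            blocks.append(("f_s", n_s))
            S = sp.identity(self.n_cells, format="csr")[np.flatnonzero(pos)]
            Bcols.append(S)
            Ball_cols.append(sp.identity(self.n_cells, format="csr"))
            prior_blocks.append(("struct", spatial, "tau_s"))
            self.hyper_names.append("tau_s")
            self.structs["tau_s"] = (offset, spatial)
            offset += n_s
        if spec.include_elevation:
            if elev_struct is None or elev_bin_idx is None:
                raise ValueError("elevation structure and bin indices required")
            m = elev_struct.n
            blocks.append(("f_z", m))
            Z = sp.csr_matrix(
                (np.ones(self.n_cells), (np.arange(self.n_cells), np.asarray(elev_bin_idx))),
                shape=(self.n_cells, m),
            )
            Bcols.append(Z[np.flatnonzero(pos)])
            Ball_cols.append(Z)
            prior_blocks.append(("struct", elev_struct, "tau_z"))
            self.hyper_names.append("tau_z")
            self.structs["tau_z"] = (offset, elev_struct)
            offset += m
        if spec.include_iid:
            n_pos = int(pos.sum())
            blocks.append(("eps", n_pos))
            Bcols.append(sp.identity(n_pos, format="csr"))
            Ball_cols.append(None)
            prior_blocks.append(("iid", n_pos, "tau_eps"))
            self.hyper_names.append("tau_eps")
            offset += n_pos
        self.hyper_names.append("kappa")
        self.ntot = offset
        self.blocks = blocks

        self.B = sp.hstack([sp.csr_matrix(c) for c in Bcols], format="csr")
        self.B_all = sp.hstack(
            [sp.csr_matrix(c) for c in Ball_cols if c is not None], format="csr"
        )
        self.ntot_nf = self.B_all.shape[1]  # latent dims entering eta_all

        # jittered structure blocks, their log-determinants and A M0 pieces
        self._prior_parts = []
        A_rows = []
        for kind, obj, tname in prior_blocks:
            if kind == "fixed":
                self._prior_parts.append(("fixed", sp.identity(obj) * spec.beta_precision, obj, 0.0, tname))
            elif kind == "iid":
                self._prior_parts.append(("iid", sp.identity(obj, format="csr"), obj, 0.0, tname))
            else:
                st: PrecisionStructure = obj
                delta = _JITTER_REL * st.Q.diagonal().max()
                Qj = (st.Q + delta * sp.identity(st.n)).tocsc()
                lu = splu(Qj)
                logdet = float(np.sum(np.log(np.abs(lu.U.diagonal()))))
                off = self.structs[tname][0]
                Acon = st.constraints
                QinvAT = lu.solve(Acon.T)
                M0 = Acon @ QinvAT  # A Qj^-1 A'
                self._prior_parts.append(("struct", Qj.tocsr(), st.n, logdet, tname))
                Afull = np.zeros((Acon.shape[0], 1))  # placeholder, expanded below
                A_rows.append((off, Acon, tname, M0))
        # full constraint matrix
        k = sum(a[1].shape[0] for a in A_rows)
        self.A = np.zeros((k, self.ntot))
        self._A_parts = []
        r = 0
        for off, Acon, tname, M0 in A_rows:
            self.A[r : r + Acon.shape[0], off : off + Acon.shape[1]] = Acon
            self._A_parts.append((r, Acon.shape[0], tname, M0))
            r += Acon.shape[0]
        self.k = k

    # -- prior pieces ------------------------------------------------------
    def q_prior(self, theta: dict) -> tuple[sp.csr_matrix, float, float]:
        """(Q_prior, logdet Q_prior, logdet A Qpr^-1 A') for hypers theta."""
        mats = []
        logdet = 0.0
        for kind, M, n, ld, tname in self._prior_parts:
            if kind == "fixed":
                mats.append(M)
                logdet += n * np.log(self.spec.beta_precision)
            else:
                tau = np.exp(theta[tname])
                mats.append(M * tau)
                logdet += n * theta[tname] + ld
        Qpr = sp.block_diag(mats, format="csr")
        logdet_AQA = 0.0
        for r, kk, tname, M0 in self._A_parts:
            tau = np.exp(theta[tname])
            sign, ld = np.linalg.slogdet(M0 / tau)
            logdet_AQA += ld
        return Qpr, logdet, logdet_AQA

    # -- Gaussian approximation at the conditional mode --------------------
    def gaussian_approx(self, theta: dict, v0=None):
        kappa = np.exp(theta["kappa"])
        Qpr, logdet_pr, logdet_AQA = self.q_prior(theta)
        v = np.zeros(self.ntot) if v0 is None else v0.copy()
        if v0 is None:
            v[0] = np.log(max(self.y.mean(), 1.0)) if self.names[0] == "intercept" else 0.0

        def objective(vv):
            eta = self.B @ vv
            ll, _, _ = truncated_nb_eta_derivs(self.y, eta, kappa, self.w)
            return ll - 0.5 * float(vv @ (Qpr @ vv))

        obj = objective(v)
        converged = False
        for it in range(self.spec.max_newton_iter):
            eta = self.B @ v
            ll, grad, curv = truncated_nb_eta_derivs(self.y, eta, kappa, self.w)
            Qpost = (Qpr + self.B.T @ sp.diags(curv) @ self.B).tocsc()
            rhs = self.B.T @ (grad + curv * eta)
            factor = splu(Qpost, permc_spec="MMD_AT_PLUS_A")
            m_G = factor.solve(rhs)
            if self.k:
                W = factor.solve(self.A.T)
                M = self.A @ W
                v_new = m_G - W @ np.linalg.solve(M, self.A @ m_G)
            else:
                v_new = m_G
            step = 1.0
            for _ in range(8):
                v_try = v + step * (v_new - v)
                obj_try = objective(v_try)
                if np.isfinite(obj_try) and obj_try >= obj - 1e-9:
                    break
                step *= 0.5
            delta = np.max(np.abs(v_try - v))
            v, obj = v_try, obj_try
            if delta < 1e-6 * (1.0 + np.max(np.abs(v))):
                converged = True
                break
        if not converged:
            raise RuntimeError(
                f"latent mode finding did not converge within {self.spec.max_newton_iter} iterations "
                f"(last step {delta:.3g}, theta={theta})"
            )
        # curvature/factor from the last iteration is evaluated within the
        # convergence tolerance of the constrained mode; reuse it
        eta = self.B @ v
        ll, _, _ = truncated_nb_eta_derivs(self.y, eta, kappa, self.w)
        logdet_post = float(np.sum(np.log(np.abs(factor.U.diagonal()))))

        # Laplace approximation of log pi(theta | y), constants dropped
        lp = ll - 0.5 * float(v @ (Qpr @ v)) + 0.5 * logdet_pr - 0.5 * logdet_post
        d = v - m_G
        lp += 0.5 * float(d @ (Qpost @ d))
        if self.k:
            W = factor.solve(self.A.T)
            M = self.A @ W  # A Qpost^-1 A'
            sign, logdet_M = np.linalg.slogdet(M)
            Am = self.A @ m_G
            lp += 0.5 * logdet_AQA - 0.5 * logdet_M - 0.5 * float(Am @ np.linalg.solve(M, Am))
        for tname in self.hyper_names:
            prior = {
                "tau_s": self.spec.prior_tau_s,
                "tau_z": self.spec.prior_tau_z,
                "tau_eps": self.spec.prior_tau_eps,
                "kappa": self.spec.prior_kappa,
            }[tname]
            lp += prior.logpdf_log(theta[tname])
        return {"v": v, "factor": factor, "lp": lp, "m_G": m_G, "Qpost": Qpost}

    def beta_conditionals(self, ga) -> tuple[np.ndarray, np.ndarray]:
        """Conditional posterior mean and SD of the fixed effects given theta."""
        factor = ga["factor"]
        E = np.zeros((self.ntot, self.p))
        E[: self.p, : self.p] = np.eye(self.p)
        S = factor.solve(E)
        if self.k:
            W = factor.solve(self.A.T)
            M = self.A @ W
            S = S - W @ np.linalg.solve(M, self.A @ S)
        var = np.clip(np.diag(S[: self.p, :]), 1e-300, None)
        return ga["v"][: self.p].copy(), np.sqrt(var)


def _mixture_quantile(weights, means, sds, q):
    lo = float(np.min(means - 8 * sds))
    hi = float(np.max(means + 8 * sds))

    def cdf(x):
        return float(np.sum(weights * norm.cdf((x - means) / sds))) - q

    return brentq(cdf, lo, hi, xtol=1e-8)


def fit_positive_part(y, w, X, names, spec: ModelSpec, spatial=None, elev_struct=None, elev_bin_idx=None, seed: int = 0):
    """Fit the positive (zero-truncated NB) part of the hurdle model.

    Low-level entry point used by :func:`fit_model` and by simulation
    studies that build their own design.  Returns a :class:`PosteriorSummary`
    (with ``pi`` filled in from the zero/positive split of ``y``).
    """
    y = np.asarray(y)
    w = np.asarray(w, dtype=float)
    model = _LatentModel(y, w, X, names, spec, spatial, elev_struct, elev_bin_idx)

    hyps = model.hyper_names
    defaults = {"tau_s": 0.0, "tau_z": np.log(10.0), "tau_eps": np.log(10.0), "kappa": np.log(2.0)}
    defaults.update(spec.theta_init)
    x0 = np.array([defaults[h] for h in hyps])

    state = {"v": None, "nfail": 0}

    def neg_lp(x):
        if np.any(np.abs(x) > 16):
            return 1e10
        theta = dict(zip(hyps, x))
        try:
            ga = model.gaussian_approx(theta, v0=state["v"])
        except (RuntimeError, np.linalg.LinAlgError):
            state["nfail"] += 1
            return 1e10
        state["v"] = ga["v"]
        return -ga["lp"]

    simplex = np.vstack([x0] + [x0 + 1.0 * e for e in np.eye(len(hyps))])
    res = minimize(
        neg_lp,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": 0.05,
            "fatol": 0.05,
            "maxfev": 50 * len(hyps),
            "adaptive": True,
            "initial_simplex": simplex,
        },
    )
    theta_mode = dict(zip(hyps, res.x))
    ga_mode = model.gaussian_approx(theta_mode, v0=state["v"])
    lp_mode = ga_mode["lp"]

    # curvature of the theta-posterior along each axis -> posterior SDs
    h = 0.4
    theta_sd = {}
    for i, name in enumerate(hyps):
        xp = res.x.copy()
        xp[i] += h
        xm = res.x.copy()
        xm[i] -= h
        fp, fm = -neg_lp(xp), -neg_lp(xm)
        c = (fp + fm - 2 * lp_mode) / h**2
        theta_sd[name] = float(1.0 / np.sqrt(-c)) if c < -1e-6 else 1.5
        theta_sd[name] = min(theta_sd[name], 3.0)

    points = [(res.x.copy(), lp_mode, ga_mode)]
    if spec.int_strategy == "grid":
        # walk outwards along each axis in steps of ~1 posterior SD until the
        # log-density has dropped by grid_logdrop; hyperparameter posteriors
        # (notably the spatial precision) are skewed, so the walk is
        # asymmetric and reaches flat tails a fixed symmetric grid would miss
        for i, name in enumerate(hyps):
            for sgn in (+1.0, -1.0):
                for k in range(1, spec.grid_max_steps + 1):
                    x = res.x.copy()
                    x[i] += sgn * k * spec.grid_step * theta_sd[name]
                    theta = dict(zip(hyps, x))
                    try:
                        ga = model.gaussian_approx(theta, v0=state["v"])
                    except (RuntimeError, np.linalg.LinAlgError):
                        break
                    points.append((x, ga["lp"], ga))
                    if ga["lp"] < lp_mode - spec.grid_logdrop:
                        break
    lps = np.array([p[1] for p in points])
    wts = np.exp(lps - lps.max())
    wts /= wts.sum()

    conds = [model.beta_conditionals(p[2]) for p in points]
    means = np.stack([c[0] for c in conds])
    sds = np.stack([c[1] for c in conds])

    mix_mean = wts @ means
    mix_var = wts @ (sds**2 + means**2) - mix_mean**2
    mix_sd = np.sqrt(np.clip(mix_var, 1e-300, None))
    q025 = np.array([_mixture_quantile(wts, means[:, j], sds[:, j], 0.025) for j in range(model.p)])
    q975 = np.array([_mixture_quantile(wts, means[:, j], sds[:, j], 0.975) for j in range(model.p)])

    eff = pd.DataFrame(
        {"mean": mix_mean, "sd": mix_sd, "q025": q025, "q975": q975},
        index=pd.Index(model.names, name="effect"),
    )
    eff["significant"] = [_sig_label(a, b) for a, b in zip(eff["q025"], eff["q975"])]
    intercept = None
    if "intercept" in eff.index:
        intercept = eff.loc["intercept"]
        eff = eff.drop(index="intercept")

    # hyperparameter summaries: log-normal from the Gaussian theta-posterior
    hyper_rows = {}
    for name in hyps:
        m, s = theta_mode[name], theta_sd[name]
        mean = float(np.exp(m + 0.5 * s**2))
        sd = float(mean * np.sqrt(np.expm1(s**2)))
        hyper_rows[name] = {"mean": mean, "sd": sd}
    hypers = pd.DataFrame(hyper_rows).T

    # fitted rate per cell from the mixture-mean linear predictor (without eps)
    eta_all = np.zeros(model.n_cells)
    for (x, lp, ga), wt in zip(points, wts):
        eta_all += wt * (model.B_all @ ga["v"][: model.ntot_nf])
    fitted_mu = np.exp(eta_all)

    n0 = int(np.sum(y == 0))
    n = len(y)
    a_, b_ = n0 + 1, (n - n0) + 1
    pi_mean = a_ / (a_ + b_)
    pi_sd = float(np.sqrt(a_ * b_ / ((a_ + b_) ** 2 * (a_ + b_ + 1))))

    return PosteriorSummary(
        effects=eff,
        intercept=intercept,
        hypers=hypers,
        pi_mean=pi_mean,
        pi_sd=pi_sd,
        fitted_mu=fitted_mu,
        theta_mode=theta_mode,
        theta_sd=theta_sd,
        log_marginal=float(lp_mode),
        meta={
            "n_cells": n,
            "n_positive": n - n0,
            "strategy": spec.int_strategy,
            "n_theta_points": len(points),
            "nm_converged": bool(res.success) or res.fun < 1e9,
        },
    )


def elevation_bins(elevation: np.ndarray, bin_width: float = 25.0):
    """Bin cell elevations into contiguous bands for the RW1 effect.

    Returns ``(bin_index per cell, n_bins)``; empty interior bands keep their
    place so the RW1 structure bridges them.
    """
    elevation = np.asarray(elevation, dtype=float)
    z0 = np.floor(elevation.min() / bin_width) * bin_width
    idx = np.floor((elevation - z0) / bin_width).astype(int)
    return idx, int(idx.max()) + 1


def fit_model(celldata, covariates, spec: ModelSpec, activity: str = "grazing", seed: int = 0) -> PosteriorSummary:
    """Fit the hurdle regression for one activity on gridded cell data.

    ``celldata`` is a :class:`alpgraze.gridding.CellData`; ``covariates`` a
    :class:`alpgraze.covariates.CovariateTable` aligned to the same active
    cells.  Builds and scales the RW2/RW1 structures, then delegates to
    :func:`fit_positive_part`.
    """
    y = celldata.counts(activity)
    w = celldata.weights(activity)
    X = covariates.X
    names = covariates.names
    spatial = None
    elev_struct = None
    elev_idx = None
    if spec.include_spatial:
        spatial = scale_precision(build_rw2d_precision(celldata.grid.active))
    if spec.include_elevation:
        elev_idx, m = elevation_bins(covariates.elevation, spec.elevation_bin_width)
        if m < 2:
            elev_idx, m = None, 0
            spec = replace(spec, include_elevation=False)
        else:
            elev_struct = scale_precision(build_rw1_precision(m))
    return fit_positive_part(
        y, w, X, names, spec, spatial=spatial, elev_struct=elev_struct, elev_bin_idx=elev_idx, seed=seed
    )
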