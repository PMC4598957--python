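"""Canonical synthetic studies: recovery, coverage, confounding, classification.

These are the package's desk-scale validation experiments, shared by the
test suite, the acceptance script and the analysis drivers.  Problem sizes
(a ~3,000-cell area for point recovery, 50 replicates of ~300 cells for
interval coverage) are chosen so each study carries real statistical
information while remaining a desk-scale computation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .covariates import (
    aspect_from_dem,
    assemble_standardize,
    distance_covariates,
    insolation,
    slope_from_dem,
    stocking_rate,
)
from .fit import ModelSpec, fit_positive_part
from .grids import Grid
from .gmrf import build_rw2d_precision, scale_precision
from .sim.counts import simulate_cell_counts
from .sim.landscape import LandscapeConfig, generate_landscape, generate_rotation
from .workflows import build_structures

#: Ground-truth coefficients of the recovery studies, in the order of the
#: standardised design matrix (intercept first).
BETA_TRUE = {
    "intercept": 1.0,
    "slope": -0.4,
    "insolation": 0.1,
    "log_dist_shed": -0.2,
    "log_dist_water": -0.1,
    "stocking_rate": 0.3,
    "nutrient-rich": 0.5,
    "sparse": -0.8,
}
#: Recovery/coverage studies use weak latent fields (marginal SD 0.1) so the
#: fixed effects are the dominant signal; strong-field behaviour is exercised
#: separately by the spatial-confounding study.
TRUTH_HYPERS = {"kappa": 3.0, "pi": 0.3, "tau_eps": 30.0, "tau_s": 100.0, "tau_z": 100.0}


def study_design(nrows: int, ncols: int, seed: int, spec: ModelSpec | None = None):
    """A synthetic area with its standardised covariates and GMRF structures."""
    spec = spec or ModelSpec()
    land = generate_landscape(LandscapeConfig(nrows=nrows, ncols=ncols, n_paddocks=3 + nrows // 20), seed=seed)
    grid = land.grid
    slope = slope_from_dem(land.dem, grid)
    aspect = aspect_from_dem(land.dem, grid)
    insol = insolation(slope, aspect, land.latitude, season=("2011-06-15", "2011-07-15"))
    sched = generate_rotation(land, period_days=14.0, seed=seed)
    stock = stocking_rate(sched, land.paddocks, grid)
    dists = distance_covariates(grid, land.shed, land.water)
    cov = assemble_standardize(grid, land.dem, slope, insol, land.veg, dists, stock)
    spec0, spatial, elev_struct, elev_idx = build_structures(grid.active, cov.elevation, spec)
    beta = np.array([BETA_TRUE[n] for n in cov.names])
    return {
        "landscape": land,
        "grid": grid,
        "cov": cov,
        "beta": beta,
        "spec": spec0,
        "spatial": spatial,
        "elev_struct": elev_struct,
        "elev_idx": elev_idx,
    }


def _simulate_and_fit(design, seed: int):
    th = TRUTH_HYPERS
    sim = simulate_cell_counts(
        design["cov"].X, design["beta"], kappa=th["kappa"], pi=th["pi"], tau_eps=th["tau_eps"],
        spatial=design["spatial"], tau_s=th["tau_s"],
        elev_struct=design["elev_struct"], elev_bin_idx=design["elev_idx"], tau_z=th["tau_z"],
        seed=seed,
    )
    summ = fit_positive_part(
        sim.y, np.ones(len(sim.y)), design["cov"].X, design["cov"].names, design["spec"],
        spatial=design["spatial"], elev_struct=design["elev_struct"], elev_bin_idx=design["elev_idx"],
        seed=seed,
    )
    return sim, summ


def recovery_study(seed: int = 1, nrows: int = 55, ncols: int = 55) -> dict:
    """Point recovery on one large model-simulated area.

    Returns the per-effect posterior z-scores of the truth, the fitted
    summary and the maximum absolute z across fixed effects.
    """
    design = study_design(nrows, ncols, seed=seed + 1000)
    sim, summ = _simulate_and_fit(design, seed=seed)
    truth = design["beta"][1:]
    z = (summ.effects["mean"].to_numpy() - truth) / summ.effects["sd"].to_numpy()
    return {
        "summary": summ,
        "effects": summ.effects.assign(truth=truth, z=z),
        "max_abs_z": float(np.max(np.abs(z))),
        "kappa_mean": float(summ.hypers.loc["kappa", "mean"]),
        "pi_mean": summ.pi_mean,
        "n_cells": design["grid"].n_active,
    }


def coverage_study(seed: int = 1, n_replicates: int = 50, nrows: int = 17, ncols: int = 18) -> dict:
    """95 % interval coverage of the fixed effects over replicate fits."""
    design = study_design(nrows, ncols, seed=seed + 2000)
    truth = design["beta"][1:]
    covered = total = 0
    per_rep = []
    for r in range(n_replicates):
        _, summ = _simulate_and_fit(design, seed=seed + 10 * r)
        eff = summ.effects
        c = (eff["q025"].to_numpy() <= truth) & (truth <= eff["q975"].to_numpy())
        covered += int(c.sum())
        total += len(c)
        per_rep.append(int(c.sum()))
    return {
        "coverage_pct": 100.0 * covered / total,
        "n_checks": total,
        "n_replicates": n_replicates,
        "n_cells": design["grid"].n_active,
        "per_replicate": per_rep,
    }


def confounding_study(seed: int = 1, nrows: int = 26, ncols: int = 26) -> dict:
    """Spatial-confounding contrast: non-spatial vs spatial fit.

    The linear predictor contains a smooth, trend-free nuisance surface —
    the non-linear component of the distance-to-shed field, orthogonalised
    against {1, x, y} — while the true log-distance coefficient is 0.  A
    fit ignoring spatial autocorrelation attributes the nuisance to the
    log-distance covariate (a significant, biased estimate); the fit with
    the planar RW2 term absorbs it and its interval covers the truth.
    """
    rng = np.random.default_rng(seed)
    grid = Grid(x0=0.0, y0=0.0, nrows=nrows, ncols=ncols)
    cx, cy = grid.centers()
    shed = (0.1 * ncols * 25.0, 0.5 * nrows * 25.0)
    d = np.hypot(cx - shed[0], cy - shed[1])
    logd = np.log(d + 12.5)
    logd_std = (logd - logd.mean()) / logd.std()
    X = np.column_stack([np.ones_like(logd_std), logd_std])

    # nuisance: smooth non-linear part of the distance surface, zero trend
    basis = np.column_stack([np.ones_like(cx), cx - cx.mean(), cy - cy.mean()])
    proj = basis @ np.linalg.lstsq(basis, logd_std, rcond=None)[0]
    nl = logd_std - proj
    nuisance = 0.8 * nl / nl.std()

    true_beta = 0.0
    n = grid.n_active
    eta = 1.2 + true_beta * logd_std + nuisance + rng.normal(0.0, 0.15, n)
    from scipy.stats import nbinom

    from .hurdle import nb_logp0

    mu = np.exp(eta)
    kappa = 5.0
    p = kappa / (kappa + mu)
    p0 = np.exp(nb_logp0(mu, kappa))
    u = p0 + (1 - p0) * rng.uniform(size=n)
    y = np.maximum(nbinom.ppf(np.clip(u, None, 1 - 1e-14), kappa, p).astype(int), 1)
    y[rng.uniform(size=n) < 0.2] = 0

    names = ["intercept", "log_dist_shed"]
    w = np.ones(n)
    s_ns = fit_positive_part(y, w, X, names, ModelSpec(include_spatial=False, include_elevation=False))
    spatial = scale_precision(build_rw2d_precision(grid.active))
    s_sp = fit_positive_part(y, w, X, names, ModelSpec(include_elevation=False), spatial=spatial)
    e_ns = s_ns.effects.loc["log_dist_shed"]
    e_sp = s_sp.effects.loc["log_dist_shed"]
    return {
        "nonspatial": e_ns,
        "spatial": e_sp,
        "true_beta": true_beta,
        "nonspatial_significant": e_ns["significant"] != "none",
        "nonspatial_bias": float(e_ns["mean"] - true_beta),
        "spatial_covers_truth": bool(e_sp["q025"] <= true_beta <= e_sp["q975"]),
    }


def classification_study(seed: int = 1, n_animals: int = 5, hours: float = 24.0) -> dict:
    """Sequence-held-out classification accuracy on default synthetic tracks."""
    from .classify import balance_undersample, evaluate_classifier, split_sequences, train_classifier
    from .metrics import compute_movement_metrics
    from .sim.tracks import inject_gaps, simulate_tracks

    land = generate_landscape(LandscapeConfig(nrows=32, ncols=32, n_paddocks=3), seed=seed + 3000)
    sched = generate_rotation(land, period_days=2.0, seed=seed)
    tracks, truth = simulate_tracks(land, sched, n_animals=n_animals, duration=pd.Timedelta(hours=hours), seed=seed)
    tracks = inject_gaps(tracks, fail_rate_per_h=0.15, recover_rate_per_h=2.0, seed=seed + 1)
    table = compute_movement_metrics(tracks)
    train, test = split_sequences(table, test_fraction=0.3, seed=seed)
    balanced = balance_undersample(train[train["complete"]].dropna(subset=["label"]), seed=seed)
    counts = balanced["label"].value_counts()
    model = train_classifier(balanced, seed=seed)
    confusion = evaluate_classifier(model, test)
    return {
        "model": model,
        "confusion": confusion,
        "macro_pct": confusion.macro_pct,
        "per_class_pct": confusion.per_class_pct,
        "balanced_counts": counts.to_dict(),
        "balanced_equal": bool(counts.nunique() == 1),
        "importances": model.importances(),
    }


def weights_worked_example() -> dict:
    """The two-cell gap-weight example: raw weights (5/6, 5/3), then
    renormalisation restoring sum(y w) = Y."""
    from .gridding import compute_weights, discretize
    from .sim.tracks import TrackSet

    grid = Grid(x0=0.0, y0=0.0, nrows=1, ncols=2, cell_size=25.0)
    t = pd.date_range("2011-06-15", periods=3, freq="20s")
    fixes = pd.DataFrame(
        {
            "animal_id": ["a", "a", "a"],
            "device_id": ["d", "d", "d"],
            "t": t,
            "x": [5.0, 6.0, 30.0],  # two fixes in cell 0, one in cell 1
            "y": [5.0, 6.0, 5.0],
            "state": ["grazing"] * 3,
            "g_t": [2, 2, 1],
        }
    )
    ts = TrackSet(fixes=fixes, devices=["d"], nominal_interval=20.0)
    cd = compute_weights(discretize(ts, grid))
    y = cd.counts("grazing")
    return {
        "w_raw": cd.table["w_raw_grazing"].to_numpy(),
        "w": cd.table["w_grazing"].to_numpy(),
        "sum_yw": float(np.sum(y * cd.table["w_grazing"].to_numpy())),
        "Y": int(y.sum()),
    }
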