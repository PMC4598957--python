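import numpy as np
import pandas as pd
import pytest

from alpgraze.fit import GammaPrior, ModelSpec, PosteriorSummary, fit_positive_part, significance
from alpgraze.gmrf import build_rw1_precision, build_rw2d_precision, scale_precision
from alpgraze.sim.counts import simulate_cell_counts


def test_intercept_only_degenerate_fit():
    n = 60
    y = np.full(n, 5)
    X = np.ones((n, 1))
    spec = ModelSpec(include_spatial=False, include_elevation=False, int_strategy="eb")
    summ = fit_positive_part(y, np.ones(n), X, ["intercept"], spec)
    assert summ.pi_mean == pytest.approx(1.0 / (n + 2))
    assert np.allclose(summ.fitted_mu, 5.0, rtol=0.05)


def test_pi_posterior_matches_beta_convention():
    rng = np.random.default_rng(0)
    n = 200
    y = rng.integers(1, 10, n)
    y[:70] = 0
    X = np.ones((n, 1))
    spec = ModelSpec(include_spatial=False, include_elevation=False, int_strategy="eb")
    summ = fit_positive_part(y, np.ones(n), X, ["intercept"], spec)
    assert summ.pi_mean == pytest.approx((70 + 1) / (n + 2))


def test_all_zero_counts_rejected():
    with pytest.raises(ValueError, match="positive"):
        fit_positive_part(np.zeros(10, dtype=int), np.ones(10), np.ones((10, 1)), ["intercept"],
                          ModelSpec(include_spatial=False, include_elevation=False))


def test_significance_classification():
    eff = pd.DataFrame(
        {"mean": [0.5, 0.1, -0.3], "sd": [0.1] * 3,
         "q025": [0.2, -0.1, -0.5], "q975": [0.8, 0.3, -0.1],
         "significant": ["positive", "none", "negative"]},
        index=pd.Index(["a", "b", "c"], name="effect"),
    )
    summ = PosteriorSummary(effects=eff, intercept=None, hypers=pd.DataFrame(), pi_mean=0.1, pi_sd=0.01,
                            fitted_mu=np.ones(1), theta_mode={}, theta_sd={}, log_marginal=0.0)
    assert significance(summ) == {"a": "positive", "b": "none", "c": "negative"}


@pytest.fixture(scope="module")
def small_sim():
    rng = np.random.default_rng(1)
    mask = np.ones((15, 15), bool)
    n = mask.sum()
    spatial = scale_precision(build_rw2d_precision(mask))
    elev = scale_precision(build_rw1_precision(8))
    bins = rng.integers(0, 8, n)
    X = np.column_stack([np.ones(n), rng.standard_normal(n), rng.integers(0, 2, n).astype(float)])
    beta = np.array([1.4, -0.5, 0.6])
    sim = simulate_cell_counts(X, beta, kappa=3.0, pi=0.25, tau_eps=30.0,
                               spatial=spatial, tau_s=10.0, elev_struct=elev, elev_bin_idx=bins, tau_z=30.0, seed=4)
    return dict(sim=sim, X=X, beta=beta, spatial=spatial, elev=elev, bins=bins, n=n)


def test_recovery_within_three_posterior_sds(small_sim):
    s = small_sim
    summ = fit_positive_part(
        s["sim"].y, np.ones(s["n"]), s["X"], ["intercept", "x1", "x2"], ModelSpec(),
        spatial=s["spatial"], elev_struct=s["elev"], elev_bin_idx=s["bins"],
    )
    z = (summ.effects["mean"].to_numpy() - s["beta"][1:]) / summ.effects["sd"].to_numpy()
    assert np.all(np.abs(z) < 3.0)
    assert np.all(summ.effects["q025"] <= summ.effects["mean"])
    assert np.all(summ.effects["mean"] <= summ.effects["q975"])
    assert summ.hypers.loc["kappa", "mean"] > 0


def test_scaling_prior_equivalence(small_sim):
    """Multiplying the structure by s and the prior rate by s leaves the
    fixed effects unchanged (tau -> tau/s compensates exactly)."""
    s = small_sim
    spec1 = ModelSpec(include_elevation=False, int_strategy="eb")
    summ1 = fit_positive_part(s["sim"].y, np.ones(s["n"]), s["X"], ["intercept", "x1", "x2"],
                              spec1, spatial=s["spatial"])
    factor = 4.0
    from alpgraze.gmrf import PrecisionStructure

    scaled = PrecisionStructure(
        Q=(s["spatial"].Q * factor).tocsr(), rank_deficiency=s["spatial"].rank_deficiency,
        constraints=s["spatial"].constraints, scaling=s["spatial"].scaling * factor,
    )
    pr = spec1.prior_tau_s
    spec2 = ModelSpec(include_elevation=False, int_strategy="eb",
                      prior_tau_s=GammaPrior(pr.a, pr.b * factor))
    summ2 = fit_positive_part(s["sim"].y, np.ones(s["n"]), s["X"], ["intercept", "x1", "x2"],
                              spec2, spatial=scaled)
    assert np.allclose(summ1.effects["mean"], summ2.effects["mean"], atol=1e-3)
    assert np.allclose(summ1.effects["sd"], summ2.effects["sd"], atol=1e-3)


def test_fit_model_wrapper_builds_structures(landscape, rotation, tracks):
    """The high-level entry point assembles structures from grid and
    elevation and returns a full summary for one activity."""
    from alpgraze.covariates import (
        assemble_standardize,
        aspect_from_dem,
        distance_covariates,
        insolation,
        slope_from_dem,
        stocking_rate,
    )
    from alpgraze.fit import fit_model
    from alpgraze.gridding import compute_weights, discretize

    ts, _ = tracks
    grid = landscape.grid
    cd = compute_weights(discretize(ts, grid))
    slope = slope_from_dem(landscape.dem, grid)
    insol = insolation(slope, aspect_from_dem(landscape.dem, grid), 46.8, season=("2011-07-01", "2011-07-02"))
    dists = distance_covariates(grid, landscape.shed, landscape.water)
    stock = stocking_rate(rotation, landscape.paddocks, grid)
    cov = assemble_standardize(grid, landscape.dem, slope, insol, landscape.veg, dists, stock)
    summ = fit_model(cd, cov, ModelSpec(int_strategy="eb"), activity="resting", seed=0)
    assert set(summ.effects.index) == set(cov.names) - {"intercept"}
    assert 0.0 < summ.pi_mean < 1.0
    assert len(summ.fitted_mu) == grid.n_active


def test_weights_act_as_frequency_weights():
    """Doubling a weight is equivalent to duplicating the observation."""
    rng = np.random.default_rng(3)
    n = 40
    X = np.column_stack([np.ones(n), rng.standard_normal(n)])
    y = rng.integers(1, 12, n)
    spec = ModelSpec(include_spatial=False, include_elevation=False, include_iid=False, int_strategy="eb")
    w = np.ones(n)
    w[0] = 2.0
    s1 = fit_positive_part(y, w, X, ["intercept", "x1"], spec)
    Xd = np.vstack([X, X[:1]])
    yd = np.r_[y, y[0]]
    s2 = fit_positive_part(yd, np.ones(n + 1), Xd, ["intercept", "x1"], spec)
    assert np.allclose(s1.effects["mean"], s2.effects["mean"], atol=1e-4)
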