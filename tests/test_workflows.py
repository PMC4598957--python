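import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from alpgraze.workflows import (
    DEFAULT_PRIOR,
    PRIOR_GRID,
    activity_budget,
    area_characteristics,
    area_correlations,
    daytime_bin,
    joint_ci_range,
    n_season_bins,
    season_bins,
    subset_analysis,
)

from conftest import make_trackset


def test_prior_grid_contains_reference_prior():
    match = PRIOR_GRID[(PRIOR_GRID["a"] == DEFAULT_PRIOR[0]) & (PRIOR_GRID["b"] == DEFAULT_PRIOR[1])]
    assert len(match) == 1
    assert match["U"].iloc[0] == pytest.approx(0.5)


def test_daytime_bins_are_six_from_midnight():
    t = pd.date_range("2011-06-15", periods=24 * 3, freq="h")
    bins = daytime_bin(pd.Series(t))
    assert set(bins) == set(range(6))
    assert bins[0] == 0 and bins[4] == 1 and bins[23] == 5


def test_season_partition_90_days():
    lengths = n_season_bins(90.0)
    assert lengths == [14.0] * 6 + [6.0]
    t0 = pd.Timestamp("2011-06-15")
    t = pd.Series([t0, t0 + pd.Timedelta(days=13.9), t0 + pd.Timedelta(days=14.0), t0 + pd.Timedelta(days=89.0)])
    assert season_bins(t, start=t0).tolist() == [0, 0, 1, 6]


def test_activity_budget_sums_and_single_activity():
    ts = make_trackset(np.arange(10.0), np.zeros(10), state="grazing")
    b = activity_budget(ts)
    assert b.loc["a"].sum() == pytest.approx(100.0)
    assert b.loc["a", "grazing"] == pytest.approx(100.0)
    assert b.loc["a", "resting"] == 0.0


def test_activity_budget_matches_truth_fractions(tracks):
    ts, truth = tracks
    b = activity_budget(ts)
    for aid, states in truth.states.items():
        for act in ("grazing", "resting", "walking"):
            assert b.loc[aid, act] == pytest.approx(100.0 * np.mean(states == act))
    assert np.allclose(b.sum(axis=1), 100.0)


@given(perm_seed=st.integers(0, 1000))
@settings(max_examples=20, deadline=None)
def test_budget_invariant_to_fix_order(perm_seed):
    rng = np.random.default_rng(7)
    states = rng.choice(["grazing", "resting", "walking"], size=50)
    ts = make_trackset(np.arange(50.0), np.zeros(50), state=states)
    b1 = activity_budget(ts)
    order = np.random.default_rng(perm_seed).permutation(50)
    fixes = ts.fixes.iloc[order].reset_index(drop=True)
    from alpgraze.sim.tracks import TrackSet

    ts2 = TrackSet(fixes=fixes.sort_values(["animal_id", "t"]).reset_index(drop=True), devices=ts.devices)
    b2 = activity_budget(ts2)
    pd.testing.assert_frame_equal(b1, b2)


def test_area_characteristics_hand_example(landscape, rotation):
    from alpgraze.covariates import slope_from_dem, stocking_rate

    slope = slope_from_dem(landscape.dem, landscape.grid)
    stock = stocking_rate(rotation, landscape.paddocks, landscape.grid)
    ch = area_characteristics(landscape, rotation, slope, stock)
    act = landscape.grid.active
    assert ch["slope_median"] == pytest.approx(np.median(slope[act]))
    assert ch["slope_sd"] == pytest.approx(np.std(slope[act]))
    assert ch["stocking_period_d"] == pytest.approx(2.0)
    shares = landscape.class_shares() * 100
    assert ch["share_rich_pct"] == pytest.approx(shares[1])
    assert ch["share_rich_pct"] + ch["share_sparse_pct"] <= 100.0


def test_uniform_slope_zero_sd(rotation):
    from alpgraze.sim.landscape import LandscapeConfig, generate_landscape
    from alpgraze.covariates import slope_from_dem, stocking_rate

    land = generate_landscape(LandscapeConfig(nrows=12, ncols=12, relief=0.0, n_paddocks=2), seed=0)
    sched = rotation
    slope = slope_from_dem(land.dem, land.grid)
    ch = area_characteristics(land, sched, slope, np.ones(land.grid.shape))
    assert ch["slope_sd"] == 0.0


def _effects_frame(values: dict) -> pd.DataFrame:
    rows = []
    for area, v in values.items():
        rows.append({"area": area, "activity": "grazing", "effect": "slope", "mean": v})
    return pd.DataFrame(rows)


def _chars_frame(values: dict, name="stock_median") -> pd.DataFrame:
    return pd.DataFrame({name: values}).rename_axis("area")


def test_spearman_perfect_monotone():
    areas = list("ABCDEF")
    eff = _effects_frame({a: i for i, a in enumerate(areas)})
    chars = _chars_frame({a: 10 + 2 * i for i, a in enumerate(areas)})
    rho = area_correlations(eff, chars, covariates=("slope",))
    assert rho.loc["stock_median", ("grazing", "slope")] == pytest.approx(1.0)


def test_spearman_anti_monotone():
    areas = list("ABCDEF")
    eff = _effects_frame({a: i for i, a in enumerate(areas)})
    chars = _chars_frame({a: -i**3 for i, a in enumerate(areas)})
    rho = area_correlations(eff, chars, covariates=("slope",))
    assert rho.loc["stock_median", ("grazing", "slope")] == pytest.approx(-1.0)


def test_spearman_ties_match_average_rank_oracle():
    areas = list("ABCDEF")
    x = [1.0, 2.0, 2.0, 3.0, 4.0, 5.0]
    y = [2.0, 1.0, 4.0, 3.0, 6.0, 5.0]
    eff = _effects_frame(dict(zip(areas, x)))
    chars = _chars_frame(dict(zip(areas, y)))
    rho = area_correlations(eff, chars, covariates=("slope",))

    def avg_ranks(v):
        v = np.asarray(v)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sv = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sv[j] == sv[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2 + 1
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    expect = np.corrcoef(rx, ry)[0, 1]
    assert rho.loc["stock_median", ("grazing", "slope")] == pytest.approx(expect)


@given(st.sampled_from(["exp", "cube", "logish"]))
@settings(max_examples=10, deadline=None)
def test_spearman_invariant_to_monotone_transforms(transform):
    areas = list("ABCDEF")
    rng = np.random.default_rng(11)
    x = rng.normal(size=6)
    y = rng.normal(size=6)
    f = {"exp": np.exp, "cube": lambda v: v**3, "logish": lambda v: np.log(v - v.min() + 1.0)}[transform]
    r1 = area_correlations(_effects_frame(dict(zip(areas, x))), _chars_frame(dict(zip(areas, y))), covariates=("slope",))
    r2 = area_correlations(_effects_frame(dict(zip(areas, f(x)))), _chars_frame(dict(zip(areas, y))), covariates=("slope",))
    v1 = r1.loc["stock_median", ("grazing", "slope")]
    v2 = r2.loc["stock_median", ("grazing", "slope")]
    assert v1 == pytest.approx(v2)


def test_constant_column_reported_missing():
    areas = list("ABCDEF")
    eff = _effects_frame({a: 1.0 for a in areas})
    chars = _chars_frame({a: float(i) for i, a in enumerate(areas)})
    rho = area_correlations(eff, chars, covariates=("slope",))
    assert np.isnan(rho.loc["stock_median", ("grazing", "slope")])


def test_too_few_areas_rejected():
    eff = _effects_frame({"A": 1.0, "B": 2.0})
    chars = _chars_frame({"A": 1.0, "B": 2.0})
    with pytest.raises(ValueError, match="3 areas"):
        area_correlations(eff, chars)


@pytest.fixture(scope="module")
def subset_setup(landscape, rotation, tracks):
    from alpgraze.covariates import (
        assemble_standardize,
        aspect_from_dem,
        distance_covariates,
        insolation,
        slope_from_dem,
        stocking_rate,
    )

    ts, _ = tracks
    grid = landscape.grid
    slope = slope_from_dem(landscape.dem, grid)
    aspect = aspect_from_dem(landscape.dem, grid)
    insol = insolation(slope, aspect, 46.8, season=("2011-07-01", "2011-07-03"))
    dists = distance_covariates(grid, landscape.shed, landscape.water)
    stock = stocking_rate(rotation, landscape.paddocks, grid)
    cov = assemble_standardize(grid, landscape.dem, slope, insol, landscape.veg, dists, stock)
    return ts, grid, cov


def test_minor_individual_skipped_under_10pct_rule(subset_setup):
    from alpgraze.fit import ModelSpec
    from alpgraze.sim.tracks import TrackSet

    ts, grid, cov = subset_setup
    fixes = ts.fixes.copy()
    # trim one animal to ~8 % of all observations
    keep = fixes["animal_id"] != "cow03"
    minority = fixes[fixes["animal_id"] == "cow03"].head(int(0.08 / 0.92 * keep.sum()))
    fixes = pd.concat([fixes[keep], minority]).sort_values(["animal_id", "t"]).reset_index(drop=True)
    ts2 = TrackSet(fixes=fixes, devices=ts.devices, nominal_interval=ts.nominal_interval)
    spec = ModelSpec(include_spatial=False, include_elevation=False, int_strategy="eb")
    eff, skipped = subset_analysis(ts2, grid, cov, by="individual", spec=spec)
    below = skipped[skipped["reason"].str.contains("threshold")]
    assert set(below["subset"]) == {"cow03"}
    assert (below["share"] < 0.10).all()
    assert "cow03" not in set(eff.get("subset", []))
    assert set(eff["subset"]) <= {"cow01", "cow02"}


def test_daytime_subsets_cover_observed_bins(subset_setup):
    from alpgraze.fit import ModelSpec

    ts, grid, cov = subset_setup
    spec = ModelSpec(include_spatial=False, include_elevation=False, int_strategy="eb")
    eff, skipped = subset_analysis(ts, grid, cov, by="daytime", spec=spec)
    # 3-hour tracks span exactly one 4-h bin
    observed = set(daytime_bin(ts.fixes["t"]))
    assert set(eff["subset"]) <= observed


def test_joint_ci_range_shape():
    df = pd.DataFrame(
        {"effect": ["slope", "slope"], "mean": [0.1, 0.2], "q025": [-0.1, 0.0], "q975": [0.3, 0.4]}
    )
    rng = joint_ci_range(df)
    assert rng.loc["slope", "q025_min"] == -0.1
    assert rng.loc["slope", "q975_max"] == 0.4
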