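"""Higher-level analysis procedures over the fitted activity models.

* prior-sensitivity sweep over the Gamma(a, b) grid for the scaled
  precisions of the spatial and elevation effects;
* spatial vs non-spatial comparison (same data, spatial flags off);
* subset regressions per individual, 4-h daytime bin and 14-d season bin,
  with minimum-share rules (10 % for individuals, 5 % otherwise) and
  weights recomputed per subset;
* activity budgets, per-area characteristics, and Spearman rank
  correlations between covariate effects and area characteristics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .fit import GammaPrior, ModelSpec, fit_positive_part, elevation_bins
from .gmrf import build_rw1_precision, build_rw2d_precision, scale_precision
from .gridding import ACTIVITIES, CellData, compute_weights, discretize

log = logging.getLogger(__name__)

#: Evaluated Gamma(a, b) priors for the scaled precisions, with the implied
#: marginal-SD upper limit U at tail probability 0.001.  The (1, 0.00025)
#: row is the reference prior used for headline results.
PRIOR_GRID = pd.DataFrame(
    [
        (1.0, 1.00e-05, 0.1),
        (1.0, 0.00025, 0.5),
        (1.0, 0.001, 1.0),
        (1.0, 0.0255, 5.0),
        (5.0, 0.185, 0.5),
        (12.0, 1.01, 0.5),
        (20.0, 2.24, 0.5),
    ],
    columns=["a", "b", "U"],
)
DEFAULT_PRIOR = (1.0, 0.00025)


def build_structures(grid_active: np.ndarray, elevation: np.ndarray, spec: ModelSpec):
    """Scaled RW2 (lattice) and RW1 (elevation-bin) structures for a model."""
    spatial = scale_precision(build_rw2d_precision(grid_active)) if spec.include_spatial else None
    elev_struct = elev_idx = None
    if spec.include_elevation:
        elev_idx, m = elevation_bins(elevation, spec.elevation_bin_width)
        if m >= 2:
            elev_struct = scale_precision(build_rw1_precision(m))
        else:
            spec = replace(spec, include_elevation=False)
            elev_idx = None
    return spec, spatial, elev_struct, elev_idx


def _fit_effects_row(summary, extra: dict) -> pd.DataFrame:
    eff = summary.effects.reset_index()
    for k, v in extra.items():
        eff[k] = v
    return eff


def prior_sensitivity(
    celldata: CellData,
    covariates,
    activity: str = "grazing",
    prior_grid: pd.DataFrame | None = None,
    spec: ModelSpec | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Refit one activity model under every prior of the grid.

    Returns a long effects table (one row per prior x covariate) with the
    posterior mean, 95 % interval and significance; fit failures are
    recorded (``error`` column) and the sweep continues.
    """
    grid = prior_grid if prior_grid is not None else PRIOR_GRID
    spec = spec or ModelSpec()
    spec0, spatial, elev_struct, elev_idx = build_structures(celldata.grid.active, covariates.elevation, spec)
    y = celldata.counts(activity)
    w = celldata.weights(activity)
    rows = []
    for _, pr in grid.iterrows():
        sp = replace(
            spec0,
            prior_tau_s=GammaPrior(float(pr["a"]), float(pr["b"])),
            prior_tau_z=GammaPrior(float(pr["a"]), float(pr["b"])),
        )
        label = f"a={pr['a']:g},b={pr['b']:g}"
        try:
            summ = fit_positive_part(
                y, w, covariates.X, covariates.names, sp,
                spatial=spatial, elev_struct=elev_struct, elev_bin_idx=elev_idx, seed=seed,
            )
        except Exception as exc:  # keep sweeping, record the failure
            log.warning("prior %s failed: %s", label, exc)
            rows.append(pd.DataFrame([{"prior": label, "prior_a": pr["a"], "prior_b": pr["b"], "error": str(exc)}]))
            continue
        eff = _fit_effects_row(summ, {"prior": label, "prior_a": pr["a"], "prior_b": pr["b"], "activity": activity})
        rows.append(eff)
    return pd.concat(rows, ignore_index=True)


def joint_ci_range(effects: pd.DataFrame) -> pd.DataFrame:
    """Joint range of the 95 % intervals across priors, per effect."""
    ok = effects.dropna(subset=["q025", "q975"]) if "q025" in effects else effects
    return ok.groupby("effect").agg(
        mean_min=("mean", "min"), mean_max=("mean", "max"),
        q025_min=("q025", "min"), q975_max=("q975", "max"),
    )


# -- subsets ---------------------------------------------------------------

def daytime_bin(timestamps: pd.Series) -> np.ndarray:
    """Six 4-hour bins per day, anchored at local midnight (bin 0 = 00-04 h)."""
    return (pd.DatetimeIndex(timestamps).hour // 4).to_numpy()


def season_bins(timestamps: pd.Series, start=None, bin_days: float = 14.0) -> np.ndarray:
    """Consecutive 14-day bins from the season start (last bin may be short)."""
    ts = pd.DatetimeIndex(timestamps)
    t0 = pd.Timestamp(start) if start is not None else ts.min()
    return ((ts - t0).total_seconds() // (bin_days * 86400.0)).astype(int).to_numpy()


def n_season_bins(season_days: float, bin_days: float = 14.0) -> list:
    """Bin lengths (days) partitioning a season, e.g. 90 d -> [14]*6 + [6]."""
    full = int(season_days // bin_days)
    rest = season_days - full * bin_days
    return [bin_days] * full + ([rest] if rest > 0 else [])


def subset_analysis(
    trackset,
    grid,
    covariates,
    by: str = "individual",
    activity: str = "grazing",
    spec: ModelSpec | None = None,
    season_start=None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subset regressions of one activity.

    ``by`` is ``individual`` (minimum share 10 % of all observations),
    ``daytime`` (six 4-h bins, minimum 5 %) or ``season`` (14-d periods,
    minimum 5 %).  Counts and gap weights are recomputed per subset.
    Returns ``(effects table, skipped table)``.
    """
    spec = spec or ModelSpec()
    fixes = trackset.fixes
    retained = fixes[fixes["state"].isin(ACTIVITIES)]
    n_all = len(retained)
    if by == "individual":
        keys = retained["animal_id"].to_numpy()
        threshold = 0.10
    elif by == "daytime":
        keys = daytime_bin(retained["t"])
        threshold = 0.05
    elif by == "season":
        keys = season_bins(retained["t"], start=season_start)
        threshold = 0.05
    else:
        raise ValueError("by must be individual, daytime or season")

    spec0, spatial, elev_struct, elev_idx = build_structures(grid.active, covariates.elevation, spec)
    from .sim.tracks import TrackSet

    rows, skipped = [], []
    for key in pd.unique(keys):
        sub = retained[keys == key]
        share = len(sub) / max(n_all, 1)
        if share < threshold:
            skipped.append({"by": by, "subset": key, "share": share, "reason": f"below {threshold:.0%} threshold"})
            log.info("subset %s=%s skipped (share %.1f %%)", by, key, 100 * share)
            continue
        ts = TrackSet(fixes=sub.sort_values(["animal_id", "t"]).reset_index(drop=True),
                      devices=trackset.devices, nominal_interval=trackset.nominal_interval)
        cd = compute_weights(discretize(ts, grid))
        y = cd.counts(activity)
        if (y > 0).sum() < 3:
            skipped.append({"by": by, "subset": key, "share": share, "reason": "too few positive cells"})
            continue
        try:
            summ = fit_positive_part(
                y, cd.weights(activity), covariates.X, covariates.names, spec0,
                spatial=spatial, elev_struct=elev_struct, elev_bin_idx=elev_idx, seed=seed,
            )
        except Exception as exc:
            skipped.append({"by": by, "subset": key, "share": share, "reason": f"fit failed: {exc}"})
            continue
        rows.append(_fit_effects_row(summ, {"by": by, "subset": key, "share": share, "activity": activity}))
    eff = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame()
    if eff.empty:
        log.warning("all %s subsets were skipped", by)
    return eff, pd.DataFrame(skipped)


# -- budgets, characteristics, correlations --------------------------------

def activity_budget(trackset) -> pd.DataFrame:
    """Percentage of grazing / resting / walking fixes per animal and pooled."""
    fixes = trackset.fixes
    retained = fixes[fixes["state"].isin(ACTIVITIES)]
    if len(retained) == 0:
        raise ValueError("no classified fixes on pasture")
    out = {}
    for aid, g in retained.groupby("animal_id"):
        out[aid] = {a: 100.0 * (g["state"] == a).mean() for a in ACTIVITIES}
    out["all"] = {a: 100.0 * (retained["state"] == a).mean() for a in ACTIVITIES}
    return pd.DataFrame(out).T[list(ACTIVITIES)]


def area_characteristics(landscape, schedule, slope_pct: np.ndarray, stock: np.ndarray) -> pd.Series:
    """Summary characteristics of one study area.

    Median and SD of slope and stocking rate over active cells, mean
    stocking period per paddock (d), and areal shares (%) of nutrient-rich
    and sparse-forage vegetation.
    """
    act = landscape.grid.active
    s = np.asarray(slope_pct)[act]
    r = np.asarray(stock)[act]
    dur = (schedule.entries["end"] - schedule.entries["start"]).dt.total_seconds() / 86400.0
    shares = landscape.class_shares() * 100.0
    return pd.Series(
        {
            "slope_median": float(np.median(s)),
            "slope_sd": float(np.std(s)),
            "stock_median": float(np.median(r)),
            "stock_sd": float(np.std(r)),
            "stocking_period_d": float(dur.mean()),
            "share_rich_pct": float(shares[1]),
            "share_sparse_pct": float(shares[2]),
        }
    )


HEADLINE_COVARIATES = ("slope", "stocking_rate", "nutrient-rich", "sparse")


def area_correlations(
    effects: pd.DataFrame,
    characteristics: pd.DataFrame,
    covariates=HEADLINE_COVARIATES,
) -> pd.DataFrame:
    """Spearman rank correlations of covariate effects with area characteristics.

    ``effects`` needs columns area, activity, effect, mean; ``characteristics``
    one row per area.  Only the headline covariates (those significant in
    the majority of models) are evaluated.  Ties get average ranks; a
    constant column yields a missing coefficient.
    """
    areas = sorted(characteristics.index)
    if len(areas) < 3:
        raise ValueError("need at least 3 areas for rank correlations")
    rows = []
    for act, ge in effects.groupby("activity"):
        for cov in covariates:
            sub = ge[ge["effect"] == cov].set_index("area")["mean"]
            if not set(areas) <= set(sub.index):
                continue
            vals = sub.loc[areas].to_numpy(dtype=float)
            for char in characteristics.columns:
                cv = characteristics.loc[areas, char].to_numpy(dtype=float)
                if np.ptp(vals) == 0 or np.ptp(cv) == 0:
                    rho = np.nan
                    log.warning("constant column for %s/%s vs %s; rho undefined", act, cov, char)
                else:
                    rho = float(spearmanr(vals, cv).statistic)
                rows.append({"activity": act, "effect": cov, "characteristic": char, "rho": rho})
    out = pd.DataFrame(rows)
    return out.pivot(index="characteristic", columns=["activity", "effect"], values="rho")
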