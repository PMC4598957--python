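"""Multi-lag movement metrics from GPS sequences.

Walking separates from the other behaviours already at the single-fix
speed, but resting and grazing only separate once displacement is averaged
over longer horizons (grazing is slow but continuous, resting is GPS noise
around a fixed point).  The metric set therefore combines speeds over
several lags, rolling speed statistics, turning-angle geometry and path
straightness — all computed strictly within one animal's contiguous
sequence (never across animals or across gaps larger than a tolerance).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

DEFAULT_LAGS = (1, 2, 3, 6, 9, 15)
DEFAULT_WINDOWS_MIN = (1.0, 3.0, 5.0)


def metric_columns(lags=DEFAULT_LAGS, windows_min=DEFAULT_WINDOWS_MIN) -> list:
    cols = [f"speed_lag{k}" for k in lags]
    cols += [f"step_lag{k}" for k in lags[:3]]
    for wm in windows_min:
        cols += [f"speed_mean_{wm:g}min", f"speed_sd_{wm:g}min"]
    cols += ["turn_cos", "turn_abs"]
    for wm in windows_min:
        cols += [f"turn_meancos_{wm:g}min", f"straightness_{wm:g}min", f"netdisp_{wm:g}min"]
    return cols


def _segment_metrics(g: pd.DataFrame, lags, windows_min, interval) -> pd.DataFrame:
    x = g["x"].to_numpy(dtype=float)
    y = g["y"].to_numpy(dtype=float)
    t = g["t"].astype("int64").to_numpy() / 1e9
    n = len(g)
    out = pd.DataFrame(index=g.index)
    for k in lags:
        sp = np.full(n, np.nan)
        if n > k:
            d = np.hypot(x[k:] - x[:-k], y[k:] - y[:-k])
            dt = t[k:] - t[:-k]
            sp[k:] = d / dt
        out[f"speed_lag{k}"] = sp
        if k in lags[:3]:
            st = np.full(n, np.nan)
            if n > k:
                st[k:] = np.hypot(x[k:] - x[:-k], y[k:] - y[:-k])
            out[f"step_lag{k}"] = st
    sp1 = out[f"speed_lag{lags[0]}"]
    for wm in windows_min:
        wsteps = max(int(round(wm * 60.0 / interval)), 2)
        out[f"speed_mean_{wm:g}min"] = sp1.rolling(wsteps, min_periods=wsteps).mean()
        out[f"speed_sd_{wm:g}min"] = sp1.rolling(wsteps, min_periods=wsteps).std()

    # turning angle between consecutive steps
    dx = np.diff(x)
    dy = np.diff(y)
    ang = np.arctan2(dy, dx)
    turn = np.full(n, np.nan)
    if n >= 3:
        dthe = np.diff(ang)
        turn[1:-1] = np.arctan2(np.sin(dthe), np.cos(dthe))
    out["turn_cos"] = np.cos(turn)
    out["turn_abs"] = np.abs(turn)
    tc = pd.Series(np.cos(turn), index=g.index)
    steps = pd.Series(np.r_[np.nan, np.hypot(dx, dy)], index=g.index)
    for wm in windows_min:
        wsteps = max(int(round(wm * 60.0 / interval)), 2)
        out[f"turn_meancos_{wm:g}min"] = tc.rolling(wsteps, min_periods=wsteps).mean()
        net = np.full(n, np.nan)
        if n > wsteps:
            net[wsteps:] = np.hypot(x[wsteps:] - x[:-wsteps], y[wsteps:] - y[:-wsteps])
        path = steps.rolling(wsteps, min_periods=wsteps).sum().to_numpy()
        with np.errstate(invalid="ignore", divide="ignore"):
            straight = np.where(path > 0, net / path, 0.0)
        straight[~np.isfinite(path) | ~np.isfinite(net)] = np.nan
        out[f"straightness_{wm:g}min"] = straight
        out[f"netdisp_{wm:g}min"] = net
    return out


def compute_movement_metrics(
    trackset,
    lags=DEFAULT_LAGS,
    windows_min=DEFAULT_WINDOWS_MIN,
    gap_tolerance: float = 60.0,
) -> pd.DataFrame:
    """Per-fix movement metrics, with labels when the fixes carry states.

    Returns one row per fix with identifying columns (animal_id, segment,
    t, x, y, label) plus the metric columns; rows whose windows reach over
    a sequence edge are flagged ``complete=False``.  Sequences are split
    wherever the time step exceeds ``gap_tolerance`` seconds.
    """
    if min(lags) < 1 or min(windows_min) <= 0:
        raise ValueError("lags and windows must be positive")
    fixes = trackset.fixes
    parts = []
    for aid, g in fixes.groupby("animal_id", sort=False):
        g = g.sort_values("t")
        if len(g) < 2:
            log.warning("animal %s has fewer than 2 fixes; skipped", aid)
            continue
        dt = g["t"].diff().dt.total_seconds()
        seg = (dt > gap_tolerance).cumsum()
        for sid, gs in g.groupby(seg):
            met = _segment_metrics(gs, lags, windows_min, trackset.nominal_interval)
            met.insert(0, "animal_id", aid)
            met.insert(1, "segment", f"{aid}-{sid}")
            met.insert(2, "t", gs["t"].values)
            met.insert(3, "x", gs["x"].values)
            met.insert(4, "y", gs["y"].values)
            met.insert(5, "label", gs["state"].values if "state" in gs else None)
            parts.append(met)
    if not parts:
        log.warning("no usable sequences; empty metric table")
        return pd.DataFrame(columns=["animal_id", "segment", "t", "x", "y", "label", "complete"])
    table = pd.concat(parts, ignore_index=True)
    mcols = metric_columns(lags, windows_min)
    table["complete"] = np.isfinite(table[mcols].to_numpy(dtype=float)).all(axis=1)
    return table
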