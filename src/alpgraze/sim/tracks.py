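"""Behaviour-switching GPS track simulation with dropouts.

Animals follow a three-state Markov chain (resting, grazing, walking) with
state-specific speed and turning regimes, moving as a biased correlated
random walk whose step destinations are weighted by ``exp(pref)`` of a
per-cell preference score — so the long-run occupancy favours preferred
cells log-linearly, matching the estimand of the activity regressions.
Animals are confined to the paddock open at each timestamp; recorded
positions carry isotropic Gaussian GPS noise (default sigma 3 m, the
typical absolute accuracy of herd-collar loggers at a 20 s fix interval).

:func:`inject_gaps` post-processes a track set with per-device two-state
(on/off) failure processes, producing realistic contiguous gaps, flags
fixes inside shed intervals, and recomputes ``g_t`` — the number of devices
delivering a fix at each timestamp — which drives the gap-correction
weights downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import Landscape, RotationSchedule

log = logging.getLogger(__name__)

STATES = ("resting", "grazing", "walking")


@dataclass
class BehaviourParams:
    """Movement regime of the simulated herd.

    ``transition`` is the per-fix (default 20 s) state transition matrix in
    the order (resting, grazing, walking); rows must sum to 1.  Speeds are
    means of per-step log-normal draws (m/s); ``turn_concentration`` is the
    von Mises concentration of heading persistence per state.  ``preference``
    maps covariate names to log-linear selection coefficients applied to
    candidate destination cells.
    """

    transition: np.ndarray = field(
        default_factory=lambda: np.array(
            [
                [0.995, 0.004, 0.001],
                [0.004, 0.993, 0.003],
                [0.008, 0.022, 0.970],
            ]
        )
    )
    speed_mps: tuple = (0.005, 0.15, 1.0)
    speed_cv: float = 0.4
    turn_concentration: tuple = (0.1, 1.0, 4.0)
    preference: dict = field(
        default_factory=lambda: {"slope": -0.5, "nutrient-rich": 0.5, "sparse": -1.0}
    )

    def validate(self) -> None:
        P = np.asarray(self.transition, dtype=float)
        if P.shape != (3, 3) or np.any(P < 0) or not np.allclose(P.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition matrix rows must be non-negative and sum to 1")

    def stationary(self) -> np.ndarray:
        """Stationary distribution (leading left eigenvector) of the chain."""
        P = np.asarray(self.transition, dtype=float)
        vals, vecs = np.linalg.eig(P.T)
        v = np.real(vecs[:, np.argmax(np.real(vals))])
        v = np.abs(v)
        return v / v.sum()


@dataclass
class TrackSet:
    """GPS fixes of a tracked herd.

    ``fixes`` columns: animal_id, device_id, t (UTC), x, y, state, g_t.
    Per animal, timestamps are strictly increasing.
    """

    fixes: pd.DataFrame
    devices: list
    nominal_interval: float = 20.0

    def __post_init__(self) -> None:
        if self.nominal_interval <= 0:
            raise ValueError("nominal interval must be positive")
        for aid, g in self.fixes.groupby("animal_id"):
            dt = g["t"].diff().dt.total_seconds().dropna()
            if (dt <= 0).any():
                raise ValueError(f"timestamps not strictly increasing for animal {aid}")

    def __len__(self) -> int:
        return len(self.fixes)

    @property
    def animals(self) -> list:
        return sorted(self.fixes["animal_id"].unique())


@dataclass
class SimulationTruth:
    """Ground truth behind a simulated track set."""

    preference_true: dict
    states: dict  # animal_id -> per-fix true state labels
    class_shares: np.ndarray
    params: BehaviourParams | None = None


def _preference_grid(landscape: Landscape, preference: dict) -> np.ndarray:
    """Per-cell selection score sum(coef * covariate)."""
    from ..covariates import slope_from_dem

    score = np.zeros(landscape.grid.shape)
    if "slope" in preference:
        slope = slope_from_dem(landscape.dem, landscape.grid)
        s = slope.std()
        score += preference["slope"] * (slope - slope.mean()) / (s if s > 0 else 1.0)
    if "nutrient-rich" in preference:
        score += preference["nutrient-rich"] * (landscape.veg == 1)
    if "sparse" in preference:
        score += preference["sparse"] * (landscape.veg == 2)
    return score


def _random_point_in_paddock(landscape: Landscape, pid: int, rng) -> np.ndarray:
    rows, cols = np.nonzero((landscape.paddocks == pid) & landscape.grid.active)
    i = rng.integers(len(rows))
    c = landscape.grid.cell_size
    x = landscape.grid.x0 + (cols[i] + rng.uniform()) * c
    y = landscape.grid.y0 + (rows[i] + rng.uniform()) * c
    return np.array([x, y])


def simulate_tracks(
    landscape: Landscape,
    schedule: RotationSchedule,
    n_animals: int = 3,
    params: BehaviourParams | None = None,
    gps_sigma: float = 3.0,
    interval: float = 20.0,
    duration: pd.Timedelta | None = None,
    n_candidates: int = 16,
    seed: int = 0,
) -> tuple[TrackSet, SimulationTruth]:
    """Simulate a herd's GPS fixes over (part of) the rotation season.

    Each animal runs an independent behaviour chain; at every fix interval
    it proposes ``n_candidates`` headings from a von Mises around its
    previous heading, weights the destinations by ``exp(preference)`` of
    their cell, discards destinations outside the open paddock, and moves
    with a state-specific log-normal speed.  ``duration`` limits simulation
    to the first part of the season (default: the whole schedule).
    """
    params = params or BehaviourParams()
    params.validate()
    if gps_sigma < 0:
        raise ValueError("gps_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    pref = _preference_grid(landscape, params.preference)
    grid = landscape.grid

    t0 = schedule.season_start
    t_end = schedule.season_end if duration is None else min(t0 + duration, schedule.season_end)
    n_steps = int(np.floor((t_end - t0).total_seconds() / interval))
    if n_steps < 1:
        raise ValueError("schedule window shorter than one fix interval")
    times = t0 + pd.to_timedelta(np.arange(n_steps) * interval, unit="s")
    open_pids = schedule.paddock_at(times)

    Ptrans = np.asarray(params.transition, dtype=float)
    cumP = np.cumsum(Ptrans, axis=1)
    speeds = np.asarray(params.speed_mps)
    kappas = np.asarray(params.turn_concentration)
    sig_ln = np.sqrt(np.log(1 + params.speed_cv**2))

    frames = []
    states_truth = {}
    for a in range(n_animals):
        aid = f"cow{a + 1:02d}"
        state = int(rng.integers(3))
        pid = int(open_pids[0])
        pos = _random_point_in_paddock(landscape, pid, rng)
        heading = rng.uniform(-np.pi, np.pi)
        xs = np.empty(n_steps)
        ys = np.empty(n_steps)
        sts = np.empty(n_steps, dtype=int)
        for i in range(n_steps):
            new_pid = int(open_pids[i])
            if new_pid != pid:
                pid = new_pid
                pos = _random_point_in_paddock(landscape, pid, rng)
            # record with GPS noise, clipped to the open paddock
            for _ in range(8):
                obs = pos + rng.normal(0.0, gps_sigma, 2) if gps_sigma > 0 else pos
                r, cc = grid.cell_of(obs[0], obs[1])
                if r >= 0 and landscape.paddocks[r, cc] == pid:
                    break
            else:
                obs = pos
            xs[i], ys[i], sts[i] = obs[0], obs[1], state
            # advance behaviour and position
            state = int(np.searchsorted(cumP[state], rng.uniform()))
            step = speeds[state] * interval * rng.lognormal(-0.5 * sig_ln**2, sig_ln)
            hs = heading + rng.vonmises(0.0, kappas[state], size=n_candidates)
            cx = pos[0] + step * np.cos(hs)
            cy = pos[1] + step * np.sin(hs)
            rr, ccol = grid.cell_of(cx, cy)
            ok = (rr >= 0) & (landscape.paddocks[np.clip(rr, 0, None), np.clip(ccol, 0, None)] == pid)
            if ok.any():
                wts = np.where(ok, np.exp(pref[np.clip(rr, 0, None), np.clip(ccol, 0, None)]), 0.0)
                j = int(np.searchsorted(np.cumsum(wts), rng.uniform() * wts.sum()))
                j = min(j, n_candidates - 1)
                pos = np.array([cx[j], cy[j]])
                heading = hs[j]
            # else: stay put (cornered against the fence)
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": aid,
                    "device_id": f"gps{a + 1:02d}",
                    "t": times,
                    "x": xs,
                    "y": ys,
                    "state": np.array(STATES)[sts],
                    "g_t": n_animals,
                }
            )
        )
        states_truth[aid] = np.array(STATES)[sts]
    fixes = pd.concat(frames, ignore_index=True)
    ts = TrackSet(fixes=fixes, devices=[f"gps{a + 1:02d}" for a in range(n_animals)], nominal_interval=interval)
    truth = SimulationTruth(
        preference_true=dict(params.preference),
        states=states_truth,
        class_shares=landscape.class_shares(),
        params=params,
    )
    return ts, truth


def inject_gaps(
    trackset: TrackSet,
    fail_rate_per_h: float = 0.0,
    recover_rate_per_h: float = 2.0,
    shed_intervals: list | None = None,
    seed: int = 0,
) -> TrackSet:
    """Apply device failures and shed periods to a track set.

    Each device runs a two-state (on/off) Markov process sampled at the fix
    interval: fixes while off are removed.  Fixes falling inside any shed
    interval are re-labelled ``in-shed`` (they are discarded later, at
    discretisation).  ``g_t`` is recomputed as the number of devices
    delivering a fix at each timestamp.
    """
    if fail_rate_per_h < 0 or recover_rate_per_h < 0:
        raise ValueError("failure rates must be non-negative")
    rng = np.random.default_rng(seed)
    dt_h = trackset.nominal_interval / 3600.0
    p_fail = min(fail_rate_per_h * dt_h, 1.0)
    p_recover = min(recover_rate_per_h * dt_h, 1.0)

    parts = []
    for dev, g in trackset.fixes.groupby("device_id", sort=False):
        g = g.sort_values("t")
        if p_fail > 0:
            n = len(g)
            u = rng.uniform(size=n)
            on = np.empty(n, dtype=bool)
            cur = True
            for i in range(n):
                cur = (u[i] >= p_fail) if cur else (u[i] < p_recover)
                on[i] = cur
            g = g[on]
        parts.append(g)
    out = pd.concat(parts, ignore_index=True) if parts else trackset.fixes.iloc[0:0].copy()
    if shed_intervals:
        inshed = np.zeros(len(out), dtype=bool)
        for s, e in shed_intervals:
            inshed |= ((out["t"] >= pd.Timestamp(s)) & (out["t"] < pd.Timestamp(e))).values
        out = out.copy()
        out.loc[inshed, "state"] = "in-shed"
    if len(out) == 0:
        log.warning("inject_gaps removed every fix")
        return TrackSet(fixes=out, devices=trackset.devices, nominal_interval=trackset.nominal_interval)
    gt = out.groupby("t")["device_id"].transform("nunique")
    out = out.copy()
    out["g_t"] = gt.astype(int)
    out = out.sort_values(["animal_id", "t"]).reset_index(drop=True)
    return TrackSet(fixes=out, devices=trackset.devices, nominal_interval=trackset.nominal_interval)
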