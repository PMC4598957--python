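"""Discretisation of classified fixes and gap-correction weights.

Classified GPS positions are counted per activity on the 25 m lattice
(half-open cells, so assignment is unambiguous).  Because logger failures
leave periods covered by fewer devices, each cell's count is weighted by

    w_i = gbar / gbar_i,

where ``gbar`` is the mean number of active loggers over all retained fixes
of the activity dataset and ``gbar_i`` the mean over the cell's own fixes:
cells observed while more loggers than average were running get w < 1,
cells observed during outages get w > 1.  The raw weights are then
renormalised so that ``sum_i y_i w_i`` equals the retained fix count
exactly, which makes the intensity normalisation conserve animal-time to
machine precision (the raw definition alone does not guarantee a mean
weight of 1).  Weighted counts are finally converted to stocking-equivalent
intensities R_i = N * n_i * P / A_i in LU ha^-1 yr^-1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Grid

log = logging.getLogger(__name__)

ACTIVITIES = ("grazing", "resting", "walking")


@dataclass
class CellData:
    """Per-activity counts, weights and bookkeeping on the active cells.

    ``table`` has one row per active cell (row-major order) with columns
    ``row, col, y_<activity>, w_<activity>, w_raw_<activity>,
    gbar_<activity>``; ``assignments`` keeps the per-fix cell assignment for
    weight (re-)computation on subsets.
    """

    grid: Grid
    table: pd.DataFrame
    assignments: pd.DataFrame
    totals: dict = field(default_factory=dict)
    n_dropped_outside: int = 0
    n_dropped_shed: int = 0

    def counts(self, activity: str) -> np.ndarray:
        return self.table[f"y_{activity}"].to_numpy()

    def weights(self, activity: str) -> np.ndarray:
        col = f"w_{activity}"
        if col not in self.table:
            raise KeyError(f"weights for {activity!r} not computed yet")
        return self.table[col].to_numpy()


def discretize(trackset, grid: Grid, activities=ACTIVITIES) -> CellData:
    """Assign classified fixes to lattice cells and count them per activity.

    In-shed fixes are discarded; fixes outside the grid (or on inactive
    cells) are dropped with a counted warning.  Per-fix logger counts
    ``g_t`` travel along in ``assignments`` for the weighting step.
    """
    fixes = trackset.fixes
    shed = fixes["state"] == "in-shed"
    n_shed = int(shed.sum())
    fixes = fixes[~shed & fixes["state"].isin(activities)]
    row, col = grid.cell_of(fixes["x"].to_numpy(), fixes["y"].to_numpy())
    inside = row >= 0
    inside &= np.where(inside, grid.active[np.clip(row, 0, None), np.clip(col, 0, None)], False)
    n_out = int((~inside).sum())
    if n_out:
        log.warning("discretize dropped %d fixes outside the active grid", n_out)

    rows_a, cols_a = np.nonzero(grid.active)
    flat_active = grid.flat_index(rows_a, cols_a)
    pos_of_flat = {f: i for i, f in enumerate(flat_active)}

    fix_flat = grid.flat_index(row[inside], col[inside])
    cell_idx = np.array([pos_of_flat[f] for f in fix_flat], dtype=int)
    asg = pd.DataFrame(
        {
            "cell": cell_idx,
            "activity": fixes["state"].to_numpy()[inside],
            "g_t": fixes["g_t"].to_numpy()[inside],
            "animal_id": fixes["animal_id"].to_numpy()[inside],
            "t": fixes["t"].to_numpy()[inside],
        }
    )
    n_cells = len(rows_a)
    table = pd.DataFrame({"row": rows_a, "col": cols_a})
    totals = {}
    for act in activities:
        y = np.bincount(asg.loc[asg["activity"] == act, "cell"], minlength=n_cells)
        table[f"y_{act}"] = y
        totals[act] = int(y.sum())
    return CellData(
        grid=grid,
        table=table,
        assignments=asg,
        totals=totals,
        n_dropped_outside=n_out,
        n_dropped_shed=n_shed,
    )


def compute_weights(celldata: CellData, activities=ACTIVITIES, renormalize: bool = True) -> CellData:
    """Gap-correction weights per activity dataset.

    ``w_raw_i = gbar / gbar_i`` from the logger counts of the retained
    fixes; with ``renormalize`` the weights are rescaled so that
    ``sum_i y_i w_i = Y`` exactly.  Cells without fixes of the activity get
    weight 1.
    """
    table = celldata.table.copy()
    asg = celldata.assignments
    if len(asg) == 0:
        raise ValueError("no retained fixes: cannot compute weights")
    for act in activities:
        sub = asg[asg["activity"] == act]
        y = table[f"y_{act}"].to_numpy()
        Y = y.sum()
        w_raw = np.ones(len(table))
        gbar_i = np.full(len(table), np.nan)
        if Y > 0:
            if (sub["g_t"] < 1).any():
                raise ValueError("retained fixes must have g_t >= 1")
            gbar = sub["g_t"].mean()
            gi = sub.groupby("cell")["g_t"].mean()
            gbar_i[gi.index] = gi.to_numpy()
            w_raw[gi.index] = gbar / gi.to_numpy()
        w = w_raw.copy()
        if renormalize and Y > 0:
            s = float(np.sum(y * w))
            w = np.where(y > 0, w * (Y / s), 1.0)
        table[f"gbar_{act}"] = gbar_i
        table[f"w_raw_{act}"] = w_raw
        table[f"w_{act}"] = w
    return CellData(
        grid=celldata.grid,
        table=table,
        assignments=asg,
        totals=dict(celldata.totals),
        n_dropped_outside=celldata.n_dropped_outside,
        n_dropped_shed=celldata.n_dropped_shed,
    )


@dataclass
class IntensityRaster:
    """Normalised activity intensity R_i in LU ha^-1 yr^-1."""

    R: np.ndarray  # shape (nrows, ncols); 0 on inactive/empty cells
    herd_lu: float
    period_yr: float
    cell_area_ha: float

    @property
    def conserved_total(self) -> float:
        """sum_i R_i * A_i, which should equal N * P."""
        return float(self.R.sum() * self.cell_area_ha)


def normalize_intensity(celldata: CellData, activity: str, herd_lu: float, period_days: float) -> IntensityRaster:
    """Convert weighted counts to intensities R_i = (N * n_i * P) / A_i.

    ``n_i = (y_i / Y) * w_i`` is the weighted share of animal-time in cell
    i, N the herd size (LU), P the grazing period in years (days / 365),
    A_i the cell area in hectares.  With renormalised weights the total
    animal-time is conserved: ``sum_i R_i A_i = N * P`` exactly.
    """
    if herd_lu <= 0 or period_days <= 0:
        raise ValueError("herd size and grazing period must be positive")
    y = celldata.counts(activity).astype(float)
    Y = y.sum()
    if Y <= 0:
        raise ValueError(f"no retained {activity} fixes")
    w = celldata.weights(activity)
    n_i = (y / Y) * w
    P_yr = period_days / 365.0
    A_ha = celldata.grid.cell_area_ha
    R = np.zeros(celldata.grid.shape)
    R[celldata.table["row"], celldata.table["col"]] = herd_lu * n_i * P_yr / A_ha
    return IntensityRaster(R=R, herd_lu=float(herd_lu), period_yr=P_yr, cell_area_ha=A_ha)
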