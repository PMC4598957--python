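"""Environmental and management covariates on the analysis grid.

Seven candidate drivers of activity intensity are derived per cell:
elevation, terrain slope (%), potential insolation, forage-quality class,
log-distance to the shed, log-distance to the nearest water source, and
paddock stocking rate (LU ha^-1 yr^-1).  They span a gradient of human
control: none for terrain, some for vegetation and shed placement, strong
for water points and rotation.  Continuous covariates are centred and
standardised over active cells; forage quality is dummy-coded against the
nutrient-poor baseline; elevation is kept unstandardised because it enters
the model only through the non-linear RW1 effect.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import Grid

log = logging.getLogger(__name__)

FORAGE_CLASSES = ("nutrient-poor", "nutrient-rich", "sparse")


def _horn_gradients(dem: np.ndarray, cell_size: float):
    """Horn 3x3 finite-difference gradients (dz/dx eastwards, dz/dy northwards).

    Edges use one-sided differences via odd-reflection padding (linear
    extrapolation of the margin)."""
    z = np.pad(np.asarray(dem, dtype=float), 1, mode="reflect", reflect_type="odd")
    c = z[:-2, 2:] + 2 * z[1:-1, 2:] + z[2:, 2:]  # east column
    a = z[:-2, :-2] + 2 * z[1:-1, :-2] + z[2:, :-2]  # west column
    n = z[2:, :-2] + 2 * z[2:, 1:-1] + z[2:, 2:]  # north row (row index grows northwards)
    s = z[:-2, :-2] + 2 * z[:-2, 1:-1] + z[:-2, 2:]  # south row
    p = (c - a) / (8.0 * cell_size)
    q = (n - s) / (8.0 * cell_size)
    return p, q


def slope_from_dem(dem: np.ndarray, grid: Grid) -> np.ndarray:
    """Terrain slope in percent (100 * tan of the steepest-descent angle)."""
    dem = np.asarray(dem, dtype=float)
    if dem.shape != grid.shape:
        raise ValueError("DEM shape does not match grid")
    if not np.all(np.isfinite(dem[grid.active])):
        raise ValueError("DEM has missing values inside the active mask")
    p, q = _horn_gradients(dem, grid.cell_size)
    return 100.0 * np.hypot(p, q)


def aspect_from_dem(dem: np.ndarray, grid: Grid) -> np.ndarray:
    """Downslope azimuth in radians, clockwise from north; 0 for flat cells."""
    p, q = _horn_gradients(np.asarray(dem, dtype=float), grid.cell_size)
    return np.arctan2(-p, -q) % (2 * np.pi)


def _solar_position(latitude_rad: float, day_of_year, hour):
    """(cos zenith, solar azimuth from north) for given days/hours (UTC~solar)."""
    decl = np.deg2rad(23.45) * np.sin(2 * np.pi * (284 + day_of_year) / 365.0)
    H = np.deg2rad(15.0 * (hour - 12.0))  # hour angle
    sin_alt = np.sin(latitude_rad) * np.sin(decl) + np.cos(latitude_rad) * np.cos(decl) * np.cos(H)
    cos_z = sin_alt
    # azimuth measured from north, clockwise
    az = np.arctan2(
        np.sin(H),
        np.cos(H) * np.sin(latitude_rad) - np.tan(decl) * np.cos(latitude_rad),
    ) + np.pi
    return cos_z, az


def insolation(
    slope_pct: np.ndarray,
    aspect_rad: np.ndarray,
    latitude: float,
    season: tuple = ("2011-06-15", "2011-09-15"),
    step_hours: float = 1.0,
    solar_constant: float = 1.361,  # kW m^-2
    transmittance: float = 0.7,
) -> np.ndarray:
    """Potential (clear-sky, direct-beam) insolation over a season, kWh m^-2.

    For every time step with the sun above the horizon the direct normal
    irradiance ``S0 * T^(1/cos z)`` is projected onto the cell surface
    (slope/aspect normal) and accumulated; no cast shadows or diffuse term.
    """
    if not -90.0 <= latitude <= 90.0:
        raise ValueError("latitude out of range")
    slope_pct = np.asarray(slope_pct, dtype=float)
    aspect_rad = np.asarray(aspect_rad, dtype=float)
    beta = np.arctan(slope_pct / 100.0)
    cos_b, sin_b = np.cos(beta), np.sin(beta)
    lat = np.deg2rad(latitude)

    t0, t1 = pd.Timestamp(season[0]), pd.Timestamp(season[1])
    days = pd.date_range(t0, t1, freq="D")
    if len(days) == 0:
        raise ValueError("empty season")
    total = np.zeros_like(slope_pct)
    hours = np.arange(0.0, 24.0, step_hours)
    for day in days.dayofyear:
        cos_z, az = _solar_position(lat, float(day), hours)
        up = cos_z > 1e-3
        for cz, a in zip(cos_z[up], az[up]):
            sin_z = np.sqrt(1.0 - cz**2)
            dni = solar_constant * transmittance ** (1.0 / cz)
            cos_inc = cz * cos_b + sin_z * sin_b * np.cos(a - aspect_rad)
            total += dni * np.clip(cos_inc, 0.0, None) * step_hours
    return total


def classify_forage(veg_types: np.ndarray, lookup: dict, grid: Grid, rarity_threshold: int = 0):
    """Reclassify a vegetation-type raster into the three forage classes.

    ``lookup`` maps each vegetation code to a class name (or to a
    ``(type name, class name)`` tuple).  If the nutrient-poor class covers
    fewer active cells than ``rarity_threshold`` it is merged into
    nutrient-rich (it is then too rare to support inference as the model
    baseline); the merge is reported in the returned flag.
    """
    veg_types = np.asarray(veg_types)
    classes = np.zeros(grid.shape, dtype=int)
    codes = np.unique(veg_types[grid.active])
    code_to_class = {}
    for code in codes:
        if code not in lookup:
            raise KeyError(f"vegetation code {code!r} missing from the lookup table")
        entry = lookup[code]
        cname = entry[1] if isinstance(entry, (tuple, list)) else entry
        if cname not in FORAGE_CLASSES:
            raise ValueError(f"unknown forage class {cname!r} for code {code!r}")
        code_to_class[code] = FORAGE_CLASSES.index(cname)
    for code, k in code_to_class.items():
        classes[veg_types == code] = k

    merged = False
    if rarity_threshold > 0:
        counts = {k: int(np.sum(classes[grid.active] == k)) for k in range(3)}
        for k, cnt in counts.items():
            if cnt < rarity_threshold:
                log.warning("forage class %r covers only %d active cells", FORAGE_CLASSES[k], cnt)
        if counts[0] < rarity_threshold:
            classes[classes == 0] = 1
            merged = True
            log.warning("nutrient-poor class too rare; merged into nutrient-rich")
    return classes, merged


def distance_covariates(grid: Grid, shed: tuple, water: list) -> pd.DataFrame:
    """Euclidean and log distances from active-cell centres to shed and water.

    The log transform uses an offset of half a cell size, ``log(d + c/2)``,
    so a cell containing the feature itself stays finite.
    """
    if len(water) < 1:
        raise ValueError("at least one water point required")
    cx, cy = grid.centers()
    d_shed = np.hypot(cx - shed[0], cy - shed[1])
    wpts = np.asarray(water, dtype=float)
    d_water = np.min(np.hypot(cx[:, None] - wpts[None, :, 0], cy[:, None] - wpts[None, :, 1]), axis=1)
    off = grid.cell_size / 2.0
    return pd.DataFrame(
        {
            "dist_shed": d_shed,
            "dist_water": d_water,
            "log_dist_shed": np.log(d_shed + off),
            "log_dist_water": np.log(d_water + off),
        }
    )


def stocking_rate(schedule, paddocks: np.ndarray, grid: Grid) -> np.ndarray:
    """Average stocking rate raster in LU ha^-1 yr^-1.

    Per paddock: sum over rotation entries of LU * (duration / 365 d),
    divided by the paddock area in hectares; broadcast to its cells.
    Never-stocked paddocks get 0.
    """
    paddocks = np.asarray(paddocks)
    rate = np.zeros(grid.shape, dtype=float)
    areas = {}
    for pid in np.unique(paddocks[grid.active]):
        areas[pid] = np.sum((paddocks == pid) & grid.active) * grid.cell_area_ha
    per_paddock = {}
    for _, row in schedule.entries.iterrows():
        pid = int(row["paddock_id"])
        if pid not in areas:
            raise KeyError(f"scheduled paddock {pid} not on the map")
        if areas[pid] <= 0:
            raise ValueError(f"paddock {pid} has zero area")
        dur_yr = (row["end"] - row["start"]).total_seconds() / 86400.0 / 365.0
        per_paddock[pid] = per_paddock.get(pid, 0.0) + row["lu"] * dur_yr / areas[pid]
    for pid, r in per_paddock.items():
        rate[(paddocks == pid)] = r
    return rate


@dataclass
class CovariateTable:
    """Per-active-cell covariates and the standardised design matrix."""

    df: pd.DataFrame  # raw covariate values per active cell (row-major order)
    X: np.ndarray  # design matrix with leading intercept column
    names: list  # column names of X ("intercept" first)
    elevation: np.ndarray  # unstandardised, for RW1 binning
    baseline_class: str
    scaling: dict = field(default_factory=dict)  # name -> (mean, sd)


CONTINUOUS = ["slope", "insolation", "log_dist_shed", "log_dist_water", "stocking_rate"]


def assemble_standardize(
    grid: Grid,
    dem: np.ndarray,
    slope_pct: np.ndarray,
    insol: np.ndarray,
    forage_class: np.ndarray,
    dist_df: pd.DataFrame,
    stock: np.ndarray,
) -> CovariateTable:
    """Assemble the standardised design matrix over active cells.

    Continuous covariates are centred/scaled to mean 0, SD 1; forage dummies
    stay 0/1 with the nutrient-poor baseline (or nutrient-rich if poor is
    absent, e.g. after a rarity merge); elevation is carried along raw.
    """
    act = grid.active
    df = pd.DataFrame(
        {
            "elevation": np.asarray(dem)[act],
            "slope": np.asarray(slope_pct)[act],
            "insolation": np.asarray(insol)[act],
            "forage": np.asarray(forage_class)[act],
            "log_dist_shed": dist_df["log_dist_shed"].to_numpy(),
            "log_dist_water": dist_df["log_dist_water"].to_numpy(),
            "stocking_rate": np.asarray(stock)[act],
        }
    )
    cols = [np.ones(len(df))]
    names = ["intercept"]
    scaling = {}
    for name in CONTINUOUS:
        v = df[name].to_numpy(dtype=float)
        sd = v.std()
        if sd <= 0:
            raise ValueError(f"covariate {name!r} has zero variance over active cells")
        cols.append((v - v.mean()) / sd)
        scaling[name] = (float(v.mean()), float(sd))
        names.append(name)
    present = sorted(set(df["forage"]))
    baseline = 0 if 0 in present else 1
    for k in present:
        if k == baseline:
            continue
        cols.append((df["forage"] == k).astype(float).to_numpy())
        names.append(FORAGE_CLASSES[k])
    X = np.column_stack(cols)
    return CovariateTable(
        df=df,
        X=X,
        names=names,
        elevation=df["elevation"].to_numpy(),
        baseline_class=FORAGE_CLASSES[baseline],
        scaling=scaling,
    )
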