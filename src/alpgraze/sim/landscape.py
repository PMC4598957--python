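"""Synthetic subalpine landscapes and paddock rotations.

Emulates the setting of a summer-grazing area: a smooth DEM in the
1,300-2,300 m range, spatially autocorrelated vegetation reclassified into
three forage-quality classes (nutrient-poor, nutrient-rich, sparse forage),
a shed, water points, and a paddock partition grazed sequentially by a herd
of known size.  Everything is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from ..grids import Grid

FORAGE_CLASSES = ("nutrient-poor", "nutrient-rich", "sparse")

#: Synthetic vegetation-type catalogue (22 generic alliance-level types) with
#: its forage-quality lookup.  The names are generic stand-ins constructed for
#: simulation and tests, not a survey nomenclature.
SYNTHETIC_VEG_LOOKUP: dict[int, tuple[str, str]] = {
    0: ("nardus-grassland", "nutrient-poor"),
    1: ("dry-calcareous-grassland", "nutrient-poor"),
    2: ("acidic-dwarf-sedge-sward", "nutrient-poor"),
    3: ("windedge-cushion-sward", "nutrient-poor"),
    4: ("matgrass-heath", "nutrient-poor"),
    5: ("unfertilized-hay-meadow", "nutrient-poor"),
    6: ("oligotrophic-pasture", "nutrient-poor"),
    7: ("fertilized-pasture", "nutrient-rich"),
    8: ("crested-dogstail-pasture", "nutrient-rich"),
    9: ("tall-herb-community", "nutrient-rich"),
    10: ("resting-place-flora", "nutrient-rich"),
    11: ("fat-meadow", "nutrient-rich"),
    12: ("snowbed-community", "nutrient-rich"),
    13: ("moist-eutrophic-meadow", "nutrient-rich"),
    14: ("spruce-forest", "sparse"),
    15: ("open-larch-forest", "sparse"),
    16: ("green-alder-shrub", "sparse"),
    17: ("dwarf-shrub-heath", "sparse"),
    18: ("rock-outcrop", "sparse"),
    19: ("scree", "sparse"),
    20: ("fen-sedge-bed", "sparse"),
    21: ("wetland-sedge-mire", "sparse"),
}


@dataclass
class LandscapeConfig:
    """Configuration of :func:`generate_landscape`.

    ``class_shares`` are the target areal fractions of the three forage
    classes (nutrient-poor, nutrient-rich, sparse); they must sum to 1.
    ``relief`` is the elevation range in metres (0 gives flat terrain).
    """

    nrows: int = 48
    ncols: int = 48
    cell_size: float = 25.0
    x0: float = 0.0
    y0: float = 0.0
    relief: float = 400.0
    z_min: float = 1700.0
    smoothness: float = 6.0  # Gaussian filter sigma, in cells
    class_shares: tuple = (0.35, 0.45, 0.20)
    n_water: int = 3
    n_paddocks: int = 4
    latitude: float = 46.8


@dataclass
class Landscape:
    """A synthetic study area on the analysis grid."""

    grid: Grid
    dem: np.ndarray  # elevation (m), shape (nrows, ncols)
    veg: np.ndarray  # forage class index into FORAGE_CLASSES
    veg_types: np.ndarray  # synthetic vegetation-type codes (SYNTHETIC_VEG_LOOKUP)
    shed: tuple  # (x, y) m
    water: list  # [(x, y), ...]
    paddocks: np.ndarray  # paddock id per cell, shape (nrows, ncols)
    latitude: float

    def __post_init__(self) -> None:
        act = self.grid.active
        if not np.all(np.isfinite(self.dem[act])):
            raise ValueError("DEM must be finite on active cells")
        if not np.all(np.isin(self.veg[act], np.arange(len(FORAGE_CLASSES)))):
            raise ValueError("vegetation raster contains unknown forage classes")
        if np.any(self.paddocks[act] < 0):
            raise ValueError("every active cell needs a paddock id")
        if len(self.water) < 1:
            raise ValueError("at least one water point required")

    @property
    def n_paddocks(self) -> int:
        return int(self.paddocks[self.grid.active].max()) + 1

    def paddock_areas_ha(self) -> pd.Series:
        ids, counts = np.unique(self.paddocks[self.grid.active], return_counts=True)
        return pd.Series(counts * self.grid.cell_area_ha, index=ids, name="area_ha")

    def class_shares(self) -> np.ndarray:
        """Realised areal fraction of each forage class over active cells."""
        v = self.veg[self.grid.active]
        return np.array([(v == k).mean() for k in range(len(FORAGE_CLASSES))])


def _smooth_field(shape, sigma, rng):
    f = gaussian_filter(rng.standard_normal(shape), sigma, mode="reflect")
    s = f.std()
    return f / s if s > 0 else f


def generate_landscape(config: LandscapeConfig = LandscapeConfig(), seed: int = 0) -> Landscape:
    """Generate a seeded synthetic landscape.

    The DEM is Gaussian-filtered white noise rescaled to ``relief`` metres
    above ``z_min`` (plus a gentle regional tilt); vegetation classes are
    obtained by thresholding an independent smoothed field at the quantiles
    of the target class shares, which makes them spatially autocorrelated
    with realised shares close to the targets.
    """
    cfg = config
    if cfg.nrows < 8 or cfg.ncols < 8:
        raise ValueError("grid must be at least 8x8")
    shares = np.asarray(cfg.class_shares, dtype=float)
    if abs(shares.sum() - 1.0) > 1e-9:
        raise ValueError("class shares must sum to 1")
    if np.any(shares < 0):
        raise ValueError("class shares must be non-negative")
    if cfg.n_paddocks < 1:
        raise ValueError("need at least one paddock")
    if cfg.n_paddocks > cfg.nrows * cfg.ncols:
        raise ValueError("more paddocks than cells")
    rng = np.random.default_rng(seed)
    grid = Grid(x0=cfg.x0, y0=cfg.y0, nrows=cfg.nrows, ncols=cfg.ncols, cell_size=cfg.cell_size)

    # DEM: smooth noise plus a regional tilt, scaled to the target range
    rough = _smooth_field((cfg.nrows, cfg.ncols), cfg.smoothness, rng)
    jj, ii = np.meshgrid(np.arange(cfg.ncols), np.arange(cfg.nrows))
    tilt = (ii - ii.mean()) / max(cfg.nrows, 1)
    raw = rough + 1.0 * tilt
    if cfg.relief > 0 and np.ptp(raw) > 0:
        dem = cfg.z_min + (raw - raw.min()) / np.ptp(raw) * cfg.relief
    else:
        dem = np.full((cfg.nrows, cfg.ncols), cfg.z_min, dtype=float)

    # forage classes by quantile-thresholding a smooth field
    vf = _smooth_field((cfg.nrows, cfg.ncols), cfg.smoothness, rng)
    qs = np.cumsum(shares)[:-1]
    cuts = np.quantile(vf, qs)
    veg = np.digitize(vf, cuts)

    # subdivide each class into synthetic vegetation types
    tf = _smooth_field((cfg.nrows, cfg.ncols), max(cfg.smoothness / 2, 1.0), rng)
    by_class = {0: range(0, 7), 1: range(7, 14), 2: range(14, 22)}
    veg_types = np.zeros_like(veg)
    for k, codes in by_class.items():
        codes = np.array(list(codes))
        sel = veg == k
        if not sel.any():
            continue
        sub = np.digitize(tf[sel], np.quantile(tf[sel], np.linspace(0, 1, len(codes) + 1)[1:-1]))
        veg_types[sel] = codes[sub]

    # shed near the southern edge, water points scattered over the area
    shed = (cfg.x0 + 0.15 * cfg.ncols * cfg.cell_size, cfg.y0 + 0.08 * cfg.nrows * cfg.cell_size)
    water = [
        (
            cfg.x0 + rng.uniform(0.1, 0.9) * cfg.ncols * cfg.cell_size,
            cfg.y0 + rng.uniform(0.1, 0.9) * cfg.nrows * cfg.cell_size,
        )
        for _ in range(max(cfg.n_water, 1))
    ]

    # paddocks: nearest-centre (Voronoi) partition of the lattice
    cr = rng.uniform(0, cfg.nrows, size=cfg.n_paddocks)
    cc = rng.uniform(0, cfg.ncols, size=cfg.n_paddocks)
    d2 = (ii[..., None] - cr[None, None, :]) ** 2 + (jj[..., None] - cc[None, None, :]) ** 2
    paddocks = np.argmin(d2, axis=2)

    return Landscape(
        grid=grid,
        dem=dem,
        veg=veg,
        veg_types=veg_types,
        shed=shed,
        water=water,
        paddocks=paddocks,
        latitude=cfg.latitude,
    )


@dataclass
class RotationSchedule:
    """Paddock rotation: which paddock holds how many livestock units when."""

    entries: pd.DataFrame  # columns paddock_id, start, end, lu

    def __post_init__(self) -> None:
        e = self.entries
        if (e["end"] <= e["start"]).any():
            raise ValueError("rotation entries must have end > start")
        for pid, g in e.groupby("paddock_id"):
            g = g.sort_values("start")
            if (g["start"].values[1:] < g["end"].values[:-1]).any():
                raise ValueError(f"overlapping entries for paddock {pid}")

    @property
    def season_start(self) -> pd.Timestamp:
        return self.entries["start"].min()

    @property
    def season_end(self) -> pd.Timestamp:
        return self.entries["end"].max()

    @property
    def total_days(self) -> float:
        return float((self.entries["end"] - self.entries["start"]).dt.total_seconds().sum() / 86400.0)

    def paddock_at(self, t) -> int:
        """Paddock open at time(s) t; -1 if none."""
        t = pd.to_datetime(t)
        scalar = not isinstance(t, (pd.DatetimeIndex, pd.Series))
        tt = pd.DatetimeIndex([t]) if scalar else pd.DatetimeIndex(t)
        out = np.full(len(tt), -1, dtype=int)
        for _, row in self.entries.iterrows():
            sel = (tt >= row["start"]) & (tt < row["end"])
            out[sel] = row["paddock_id"]
        return int(out[0]) if scalar else out


def generate_rotation(
    landscape: Landscape,
    herd_lu: float = 50.0,
    period_days: float | list = 11.0,
    start: str | pd.Timestamp = "2011-06-15",
    paddock_order: list | None = None,
    seed: int = 0,
) -> RotationSchedule:
    """Sequential rotation through the landscape's paddocks.

    One entry per paddock, occupied back-to-back for ``period_days`` each
    (scalar or per-paddock list); total grazed days equal the sum of periods.
    """
    n_p = landscape.n_paddocks
    if paddock_order is None:
        paddock_order = list(range(n_p))
    if not set(paddock_order) <= set(range(n_p)):
        raise ValueError("paddock_order refers to unknown paddocks")
    periods = np.broadcast_to(np.asarray(period_days, dtype=float), (len(paddock_order),))
    if np.any(periods <= 0):
        raise ValueError("stocking periods must be positive")
    t = pd.Timestamp(start)
    rows = []
    for pid, days in zip(paddock_order, periods):
        end = t + pd.Timedelta(days=float(days))
        rows.append({"paddock_id": int(pid), "start": t, "end": end, "lu": float(herd_lu)})
        t = end
    return RotationSchedule(entries=pd.DataFrame(rows))
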