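"""File formats: track CSVs, ESRI ASCII rasters, GeoJSON, schedules.

All tabular outputs are comma-separated UTF-8 with ISO 8601 UTC timestamps
and a provenance comment header (# key: value) so runs are traceable and
round trips are bit-exact.  Rasters use the ESRI ASCII grid format (plain
text, row-major from the north-west corner); vector features (shed, water,
paddock outlines) are GeoJSON in projected metre coordinates.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .grids import Grid

log = logging.getLogger(__name__)


def provenance_header(**meta) -> str:
    from . import __version__

    lines = [f"# alpgraze {__version__}"]
    for k, v in meta.items():
        lines.append(f"# {k}: {v}")
    return "\n".join(lines) + "\n"


def config_hash(text: str) -> str:
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, **meta) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(provenance_header(**meta))
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


# -- GPS tracks ------------------------------------------------------------

TRACK_COLUMNS = ["animal_id", "device_id", "timestamp", "x", "y", "state", "g_t"]


def write_tracks(trackset, path, **meta) -> None:
    df = trackset.fixes.rename(columns={"t": "timestamp"})[
        [c for c in TRACK_COLUMNS if c in trackset.fixes.columns or c == "timestamp"]
    ].copy()
    df["timestamp"] = pd.DatetimeIndex(df["timestamp"]).strftime("%Y-%m-%dT%H:%M:%SZ")
    write_table(df, path, nominal_interval_s=trackset.nominal_interval, **meta)


def read_tracks(path, nominal_interval: float = 20.0):
    """Read a track CSV into a TrackSet.

    Requires columns animal_id, device_id, timestamp, x, y; state and g_t
    are optional (g_t defaults to 1).  Rejects unparseable timestamps and
    duplicate (animal, timestamp) pairs, naming the offending row.
    """
    from .sim.tracks import TrackSet

    df = read_table(path)
    for col in ["animal_id", "device_id", "timestamp", "x", "y"]:
        if col not in df.columns:
            raise ValueError(f"track file {path} is missing column {col!r}")
    ts = pd.to_datetime(df["timestamp"], errors="coerce", utc=True).dt.tz_localize(None)
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna())[0])
        raise ValueError(f"unparseable timestamp in row {row + 2} of {path}: {df['timestamp'].iloc[row]!r}")
    df = df.assign(t=ts).drop(columns=["timestamp"])
    dup = df.duplicated(subset=["animal_id", "t"])
    if dup.any():
        row = int(np.flatnonzero(dup)[0])
        raise ValueError(f"duplicate (animal, timestamp) at row {row + 2} of {path}")
    if "state" not in df:
        df["state"] = pd.NA
    if "g_t" not in df:
        df["g_t"] = 1
    df = df.sort_values(["animal_id", "t"]).reset_index(drop=True)
    devices = sorted(df["device_id"].unique())
    return TrackSet(fixes=df[["animal_id", "device_id", "t", "x", "y", "state", "g_t"]], devices=devices, nominal_interval=nominal_interval)


# -- rasters (ESRI ASCII grid) ---------------------------------------------

def write_ascii_grid(arr: np.ndarray, grid: Grid, path, nodata: float = -9999.0) -> None:
    """Write a grid-aligned raster as an ESRI ASCII grid (text)."""
    arr = np.asarray(arr, dtype=float)
    if arr.shape != grid.shape:
        raise ValueError("array shape does not match grid")
    out = np.where(grid.active & np.isfinite(arr), arr, nodata)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"ncols {grid.ncols}\n")
        fh.write(f"nrows {grid.nrows}\n")
        fh.write(f"xllcorner {grid.x0:.6f}\n")
        fh.write(f"yllcorner {grid.y0:.6f}\n")
        fh.write(f"cellsize {grid.cell_size:.6f}\n")
        fh.write(f"NODATA_value {nodata:g}\n")
        for i in range(grid.nrows - 1, -1, -1):  # north to south
            fh.write(" ".join(f"{v:.6f}" for v in out[i]) + "\n")


def read_ascii_grid(path):
    """Read an ESRI ASCII grid -> (array, Grid).

    NODATA cells become NaN and are marked inactive in the returned grid.
    """
    header = {}
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines) and lines[i].split()[0].lower() in {
        "ncols", "nrows", "xllcorner", "yllcorner", "cellsize", "nodata_value"
    }:
        k, v = lines[i].split()[:2]
        header[k.lower()] = float(v)
        i += 1
    nrows, ncols = int(header["nrows"]), int(header["ncols"])
    nodata = header.get("nodata_value", -9999.0)
    data = np.loadtxt(lines[i:], dtype=float)
    data = data.reshape(nrows, ncols)[::-1]  # back to south-first rows
    mask = ~np.isclose(data, nodata)
    data = np.where(mask, data, np.nan)
    grid = Grid(
        x0=header["xllcorner"], y0=header["yllcorner"], nrows=nrows, ncols=ncols,
        cell_size=header["cellsize"], active=mask,
    )
    return data, grid


def check_alignment(raster_grid: Grid, analysis_grid: Grid) -> None:
    """Raise when a raster's geometry does not match the analysis grid."""
    a, b = raster_grid, analysis_grid
    same = (
        np.isclose(a.cell_size, b.cell_size)
        and np.isclose(a.x0, b.x0)
        and np.isclose(a.y0, b.y0)
        and a.shape == b.shape
    )
    if not same:
        raise ValueError(
            "raster geometry "
            f"(origin=({a.x0}, {a.y0}), cell={a.cell_size}, shape={a.shape}) does not match analysis grid "
            f"(origin=({b.x0}, {b.y0}), cell={b.cell_size}, shape={b.shape})"
        )


# -- vector features and schedules -----------------------------------------

def landscape_to_geojson(landscape) -> dict:
    """Shed, water points and dissolved paddock outlines as GeoJSON."""
    from shapely.geometry import Point, box, mapping
    from shapely.ops import unary_union

    grid = landscape.grid
    feats = [
        {"type": "Feature", "properties": {"kind": "shed"}, "geometry": mapping(Point(*landscape.shed))}
    ]
    for i, (x, y) in enumerate(landscape.water):
        feats.append({"type": "Feature", "properties": {"kind": "water", "id": i}, "geometry": mapping(Point(x, y))})
    c = grid.cell_size
    for pid in range(landscape.n_paddocks):
        rows, cols = np.nonzero((landscape.paddocks == pid) & grid.active)
        boxes = [box(grid.x0 + j * c, grid.y0 + i * c, grid.x0 + (j + 1) * c, grid.y0 + (i + 1) * c) for i, j in zip(rows, cols)]
        if boxes:
            feats.append(
                {"type": "Feature", "properties": {"kind": "paddock", "id": int(pid)}, "geometry": mapping(unary_union(boxes))}
            )
    return {"type": "FeatureCollection", "features": feats}


def write_geojson(obj: dict, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh)


def write_schedule(schedule, path, **meta) -> None:
    df = schedule.entries.copy()
    for col in ("start", "end"):
        df[col] = pd.DatetimeIndex(df[col]).strftime("%Y-%m-%dT%H:%M:%SZ")
    write_table(df, path, **meta)


def read_schedule(path):
    from .sim.landscape import RotationSchedule

    df = read_table(path)
    for col in ("start", "end"):
        df[col] = pd.to_datetime(df[col], utc=True).dt.tz_localize(None)
    return RotationSchedule(entries=df[["paddock_id", "start", "end", "lu"]])
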