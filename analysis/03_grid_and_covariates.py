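"""Discretise the classified fixes and derive the covariates.

Counts fixes per activity on the 25 m lattice, computes gap-correction
weights and normalised intensity rasters (LU/ha/yr), then assembles the
standardised covariate matrix (slope, insolation, forage class, log
distances, stocking rate) and the area characteristics.
"""

import logging

from _common import AREA_DIR, SEED, demo_config
from alpgraze import io
from alpgraze.covariates import (
    aspect_from_dem,
    assemble_standardize,
    classify_forage,
    distance_covariates,
    insolation,
    slope_from_dem,
    stocking_rate,
)
from alpgraze.gridding import ACTIVITIES, compute_weights, discretize, normalize_intensity
from alpgraze.sim.landscape import SYNTHETIC_VEG_LOOKUP
from alpgraze.workflows import area_characteristics
from alpgraze.sim.landscape import Landscape

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")
cfg = demo_config()

tracks = io.read_tracks(AREA_DIR / "tracks_classified.csv")
dem, grid = io.read_ascii_grid(AREA_DIR / "dem.asc")
veg_types, g2 = io.read_ascii_grid(AREA_DIR / "veg_types.asc")
io.check_alignment(g2, grid)
paddocks, _ = io.read_ascii_grid(AREA_DIR / "paddocks.asc")
sched = io.read_schedule(AREA_DIR / "schedule.csv")
import json

feats = json.loads((AREA_DIR / "features.geojson").read_text())
shed = next(f["geometry"]["coordinates"] for f in feats["features"] if f["properties"]["kind"] == "shed")
water = [f["geometry"]["coordinates"] for f in feats["features"] if f["properties"]["kind"] == "water"]

celldata = compute_weights(discretize(tracks, grid))
print(f"retained fixes per activity: {celldata.totals} "
      f"(dropped: {celldata.n_dropped_outside} outside, {celldata.n_dropped_shed} in shed)")
for act in ACTIVITIES:
    if celldata.counts(act).sum() > 0:
        R = normalize_intensity(celldata, act, herd_lu=cfg.herd_lu, period_days=sched.total_days)
        io.write_ascii_grid(R.R, grid, AREA_DIR / f"intensity_{act}.asc")
        print(f"{act}: peak intensity {R.R.max():.2f} LU/ha/yr, total {R.conserved_total:.2f} LU*yr "
              f"(= N*P = {cfg.herd_lu * sched.total_days / 365:.2f})")

slope = slope_from_dem(dem, grid)
aspect = aspect_from_dem(dem, grid)
insol = insolation(slope, aspect, cfg.latitude, season=(sched.season_start, sched.season_end))
forage, merged = classify_forage(veg_types.astype(int), SYNTHETIC_VEG_LOOKUP, grid, rarity_threshold=5)
dists = distance_covariates(grid, shed, water)
stock = stocking_rate(sched, paddocks.astype(int), grid)
cov = assemble_standardize(grid, dem, slope, insol, forage, dists, stock)

export = cov.df.copy()
export.insert(0, "row", celldata.table["row"])
export.insert(1, "col", celldata.table["col"])
for act in ACTIVITIES:
    export[f"y_{act}"] = celldata.counts(act)
    export[f"w_{act}"] = celldata.weights(act)
io.write_table(export, AREA_DIR / "cells.csv", seed=SEED, baseline=cov.baseline_class)

chars = area_characteristics(
    Landscape(grid=grid, dem=dem, veg=forage, veg_types=veg_types.astype(int), shed=tuple(shed),
              water=[tuple(w) for w in water], paddocks=paddocks.astype(int), latitude=cfg.latitude),
    sched, slope, stock,
)
io.write_table(chars.rename("value").rename_axis("characteristic").reset_index(),
               AREA_DIR / "area_characteristics.csv", seed=SEED)
print(f"covariate matrix: {cov.X.shape[0]} cells x {len(cov.names)} columns "
      f"(baseline {cov.baseline_class}{', poor merged' if merged else ''})")
print(chars.round(2).to_string())
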