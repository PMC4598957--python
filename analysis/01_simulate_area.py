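"""Simulate the demo study area: landscape, rotation and GPS tracks.

Writes the raw inputs of the analysis (tracks with true behaviour labels,
DEM, vegetation types, paddocks, schedule) under results/area_demo/ and
reports the realised data volumes.
"""

import logging

import pandas as pd

from _common import AREA_DIR, demo_config
from alpgraze import io
from alpgraze.sim.landscape import LandscapeConfig, generate_landscape, generate_rotation
from alpgraze.sim.tracks import inject_gaps, simulate_tracks

logging.basicConfig(level=logging.INFO, format="%(levelname)s %(message)s")

cfg = demo_config()
lcfg = LandscapeConfig(nrows=cfg.nrows, ncols=cfg.ncols, n_paddocks=cfg.n_paddocks,
                       class_shares=cfg.class_shares, n_water=cfg.n_water, latitude=cfg.latitude)
land = generate_landscape(lcfg, seed=cfg.seed)
sched = generate_rotation(land, herd_lu=cfg.herd_lu, period_days=cfg.period_days, seed=cfg.seed + 1)
tracks, truth = simulate_tracks(land, sched, n_animals=cfg.n_animals,
                                duration=pd.Timedelta(hours=cfg.track_hours), seed=cfg.seed + 2)
n_raw = len(tracks)
tracks = inject_gaps(tracks, fail_rate_per_h=cfg.fail_rate_per_h,
                     recover_rate_per_h=cfg.recover_rate_per_h, seed=cfg.seed + 3)

io.write_tracks(tracks, AREA_DIR / "tracks.csv", seed=cfg.seed)
io.write_ascii_grid(land.dem, land.grid, AREA_DIR / "dem.asc")
io.write_ascii_grid(land.veg_types.astype(float), land.grid, AREA_DIR / "veg_types.asc")
io.write_ascii_grid(land.paddocks.astype(float), land.grid, AREA_DIR / "paddocks.asc")
io.write_geojson(io.landscape_to_geojson(land), AREA_DIR / "features.geojson")
io.write_schedule(sched, AREA_DIR / "schedule.csv", seed=cfg.seed)

shares = land.class_shares()
print(f"area: {land.grid.n_active} cells of {land.grid.cell_area_ha} ha "
      f"({land.grid.n_active * land.grid.cell_area_ha:.0f} ha), {land.n_paddocks} paddocks")
print(f"forage shares: poor {shares[0]:.2f}, rich {shares[1]:.2f}, sparse {shares[2]:.2f}")
print(f"tracks: {n_raw} fixes simulated, {len(tracks)} retained after device dropouts "
      f"({100 * len(tracks) / n_raw:.1f} % uptime)")
print(f"wrote inputs to {AREA_DIR}")
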