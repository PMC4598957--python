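"""Pipeline configuration from a single INI-style key-value file."""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field
from pathlib import Path


@dataclass
class PipelineConfig:
    """Parsed pipeline configuration with explicit seeds everywhere."""

    out_dir: Path = Path("results")
    # simulation (synthetic study area); ignored when tracks are provided
    simulate: bool = True
    nrows: int = 48
    ncols: int = 48
    cell_size: float = 25.0
    relief: float = 400.0
    class_shares: tuple = (0.35, 0.45, 0.20)
    n_water: int = 3
    n_paddocks: int = 4
    latitude: float = 46.8
    herd_lu: float = 50.0
    period_days: float = 7.5
    n_animals: int = 3
    track_hours: float = 24.0
    gps_sigma: float = 3.0
    fail_rate_per_h: float = 0.1
    recover_rate_per_h: float = 2.0
    # optional external inputs
    tracks_path: Path | None = None
    dem_path: Path | None = None
    veg_path: Path | None = None
    # classifier
    train_fraction: float = 0.5
    n_estimators: int = 200
    # model
    activities: tuple = ("grazing", "resting", "walking")
    int_strategy: str = "grid"
    prior_a: float = 1.0
    prior_b: float = 0.00025
    run_sensitivity: bool = False
    run_subsets: bool = False
    season_days: float = 90.0
    # seeds
    seed: int = 0
    raw: dict = field(default_factory=dict)


def _get(cp, section, key, cast, default):
    if cp.has_option(section, key):
        v = cp.get(section, key)
        if cast is bool:
            return cp.getboolean(section, key)
        if cast is tuple:
            return tuple(float(x) for x in v.split(","))
        return cast(v)
    return default


def read_config(path) -> PipelineConfig:
    cp = configparser.ConfigParser()
    text = Path(path).read_text()
    cp.read_string(text)
    cfg = PipelineConfig()
    cfg.raw = {s: dict(cp[s]) for s in cp.sections()}
    g = lambda s, k, cast, d: _get(cp, s, k, cast, d)
    cfg.out_dir = Path(g("paths", "out_dir", str, "results"))
    for k in ("tracks_path", "dem_path", "veg_path"):
        v = g("paths", k.replace("_path", ""), str, None)
        setattr(cfg, k, Path(v) if v else None)
    cfg.simulate = g("simulation", "enabled", bool, cfg.tracks_path is None)
    cfg.nrows = g("simulation", "nrows", int, cfg.nrows)
    cfg.ncols = g("simulation", "ncols", int, cfg.ncols)
    cfg.cell_size = g("grid", "cell_size", float, cfg.cell_size)
    cfg.relief = g("simulation", "relief", float, cfg.relief)
    cfg.class_shares = g("simulation", "class_shares", tuple, cfg.class_shares)
    cfg.n_water = g("simulation", "n_water", int, cfg.n_water)
    cfg.n_paddocks = g("simulation", "n_paddocks", int, cfg.n_paddocks)
    cfg.latitude = g("simulation", "latitude", float, cfg.latitude)
    cfg.herd_lu = g("simulation", "herd_lu", float, cfg.herd_lu)
    cfg.period_days = g("simulation", "period_days", float, cfg.period_days)
    cfg.n_animals = g("simulation", "n_animals", int, cfg.n_animals)
    cfg.track_hours = g("simulation", "track_hours", float, cfg.track_hours)
    cfg.gps_sigma = g("simulation", "gps_sigma", float, cfg.gps_sigma)
    cfg.fail_rate_per_h = g("simulation", "fail_rate_per_h", float, cfg.fail_rate_per_h)
    cfg.recover_rate_per_h = g("simulation", "recover_rate_per_h", float, cfg.recover_rate_per_h)
    cfg.train_fraction = g("classifier", "train_fraction", float, cfg.train_fraction)
    cfg.n_estimators = g("classifier", "n_estimators", int, cfg.n_estimators)
    cfg.int_strategy = g("model", "int_strategy", str, cfg.int_strategy)
    cfg.prior_a = g("model", "prior_a", float, cfg.prior_a)
    cfg.prior_b = g("model", "prior_b", float, cfg.prior_b)
    cfg.run_sensitivity = g("model", "run_sensitivity", bool, cfg.run_sensitivity)
    cfg.run_subsets = g("model", "run_subsets", bool, cfg.run_subsets)
    cfg.seed = g("seeds", "seed", int, cfg.seed)
    return cfg
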