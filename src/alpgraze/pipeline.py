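"""End-to-end pipeline: simulate/ingest -> classify -> grid -> covariates -> fit.

Each stage logs its row/cell counts and writes CSV outputs with a
provenance header (config hash plus seeds), so reruns with identical
configuration and seeds are bitwise identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .classify import balance_undersample, classify_positions, evaluate_classifier, split_sequences, train_classifier
from .config import PipelineConfig
from .covariates import (
    aspect_from_dem,
    assemble_standardize,
    classify_forage,
    distance_covariates,
    insolation,
    slope_from_dem,
    stocking_rate,
)
from .fit import GammaPrior, ModelSpec, fit_positive_part
from .gridding import ACTIVITIES, compute_weights, discretize, normalize_intensity
from .metrics import compute_movement_metrics
from .sim.landscape import SYNTHETIC_VEG_LOOKUP, LandscapeConfig, generate_landscape, generate_rotation
from .sim.tracks import inject_gaps, simulate_tracks
from .workflows import activity_budget, area_characteristics, build_structures, prior_sensitivity, subset_analysis

log = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, exc: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {exc}")
        self.stage = stage


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run all stages and return a bundle of result objects/paths."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = io.config_hash(json.dumps(cfg.raw, sort_keys=True, default=str))
    meta = {"config_hash": chash, "seed": cfg.seed}
    bundle: dict = {"out_dir": out}

    # -- stage: simulate / ingest -----------------------------------------
    try:
        if cfg.simulate:
            lcfg = LandscapeConfig(
                nrows=cfg.nrows, ncols=cfg.ncols, cell_size=cfg.cell_size, relief=cfg.relief,
                class_shares=cfg.class_shares, n_water=cfg.n_water, n_paddocks=cfg.n_paddocks,
                latitude=cfg.latitude,
            )
            landscape = generate_landscape(lcfg, seed=cfg.seed)
            schedule = generate_rotation(landscape, herd_lu=cfg.herd_lu, period_days=cfg.period_days, seed=cfg.seed + 1)
            tracks, truth = simulate_tracks(
                landscape, schedule, n_animals=cfg.n_animals, gps_sigma=cfg.gps_sigma,
                duration=pd.Timedelta(hours=cfg.track_hours), seed=cfg.seed + 2,
            )
            tracks = inject_gaps(
                tracks, fail_rate_per_h=cfg.fail_rate_per_h, recover_rate_per_h=cfg.recover_rate_per_h,
                seed=cfg.seed + 3,
            )
            io.write_tracks(tracks, out / "tracks.csv", **meta)
            io.write_ascii_grid(landscape.dem, landscape.grid, out / "dem.asc")
            io.write_ascii_grid(landscape.veg_types.astype(float), landscape.grid, out / "veg_types.asc")
            io.write_geojson(io.landscape_to_geojson(landscape), out / "features.geojson")
            io.write_schedule(schedule, out / "schedule.csv", **meta)
            bundle.update(landscape=landscape, schedule=schedule, truth=truth)
            log.info("simulate: %d fixes, %d paddocks, season %.1f d", len(tracks), landscape.n_paddocks, schedule.total_days)
        else:
            tracks = io.read_tracks(cfg.tracks_path)
            raise NotImplementedError("external landscape ingestion requires dem/veg/schedule paths")
        grid = bundle["landscape"].grid
    except Exception as exc:  # noqa: BLE001
        raise StageError("simulate", exc) from exc

    # -- stage: classify ----------------------------------------------------
    try:
        table = compute_movement_metrics(tracks)
        train, heldout = split_sequences(table, test_fraction=1.0 - cfg.train_fraction, seed=cfg.seed + 4)
        balanced = balance_undersample(train[train["complete"]].dropna(subset=["label"]), seed=cfg.seed + 5)
        model = train_classifier(balanced, n_estimators=cfg.n_estimators, seed=cfg.seed + 6)
        confusion = evaluate_classifier(model, heldout)
        log.info("classify: %s", confusion)
        unlabeled = replace_states_with_na(tracks)
        classified = classify_positions(model, unlabeled)
        # carry the in-shed flags through (predictions only apply on pasture)
        classified.fixes.loc[tracks.fixes["state"].values == "in-shed", "state"] = "in-shed"
        io.write_tracks(classified, out / "tracks_classified.csv", **meta)
        io.write_table(confusion.matrix.reset_index(names="truth"), out / "confusion.csv", **meta, summary=str(confusion))
        bundle.update(classifier=model, confusion=confusion, tracks=classified)
    except Exception as exc:  # noqa: BLE001
        raise StageError("classify", exc) from exc

    # -- stage: gridify -----------------------------------------------------
    try:
        celldata = compute_weights(discretize(classified, grid))
        budget = activity_budget(classified)
        io.write_table(budget.reset_index(names="animal"), out / "activity_budget.csv", **meta)
        log.info("gridify: %d active cells, totals %s (dropped %d outside, %d in shed)",
                 grid.n_active, celldata.totals, celldata.n_dropped_outside, celldata.n_dropped_shed)
        for act in ACTIVITIES:
            if celldata.counts(act).sum() > 0:
                R = normalize_intensity(celldata, act, herd_lu=cfg.herd_lu, period_days=schedule.total_days)
                io.write_ascii_grid(R.R, grid, out / f"intensity_{act}.asc")
        bundle.update(celldata=celldata, budget=budget)
    except Exception as exc:  # noqa: BLE001
        raise StageError("gridify", exc) from exc

    # -- stage: covariates --------------------------------------------------
    try:
        landscape = bundle["landscape"]
        slope = slope_from_dem(landscape.dem, grid)
        aspect = aspect_from_dem(landscape.dem, grid)
        season = (schedule.season_start, schedule.season_end)
        insol = insolation(slope, aspect, landscape.latitude, season=season)
        forage, merged = classify_forage(landscape.veg_types, SYNTHETIC_VEG_LOOKUP, grid, rarity_threshold=5)
        dists = distance_covariates(grid, landscape.shed, landscape.water)
        stock = stocking_rate(schedule, landscape.paddocks, grid)
        cov = assemble_standardize(grid, landscape.dem, slope, insol, forage, dists, stock)
        export = cov.df.copy()
        export.insert(0, "row", celldata.table["row"])
        export.insert(1, "col", celldata.table["col"])
        io.write_table(export, out / "covariates.csv", **meta, baseline=cov.baseline_class, forage_merged=merged)
        chars = area_characteristics(landscape, schedule, slope, stock)
        chars_df = chars.rename("value").rename_axis("characteristic").reset_index()
        io.write_table(chars_df, out / "area_characteristics.csv", **meta)
        log.info("covariates: %d cells, baseline %s%s", grid.n_active, cov.baseline_class,
                 " (nutrient-poor merged)" if merged else "")
        bundle.update(covariates=cov, characteristics=chars, slope=slope, stock=stock)
    except Exception as exc:  # noqa: BLE001
        raise StageError("covariates", exc) from exc

    # -- stage: fit ---------------------------------------------------------
    try:
        spec = ModelSpec(
            prior_tau_s=GammaPrior(cfg.prior_a, cfg.prior_b),
            prior_tau_z=GammaPrior(cfg.prior_a, cfg.prior_b),
            int_strategy=cfg.int_strategy,
        )
        spec0, spatial, elev_struct, elev_idx = build_structures(grid.active, cov.elevation, spec)
        effects_rows, hyper_rows = [], []
        summaries = {}
        for act in ACTIVITIES:
            y = celldata.counts(act)
            if (y > 0).sum() < 10:
                log.warning("fit: too few %s cells; skipped", act)
                continue
            summ = fit_positive_part(
                y, celldata.weights(act), cov.X, cov.names, spec0,
                spatial=spatial, elev_struct=elev_struct, elev_bin_idx=elev_idx, seed=cfg.seed,
            )
            summaries[act] = summ
            eff = summ.effects.reset_index()
            eff["activity"] = act
            effects_rows.append(eff)
            hy = summ.hypers.reset_index(names="parameter")
            hy.loc[len(hy)] = ["pi", summ.pi_mean, summ.pi_sd]
            hy["activity"] = act
            hyper_rows.append(hy)
            log.info("fit %s: %s", act, {n: f"{r['mean']:.2f}" for n, r in summ.effects.iterrows()})
        io.write_table(pd.concat(effects_rows, ignore_index=True), out / "effects.csv", **meta)
        io.write_table(pd.concat(hyper_rows, ignore_index=True), out / "parameters.csv", **meta)
        bundle["summaries"] = summaries
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise StageError("fit", exc) from exc

    # -- optional stages ----------------------------------------------------
    if cfg.run_sensitivity:
        try:
            sens = prior_sensitivity(celldata, cov, activity="grazing", spec=spec, seed=cfg.seed)
            io.write_table(sens, out / "prior_sensitivity.csv", **meta)
            bundle["sensitivity"] = sens
        except Exception as exc:  # noqa: BLE001
            raise StageError("sensitivity", exc) from exc
    if cfg.run_subsets:
        try:
            for by in ("individual", "daytime", "season"):
                eff, skipped = subset_analysis(classified, grid, cov, by=by, spec=spec, seed=cfg.seed)
                if not eff.empty:
                    io.write_table(eff, out / f"subsets_{by}.csv", **meta)
                if not skipped.empty:
                    io.write_table(skipped, out / f"subsets_{by}_skipped.csv", **meta)
        except Exception as exc:  # noqa: BLE001
            raise StageError("subsets", exc) from exc
    return bundle


def replace_states_with_na(trackset):
    from .sim.tracks import TrackSet

    fixes = trackset.fixes.copy()
    fixes["state"] = pd.NA
    return TrackSet(fixes=fixes, devices=trackset.devices, nominal_interval=trackset.nominal_interval)
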