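"""End-to-end pipeline: simulate -> preprocess -> train -> detect -> map ->
phenology -> cluster -> associate.

Each stage reads the artifacts of its upstream stages from the output
directory, writes its own outputs (GeoTIFF rasters and CSV tables) plus a
``manifest.json`` recording the seed and a hash of the parameters and
inputs; a stage whose manifest is unchanged is skipped unless forced.
"""

from __future__ import annotations

import copy
import datetime as _dt
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association as assoc
from . import clustering, detector, mapping, phenology, radiometry, raster
from . import synthetic

__all__ = ["STAGES", "default_config", "demo_config", "load_config",
           "run_pipeline"]

log = logging.getLogger("bloomsat")

STAGES = ("simulate", "preprocess", "train", "detect", "map",
          "phenology", "cluster", "associate")


def default_config() -> dict:
    """Baseline pipeline configuration (a small synthetic study)."""
    return {
        "seed": 0,
        "output_dir": "bloomsat_out",
        "world": {
            "grid_rows": 20, "grid_cols": 20, "patch_pixels": 16,
            "background_fraction": 0.08, "two_peak_fraction": 0.05,
            "cloud_prob": 0.10, "n_soil_patches": 2,
            "covariate_link": {"elevation": 1.0, "slope": 0.5,
                               "tree_cover": 0.5},
            "populations": [
                {"peak_day": 60, "duration_days": 90, "amplitude": 0.9,
                 "center_row": 5.0, "center_col": 5.0, "spread_cells": 5.0},
                {"peak_day": 150, "duration_days": 80, "amplitude": 0.8,
                 "center_row": 14.0, "center_col": 14.0,
                 "spread_cells": 5.0},
                {"peak_day": 300, "duration_days": 70, "amplitude": 0.7,
                 "center_row": 5.0, "center_col": 14.0, "spread_cells": 5.0},
            ],
        },
        "scenes": {"start_year": 2017, "n_years": 4, "per_month": 1},
        "detector": {
            "kind": "cnn",  # or "color" for the deterministic rule
            "n_blocks": 2, "base_filters": 8, "dense_units": 32,
            "dropout_rate": 0.3, "learning_rate": 1e-3, "batch_size": 32,
            "epochs": 8, "max_train_patches": 1500,
            "min_clump": 9, "delta": 10,
        },
        "mapping": {"min_detections": 4, "cloud_cell_threshold": 0.5},
        "clustering": {"k": None, "k_max": 8},
        "association": {"n_boot": 100,
                        "covariates": list(synthetic.COVARIATE_NAMES)},
    }


def demo_config() -> dict:
    """The packaged demo: 20x20 grid, 48 monthly scenes, tiny detector."""
    return default_config()


def load_config(path: str | Path) -> dict:
    """Read a YAML config file, merged over the defaults."""
    with open(path) as fh:
        user = yaml.safe_load(fh) or {}
    cfg = default_config()
    _deep_update(cfg, user)
    return cfg


def _deep_update(base: dict, other: dict) -> None:
    for k, v in other.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v


def _params_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage_dir(cfg: dict, stage: str) -> Path:
    return Path(cfg["output_dir"]) / stage


def _manifest_current(stage_dir: Path, payload: dict) -> bool:
    mpath = stage_dir / "manifest.json"
    if not mpath.exists():
        return False
    try:
        return json.loads(mpath.read_text()).get("hash") == \
            _params_hash(payload)
    except json.JSONDecodeError:
        return False


def _write_manifest(stage_dir: Path, stage: str, cfg: dict,
                    payload: dict) -> None:
    stage_dir.mkdir(parents=True, exist_ok=True)
    (stage_dir / "manifest.json").write_text(json.dumps({
        "stage": stage, "seed": cfg["seed"],
        "hash": _params_hash(payload),
        "params": payload,
    }, indent=2, default=str))


def _require(cfg: dict, stage: str, filename: str) -> Path:
    path = _stage_dir(cfg, stage) / filename
    if not path.exists():
        raise FileNotFoundError(
            f"missing artifact {path}: run stage '{stage}' first")
    return path


def _world_config(cfg: dict) -> synthetic.WorldConfig:
    w = copy.deepcopy(cfg["world"])
    pops = tuple(synthetic.PopulationConfig(**p)
                 for p in w.pop("populations", []))
    return synthetic.WorldConfig(populations=pops, seed=cfg["seed"], **w)


def _scene_dates(cfg: dict) -> list[_dt.date]:
    s = cfg["scenes"]
    dates = []
    for year in range(s["start_year"], s["start_year"] + s["n_years"]):
        for month in range(1, 13):
            for k in range(s["per_month"]):
                day = min(28, 3 + k * (26 // max(1, s["per_month"])))
                dates.append(_dt.date(year, month, day))
    return dates


def _load_world(cfg: dict) -> synthetic.SyntheticWorld:
    _require(cfg, "simulate", "presence.csv")
    return synthetic.load_world(_stage_dir(cfg, "simulate"),
                                _world_config(cfg))


# ---------------------------------------------------------------------------
# stages

def _stage_simulate(cfg: dict) -> None:
    out = _stage_dir(cfg, "simulate")
    world = synthetic.generate_world(_world_config(cfg))
    synthetic.save_world(world, out)
    dates = _scene_dates(cfg)
    scene_rows = []
    transform = (world.config.x_origin_m, world.config.y_origin_m,
                 world.config.cell_size_m / world.config.patch_pixels)
    for i, date in enumerate(dates):
        scene = synthetic.render_scene(world, date,
                                       seed=cfg["seed"] * 100003 + i)
        name = f"scene_{date.isoformat()}"
        raster.write_raster(out / f"{name}.tif", scene.bands,
                            transform=transform,
                            band_names=list(radiometry.BAND_NAMES))
        raster.write_raster(out / f"{name}_cloud.tif",
                            scene.cloud_mask.astype(np.uint8),
                            transform=transform)
        scene_rows.append({"date": date.isoformat(), "file": f"{name}.tif",
                           "cloud_file": f"{name}_cloud.tif"})
    pd.DataFrame(scene_rows).to_csv(out / "scenes.csv", index=False)


def _read_scenes(cfg: dict, stage: str) -> list[radiometry.SceneStack]:
    index = pd.read_csv(_require(cfg, stage, "scenes.csv"))
    scenes = []
    for rec in index.itertuples():
        bands, _ = raster.read_raster(_stage_dir(cfg, stage) / rec.file)
        cloud, _ = raster.read_raster(
            _stage_dir(cfg, stage) / rec.cloud_file)
        scenes.append(radiometry.SceneStack(
            bands, _dt.date.fromisoformat(rec.date),
            cloud_mask=cloud.astype(bool)))
    return scenes


def _stage_preprocess(cfg: dict) -> None:
    out = _stage_dir(cfg, "preprocess")
    out.mkdir(parents=True, exist_ok=True)
    scenes = _read_scenes(cfg, "simulate")
    kept = radiometry.select_scenes(scenes)
    rows = []
    for scene in kept:
        conv = radiometry.convert_scene(scene)
        name = f"scene_{scene.date.isoformat()}"
        raster.write_raster(out / f"{name}.tif", conv.bands,
                            band_names=list(radiometry.BAND_NAMES))
        raster.write_raster(out / f"{name}_cloud.tif",
                            conv.cloud_mask.astype(np.uint8))
        rows.append({"date": scene.date.isoformat(), "file": f"{name}.tif",
                     "cloud_file": f"{name}_cloud.tif"})
    pd.DataFrame(rows).to_csv(out / "scenes.csv", index=False)
    log.info("preprocess: kept %d of %d scenes", len(kept), len(scenes))


def _detector_config(cfg: dict, core: int) -> detector.DetectorConfig:
    d = cfg["detector"]
    return detector.DetectorConfig(
        n_blocks=d["n_blocks"], base_filters=d["base_filters"],
        dense_units=d["dense_units"], dropout_rate=d["dropout_rate"],
        learning_rate=d["learning_rate"], batch_size=d["batch_size"],
        epochs=d["epochs"], input_side=core + 2 * radiometry.BORDER_PIXELS,
        seed=cfg["seed"],
    )


def _stage_train(cfg: dict) -> None:
    out = _stage_dir(cfg, "train")
    out.mkdir(parents=True, exist_ok=True)
    if cfg["detector"]["kind"] != "cnn":
        (out / "SKIPPED.txt").write_text("color-rule detector needs no "
                                         "training\n")
        return
    world = _load_world(cfg)
    scenes = _read_scenes(cfg, "preprocess")
    core = world.config.patch_pixels
    patches, labels = [], []
    for scene in scenes:
        bloom = world.bloom_mask(scene.date)
        for p in radiometry.tile_scene(scene, core=core):
            patches.append(p.pixels)
            labels.append(int(bloom[p.grid_row, p.grid_col]))
    patches = np.stack(patches)
    labels = np.array(labels)
    rng = np.random.default_rng(cfg["seed"])
    n_max = cfg["detector"]["max_train_patches"]
    if patches.shape[0] > n_max:
        # balanced subsample: keep every bloom patch, fill with background
        pos = np.nonzero(labels == 1)[0]
        neg = np.nonzero(labels == 0)[0]
        n_pos = min(pos.size, n_max // 2)
        pos = rng.choice(pos, n_pos, replace=False)
        neg = rng.choice(neg, n_max - n_pos, replace=False)
        idx = rng.permutation(np.concatenate([pos, neg]))
        patches, labels = patches[idx], labels[idx]
    dcfg = _detector_config(cfg, core)
    model = detector.build_detector(dcfg)
    model, history = detector.train_detector(model, patches, labels, dcfg)
    model.save_weights(out / "weights.npz")
    history.to_frame().to_csv(out / "history.csv", index=False)
    log.info("train: best epoch %d, weighted accuracy %.4f",
             history.best_epoch, history.best_weighted_accuracy)


def _stage_detect(cfg: dict) -> None:
    out = _stage_dir(cfg, "detect")
    out.mkdir(parents=True, exist_ok=True)
    world = _load_world(cfg)
    core = world.config.patch_pixels
    scenes = _read_scenes(cfg, "preprocess")
    kind = cfg["detector"]["kind"]
    model = None
    if kind == "cnn":
        model = detector.build_detector(_detector_config(cfg, core))
        model.load_weights(_require(cfg, "train", "weights.npz"))
    rows = []
    for scene in scenes:
        patches = radiometry.tile_scene(scene, core=core)
        grid = radiometry.grid_shape(*scene.shape, core)
        if kind == "cnn":
            preds = detector.predict_patches(
                model, np.stack([p.pixels for p in patches]))
        else:
            preds = np.array([detector.reference_color_detector(
                p.pixels, cfg["detector"]["min_clump"],
                cfg["detector"]["delta"]) for p in patches])
        presence = mapping.spatialize_predictions(preds, grid)
        name = f"presence_{scene.date.isoformat()}.tif"
        raster.write_raster(out / name, presence)
        rows.append({"date": scene.date.isoformat(), "file": name})
    pd.DataFrame(rows).to_csv(out / "detections.csv", index=False)


def _stage_map(cfg: dict) -> None:
    out = _stage_dir(cfg, "map")
    out.mkdir(parents=True, exist_ok=True)
    world = _load_world(cfg)
    core = world.config.patch_pixels
    scenes = _read_scenes(cfg, "preprocess")
    index = pd.read_csv(_require(cfg, "detect", "detections.csv"))
    presence_by_date = {
        rec.date: raster.read_raster(_stage_dir(cfg, "detect") / rec.file)[0]
        for rec in index.itertuples()}
    rasters, clouds, dates = [], [], []
    for scene in scenes:
        rasters.append(presence_by_date[scene.date.isoformat()])
        clouds.append(mapping.cell_cloud_mask(
            scene.cloud_mask, core, cfg["mapping"]["cloud_cell_threshold"]))
        dates.append(scene.date)
    series = mapping.accumulate_daily_states(rasters, clouds, dates)
    np.save(out / "states.npy", series.states)
    pd.DataFrame({"date": [d.isoformat() for d in series.dates]}).to_csv(
        out / "dates.csv", index=False)
    summary = mapping.frequency_map(series, cfg["mapping"]["min_detections"])
    raster.write_raster(out / "frequency_pct.tif",
                        np.nan_to_num(summary.frequency_pct,
                                      nan=-1.0).astype(np.float32),
                        nodata=-1.0)
    raster.write_raster(out / "n_detected.tif",
                        summary.n_detected.astype(np.uint16))
    series.to_frame().to_csv(out / "states.csv", index=False)


def _load_series(cfg: dict) -> mapping.ObservationSeries:
    states = np.load(_require(cfg, "map", "states.npy"))
    dates = [_dt.date.fromisoformat(d) for d in
             pd.read_csv(_require(cfg, "map", "dates.csv"))["date"]]
    return mapping.ObservationSeries(dates, states)


def _stage_phenology(cfg: dict) -> None:
    out = _stage_dir(cfg, "phenology")
    out.mkdir(parents=True, exist_ok=True)
    series = _load_series(cfg)
    rows, cols = series.grid_shape
    min_det = cfg["mapping"]["min_detections"]
    fit_rows, event_rows = [], []
    for r in range(rows):
        for c in range(cols):
            states = series.pixel(r, c)
            if (states == mapping.DETECTED).sum() < min_det:
                continue
            ms = phenology.monthly_series(series.dates, states)
            result = phenology.analyze_pixel(ms, min_det)
            if result is None:
                continue
            fit, daily, events = result
            pid = r * cols + c
            fit_rows.append({
                "pixel_id": pid, "bloom0": fit.bloom0, "pow0": fit.pow0,
                "p4": fit.p4, "p6": fit.p6, "p12": fit.p12,
                "rho4": fit.rho4, "rho6": fit.rho6, "rho12": fit.rho12,
                "weighted_r2": fit.weighted_r2,
            })
            for ev in events:
                event_rows.append({
                    "pixel_id": pid, "start_day": ev.start_day,
                    "peak_day": ev.peak_day, "end_day": ev.end_day,
                    "start_value": ev.start_value,
                    "peak_value": ev.peak_value,
                    "end_value": ev.end_value,
                    "duration_days": ev.duration_days,
                })
    pd.DataFrame(fit_rows).to_csv(out / "fits.csv", index=False)
    pd.DataFrame(event_rows).to_csv(out / "events.csv", index=False)
    log.info("phenology: %d pixels fitted, %d events",
             len(fit_rows), len(event_rows))


def _stage_cluster(cfg: dict) -> None:
    out = _stage_dir(cfg, "cluster")
    out.mkdir(parents=True, exist_ok=True)
    events = pd.read_csv(_require(cfg, "phenology", "events.csv"))
    world = _load_world(cfg)
    if events.empty:
        pd.DataFrame().to_csv(out / "assignments.csv", index=False)
        pd.DataFrame().to_csv(out / "clusters.csv", index=False)
        return
    table = clustering.build_feature_table(events, world.coordinates())
    model = clustering.cluster_populations(
        table, k=cfg["clustering"]["k"], k_max=cfg["clustering"]["k_max"],
        seed=cfg["seed"])
    table.assign(cluster=model.assignments).to_csv(
        out / "assignments.csv", index=False)
    model.summary().to_csv(out / "clusters.csv", index=False)
    np.savetxt(out / "within_ss_curve.csv", model.within_ss_curve,
               delimiter=",")


def _stage_associate(cfg: dict) -> None:
    out = _stage_dir(cfg, "associate")
    out.mkdir(parents=True, exist_ok=True)
    world = _load_world(cfg)
    series = _load_series(cfg)
    counts = series.counts()
    presence = counts["detected"] >= cfg["mapping"]["min_detections"]
    results = []
    for i, name in enumerate(cfg["association"]["covariates"]):
        classes = assoc.quantile_classes(world.covariates[name])
        labels = classes.labels[presence]
        res = assoc.bootstrap_association(
            labels, classes, n_boot=cfg["association"]["n_boot"],
            seed=cfg["seed"] * 1009 + i, covariate=name)
        results.append(res)
    pd.concat(results, ignore_index=True).to_csv(
        out / "association.csv", index=False)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "preprocess": _stage_preprocess,
    "train": _stage_train,
    "detect": _stage_detect,
    "map": _stage_map,
    "phenology": _stage_phenology,
    "cluster": _stage_cluster,
    "associate": _stage_associate,
}


def run_pipeline(
    config: dict,
    stages: list[str] | None = None,
    force: bool = False,
) -> Path:
    """Run the requested stages in dependency order; returns the output dir.

    A stage whose manifest (parameters + seed + upstream hashes) is
    unchanged is skipped unless ``force``.
    """
    stages = list(stages or STAGES)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    ordered = [s for s in STAGES if s in stages]
    upstream_hash = ""
    for stage in STAGES:
        payload = {"config": {k: config.get(k) for k in
                              ("seed", "world", "scenes", "detector",
                               "mapping", "clustering", "association")},
                   "stage": stage, "upstream": upstream_hash}
        sdir = _stage_dir(config, stage)
        if stage in ordered:
            if not force and _manifest_current(sdir, payload):
                log.info("%s: up to date, skipping", stage)
            else:
                t0 = time.time()
                log.info("%s: running (seed=%s)", stage, config["seed"])
                _STAGE_FUNCS[stage](config)
                _write_manifest(sdir, stage, config, payload)
                log.info("%s: done in %.1f s", stage, time.time() - t0)
        upstream_hash = _params_hash(payload)
    return Path(config["output_dir"])
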