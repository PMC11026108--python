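"""Pipeline orchestration: simulate -> preprocess -> detect events ->
resilience metrics -> urban-rural comparison -> predictors -> driver
screens -> pixel attribution.

Every stage output is a CSV with a short provenance header (config hash,
seed, stage) so a rerun with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import compare, drivers_city, drivers_pixel
from .cohort import make_driver_cohort
from .events import detect_hot_events, events_frame
from .predictors import NON_LAND_COVER_CITY_PREDICTORS, assemble_predictor_table, COLUMN_DICTIONARY
from .preprocess import deseasonalize, screen_pixels
from .resilience import compute_records, rebase_evi
from .scene import CityScene, LAND_COVER_TYPES, SceneConfig, generate_ensemble

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "preprocess", "detect_events", "metrics",
    "compare", "predictors", "drivers_city", "drivers_pixel",
)


@dataclass
class RunConfig:
    """End-to-end run settings.

    Without an explicit city list the driver cohort of ``n_cities``
    synthetic cities is used.  Threshold overrides mirror the analysis
    knobs: hot-month quantile q, event concatenation gap, pre/post
    windows.
    """

    seed: int = 0
    out_dir: str = "urbanveg_run"
    n_cities: int = 8
    n_members: int = 2
    q: float = 0.90
    gap_concat: int = 3
    pre_window: int = 3
    post_window: int = 3
    rf_trees: int = 200
    min_group_rows: int = 50
    stages: tuple[str, ...] = STAGES
    scene_overrides: dict = field(default_factory=dict)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "stages" in d:
            d["stages"] = tuple(d["stages"])
        return cls(**d)


def write_csv(df: pd.DataFrame, path: Path, run: RunConfig, stage: str) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# urbanveg stage={stage} config_hash={run.config_hash()} seed={run.seed}\n")
        df.to_csv(fh, index=False)


def read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def process_scene(
    scene: CityScene,
    q: float = 0.90,
    gap_concat: int = 3,
    pre_window: int = 3,
    post_window: int = 3,
) -> dict:
    """Single-scene pipeline core.

    Deseasonalizes EVI, detects hot events on the city-average (urban +
    rural) mean-temperature series, screens pixels, and computes the
    per-pixel-per-event resilience records on rebased EVI.
    """
    cfg = scene.config
    T = scene.n_months
    evi_flat = scene.evi.reshape(T, -1)
    anomalies, evi_clim = deseasonalize(evi_flat, cfg.years)
    long_term_mean = evi_flat.mean(axis=0)
    rebased = rebase_evi(anomalies, long_term_mean[None, :])

    city_tmean = scene.area_mean(scene.tmean)
    events, temp_clim = detect_hot_events(
        city_tmean, cfg.years, q=q, gap_concat=gap_concat,
        city_id=cfg.city_id, dataset_id=scene.dataset_id,
    )

    cropland = scene.land_cover.get("Crop", np.zeros(cfg.shape)).ravel()
    screen = screen_pixels(cropland, long_term_mean)
    area = np.full(evi_flat.shape[1], "", dtype=object)
    area[scene.urban_mask.ravel()] = "urban"
    area[scene.rural_mask.ravel()] = "rural"
    keep = screen.keep.ravel() & (area != "")

    records = compute_records(
        rebased, events,
        pre_window=pre_window, post_window=post_window,
        pixel_keep=keep, pixel_area=area,
        city_id=cfg.city_id, dataset_id=scene.dataset_id,
    )
    anomalies3d = anomalies.reshape(scene.evi.shape)
    return {
        "events": events,
        "temp_climatology": temp_clim,
        "evi_climatology": evi_clim,
        "anomalies": anomalies3d,
        "screen": screen,
        "records": records,
    }


def run_pipeline(run: RunConfig, configs: list[SceneConfig] | None = None) -> dict:
    """Execute the configured stages end to end; returns the artifact bundle
    (DataFrames) and writes one CSV per stage under run.out_dir."""
    out = Path(run.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    if configs is None:
        configs = make_driver_cohort(n_cities=run.n_cities, seed=run.seed)
    if run.scene_overrides:
        configs = [dataclasses.replace(c, **run.scene_overrides) for c in configs]

    if "simulate" not in run.stages:
        raise ValueError("pipeline needs the simulate stage (no external loader configured)")
    scenes = []
    for cfg in configs:
        scenes.extend(generate_ensemble(cfg, run.n_members))
    bundle["scenes"] = scenes
    write_csv(
        pd.DataFrame(
            {
                "city": [s.config.city_id for s in scenes],
                "dataset": [s.dataset_id for s in scenes],
                "region": [s.config.region for s in scenes],
                "n_urban": [int(s.urban_mask.sum()) for s in scenes],
                "n_rural": [int(s.rural_mask.sum()) for s in scenes],
                "n_clipped": [s.n_clipped for s in scenes],
            }
        ),
        out / "scenes.csv", run, "simulate",
    )

    needed = {"preprocess", "detect_events", "metrics", "compare", "predictors",
              "drivers_city", "drivers_pixel"} & set(run.stages)
    if not needed:
        return bundle
    for stage in ("preprocess", "detect_events", "metrics"):
        if stage not in run.stages:
            raise ValueError(f"stage '{stage}' is required by later stages but toggled off")

    processed = [
        process_scene(s, q=run.q, gap_concat=run.gap_concat,
                      pre_window=run.pre_window, post_window=run.post_window)
        for s in scenes
    ]
    bundle["processed"] = processed

    ev_frames = [
        events_frame(p["events"], start_year=s.config.start_year)
        for s, p in zip(scenes, processed)
    ]
    events_df = pd.concat(ev_frames, ignore_index=True)
    bundle["events"] = events_df
    write_csv(events_df, out / "events.csv", run, "detect_events")

    screen_df = pd.DataFrame(
        {
            "city": [s.config.city_id for s in scenes],
            "dataset": [s.dataset_id for s in scenes],
            "n_kept": [int(p["screen"].keep.sum()) for p in processed],
            "n_dropped": [int((~p["screen"].keep).sum()) for p in processed],
        }
    )
    write_csv(screen_df, out / "pixel_screen.csv", run, "preprocess")

    records = pd.concat([p["records"] for p in processed], ignore_index=True)
    bundle["records"] = records
    write_csv(records, out / "records.csv", run, "metrics")

    if "compare" in run.stages:
        region = {c.city_id: c.region for c in configs}
        summary = compare.city_season_summary(records, region=region)
        deltas = compare.event_level_deltas(records)
        bundle["summary"] = summary
        bundle["event_deltas"] = deltas
        write_csv(summary, out / "city_season_summary.csv", run, "compare")
        write_csv(deltas, out / "event_deltas.csv", run, "compare")
        (out / "report.txt").write_text(compare.seasonal_report(deltas) + "\n")

    if "predictors" in run.stages:
        city_tabs, pixel_tabs = [], []
        for s, p in zip(scenes, processed):
            c_df, px_df = assemble_predictor_table(s, p["events"], p["anomalies"], records=p["records"])
            city_tabs.append(c_df)
            pixel_tabs.append(px_df)
        city_table = pd.concat(city_tabs, ignore_index=True)
        pixel_table = pd.concat(pixel_tabs, ignore_index=True)
        bundle["city_table"] = city_table
        bundle["pixel_table"] = pixel_table
        write_csv(city_table, out / "predictors_city.csv", run, "predictors")
        write_csv(pixel_table, out / "predictors_pixel.csv", run, "predictors")
        write_csv(COLUMN_DICTIONARY, out / "predictor_dictionary.csv", run, "predictors")

    if "drivers_city" in run.stages:
        if "predictors" not in run.stages or "compare" not in run.stages:
            raise ValueError("drivers_city requires the predictors and compare stages")
        merged = bundle["city_table"].merge(
            bundle["event_deltas"], on=["city", "dataset", "event", "season"], how="inner",
        )
        screens = []
        for metric in compare.METRICS:
            sub = merged[merged["metric"] == metric]
            for response in ("delta_frac_pos", "delta_median_abs"):
                if sub[response].notna().sum() >= drivers_city.MIN_SPEARMAN_ROWS:
                    sc = drivers_city.screen_drivers(
                        sub, response, NON_LAND_COVER_CITY_PREDICTORS
                    )
                    sc.insert(0, "metric", metric)
                    screens.append(sc)
        screen_result = (
            pd.concat(screens, ignore_index=True) if screens else pd.DataFrame()
        )
        bundle["driver_screen"] = screen_result
        write_csv(screen_result, out / "drivers_city.csv", run, "drivers_city")

    if "drivers_pixel" in run.stages:
        if "predictors" not in run.stages:
            raise ValueError("drivers_pixel requires the predictors stage")
        city_lc = bundle["city_table"].groupby("city", as_index=False)[list(LAND_COVER_TYPES)].mean()
        groups = drivers_pixel.build_groups(city_lc)
        contrib_tabs = []
        for group, cities in groups.items():
            for metric in compare.METRICS:
                for target in ("sign", "magnitude"):
                    try:
                        X, y, baseline, names = drivers_pixel.prepare_group_matrix(
                            bundle["pixel_table"], cities, group, metric, target
                        )
                        forest, oob = drivers_pixel.fit_rf(
                            X, y, task=target, seed=run.seed,
                            n_estimators=run.rf_trees, min_rows=run.min_group_rows,
                        )
                    except ValueError as exc:
                        logger.info("skipping %s/%s/%s: %s", group, metric, target, exc)
                        continue
                    tab = drivers_pixel.contribution_table(forest, X, names, baseline)
                    tab.insert(0, "group", group)
                    tab.insert(1, "metric", metric)
                    tab.insert(2, "target", target)
                    tab["oob_score"] = oob
                    contrib_tabs.append(tab)
        contrib = pd.concat(contrib_tabs, ignore_index=True) if contrib_tabs else pd.DataFrame()
        bundle["contributions"] = contrib
        write_csv(contrib, out / "drivers_pixel.csv", run, "drivers_pixel")

    return bundle
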