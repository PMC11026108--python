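"""Ready-made multi-city study designs built on the scene generator.

These encode the "stated worlds" used throughout the tests and the demo
pipeline:

* :func:`make_seasonal_events` — one long, intense event per season, so
  both concurrent and delayed responses exist year-round;
* :func:`make_damping_city` — urban responses uniformly damped, the
  world in which urban magnitudes are smaller in every season;
* :func:`make_driver_cohort` — cities spanning an east-west-like
  gradient where irrigation (VPD decoupling) and urban optimal-temperature
  offsets drive the sign of urban-rural differences;
* :func:`make_attribution_city` — impervious fraction as the sole driver
  of urban response damping, for the pixel-attribution analysis.
"""

from __future__ import annotations

import numpy as np

from .scene import ImposedEvent, SceneConfig


def make_seasonal_events(years: int = 19, length: int = 5, exceedance: float = 2.5) -> tuple[ImposedEvent, ...]:
    """One event per season (DJF, MAM, JJA, SON starts), in separate years.

    Default length 5 months and exceedance 2.5 degC puts every event in the
    long-and-intense stratum (duration >= 4, intensity >= 2), so the
    delayed-loss term is active.
    """
    starts = [
        (3, 11),  # Dec of year 3 -> DJF
        (6, 2),  # Mar -> MAM
        (9, 5),  # Jun -> JJA
        (12, 8),  # Sep -> SON
    ]
    events = []
    for year, month in starts:
        t0 = 12 * year + month
        if t0 + length + 3 > 12 * years:
            raise ValueError("record too short for the seasonal event layout")
        events.append(ImposedEvent(start=t0, length=length, exceedance=exceedance))
    return tuple(events)


def make_damping_city(seed: int, damping: float = 0.5, **overrides) -> SceneConfig:
    """City with urban responses damped by ``damping`` and long-intense
    events in all four seasons."""
    kw = dict(
        shape=(14, 14),
        urban_radius=3.5,
        rural_ring=3.5,
        events=make_seasonal_events(),
        damping=damping,
        city_id=f"damp{seed:03d}",
        seed=seed,
    )
    kw.update(overrides)
    return SceneConfig(**kw)


def make_driver_cohort(
    n_cities: int = 16,
    seed: int = 0,
    years: int = 19,
    shape: tuple[int, int] = (14, 14),
) -> list[SceneConfig]:
    """Cities along a synthetic aridity gradient.

    A per-city "westness" w in [0, 1] sets (i) irrigation of the urban
    area (w > 0.5), which decouples urban EVI from VPD, (ii) a positive
    urban optimal-temperature offset growing with w, and (iii) the urban
    concurrent-gain advantage that actually produces more positive urban
    responses.  SPI coupling is off so the water-stress pathway acts
    through VPD; everything else (climate, UHI, impervious cover, events)
    varies independently of w.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 104729]))
    lc_rng = np.random.default_rng(np.random.SeedSequence([seed, 222]))
    west_types = ("Shrub", "Grass")
    east_types = ("Deciduous Forest", "Evergreen Forest", "Wetland", "Crop")
    configs = []
    for i in range(n_cities):
        w = (i + 0.5) / n_cities  # even spread; noise enters via other knobs
        irrigated = w > 0.5
        opt_offset = 4.0 * w + rng.normal(0.0, 0.25)
        extra_gain = 0.036 * (w - 0.5) + 0.005 * irrigated + rng.normal(0.0, 0.002)

        # nuisance variation, independent of w
        tmean_annual = rng.uniform(10.0, 16.0)
        dtmax = rng.uniform(0.5, 2.0)
        dtmin = rng.uniform(1.0, 3.0)
        imp_center = rng.uniform(0.6, 0.9)

        # rural land-cover mosaic: a region-typical dominant type plus minors
        pool = west_types if w > 0.5 else east_types
        dominant = pool[int(lc_rng.integers(len(pool)))]
        minors = [t for t in ("Grass", "Mixed Forest", "Deciduous Forest") if t != dominant]
        land_cover = {dominant: float(lc_rng.uniform(0.40, 0.60))}
        for t in minors[:2]:
            land_cover[t] = float(lc_rng.uniform(0.05, 0.18))

        ev_year = int(rng.integers(5, years - 3))
        events = (
            ImposedEvent(start=12 * ev_year + 5, length=4, exceedance=2.5),  # JJA
            ImposedEvent(start=12 * int(rng.integers(1, 4)) + 2, length=3, exceedance=2.2),  # MAM
        )
        configs.append(
            SceneConfig(
                shape=shape,
                years=years,
                urban_radius=3.5,
                rural_ring=3.5,
                tmean_annual=tmean_annual,
                dtmax_urban=dtmax,
                dtmin_urban=dtmin,
                impervious_center=imp_center,
                land_cover=land_cover,
                events=events,
                irrigated=bool(irrigated),
                opt_urban_offset=float(opt_offset),
                opt_gain=0.006,
                urban_extra_gain=float(extra_gain),
                spi_coupling=0.0,
                vpd_coupling=-0.06,
                elev_relief=0.0,
                elev_noise_sd=250.0,  # wide, spatially unstructured relief: both
                # areas sample a broad temperature range, identifying the optimum
                city_id=f"city{i:02d}",
                region="west" if w > 0.5 else "east",
                seed=seed * 1000 + i,
            )
        )
    return configs


def make_attribution_city(
    seed: int,
    shape: tuple[int, int] = (26, 26),
    impervious_damping: float = 0.9,
    n_events: int = 3,
) -> SceneConfig:
    """Controlled single-driver world for the pixel attribution analysis.

    The impervious fraction is the sole driver of urban response damping
    (d_pixel = 1 - k * impervious); land cover is uniform (decoupled from
    imperviousness), there is no irrigation or optimum offset, and EVI
    noise is reduced so the isolated driver is identifiable from a single
    city.  Events are staggered across the calendar so each month's
    in-sample 90th-percentile threshold is inflated by at most one event
    year.
    """
    layout = ((4, 5), (9, 1), (14, 9))
    events = tuple(
        ImposedEvent(start=12 * y + m, length=4, exceedance=3.0)
        for y, m in layout[:n_events]
    )
    return SceneConfig(
        shape=shape,
        urban_radius=8.0,
        rural_ring=4.0,
        events=events,
        damping=1.0,
        impervious_damping=impervious_damping,
        land_cover_mode="uniform",
        land_cover={"Grass": 0.6, "Shrub": 0.2},
        evi_noise_sd=0.01,
        city_id=f"attr{seed:03d}",
        seed=seed,
    )


def match_imposed_events(detected, config: SceneConfig) -> dict[int, int]:
    """Map imposed-event index -> detected-event index by span overlap.

    Detection runs on the realized series, so an imposed episode can be
    shifted or extended by spontaneous hot months; the detected event
    overlapping the imposed span is its observable counterpart.  Imposed
    events with no overlapping detection are omitted.
    """
    out: dict[int, int] = {}
    for k, imp in enumerate(config.events):
        lo, hi = imp.start, imp.start + imp.length - 1
        for i, ev in enumerate(detected):
            if ev.start <= hi and ev.end >= lo:
                out[k] = i
                break
    return out


def driver_screen_experiment(seed: int, n_cities: int = 16) -> dict[str, float]:
    """One replicate of the city-scale driver-recovery study.

    Generates the cohort, runs the per-scene pipeline, assembles the
    city-event predictor table joined to the urban-rural sign deltas for
    resistance (intense events only, where the configured response
    operates), and returns |Spearman rho| per non-land-cover predictor.
    """
    import pandas as pd

    from .compare import event_level_deltas
    from .drivers_city import spearman_screen
    from .predictors import NON_LAND_COVER_CITY_PREDICTORS, assemble_predictor_table
    from .scene import generate_scene
    from .workbench import process_scene

    tabs = []
    for cfg in make_driver_cohort(n_cities=n_cities, seed=seed):
        scene = generate_scene(cfg)
        out = process_scene(scene)
        city_df, _ = assemble_predictor_table(scene, out["events"], out["anomalies"])
        deltas = event_level_deltas(out["records"])
        deltas = deltas[deltas["metric"] == "resistance"]
        tabs.append(
            city_df.merge(deltas, on=["city", "dataset", "event", "season"], how="inner")
        )
    table = pd.concat(tabs, ignore_index=True)
    table = table[table["event_intensity"] >= 2.0]
    rhos = {}
    for pred in NON_LAND_COVER_CITY_PREDICTORS:
        rho, _ = spearman_screen(table[pred], table["delta_frac_pos"])
        rhos[pred] = abs(rho) if np.isfinite(rho) else 0.0
    return rhos


def attribution_experiment(seed: int, n_estimators: int = 300):
    """One replicate of the pixel-attribution study in the single-driver
    (impervious damping) world.

    Returns the contribution summary table for the magnitude regression of
    resistance, restricted to detected events matching the imposed spans.
    """
    from . import drivers_pixel as dp
    from .predictors import assemble_predictor_table
    from .scene import generate_scene
    from .workbench import process_scene

    cfg = make_attribution_city(seed)
    scene = generate_scene(cfg)
    out = process_scene(scene)
    _, pixel_df = assemble_predictor_table(
        scene, out["events"], out["anomalies"], records=out["records"], pixel_rows="all"
    )
    keep = set(match_imposed_events(out["events"], cfg).values())
    pixel_df = pixel_df[pixel_df["event"].isin(keep)]
    X, y, baseline, names = dp.prepare_group_matrix(
        pixel_df, [cfg.city_id], "Grass", "resistance", "magnitude"
    )
    forest, oob = dp.fit_rf(X, y, "magnitude", seed=seed, n_estimators=n_estimators)
    table = dp.contribution_table(forest, X, names, baseline)
    table["oob_score"] = oob
    return forest, X, baseline, table
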