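"""Driver variables for the urban-rural difference analyses.

Two granularities are produced from a scene and its hot events:

* city-event rows (one per event per ensemble member) carrying
  urban-minus-rural ``*_diff`` predictors, city background climate,
  event characteristics and rural land-cover fractions — the inputs of
  the city-scale correlation/GAM screen;
* pixel-event rows (one per urban pixel per event by default) carrying
  the pixel-local predictors — the inputs of the within-group
  random-forest attribution.

Water-stress status is summarized by the Spearman correlation of EVI
anomalies with SPI and with VPD over growing-season months; optimal
growth temperatures are the 1-degC-bin argmax of annual growing-season
(temperature, EVI) pairs; urban-heat-island intensity is the pixel minus
rural-mean temperature averaged over the event plus 3 post months.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .events import HotEvent, SEASON_OF_MONTH
from .scene import CityScene, GROWING_SEASON, LAND_COVER_TYPES

MIN_CORR_POINTS = 6
MIN_OCCUPIED_BINS = 3
TEMP_BIN_DEGC = 1.0


def _spearman(x: np.ndarray, y: np.ndarray) -> float:
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < MIN_CORR_POINTS or np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    return float(stats.spearmanr(x, y).statistic)


def water_stress_corr(
    evi_anom: np.ndarray,
    spi: np.ndarray,
    vpd: np.ndarray,
    months: np.ndarray | None = None,
    window: tuple[int, ...] = GROWING_SEASON,
) -> tuple[np.ndarray, np.ndarray]:
    """Spearman correlation of EVI anomalies with SPI and VPD over
    growing-season months across all years.

    evi_anom may be (T,) or (T, n_pixels); returns per-pixel arrays
    (scalars for 1-D input).  Fewer than 6 paired points or zero variance
    yields NaN.
    """
    anom = np.asarray(evi_anom, dtype=float)
    squeeze = anom.ndim == 1
    if squeeze:
        anom = anom[:, None]
    T = anom.shape[0]
    if months is None:
        months = np.arange(T) % 12 + 1
    sel = np.isin(months, window)
    spi_w = np.asarray(spi, dtype=float)[sel]
    vpd_w = np.asarray(vpd, dtype=float)[sel]
    corr_spi = np.array([_spearman(anom[sel, p], spi_w) for p in range(anom.shape[1])])
    corr_vpd = np.array([_spearman(anom[sel, p], vpd_w) for p in range(anom.shape[1])])
    if squeeze:
        return float(corr_spi[0]), float(corr_vpd[0])
    return corr_spi, corr_vpd


def _annual_gs_means(series: np.ndarray, months: np.ndarray, window) -> np.ndarray:
    """(T, ...) -> (years, ...) growing-season means."""
    sel = np.isin(months, window)
    years = series.shape[0] // 12
    return series[sel].reshape(years, -1, *series.shape[1:]).mean(axis=1)


def binned_optimum(temps: np.ndarray, evi: np.ndarray, bin_width: float = TEMP_BIN_DEGC) -> tuple[float, bool]:
    """Center of the temperature bin with the highest mean EVI.

    Returns (optimum, at_boundary).  NaN when fewer than 3 bins are
    occupied (the peak is then unidentifiable).
    """
    t = np.asarray(temps, dtype=float).ravel()
    e = np.asarray(evi, dtype=float).ravel()
    ok = ~(np.isnan(t) | np.isnan(e))
    t, e = t[ok], e[ok]
    if t.size == 0:
        return np.nan, False
    bins = np.floor(t / bin_width).astype(int)
    uniq = np.unique(bins)
    if uniq.size < MIN_OCCUPIED_BINS:
        return np.nan, False
    means = np.array([e[bins == b].mean() for b in uniq])
    best = uniq[int(np.argmax(means))]
    boundary = best == uniq.min() or best == uniq.max()
    return float((best + 0.5) * bin_width), bool(boundary)


def optimal_temperatures(
    evi: np.ndarray,
    tmax: np.ndarray,
    tmin: np.ndarray,
    months: np.ndarray | None = None,
    window: tuple[int, ...] = GROWING_SEASON,
) -> tuple[float, float]:
    """Area-level optimal daytime/nighttime growth temperatures.

    Pools annual growing-season (temperature, EVI) pairs across all years
    and pixels of the supplied arrays, bins temperature at 1 degC, and
    takes the center of the bin with maximum mean EVI.
    """
    evi = np.atleast_2d(np.asarray(evi, dtype=float).T).T
    if months is None:
        months = np.arange(evi.shape[0]) % 12 + 1
    e = _annual_gs_means(evi, months, window)
    tx = _annual_gs_means(np.atleast_2d(np.asarray(tmax, dtype=float).T).T, months, window)
    tn = _annual_gs_means(np.atleast_2d(np.asarray(tmin, dtype=float).T).T, months, window)
    opt_tmax, _ = binned_optimum(tx, e)
    opt_tmin, _ = binned_optimum(tn, e)
    return opt_tmax, opt_tmin


def uhi_intensity(
    t_pixel: np.ndarray,
    t_rural_mean: np.ndarray,
    event: HotEvent,
    post_window: int = 3,
) -> np.ndarray:
    """Mean of (pixel T - rural-mean T) over the event span plus 3 post
    months; truncated windows use the available months."""
    t_pixel = np.asarray(t_pixel, dtype=float)
    T = t_pixel.shape[0]
    hi = min(ev_end := event.end + 1 + post_window, T)
    sl = slice(event.start, hi)
    diff = t_pixel[sl] - np.asarray(t_rural_mean, dtype=float)[sl, None] if t_pixel.ndim == 2 else (
        t_pixel[sl] - np.asarray(t_rural_mean, dtype=float)[sl]
    )
    return diff.mean(axis=0)


COLUMN_DICTIONARY = pd.DataFrame(
    [
        ("corr_spi", "unitless [-1,1]", "both", "Spearman corr of EVI anomalies with SPI, growing season"),
        ("corr_vpd", "unitless [-1,1]", "both", "Spearman corr of EVI anomalies with VPD, growing season"),
        ("corr_spi_diff", "unitless", "city", "urban mean corr_spi minus rural mean"),
        ("corr_vpd_diff", "unitless", "city", "urban mean corr_vpd minus rural mean"),
        ("optimal_tmax", "degC", "both", "binned-argmax optimal daytime growth temperature"),
        ("optimal_tmin", "degC", "both", "binned-argmax optimal nighttime growth temperature"),
        ("optimal_tmax_diff", "degC", "city", "urban minus rural optimal tmax"),
        ("optimal_tmin_diff", "degC", "city", "urban minus rural optimal tmin"),
        ("background_tmean", "degC", "city", "climatological seasonal mean city-average tmean"),
        ("event_intensity", "degC", "city", "mean exceedance over the event span"),
        ("event_duration", "months", "city", "event span length"),
        ("impervious_frac", "[0,1]", "both", "impervious fraction (urban mean at city level)"),
        ("elev", "m", "both", "elevation (city mean at city level)"),
        ("elev_diff", "m", "city", "urban mean minus rural mean elevation"),
        ("spi_in_post_event", "unitless", "city", "mean SPI over event + 3 post months"),
        ("vpd_in_post_event", "kPa", "city", "mean VPD over event + 3 post months"),
        ("dtmax_in_post_event", "degC", "both", "pixel minus rural-mean tmax over event + 3 post months"),
        ("dtmin_in_post_event", "degC", "both", "pixel minus rural-mean tmin over event + 3 post months"),
    ]
    + [(lc, "[0,1]", "both", "rural land-cover fraction") for lc in LAND_COVER_TYPES],
    columns=["name", "units", "granularity", "description"],
)

NON_LAND_COVER_CITY_PREDICTORS = [
    "corr_spi_diff", "corr_vpd_diff", "optimal_tmax_diff", "optimal_tmin_diff",
    "background_tmean", "event_intensity", "event_duration", "impervious_frac",
    "elev_diff", "spi_in_post_event", "vpd_in_post_event",
    "dtmax_in_post_event", "dtmin_in_post_event",
]


def _flat(series3d: np.ndarray) -> np.ndarray:
    return series3d.reshape(series3d.shape[0], -1)


def assemble_predictor_table(
    scene: CityScene,
    events: list[HotEvent],
    evi_anomalies: np.ndarray,
    records: pd.DataFrame | None = None,
    pixel_rows: str = "urban",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build (city_event_table, pixel_event_table) for one scene.

    evi_anomalies: (T, R, C) deseasonalized EVI.  If ``records`` is given,
    the pixel table joins each pixel-event's resistance/recovery.
    pixel_rows: 'urban' (default, matching the urban-response attribution)
    or 'all'.
    """
    cfg = scene.config
    months = scene.months
    urban_f = scene.urban_mask.ravel()
    rural_f = scene.rural_mask.ravel()
    anom = _flat(np.asarray(evi_anomalies, dtype=float))
    evi = _flat(scene.evi)
    tmax = _flat(scene.tmax)
    tmin = _flat(scene.tmin)
    elev = scene.elevation.ravel()
    imperv = scene.impervious.ravel()

    corr_spi, corr_vpd = water_stress_corr(anom, scene.spi, scene.vpd, months)
    opt_u = optimal_temperatures(evi[:, urban_f], tmax[:, urban_f], tmin[:, urban_f], months)
    opt_r = optimal_temperatures(evi[:, rural_f], tmax[:, rural_f], tmin[:, rural_f], months)
    rural_lc = {
        lc: float(frac.ravel()[rural_f].mean()) for lc, frac in scene.land_cover.items()
    }
    for lc in LAND_COVER_TYPES:
        rural_lc.setdefault(lc, 0.0)

    city_tmean = scene.area_mean(scene.tmean)
    tmean_clim = np.array([city_tmean[months == m].mean() for m in range(1, 13)])
    season_members = {s: [m for m, lab in SEASON_OF_MONTH.items() if lab == s]
                      for s in ("DJF", "MAM", "JJA", "SON")}

    rural_tmax_mean = tmax[:, rural_f].mean(axis=1)
    rural_tmin_mean = tmin[:, rural_f].mean(axis=1)

    # per-pixel optimal temperatures from that pixel's own annual pairs
    ann_evi = _annual_gs_means(evi, months, GROWING_SEASON)
    ann_tmax = _annual_gs_means(tmax, months, GROWING_SEASON)
    ann_tmin = _annual_gs_means(tmin, months, GROWING_SEASON)
    n_pix = evi.shape[1]
    pix_opt_tmax = np.full(n_pix, np.nan)
    pix_opt_tmin = np.full(n_pix, np.nan)
    sel_pix = urban_f | rural_f if pixel_rows == "all" else urban_f
    for p in np.flatnonzero(sel_pix):
        pix_opt_tmax[p], _ = binned_optimum(ann_tmax[:, p], ann_evi[:, p])
        pix_opt_tmin[p], _ = binned_optimum(ann_tmin[:, p], ann_evi[:, p])

    city_rows, pixel_rows_out = [], []
    for ev_idx, ev in enumerate(events):
        T = scene.n_months
        hi = min(ev.end + 1 + 3, T)
        sl = slice(ev.start, hi)
        dtmax = uhi_intensity(tmax, rural_tmax_mean, ev)
        dtmin = uhi_intensity(tmin, rural_tmin_mean, ev)

        row = {
            "city": cfg.city_id,
            "region": cfg.region,
            "dataset": scene.dataset_id,
            "event": ev_idx,
            "season": ev.season,
            "event_duration": ev.duration,
            "event_intensity": ev.intensity,
            "corr_spi_diff": np.nanmean(corr_spi[urban_f]) - np.nanmean(corr_spi[rural_f]),
            "corr_vpd_diff": np.nanmean(corr_vpd[urban_f]) - np.nanmean(corr_vpd[rural_f]),
            "optimal_tmax_diff": opt_u[0] - opt_r[0],
            "optimal_tmin_diff": opt_u[1] - opt_r[1],
            "background_tmean": float(np.mean(tmean_clim[[m - 1 for m in season_members[ev.season]]])),
            "impervious_frac": float(imperv[urban_f].mean()),
            "elev_diff": float(elev[urban_f].mean() - elev[rural_f].mean()),
            "spi_in_post_event": float(scene.spi[sl].mean()),
            "vpd_in_post_event": float(scene.vpd[sl].mean()),
            "dtmax_in_post_event": float(dtmax[urban_f].mean()),
            "dtmin_in_post_event": float(dtmin[urban_f].mean()),
        }
        row.update(rural_lc)
        city_rows.append(row)

        lc_flat = {lc: frac.ravel() for lc, frac in scene.land_cover.items()}
        for p in np.flatnonzero(sel_pix):
            prow = {
                "city": cfg.city_id,
                "dataset": scene.dataset_id,
                "event": ev_idx,
                "season": ev.season,
                "pixel": int(p),
                "area": "urban" if urban_f[p] else "rural",
                "corr_spi": corr_spi[p],
                "corr_vpd": corr_vpd[p],
                "optimal_tmax": pix_opt_tmax[p],
                "optimal_tmin": pix_opt_tmin[p],
                "dtmax_in_post_event": float(dtmax[p]),
                "dtmin_in_post_event": float(dtmin[p]),
                "impervious_frac": float(imperv[p]),
                "elev": float(elev[p]),
            }
            for lc in LAND_COVER_TYPES:
                prow[lc] = float(lc_flat[lc][p]) if lc in lc_flat else 0.0
            pixel_rows_out.append(prow)

    city_df = pd.DataFrame(city_rows)
    pixel_df = pd.DataFrame(pixel_rows_out)

    # invariant checks on every assembly
    for col in ("corr_spi_diff", "corr_vpd_diff"):
        v = city_df[col].dropna()
        assert ((v >= -2) & (v <= 2)).all()
    for df, cols in ((city_df, LAND_COVER_TYPES), (pixel_df, LAND_COVER_TYPES)):
        if len(df):
            for lc in cols:
                v = df[lc].dropna()
                assert ((v >= 0) & (v <= 1)).all(), f"fraction out of range: {lc}"

    if records is not None and len(pixel_df):
        keys = ["city", "dataset", "pixel", "event"]
        metrics = records[keys + ["resistance", "recovery", "valid_resistance", "valid_recovery"]]
        pixel_df = pixel_df.merge(metrics, on=keys, how="left")
    return city_df, pixel_df
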