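"""Synthetic city scenes for testing the resilience pipeline end to end.

A scene is a small gridded "city": an urban core surrounded by a rural
ring, with monthly temperature (mean/max/min), EVI, SPI and VPD series per
pixel plus static layers (impervious fraction, land-cover fractions,
elevation).  Every stochastic ingredient is seeded, and the heat-response
parameters (concurrent gain, delayed loss, urban damping, irrigation
decoupling) are recorded as ground truth so downstream estimators can be
checked against what was actually simulated.

The temperature model is a monthly climatological cycle plus a shared
AR(1) anomaly, an elevation lapse, an urban-heat-island offset on urban
pixels, and any imposed hot-event exceedances.  EVI is a seasonal cycle
plus a concurrent positive response to event exceedance, a delayed loss
spread over the three post-event months when the event is long and intense
enough, a water-stress coupling to SPI/VPD (suppressed for irrigated urban
pixels), an optional optimal-temperature curvature term, and white noise.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import xarray as xr
import yaml

GROWING_SEASON = (4, 5, 6, 7, 8, 9, 10)  # calendar months, Apr-Oct

LAND_COVER_TYPES = (
    "Crop",
    "Deciduous Forest",
    "Evergreen Forest",
    "Grass",
    "Mixed Forest",
    "Shrub",
    "Wetland",
)


@dataclass(frozen=True)
class ImposedEvent:
    """A heat episode forced into the record.

    start is a 0-based month index into the record, length in months,
    exceedance the temperature excess in degC added uniformly over the span.
    """

    start: int
    length: int
    exceedance: float


def _seasonal_cycle(mean: float, amplitude: float, phase_month: float = 7.0) -> np.ndarray:
    """12-vector peaking at phase_month (July by default)."""
    m = np.arange(1, 13)
    return mean - amplitude * np.cos(2 * np.pi * (m - (phase_month - 6.0)) / 12.0)


@dataclass
class SceneConfig:
    """Parameters of one synthetic city.

    Temperature units degC, VPD kPa, EVI unitless in [0, 1].  The urban
    response terms (concurrent gain, delayed loss) are multiplied by
    ``damping`` (and optionally further damped in proportion to the pixel
    impervious fraction), so ``damping < 1`` makes urban responses smaller
    in magnitude than rural ones.
    """

    shape: tuple[int, int] = (16, 16)
    pixel_size: str = "1km"
    years: int = 19
    start_year: int = 2001
    urban_radius: float = 4.0
    rural_ring: float = 4.0

    # temperature
    tmean_monthly: np.ndarray | None = None  # explicit 12-vector overrides the sinusoid
    tmean_annual: float = 13.0
    tmean_amplitude: float = 11.0
    diurnal_half_range: float = 6.0
    dtmax_urban: float = 1.0  # daytime UHI offset, degC
    dtmin_urban: float = 2.0  # nighttime UHI offset, degC
    ar1_coef: float = 0.5
    anom_sd: float = 0.8
    pixel_temp_noise_sd: float = 0.1
    lapse_rate: float = 6.5  # degC per km of elevation

    events: tuple[ImposedEvent, ...] = ()

    # EVI response
    evi_monthly: np.ndarray | None = None
    evi_mean: float = 0.35
    evi_amplitude: float = 0.20
    gain_concurrent: float = 0.02  # EVI per degC of positive exceedance
    gain_delayed: float = 0.15  # EVI loss per (month over D0) per (degC over I0)
    delay_duration_threshold: float = 4.0  # D0, months
    delay_intensity_threshold: float = 2.0  # I0, degC
    damping: float = 1.0  # urban response multiplier, in (0, 1]
    impervious_damping: float = 0.0  # extra urban damping: d_pixel = damping*(1 - k*imp)
    urban_extra_gain: float = 0.0  # additive urban concurrent gain (may be negative)
    irrigated: bool = False  # decouple urban EVI from SPI/VPD
    spi_coupling: float = 0.01  # EVI per SPI unit (moderate moisture coupling)
    vpd_coupling: float = -0.03  # EVI per kPa of VPD anomaly
    opt_tmax: float = 26.0  # optimal daytime growth temperature, degC
    opt_urban_offset: float = 0.0  # urban shift of the optimum, degC
    opt_gain: float = 0.0  # EVI curvature per degC^2 (0 disables the term)
    evi_noise_sd: float = 0.02

    # moisture series
    spi_sd: float = 1.0  # keep at 1 (SPI is standardized); 0 disables moisture noise
    spi_ar1: float = 0.4
    vpd_monthly: np.ndarray | None = None
    vpd_mean: float = 0.9
    vpd_amplitude: float = 0.5
    vpd_logsd: float = 0.3
    vpd_temp_rho: float = 0.6  # correlation of log-VPD anomaly with temperature anomaly

    # static layers
    land_cover: dict[str, float] = field(
        default_factory=lambda: {"Deciduous Forest": 0.55, "Grass": 0.25, "Shrub": 0.10}
    )
    land_cover_mode: str = "impervious_coupled"  # or "uniform"
    impervious_center: float = 0.8
    impervious_edge: float = 0.1
    elev_base: float = 200.0
    elev_relief: float = 400.0
    elev_noise_sd: float = 30.0

    city_id: str = "city00"
    region: str = "east"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.years < 2:
            raise ValueError("years must be >= 2 (climatology needs replication)")
        if not (0.0 < self.damping <= 1.0):
            raise ValueError("damping must be in (0, 1]")
        n_months = 12 * self.years
        for ev in self.events:
            if ev.length < 1:
                raise ValueError(f"event length must be >= 1, got {ev.length}")
            if ev.start < 0 or ev.start + ev.length > n_months:
                raise ValueError(
                    f"event [{ev.start}, {ev.start + ev.length}) lies outside the "
                    f"{n_months}-month record"
                )
        bad = set(self.land_cover) - set(LAND_COVER_TYPES)
        if bad:
            raise ValueError(f"unknown land-cover types: {sorted(bad)}")
        total = sum(self.land_cover.values())
        if total > 1.0 + 1e-9 or any(v < 0 for v in self.land_cover.values()):
            raise ValueError("land-cover fractions must be >= 0 and sum to <= 1")
        for name in ("impervious_center", "impervious_edge"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.impervious_damping < 0 or self.impervious_damping > 1:
            raise ValueError("impervious_damping must be in [0, 1]")
        if self.land_cover_mode not in ("impervious_coupled", "uniform"):
            raise ValueError("land_cover_mode must be 'impervious_coupled' or 'uniform'")

    @property
    def n_months(self) -> int:
        return 12 * self.years

    def tmean_cycle(self) -> np.ndarray:
        if self.tmean_monthly is not None:
            c = np.asarray(self.tmean_monthly, dtype=float)
            if c.shape != (12,):
                raise ValueError("tmean_monthly must have 12 entries")
            return c
        return _seasonal_cycle(self.tmean_annual, self.tmean_amplitude)

    def evi_cycle(self) -> np.ndarray:
        if self.evi_monthly is not None:
            c = np.asarray(self.evi_monthly, dtype=float)
            if c.shape != (12,):
                raise ValueError("evi_monthly must have 12 entries")
            return c
        return _seasonal_cycle(self.evi_mean, self.evi_amplitude)

    def vpd_cycle(self) -> np.ndarray:
        if self.vpd_monthly is not None:
            c = np.asarray(self.vpd_monthly, dtype=float)
            if c.shape != (12,):
                raise ValueError("vpd_monthly must have 12 entries")
            return c
        return _seasonal_cycle(self.vpd_mean, self.vpd_amplitude)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["events"] = [dataclasses.asdict(ev) for ev in self.events]
        for key in ("tmean_monthly", "evi_monthly", "vpd_monthly"):
            if d[key] is not None:
                d[key] = [float(v) for v in d[key]]
        d["shape"] = list(d["shape"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SceneConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["shape"] = tuple(d["shape"])
        d["events"] = tuple(ImposedEvent(**ev) for ev in d.get("events", ()))
        return cls(**d)


@dataclass
class CityScene:
    """One realization of a synthetic (or loaded) city.

    Monthly series have shape (n_months, rows, cols); static layers
    (rows, cols).  ``truth`` records the imposed events and response
    parameters used by the generator.
    """

    config: SceneConfig
    dataset_id: str
    urban_mask: np.ndarray
    rural_mask: np.ndarray
    impervious: np.ndarray
    land_cover: dict[str, np.ndarray]
    elevation: np.ndarray
    tmean: np.ndarray
    tmax: np.ndarray
    tmin: np.ndarray
    evi: np.ndarray
    spi: np.ndarray
    vpd: np.ndarray
    n_clipped: int = 0
    truth: dict = field(default_factory=dict)

    @property
    def n_months(self) -> int:
        return self.tmean.shape[0]

    @property
    def months(self) -> np.ndarray:
        """Calendar month (1-12) of each time step."""
        return np.arange(self.n_months) % 12 + 1

    def area_mean(self, series: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
        """Spatial mean of a (T, R, C) series over a pixel mask (default: urban+rural)."""
        if mask is None:
            mask = self.urban_mask | self.rural_mask
        return series[:, mask].mean(axis=1)

    def to_dataset(self) -> xr.Dataset:
        coords = {
            "time": np.arange(self.n_months),
            "row": np.arange(self.tmean.shape[1]),
            "col": np.arange(self.tmean.shape[2]),
        }
        data = {
            name: (("time", "row", "col"), getattr(self, name))
            for name in ("tmean", "tmax", "tmin", "evi")
        }
        data["spi"] = ("time",), self.spi
        data["vpd"] = ("time",), self.vpd
        data["urban_mask"] = ("row", "col"), self.urban_mask.astype(np.int8)
        data["rural_mask"] = ("row", "col"), self.rural_mask.astype(np.int8)
        data["impervious"] = ("row", "col"), self.impervious
        data["elevation"] = ("row", "col"), self.elevation
        for lc, frac in self.land_cover.items():
            data[f"lc_{lc.replace(' ', '_')}"] = ("row", "col"), frac
        ds = xr.Dataset(data, coords=coords)
        ds.attrs["dataset_id"] = self.dataset_id
        ds.attrs["city_id"] = self.config.city_id
        ds.attrs["start_year"] = self.config.start_year
        return ds

    def save_netcdf(self, path) -> None:
        # NetCDF3 via the scipy engine: no external netCDF library needed
        self.to_dataset().to_netcdf(path, engine="scipy")

    def to_frame(self) -> pd.DataFrame:
        """Tidy per-pixel-per-month table (small grids only)."""
        T, R, C = self.tmean.shape
        t, r, c = np.meshgrid(np.arange(T), np.arange(R), np.arange(C), indexing="ij")
        return pd.DataFrame(
            {
                "time": t.ravel(),
                "row": r.ravel(),
                "col": c.ravel(),
                "tmean": self.tmean.ravel(),
                "tmax": self.tmax.ravel(),
                "tmin": self.tmin.ravel(),
                "evi": self.evi.ravel(),
            }
        )


def _radial_distance(shape: tuple[int, int]) -> np.ndarray:
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    return np.hypot(rr - (rows - 1) / 2.0, cc - (cols - 1) / 2.0)


def _event_exceedance(config: SceneConfig) -> np.ndarray:
    exc = np.zeros(config.n_months)
    for ev in config.events:
        exc[ev.start : ev.start + ev.length] += ev.exceedance
    return exc


def _delayed_loss(config: SceneConfig) -> np.ndarray:
    """Per-month EVI loss in the 3 months after each imposed event.

    Total loss = b * max(0, L - D0) * max(0, I - I0), spread uniformly over
    the post window (months past the end of the record are dropped).
    """
    loss = np.zeros(config.n_months)
    for ev in config.events:
        total = (
            config.gain_delayed
            * max(0.0, ev.length - config.delay_duration_threshold)
            * max(0.0, ev.exceedance - config.delay_intensity_threshold)
        )
        if total <= 0:
            continue
        end = ev.start + ev.length
        post = np.arange(end, min(end + 3, config.n_months))
        loss[post] += total / 3.0
    return loss


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    x = np.empty(n)
    stat_sd = sd / np.sqrt(max(1e-12, 1.0 - phi**2)) if abs(phi) < 1 else sd
    x[0] = rng.normal(0.0, stat_sd)
    eps = rng.normal(0.0, sd, n)
    for t in range(1, n):
        x[t] = phi * x[t - 1] + eps[t]
    return x


def generate_scene(config: SceneConfig, member: int = 0) -> CityScene:
    """Simulate one city scene; deterministic for a given (config.seed, member).

    Static layers depend only on config.seed, so ensemble members share
    masks, land cover and elevation while anomaly and noise realizations
    differ.
    """
    T = config.n_months
    R, C = config.shape
    months = np.arange(T) % 12 + 1

    static_rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7919]))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, int(member)]))

    dist = _radial_distance(config.shape)
    urban = dist <= config.urban_radius
    rural = (dist > config.urban_radius) & (dist <= config.urban_radius + config.rural_ring)

    with np.errstate(invalid="ignore"):
        prof = np.clip(1.0 - dist / max(config.urban_radius, 1e-9), 0.0, 1.0)
    impervious = np.where(
        urban, config.impervious_edge + (config.impervious_center - config.impervious_edge) * prof, 0.0
    )
    if config.land_cover_mode == "uniform":
        # fractions independent of imperviousness, scaled so the per-pixel
        # sum with impervious stays <= 1
        scale = 1.0 - float(impervious.max())
        land_cover = {
            lc: np.full((R, C), frac * scale) for lc, frac in config.land_cover.items()
        }
    else:
        land_cover = {lc: frac * (1.0 - impervious) for lc, frac in config.land_cover.items()}

    cols = np.broadcast_to(np.arange(C), (R, C)).astype(float)
    elevation = (
        config.elev_base
        + config.elev_relief * cols / max(C - 1, 1)
        + static_rng.normal(0.0, config.elev_noise_sd, (R, C))
    )

    # --- temperature ---------------------------------------------------
    clim = config.tmean_cycle()[months - 1]  # (T,)
    anom = _ar1(rng, T, config.ar1_coef, config.anom_sd)
    exc = _event_exceedance(config)
    lapse_off = -config.lapse_rate * (elevation - elevation.mean()) / 1000.0
    dtmean_u = 0.5 * (config.dtmax_urban + config.dtmin_urban)

    base = (clim + anom + exc)[:, None, None] + lapse_off[None, :, :]
    if config.pixel_temp_noise_sd > 0:
        base = base + rng.normal(0.0, config.pixel_temp_noise_sd, (T, R, C))
    tmean = base + dtmean_u * urban
    tmax = tmean + config.diurnal_half_range + (config.dtmax_urban - dtmean_u) * urban
    tmin = tmean - config.diurnal_half_range + (config.dtmin_urban - dtmean_u) * urban

    # --- moisture -------------------------------------------------------
    spi_raw = _ar1(rng, T, config.spi_ar1, 1.0)
    spi = config.spi_sd * spi_raw * np.sqrt(1.0 - config.spi_ar1**2)  # unit stationary variance
    anom_stat_sd = config.anom_sd / np.sqrt(max(1e-12, 1.0 - config.ar1_coef**2))
    z_t = anom / max(anom_stat_sd, 1e-12)
    z = config.vpd_temp_rho * z_t + np.sqrt(1.0 - config.vpd_temp_rho**2) * rng.normal(0.0, 1.0, T)
    vpd_clim = config.vpd_cycle()[months - 1]
    vpd = vpd_clim * np.exp(config.vpd_logsd * z - 0.5 * config.vpd_logsd**2)

    # --- EVI ------------------------------------------------------------
    evi_clim = config.evi_cycle()[months - 1]
    exc_pos = np.maximum(exc, 0.0)
    loss = _delayed_loss(config)
    water = config.spi_coupling * spi + config.vpd_coupling * (vpd - vpd_clim)

    d_pixel = np.where(
        urban, config.damping * (1.0 - config.impervious_damping * impervious), 1.0
    )
    gain_pixel = np.where(urban, config.gain_concurrent + config.urban_extra_gain, config.gain_concurrent)
    response = d_pixel[None, :, :] * (
        gain_pixel[None, :, :] * exc_pos[:, None, None] - loss[:, None, None]
    )

    water_weight = np.where(urban & config.irrigated, 0.0, 1.0)
    evi = (
        evi_clim[:, None, None]
        + response
        + water_weight[None, :, :] * water[:, None, None]
    )
    if config.opt_gain > 0:
        opt_pixel = np.where(urban, config.opt_tmax + config.opt_urban_offset, config.opt_tmax)
        in_gs = np.isin(months, GROWING_SEASON)
        curv = -config.opt_gain * (tmax - opt_pixel[None, :, :]) ** 2
        evi = evi + np.where(in_gs[:, None, None], curv, 0.0)
    if config.evi_noise_sd > 0:
        evi = evi + rng.normal(0.0, config.evi_noise_sd, (T, R, C))

    clipped = int(np.sum((evi < 0.0) | (evi > 1.0)))
    evi = np.clip(evi, 0.0, 1.0)

    truth = {
        "events": [dataclasses.asdict(ev) for ev in config.events],
        "gain_concurrent": config.gain_concurrent,
        "gain_delayed": config.gain_delayed,
        "damping": config.damping,
        "impervious_damping": config.impervious_damping,
        "urban_extra_gain": config.urban_extra_gain,
        "irrigated": config.irrigated,
        "dtmax_urban": config.dtmax_urban,
        "dtmin_urban": config.dtmin_urban,
        "opt_tmax": config.opt_tmax,
        "opt_urban_offset": config.opt_urban_offset,
    }
    return CityScene(
        config=config,
        dataset_id=f"member{member:02d}",
        urban_mask=urban,
        rural_mask=rural,
        impervious=impervious,
        land_cover=land_cover,
        elevation=elevation,
        tmean=tmean,
        tmax=tmax,
        tmin=tmin,
        evi=evi,
        spi=spi,
        vpd=vpd,
        n_clipped=clipped,
        truth=truth,
    )


def generate_ensemble(config: SceneConfig, n_members: int) -> list[CityScene]:
    """Ensemble sharing climatology, events and static layers; anomaly
    realizations differ per member (emulating multiple temperature sources)."""
    if n_members < 1:
        raise ValueError("n_members must be >= 1")
    return [generate_scene(config, member=i) for i in range(n_members)]


def load_netcdf(path, config: SceneConfig | None = None) -> CityScene:
    """Rehydrate a scene written by CityScene.save_netcdf.

    If no config is given a minimal one is reconstructed from the file
    dimensions (ground-truth response parameters are not recoverable).
    """
    ds = xr.open_dataset(path, engine="scipy")
    T = ds.sizes["time"]
    shape = (ds.sizes["row"], ds.sizes["col"])
    if config is None:
        config = SceneConfig(
            shape=shape,
            years=T // 12,
            start_year=int(ds.attrs.get("start_year", 2001)),
            city_id=str(ds.attrs.get("city_id", "city00")),
        )
    land_cover = {
        name[3:].replace("_", " "): ds[name].values
        for name in ds.data_vars
        if name.startswith("lc_")
    }
    return CityScene(
        config=config,
        dataset_id=str(ds.attrs.get("dataset_id", "member00")),
        urban_mask=ds["urban_mask"].values.astype(bool),
        rural_mask=ds["rural_mask"].values.astype(bool),
        impervious=ds["impervious"].values,
        land_cover=land_cover,
        elevation=ds["elevation"].values,
        tmean=ds["tmean"].values,
        tmax=ds["tmax"].values,
        tmin=ds["tmin"].values,
        evi=ds["evi"].values,
        spi=ds["spi"].values,
        vpd=ds["vpd"].values,
        truth={},
    )
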