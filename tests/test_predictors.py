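import dataclasses

import numpy as np
import pytest

from urbanveg.events import HotEvent
from urbanveg.predictors import (
    assemble_predictor_table,
    binned_optimum,
    optimal_temperatures,
    uhi_intensity,
    water_stress_corr,
)
from urbanveg.scene import SceneConfig, generate_scene
from urbanveg.workbench import process_scene


class TestWaterStressCorr:
    def test_perfect_monotone(self, rng):
        T = 12 * 5
        spi = rng.normal(0, 1, T)
        vpd = rng.normal(1, 0.2, T)
        corr_spi, corr_vpd = water_stress_corr(spi.copy(), spi, vpd)
        assert corr_spi == pytest.approx(1.0)

    def test_constant_anomalies_missing(self):
        T = 12 * 5
        corr_spi, corr_vpd = water_stress_corr(
            np.zeros(T), np.arange(T, dtype=float), np.arange(T, dtype=float)
        )
        assert np.isnan(corr_spi) and np.isnan(corr_vpd)

    def test_too_few_points_missing(self):
        months = np.array([1, 2, 3, 4, 5, 6] * 2)
        out = water_stress_corr(
            np.arange(12.0), np.arange(12.0), np.arange(12.0), months=months,
            window=(4,),
        )
        assert np.isnan(out[0])

    def test_irrigated_urban_decoupled_from_vpd(self):
        """With the irrigation flag set, urban EVI anomalies are uncorrelated
        with VPD while rural anomalies respond to it."""
        cfg = SceneConfig(
            shape=(10, 10), urban_radius=2.5, rural_ring=2.5,
            irrigated=True, vpd_coupling=-0.06, spi_coupling=0.0,
            evi_noise_sd=0.01, seed=4,
        )
        s = generate_scene(cfg)
        anom = s.evi.reshape(s.n_months, -1) - np.tile(
            cfg.evi_cycle(), cfg.years
        )[:, None]
        _, corr_vpd = water_stress_corr(anom, s.spi, s.vpd, s.months)
        urb = np.nanmean(corr_vpd[s.urban_mask.ravel()])
        rur = np.nanmean(corr_vpd[s.rural_mask.ravel()])
        assert abs(urb) < 0.15
        assert rur < -0.3


class TestOptimalTemperatures:
    def test_concave_quadratic_recovered(self, rng):
        """Noiseless concave response peaking at 24 degC is located within
        half a bin width."""
        temps = rng.uniform(18, 30, 600)
        evi = 0.6 - 0.002 * (temps - 24.0) ** 2
        opt, boundary = binned_optimum(temps, evi)
        assert opt == pytest.approx(24.0, abs=0.5)
        assert not boundary

    def test_monotone_response_flags_boundary(self, rng):
        temps = rng.uniform(10, 20, 400)
        opt, boundary = binned_optimum(temps, 0.01 * temps)
        assert boundary
        assert opt > 18.5

    def test_degenerate_temperature_missing(self):
        opt, _ = binned_optimum(np.full(50, 21.3), np.linspace(0, 1, 50))
        assert np.isnan(opt)

    def test_scene_level_recovery(self):
        """Generator optimum (26 degC daytime) recovered from rural pixels of
        a low-noise scene with wide unstructured relief."""
        cfg = SceneConfig(
            shape=(12, 12), urban_radius=3, rural_ring=3,
            opt_gain=0.006, opt_tmax=26.0, elev_relief=0.0, elev_noise_sd=250.0,
            evi_noise_sd=0.005, seed=1,
        )
        s = generate_scene(cfg)
        rural = s.rural_mask.ravel()
        evi = s.evi.reshape(s.n_months, -1)[:, rural]
        tmax = s.tmax.reshape(s.n_months, -1)[:, rural]
        tmin = s.tmin.reshape(s.n_months, -1)[:, rural]
        opt_tmax, opt_tmin = optimal_temperatures(evi, tmax, tmin, s.months)
        assert opt_tmax == pytest.approx(26.0, abs=1.5)


class TestUhiIntensity:
    def test_noiseless_offsets_exact(self, quiet_config):
        cfg = dataclasses.replace(quiet_config, dtmax_urban=1.0, dtmin_urban=2.0)
        s = generate_scene(cfg)
        ev = HotEvent(start=24, end=27, season="JJA")
        tmin = s.tmin.reshape(s.n_months, -1)
        rural_mean = tmin[:, s.rural_mask.ravel()].mean(axis=1)
        dt = uhi_intensity(tmin, rural_mean, ev)
        assert np.allclose(dt[s.urban_mask.ravel()], 2.0, atol=1e-12)
        assert np.allclose(dt[s.rural_mask.ravel()], 0.0, atol=1e-12)

    def test_noisy_estimate_within_sampling_error(self):
        cfg = SceneConfig(
            shape=(10, 10), urban_radius=2.5, rural_ring=2.5,
            dtmin_urban=2.0, pixel_temp_noise_sd=0.5, lapse_rate=0.0,
            elev_noise_sd=0.0, seed=8,
        )
        s = generate_scene(cfg)
        ev = HotEvent(start=60, end=64, season="JJA")  # 8-month window
        tmin = s.tmin.reshape(s.n_months, -1)
        rural_mean = tmin[:, s.rural_mask.ravel()].mean(axis=1)
        dt = uhi_intensity(tmin, rural_mean, ev)
        urb = dt[s.urban_mask.ravel()]
        # per-pixel noise of an 8-month mean difference ~ sd*sqrt(2/8)
        assert np.abs(urb.mean() - 2.0) < 3 * 0.5 / np.sqrt(8)


class TestAssemble:
    def test_city_row_matches_config_truth(self, quiet_config):
        cfg = dataclasses.replace(
            quiet_config, dtmax_urban=1.0, dtmin_urban=2.0,
            events=(),
        )
        s = generate_scene(cfg)
        ev = HotEvent(start=24, end=26, season="MAM")
        ev.intensity = 2.0
        city_df, pixel_df = assemble_predictor_table(s, [ev], np.zeros_like(s.evi))
        row = city_df.iloc[0]
        assert row["dtmin_in_post_event"] == pytest.approx(2.0, abs=1e-9)
        assert row["dtmax_in_post_event"] == pytest.approx(1.0, abs=1e-9)
        assert row["event_duration"] == 3

    def test_diff_columns_recompute(self, small_scene):
        out = process_scene(small_scene)
        city_df, _ = assemble_predictor_table(
            small_scene, out["events"], out["anomalies"]
        )
        s = small_scene
        elev = s.elevation.ravel()
        expected = elev[s.urban_mask.ravel()].mean() - elev[s.rural_mask.ravel()].mean()
        assert np.allclose(city_df["elev_diff"], expected)

    def test_bounds_invariants(self, small_scene):
        out = process_scene(small_scene)
        city_df, pixel_df = assemble_predictor_table(
            small_scene, out["events"], out["anomalies"], records=out["records"]
        )
        for col in ("corr_spi", "corr_vpd"):
            v = pixel_df[col].dropna()
            assert ((v >= -1) & (v <= 1)).all()
        assert ((pixel_df["impervious_frac"] >= 0) & (pixel_df["impervious_frac"] <= 1)).all()
        # ensemble structure: one city row per event
        assert len(city_df) == len(out["events"])
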