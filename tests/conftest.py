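import numpy as np
import pytest

from urbanveg.scene import ImposedEvent, SceneConfig, generate_scene


@pytest.fixture
def quiet_config():
    """All stochastic terms off: series equal their climatological cycles."""
    return SceneConfig(
        shape=(8, 8),
        years=5,
        urban_radius=2.0,
        rural_ring=2.0,
        anom_sd=0.0,
        pixel_temp_noise_sd=0.0,
        evi_noise_sd=0.0,
        lapse_rate=0.0,
        elev_noise_sd=0.0,
        dtmax_urban=0.0,
        dtmin_urban=0.0,
        spi_sd=0.0,
        spi_coupling=0.0,
        vpd_logsd=0.0,
        vpd_coupling=0.0,
        opt_gain=0.0,
        seed=0,
    )


@pytest.fixture
def small_scene():
    cfg = SceneConfig(
        shape=(10, 10),
        urban_radius=2.5,
        rural_ring=2.5,
        events=(ImposedEvent(start=12 * 9 + 5, length=5, exceedance=2.5),),
        seed=11,
    )
    return generate_scene(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
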