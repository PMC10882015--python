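import numpy as np
import pytest

import heatrun as hr

FLAT_TMAX = tuple([29.5] * 12)
FLAT_TMIN = tuple([22.5] * 12)


@pytest.fixture
def quiet_config():
    """Stationary background: flat seasonal cycle, iid noise, no trend.

    Used wherever injected events must be the only heatwaves: the flat
    cycle keeps the pooled percentile threshold from concentrating natural
    exceedance runs in the hottest month.
    """

    def make(seed=0, grid_shape=(2, 2), n_years=32, noise_sd=0.5):
        return hr.SyntheticClimateConfig(
            n_years=n_years,
            start_year=1961,
            grid_shape=grid_shape,
            tmax_annual_cycle=FLAT_TMAX,
            tmin_annual_cycle=FLAT_TMIN,
            noise_model="iid",
            ar1_phi=None,
            noise_sd=noise_sd,
            trend_per_decade=0.0,
            diurnal_offset_sd=0.2,
            seed=seed,
        )

    return make


@pytest.fixture
def small_grid():
    return hr.GridDefinition(
        lat=np.array([0.0, 0.25]),
        lon=np.array([100.0, 100.25]),
        cell_size=0.25,
        land_mask=np.ones((2, 2), dtype=bool),
    )


def make_event(cell=(0, 0), year=2000, duration=4, peak=38.0, cumex=6.0,
               mode="day", percentile=95.0, start_index=0):
    return hr.HeatwaveEvent(
        cell=cell,
        start_index=start_index,
        year=year,
        start_date=f"{year}-04-01",
        end_date=f"{year}-04-{duration:02d}",
        duration=duration,
        peak_tmax=peak,
        cumulative_exceedance=cumex,
        mode=mode,
        percentile=percentile,
    )
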