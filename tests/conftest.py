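from datetime import date

import pytest

from etcast import CanopyState, ClairParams, SensorSpec, SiteMeta, WeatherDaily


@pytest.fixture
def site():
    return SiteMeta(site_id="aws16", latitude=40.13, longitude=15.46,
                    elevation=413.0)


@pytest.fixture
def summer_day():
    """A typical Mediterranean mid-summer observation day."""
    return WeatherDaily(
        date=date(2014, 7, 15), t_max=30.0, t_min=18.0, rh_mean=60.0,
        ws10=3.0, rs=289.35,
    )


@pytest.fixture
def sensor():
    return SensorSpec(
        sensor_id="threeband",
        bands=(("green", 0.35), ("red", 0.30), ("nir", 0.35)),
        soil_line_slope=1.2,
    )


@pytest.fixture
def clair():
    return ClairParams(wdvi_inf=0.5, alpha_star=0.35)


@pytest.fixture
def canopy_series():
    return [
        CanopyState(date=date(2014, 6, 10), lai=0.5, albedo=0.15),
        CanopyState(date=date(2014, 6, 20), lai=1.5, albedo=0.165),
        CanopyState(date=date(2014, 7, 20), lai=4.5, albedo=0.19),
    ]
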