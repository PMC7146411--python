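from datetime import date, timedelta

import numpy as np
import pandas as pd
import pytest

from etcast import (
    CanopyState,
    WeatherDaily,
    accumulate,
    crop_coefficient,
    et0_pm_values,
    etc_pm_values,
    forecast_etc,
)
from etcast.meteo import extraterrestrial_radiation
from etcast.et import et0_hs_values


class TestAccumulate:
    def test_unit_dailies(self):
        assert accumulate([1, 1, 1, 1, 1]) == {1: 1, 3: 3, 5: 5}

    def test_zeros(self):
        assert accumulate({l: 0.0 for l in range(1, 6)}) == {1: 0, 3: 0, 5: 0}

    def test_monotone_for_nonnegative(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            acc = accumulate(rng.uniform(0, 8, 5))
            assert acc[5] >= acc[3] >= acc[1]

    def test_missing_lead(self):
        with pytest.raises(ValueError, match="missing leads"):
            accumulate({1: 1.0, 2: 1.0, 3: 1.0, 4: 1.0})


class TestCropCoefficient:
    def test_reference_parameters_give_unit_kc(self, summer_day, site):
        grass = CanopyState(date=date(2014, 6, 1), lai=1.0, albedo=0.23)
        kc = crop_coefficient(summer_day, grass, site, h_c=0.12, r_s=70.0)
        assert kc.kc == pytest.approx(1.0, rel=0.02)

    def test_sparse_canopy_kc_scale(self, summer_day, site):
        early = CanopyState(date=date(2014, 6, 1), lai=0.5, albedo=0.15)
        kc = crop_coefficient(summer_day, early, site)
        assert 0.3 < kc.kc < 0.8  # early-season maize is around one half

    def test_dense_canopy_kc_scale(self, summer_day, site):
        dense = CanopyState(date=date(2014, 7, 1), lai=5.0, albedo=0.20)
        kc = crop_coefficient(summer_day, dense, site)
        assert 0.9 < kc.kc < 1.4  # mid-season maize reaches ~1.1-1.2

    def test_series_selects_held_state(self, summer_day, site, canopy_series):
        kc = crop_coefficient(summer_day, canopy_series, site)
        assert kc.canopy_date == date(2014, 6, 20)

    def test_undefined_kc_when_et0_vanishes(self, site):
        wx = WeatherDaily(date=date(2014, 12, 21), t_max=0.5, t_min=0.0,
                          rh_mean=100.0, ws10=0.0, rs=0.0)
        canopy = CanopyState(date=date(2014, 6, 1), lai=3.0, albedo=0.18)
        with pytest.raises(ValueError, match="Kc undefined"):
            crop_coefficient(wx, canopy, site)

    def test_unit_handling_regression(self, summer_day, site):
        """Kc is unchanged when RS passes through the W->MJ->W conversion."""
        canopy = CanopyState(date=date(2014, 6, 1), lai=3.0, albedo=0.18)
        kc1 = crop_coefficient(summer_day, canopy, site).kc
        rs_mj = summer_day.rs * 0.0864
        wx2 = WeatherDaily(date=summer_day.date, t_max=summer_day.t_max,
                           t_min=summer_day.t_min, rh_mean=summer_day.rh_mean,
                           ws10=summer_day.ws10, rs=rs_mj / 0.0864)
        kc2 = crop_coefficient(wx2, canopy, site).kc
        assert kc1 == kc2


def _forecast_frame(site_id, t0, t_mean=24.0, spread=12.0):
    rows = []
    for lead in range(1, 6):
        rows.append({
            "site_id": site_id, "issue_date": t0, "lead_days": lead,
            "t_mean": t_mean, "t_max": t_mean + spread / 2,
            "t_min": t_mean - spread / 2, "rh_mean": 60.0, "ws10": 3.0,
            "rs_wm2": 280.0, "pressure_kpa": np.nan,
        })
    return pd.DataFrame(rows)


class TestForecastEtc:
    def test_constant_temperature_gives_near_constant_hs(self, summer_day, site):
        canopy = CanopyState(date=date(2014, 6, 1), lai=3.0, albedo=0.18)
        kc = crop_coefficient(summer_day, canopy, site)
        fc = _forecast_frame(site.site_id, summer_day.date)
        out = forecast_etc(kc, fc, site, canopy, k_hs=0.85, method="HS")
        values = np.array([out.etc_hs[l] for l in range(1, 6)])
        # identical forecast temperature: daily values differ only through
        # the slow drift of extraterrestrial radiation with the valid date
        assert values.std() / values.mean() < 0.01
        assert out.accumulated_hs[5] == pytest.approx(values.sum())

    def test_hs_path_is_kc_times_hargreaves(self, summer_day, site):
        canopy = CanopyState(date=date(2014, 6, 1), lai=3.0, albedo=0.18)
        kc = crop_coefficient(summer_day, canopy, site)
        fc = _forecast_frame(site.site_id, summer_day.date)
        out = forecast_etc(kc, fc, site, canopy, k_hs=0.85, method="HS")
        doy = (pd.Timestamp(summer_day.date) + pd.Timedelta(days=1)).dayofyear
        ra = extraterrestrial_radiation(site.latitude, doy)
        expected = kc.kc * float(et0_hs_values(24.0, 30.0, 18.0, ra, 0.85))
        assert out.etc_hs[1] == pytest.approx(expected)

    def test_pm_path_with_observed_weather_matches_best_estimate(
        self, summer_day, site
    ):
        """Feeding the observations as 'forecast' reproduces ETc-PM,obs."""
        canopy = CanopyState(date=date(2014, 6, 1), lai=3.0, albedo=0.18)
        kc = crop_coefficient(summer_day, canopy, site)
        fc = _forecast_frame(site.site_id, summer_day.date,
                             t_mean=summer_day.t_mean)
        fc["rs_wm2"] = summer_day.rs
        out = forecast_etc(kc, fc, site, canopy, method="PM")
        for lead in range(1, 6):
            doy = (pd.Timestamp(summer_day.date)
                   + pd.Timedelta(days=lead)).dayofyear
            best = etc_pm_values(
                summer_day.t_max, summer_day.t_min, summer_day.rh_mean,
                summer_day.ws10, summer_day.rs, site.latitude,
                site.elevation, doy, canopy.lai, canopy.albedo,
            )
            assert out.etc_pm[lead] == pytest.approx(float(best), abs=1e-12)

    def test_issue_date_mismatch_rejected(self, summer_day, site):
        canopy = CanopyState(date=date(2014, 6, 1), lai=3.0, albedo=0.18)
        kc = crop_coefficient(summer_day, canopy, site)
        fc = _forecast_frame(site.site_id, summer_day.date + timedelta(days=1))
        with pytest.raises(ValueError, match="issue_date"):
            forecast_etc(kc, fc, site, canopy)

    def test_missing_variable_for_pm_path(self, summer_day, site):
        canopy = CanopyState(date=date(2014, 6, 1), lai=3.0, albedo=0.18)
        kc = crop_coefficient(summer_day, canopy, site)
        fc = _forecast_frame(site.site_id, summer_day.date)
        fc["rh_mean"] = np.nan
        with pytest.raises(ValueError, match="rh_mean"):
            forecast_etc(kc, fc, site, canopy, method="PM")
        # the HS path does not need humidity
        out = forecast_etc(kc, fc, site, canopy, k_hs=0.85, method="HS")
        assert set(out.etc_hs) == {1, 2, 3, 4, 5}
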