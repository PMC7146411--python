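from datetime import date

import numpy as np
import pandas as pd
import pytest

from etcast import (
    default_climatologies,
    gen_canopy_season,
    gen_forecasts,
    gen_weather,
    retrieve_lai,
)
from etcast.meteo import WM2_TO_MJ_DAY, clear_sky_radiation, extraterrestrial_radiation
from etcast.nwp import fit_mean_bias
from etcast.synthetic import DEFAULT_CLAIR, DEFAULT_SENSOR, ForecastErrorModel


class TestWeatherGenerator:
    def test_deterministic_for_fixed_seed(self):
        clim = default_climatologies(1)[0]
        a = gen_weather(clim, date(2012, 6, 1), date(2012, 9, 30), seed=9)
        b = gen_weather(clim, date(2012, 6, 1), date(2012, 9, 30), seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_long_run_temperature_mean(self):
        clim = default_climatologies(1)[0]
        frames = [
            gen_weather(clim, date(y, 6, 1), date(y, 9, 30), seed=100 + y)
            for y in range(2010, 2016)
        ]
        t = pd.concat(frames)["t_mean"]
        assert abs(t.mean() - clim.mean_t) < 0.3

    def test_radiation_never_exceeds_clear_sky(self):
        clim = default_climatologies(2)[1]
        wx = gen_weather(clim, date(2012, 6, 1), date(2012, 9, 30), seed=3)
        doy = pd.to_datetime(wx["date"]).dt.dayofyear.to_numpy()
        ra = extraterrestrial_radiation(clim.site.latitude, doy)
        cap = clear_sky_radiation(ra, clim.site.elevation) / WM2_TO_MJ_DAY
        assert np.all(wx["rs_wm2"].to_numpy() <= cap + 1e-9)

    def test_extremes_bracket_mean(self):
        clim = default_climatologies(1)[0]
        wx = gen_weather(clim, date(2012, 6, 1), date(2012, 9, 30), seed=4)
        assert (wx["t_min"] <= wx["t_mean"]).all()
        assert (wx["t_mean"] <= wx["t_max"]).all()

    def test_empty_range_rejected(self):
        clim = default_climatologies(1)[0]
        with pytest.raises(ValueError):
            gen_weather(clim, date(2012, 6, 2), date(2012, 6, 1), seed=1)


class TestForecastGenerator:
    def test_degenerate_error_model_reproduces_truth_plus_bias(self):
        clim = default_climatologies(1)[0]
        wx = gen_weather(clim, date(2014, 6, 1), date(2014, 6, 20), seed=11)
        base = ForecastErrorModel()
        model = ForecastErrorModel(
            bias={"T": -0.68, "RH": 0.0, "WS10": 0.0, "RS": 0.0, "P": 0.0},
            noise_sd={k: 0.0 for k in base.noise_sd},
            member_sd={k: 0.0 for k in base.member_sd},
        )
        fc = gen_forecasts(wx, model, seed=12)
        truth = wx.set_index("date")
        for r in fc.itertuples():
            valid = r.issue_date + pd.Timedelta(days=r.lead_days)
            valid = valid.date() if hasattr(valid, "date") else valid
            row = truth.loc[valid]
            assert r.t_mean == pytest.approx(row.t_mean - 0.68, abs=1e-12)
            assert r.t_max == pytest.approx(row.t_max - 0.68, abs=1e-12)
            assert r.t_min == pytest.approx(row.t_min - 0.68, abs=1e-12)
            assert r.rh_mean == pytest.approx(row.rh_mean, abs=1e-12)
            assert r.ws10 == pytest.approx(row.ws10, abs=1e-12)
            assert r.rs_wm2 == pytest.approx(row.rs_wm2, abs=1e-10)

    def test_injected_bias_recovered_over_reference_seasons(self):
        clim = default_climatologies(1)[0]
        frames, fcs = [], []
        for i, year in enumerate((2010, 2011, 2012, 2013)):
            wx = gen_weather(clim, date(year, 6, 1), date(year, 10, 5),
                             seed=20 + i)
            frames.append(wx)
            fcs.append(gen_forecasts(wx, ForecastErrorModel(), seed=40 + i))
        table = fit_mean_bias(pd.concat(fcs), pd.concat(frames),
                              variables=("t_mean",))
        biases = [table.get(clim.site.site_id, "t_mean", l)
                  for l in range(1, 6)]
        assert np.mean(biases) == pytest.approx(-0.68, abs=0.05)

    def test_noise_grows_with_lead(self):
        clim = default_climatologies(1)[0]
        frames, fcs = [], []
        for i in range(4):
            wx = gen_weather(clim, date(2010 + i, 6, 1), date(2010 + i, 10, 5),
                             seed=60 + i)
            frames.append(wx)
            fcs.append(gen_forecasts(wx, ForecastErrorModel(), seed=80 + i))
        fc = pd.concat(fcs)
        obs = pd.concat(frames).set_index("date")["t_mean"]
        rmse = {}
        for lead in (1, 5):
            sub = fc[fc["lead_days"] == lead]
            valid = [d + pd.Timedelta(days=lead) for d in sub["issue_date"]]
            valid = [v.date() if hasattr(v, "date") else v for v in valid]
            err = sub["t_mean"].to_numpy() - obs.loc[valid].to_numpy()
            rmse[lead] = np.sqrt(np.mean(err**2))
        assert rmse[5] > rmse[1]

    def test_deterministic_for_fixed_seed(self):
        clim = default_climatologies(1)[0]
        wx = gen_weather(clim, date(2014, 6, 1), date(2014, 6, 15), seed=7)
        a = gen_forecasts(wx, ForecastErrorModel(members=4), seed=8)
        b = gen_forecasts(wx, ForecastErrorModel(members=4), seed=8)
        pd.testing.assert_frame_equal(a, b)


class TestCanopyGenerator:
    def test_lai_peaks_at_flowering(self):
        states, _ = gen_canopy_season(
            "f", date(2014, 6, 1), date(2014, 9, 30),
            flowering=date(2014, 7, 27), sampling_interval=7,
        )
        by_date = {s.date: s.lai for s in states}
        assert by_date[date(2014, 7, 27)] == pytest.approx(5.0)
        assert max(by_date.values()) == pytest.approx(5.0)

    def test_reflectance_round_trip(self):
        states, refl = gen_canopy_season(
            "f", date(2014, 6, 1), date(2014, 9, 30),
            flowering=date(2014, 8, 1),
        )
        lai = retrieve_lai(refl["rho_red"].to_numpy(),
                           refl["rho_nir"].to_numpy(),
                           DEFAULT_SENSOR, DEFAULT_CLAIR)
        assert np.allclose(lai, [s.lai for s in states], atol=1e-9)

    def test_albedo_tracks_development(self):
        # flowering on a sampling date so the retrieved peak hits lai_max
        states, _ = gen_canopy_season(
            "f", date(2014, 6, 1), date(2014, 9, 30),
            flowering=date(2014, 7, 27),
        )
        albs = [s.albedo for s in states]
        lais = [s.lai for s in states]
        assert albs[0] < 0.16  # early season near the bare-soil end
        assert max(albs) == pytest.approx(0.20, abs=1e-9)
        assert np.argmax(albs) == np.argmax(lais)

    def test_flowering_outside_season_rejected(self):
        with pytest.raises(ValueError):
            gen_canopy_season("f", date(2014, 6, 1), date(2014, 9, 30),
                              flowering=date(2014, 10, 15))
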