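from datetime import date

import numpy as np
import pandas as pd
import pytest

from etcast import SiteMeta, apply_bias_correction, fit_mean_bias, interpolate_to_site
from etcast.nwp import reduce_daily, reduce_daily_array
from etcast.synthetic import ForecastErrorModel, default_climatologies, gen_forecasts, gen_weather


def make_site(lat=40.0, lon=15.0):
    return SiteMeta(site_id="s", latitude=lat, longitude=lon, elevation=100.0)


class TestInterpolation:
    def test_site_on_a_node(self):
        nodes = [((40.0, 15.0), 3.0), ((40.1, 15.0), 6.0), ((40.0, 15.1), 9.0)]
        assert interpolate_to_site(nodes, make_site(40.0, 15.0)) == pytest.approx(3.0)

    def test_centroid_of_triangle(self):
        nodes = [((40.0, 15.0), 3.0), ((40.3, 15.0), 6.0), ((40.0, 15.3), 9.0)]
        site = make_site(40.1, 15.1)  # centroid in planar coordinates
        # centroid weights are equal up to the cos(lat) metric distortion
        assert interpolate_to_site(nodes, site) == pytest.approx(6.0, rel=1e-3)

    def test_constant_field_is_preserved_anywhere(self):
        nodes = [((40.0, 15.0), 5.0), ((40.3, 15.1), 5.0), ((39.9, 15.3), 5.0)]
        for lat, lon in [(40.1, 15.1), (41.0, 16.0), (39.0, 14.0)]:
            assert interpolate_to_site(nodes, make_site(lat, lon)) == pytest.approx(5.0)

    def test_outside_triangle_clips_to_edge(self):
        nodes = [((40.0, 15.0), 0.0), ((40.2, 15.0), 10.0), ((40.1, 15.2), 100.0)]
        v = interpolate_to_site(nodes, make_site(40.1, 14.5))  # far west
        assert 0.0 <= v <= 10.0  # projection onto the western edge

    def test_collinear_falls_back_to_idw(self):
        nodes = [((40.0, 15.0), 2.0), ((40.1, 15.0), 4.0), ((40.2, 15.0), 6.0)]
        with pytest.warns(UserWarning, match="collinear"):
            v = interpolate_to_site(nodes, make_site(40.1, 15.05))
        assert 2.0 < v < 6.0


class TestReduceDaily:
    def test_single_member_is_mean_of_steps(self):
        steps = np.arange(8.0)[None, :]  # one member
        assert reduce_daily_array(steps) == pytest.approx(3.5)

    def test_majority_member_wins(self):
        a = np.full(8, 2.0)
        b = np.full(8, 9.0)
        values = np.stack([a, a, b])  # members (a, a, b)
        assert reduce_daily_array(values) == pytest.approx(2.0)

    def test_member_permutation_invariance(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(5, 8))
        perm = values[rng.permutation(5)]
        assert reduce_daily_array(values) == pytest.approx(reduce_daily_array(perm))

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(4, 8))
        assert reduce_daily_array(values + 3.0) == pytest.approx(
            reduce_daily_array(values) + 3.0
        )

    def test_long_format_path_matches_array_path(self):
        clim = default_climatologies(1)[0]
        wx = gen_weather(clim, date(2014, 6, 1), date(2014, 6, 10), seed=5)
        model = ForecastErrorModel(members=4)
        reduced, long_df = gen_forecasts(
            wx, model, seed=6, as_long=True
        )
        via_records = reduce_daily(long_df)
        merged = reduced.merge(
            via_records, on=["site_id", "issue_date", "lead_days"],
            suffixes=("_fast", "_rec"),
        )
        assert len(merged) == len(reduced) > 0
        for col in ("t_mean", "t_max", "t_min", "rh_mean", "ws10", "rs_wm2"):
            assert np.allclose(merged[f"{col}_fast"], merged[f"{col}_rec"])

    def test_incomplete_day_dropped(self):
        clim = default_climatologies(1)[0]
        wx = gen_weather(clim, date(2014, 6, 1), date(2014, 6, 8), seed=5)
        _, long_df = gen_forecasts(wx, ForecastErrorModel(members=2), seed=6,
                                   as_long=True)
        # remove one 3-hourly step of T for every member of one valid day
        drop_time = long_df["valid_time"].iloc[0]
        broken = long_df[~((long_df["valid_time"] == drop_time)
                           & (long_df["variable"] == "T"))]
        out = reduce_daily(broken)
        full = reduce_daily(long_df)
        assert out["t_mean"].isna().sum() == 1
        assert full["t_mean"].isna().sum() == 0


def _paired_frames(bias=1.0, n=40, noise=0.0, seed=0):
    rng = np.random.default_rng(seed)
    dates = pd.date_range("2012-06-01", periods=n, freq="D")
    obs = pd.DataFrame({
        "site_id": "s1",
        "date": dates.date,
        "t_mean": 22 + rng.normal(0, 2, n),
    })
    rows = []
    for lead in (1, 2):
        issue = dates - pd.Timedelta(days=lead)
        rows.append(pd.DataFrame({
            "site_id": "s1",
            "issue_date": issue.date,
            "lead_days": lead,
            "t_mean": obs["t_mean"].to_numpy() + bias
            + rng.normal(0, noise, n),
        }))
    return pd.concat(rows, ignore_index=True), obs


class TestBiasCorrection:
    def test_constant_offset_recovered(self):
        fc, obs = _paired_frames(bias=1.0)
        table = fit_mean_bias(fc, obs, variables=("t_mean",))
        assert table.get("s1", "t_mean", 1) == pytest.approx(1.0)
        assert table.get("s1", "t_mean", 2) == pytest.approx(1.0)

    def test_perfect_forecast_has_zero_bias(self):
        fc, obs = _paired_frames(bias=0.0)
        table = fit_mean_bias(fc, obs, variables=("t_mean",))
        assert table.get("s1", "t_mean", 1) == pytest.approx(0.0, abs=1e-12)

    def test_fit_then_apply_zeroes_sample_mean(self):
        fc, obs = _paired_frames(bias=-0.68, noise=1.0)
        table = fit_mean_bias(fc, obs, variables=("t_mean",))
        corrected = apply_bias_correction(fc, table)
        merged = corrected.copy()
        merged["valid_date"] = [
            d + pd.Timedelta(days=int(l))
            for d, l in zip(pd.to_datetime(merged["issue_date"]),
                            merged["lead_days"])
        ]
        obs_t = obs.set_index(pd.to_datetime(obs["date"]))["t_mean"]
        for lead in (1, 2):
            sub = merged[merged["lead_days"] == lead]
            resid = sub["t_mean"].to_numpy() - obs_t.loc[sub["valid_date"]].to_numpy()
            assert resid.mean() == pytest.approx(0.0, abs=1e-9)

    def test_rmse_decomposition_on_fitting_sample(self):
        fc, obs = _paired_frames(bias=-0.68, noise=1.2, seed=3)
        table = fit_mean_bias(fc, obs, variables=("t_mean",))
        corrected = apply_bias_correction(fc, table)
        obs_t = obs.set_index(pd.to_datetime(obs["date"]))["t_mean"]
        for frame, which in ((fc, "raw"), (corrected, "corr")):
            sub = frame[frame["lead_days"] == 1]
            valid = pd.to_datetime(sub["issue_date"]) + pd.Timedelta(days=1)
            err = sub["t_mean"].to_numpy() - obs_t.loc[valid].to_numpy()
            if which == "raw":
                raw_rmse2 = np.mean(err**2)
                raw_bias = err.mean()
            else:
                corr_rmse2 = np.mean(err**2)
        assert corr_rmse2 == pytest.approx(raw_rmse2 - raw_bias**2, abs=1e-9)

    def test_only_tabled_variables_touched(self):
        fc, obs = _paired_frames(bias=1.0)
        fc["rh_mean"] = 55.0
        table = fit_mean_bias(fc, obs, variables=("t_mean",))
        corrected = apply_bias_correction(fc, table)
        assert (corrected["rh_mean"] == 55.0).all()

    def test_insufficient_pairs_rejected(self):
        fc, obs = _paired_frames(n=10)
        with pytest.raises(ValueError, match="paired days"):
            fit_mean_bias(fc, obs, variables=("t_mean",), min_pairs=30)

    def test_missing_entry_passthrough_and_strict(self):
        fc, obs = _paired_frames()
        table = fit_mean_bias(fc, obs, variables=("t_mean",))
        extra = fc.copy()
        extra.loc[extra.index[-1], "site_id"] = "other"
        with pytest.warns(UserWarning, match="no bias entry"):
            out = apply_bias_correction(extra, table)
        untouched = out[out["site_id"] == "other"]["t_mean"]
        assert (untouched == extra[extra["site_id"] == "other"]["t_mean"]).all()
        with pytest.raises(KeyError):
            apply_bias_correction(extra, table, strict=True)


def test_bias_table_json_round_trip(tmp_path):
    fc, obs = _paired_frames(bias=0.5)
    table = fit_mean_bias(fc, obs, variables=("t_mean",),
                          reference_period=("2012-06-01", "2012-07-10"))
    path = tmp_path / "bias.json"
    table.to_json(path)
    from etcast import BiasTable

    back = BiasTable.from_json(path)
    assert back.entries == table.entries
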