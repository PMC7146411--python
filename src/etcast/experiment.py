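"""End-to-end synthetic forecasting experiment.

Runs the full methodology at desk scale on synthetic inputs: an 18-station
network, four reference irrigation seasons for calibrating the
Hargreaves-Samani factor and the forecast temperature bias, one evaluation
season with ensemble forecasts at leads 1-5 days, and two maize canopy
seasons (a vigorous, weekly-sampled field and a weaker, fortnightly-sampled
one) crossed with every station.  Skill (BIAS/RMSE) is computed per station
for daily values at each lead and for ETc accumulated over 1/3/5 days,
for both the temperature-only (HS) and full-variable (PM) forecast paths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date as _date

import numpy as np
import pandas as pd

from . import et, meteo
from .calibration import KhsFit, calibrate_khs
from .canopy import CanopyState
from .evaluation import SkillRecord, bias_rmse
from .forecast import HORIZONS
from .nwp import TEMPERATURE_COLUMNS, BiasTable, apply_bias_correction, fit_mean_bias
from .synthetic import (
    ForecastErrorModel,
    SiteClimatology,
    default_climatologies,
    gen_canopy_season,
    gen_forecasts,
    gen_weather,
)

__all__ = ["ExperimentResult", "run_synthetic_experiment", "held_canopy_arrays"]

_SEASON = (6, 1, 9, 30)  # June 1 - September 30
_TAIL_DAYS = 5  # extra truth days so every lead of the last issue date exists


@dataclass
class ExperimentResult:
    """Outputs of one synthetic experiment run."""

    skill: pd.DataFrame  # site_id, target, field_id-pooled skill rows
    khs_fits: dict  # site_id -> KhsFit
    bias_tables: dict  # site_id -> BiasTable
    kc: pd.DataFrame  # field_id, site_id, date, kc
    eval_weather: pd.DataFrame | None = None  # observed eval-season weather
    eval_forecasts: pd.DataFrame | None = None  # bias-corrected daily forecasts

    def records(self) -> list[SkillRecord]:
        return [
            SkillRecord(
                site_id=r.site_id,
                target=r.target,
                lead_or_horizon=int(r.lead_or_horizon),
                bias=r.bias,
                rmse=r.rmse,
                n=int(r.n),
            )
            for r in self.skill.itertuples()
        ]


def _season_range(year: int) -> tuple[_date, _date, _date]:
    start = _date(year, _SEASON[0], _SEASON[1])
    end = _date(year, _SEASON[2], _SEASON[3])
    return start, end, end + pd.Timedelta(days=_TAIL_DAYS).to_pytimedelta()


def held_canopy_arrays(states: list[CanopyState], dates) -> tuple[np.ndarray, np.ndarray]:
    """LAI and albedo step functions (forward fill) over a date array."""
    obs_dates = np.array([np.datetime64(s.date) for s in states])
    lai = np.array([s.lai for s in states])
    alb = np.array([s.albedo for s in states])
    d = np.array([np.datetime64(x) for x in dates])
    idx = np.searchsorted(obs_dates, d, side="right") - 1
    if np.any(idx < 0):
        raise ValueError("date precedes first canopy observation")
    return lai[idx], alb[idx]


def _weather_arrays(df: pd.DataFrame) -> dict:
    doy = pd.to_datetime(df["date"]).dt.dayofyear.to_numpy()
    return {
        "t_max": df["t_max"].to_numpy(),
        "t_min": df["t_min"].to_numpy(),
        "t_mean": df["t_mean"].to_numpy(),
        "rh_mean": df["rh_mean"].to_numpy(),
        "ws10": df["ws10"].to_numpy(),
        "rs_wm2": df["rs_wm2"].to_numpy(),
        "pressure": df["pressure_kpa"].to_numpy(),
        "doy": doy,
    }


def _et0_pm(df: pd.DataFrame, clim: SiteClimatology) -> np.ndarray:
    w = _weather_arrays(df)
    return et.et0_pm_values(
        w["t_max"], w["t_min"], w["rh_mean"], w["ws10"], w["rs_wm2"],
        clim.site.latitude, clim.site.elevation, w["doy"],
        pressure=w["pressure"], t_mean=w["t_mean"],
    )


def _etc_pm_obs(df: pd.DataFrame, clim: SiteClimatology, lai, albedo) -> np.ndarray:
    w = _weather_arrays(df)
    return et.etc_pm_values(
        w["t_max"], w["t_min"], w["rh_mean"], w["ws10"], w["rs_wm2"],
        clim.site.latitude, clim.site.elevation, w["doy"], lai, albedo,
        pressure=w["pressure"], t_mean=w["t_mean"],
    )


def _forecast_matrix(fc: pd.DataFrame, issue_dates, col) -> np.ndarray:
    """(n_issue, 5) matrix of one forecast column, rows ordered by issue."""
    pivot = fc.pivot_table(index="issue_date", columns="lead_days", values=col)
    pivot = pivot.reindex(issue_dates)
    return pivot[[1, 2, 3, 4, 5]].to_numpy()


def run_synthetic_experiment(
    seed: int,
    n_sites: int = 18,
    ref_years: tuple = (2010, 2011, 2012, 2013),
    eval_year: int = 2014,
    error_model: ForecastErrorModel | None = None,
    climatologies: list[SiteClimatology] | None = None,
    fields: dict[str, list[CanopyState]] | None = None,
) -> ExperimentResult:
    """Run calibration, bias correction, forecasting and verification.

    All randomness derives from ``seed`` through spawned child generators,
    so a fixed seed reproduces the experiment bit for bit.
    """
    model = error_model if error_model is not None else ForecastErrorModel()
    clims = climatologies if climatologies is not None else default_climatologies(n_sites)
    clims = clims[:n_sites]
    root = np.random.SeedSequence(seed)
    site_seeds = root.spawn(len(clims))

    # two canopy scenarios shared across stations: a vigorous weekly-sampled
    # field and a weaker fortnightly-sampled one
    s_start, s_end, _ = _season_range(eval_year)
    if fields is None:
        fields = {
            "field_vigorous": gen_canopy_season(
                "field_vigorous", s_start, s_end,
                flowering=_date(eval_year, 8, 1), lai_max=5.0,
                sampling_interval=7,
            )[0],
            "field_weak": gen_canopy_season(
                "field_weak", s_start, s_end,
                flowering=_date(eval_year, 8, 10), lai_max=3.5,
                sampling_interval=15,
            )[0],
        }

    skill_rows = []
    khs_fits: dict[str, KhsFit] = {}
    bias_tables: dict[str, BiasTable] = {}
    kc_rows = []
    eval_weather_frames = []
    eval_fc_frames = []

    for clim, sseq in zip(clims, site_seeds):
        rng = np.random.default_rng(sseq)
        site_id = clim.site.site_id

        # --- reference seasons: observed weather + temperature forecasts
        ref_weather, ref_fc = [], []
        for year in ref_years:
            start, end, tail = _season_range(year)
            wx = gen_weather(clim, start, tail, rng)
            ref_weather.append(wx)
            fc = gen_forecasts(
                wx, model, rng, variables=("T",),
                issue_dates=[d for d in wx["date"] if d <= end],
            )
            ref_fc.append(fc)
        ref_weather = pd.concat(ref_weather, ignore_index=True)
        ref_fc = pd.concat(ref_fc, ignore_index=True)

        # --- Hargreaves-Samani local calibration on the reference seasons
        in_season = pd.to_datetime(ref_weather["date"]).dt.month.isin(
            range(_SEASON[0], _SEASON[2] + 1)
        )
        cal = ref_weather[in_season]
        ra_cal = meteo.extraterrestrial_radiation(
            clim.site.latitude, pd.to_datetime(cal["date"]).dt.dayofyear.to_numpy()
        )
        hs_unit = et.et0_hs_values(
            cal["t_mean"].to_numpy(), cal["t_max"].to_numpy(),
            cal["t_min"].to_numpy(), ra_cal, 1.0,
        )
        khs_fits[site_id] = calibrate_khs(
            hs_unit, _et0_pm(cal, clim), site_id=site_id,
            reference_period=(str(ref_years[0]), str(ref_years[-1])),
        )

        # --- temperature bias correction fitted on the reference seasons
        table = fit_mean_bias(
            ref_fc, ref_weather, variables=TEMPERATURE_COLUMNS,
        )
        bias_tables[site_id] = table

        # --- evaluation season: observed weather, forecasts, correction
        start, end, tail = _season_range(eval_year)
        wx_eval = gen_weather(clim, start, tail, rng)
        issue_dates = [d for d in wx_eval["date"] if d <= end]
        fc_eval = gen_forecasts(
            wx_eval, model, rng, issue_dates=issue_dates,
        )
        fc_eval = apply_bias_correction(fc_eval, table)
        eval_weather_frames.append(wx_eval)
        eval_fc_frames.append(fc_eval)

        n_issue = len(issue_dates)
        eval_dates = wx_eval["date"].tolist()
        date_pos = {d: i for i, d in enumerate(eval_dates)}
        issue_idx = np.array([date_pos[d] for d in issue_dates])
        valid_idx = issue_idx[:, None] + np.arange(1, 6)[None, :]
        valid_doy = pd.to_datetime(wx_eval["date"]).dt.dayofyear.to_numpy()[valid_idx]

        cols = {
            c: _forecast_matrix(fc_eval, issue_dates, c)
            for c in ("t_mean", "t_max", "t_min", "rh_mean", "ws10",
                      "rs_wm2", "pressure_kpa")
        }
        et0_eval = _et0_pm(wx_eval, clim)

        for field_id, states in fields.items():
            lai_day, alb_day = held_canopy_arrays(states, eval_dates)
            best = _etc_pm_obs(wx_eval, clim, lai_day, alb_day)

            kc = best[issue_idx] / et0_eval[issue_idx]
            kc_rows.append(
                pd.DataFrame(
                    {"field_id": field_id, "site_id": site_id,
                     "date": issue_dates, "kc": kc}
                )
            )

            # HS path: Kc(t0) x calibrated Hargreaves-Samani on corrected T
            ra_valid = meteo.extraterrestrial_radiation(
                clim.site.latitude, valid_doy
            )
            et0_hs = et.et0_hs_values(
                cols["t_mean"], cols["t_max"], cols["t_min"], ra_valid,
                khs_fits[site_id].k_hs,
            )
            etc_hs = kc[:, None] * et0_hs

            # PM path: one-step equation on full forecast weather with the
            # canopy held at t0
            etc_pm = et.etc_pm_values(
                cols["t_max"], cols["t_min"], cols["rh_mean"], cols["ws10"],
                cols["rs_wm2"], clim.site.latitude, clim.site.elevation,
                valid_doy, lai_day[issue_idx][:, None],
                alb_day[issue_idx][:, None],
                pressure=cols["pressure_kpa"], t_mean=cols["t_mean"],
            )

            best_leads = best[valid_idx]  # (n_issue, 5)
            for path, daily in (("HS", etc_hs), ("PM", etc_pm)):
                for j, lead in enumerate(range(1, 6)):
                    b, r, n = bias_rmse(daily[:, j], best_leads[:, j])
                    skill_rows.append(
                        (site_id, field_id, f"ETc-{path}-daily", lead, b, r, n)
                    )
                for h in HORIZONS:
                    acc_f = daily[:, :h].sum(axis=1)
                    acc_o = best_leads[:, :h].sum(axis=1)
                    b, r, n = bias_rmse(acc_f, acc_o)
                    skill_rows.append(
                        (site_id, field_id, f"ETc-{path}-acc", h, b, r, n)
                    )

    per_field = pd.DataFrame(
        skill_rows,
        columns=["site_id", "field_id", "target", "lead_or_horizon",
                 "bias", "rmse", "n"],
    )
    # pool the two canopy scenarios per site (RMSE pooled in quadrature)
    pooled = (
        per_field.groupby(["site_id", "target", "lead_or_horizon"])
        .apply(
            lambda g: pd.Series(
                {
                    "bias": np.average(g["bias"], weights=g["n"]),
                    "rmse": np.sqrt(np.average(g["rmse"] ** 2, weights=g["n"])),
                    "n": g["n"].sum(),
                }
            ),
            include_groups=False,
        )
        .reset_index()
    )
    return ExperimentResult(
        skill=pooled,
        khs_fits=khs_fits,
        bias_tables=bias_tables,
        kc=pd.concat(kc_rows, ignore_index=True),
        eval_weather=pd.concat(eval_weather_frames, ignore_index=True),
        eval_forecasts=pd.concat(eval_fc_frames, ignore_index=True),
    )
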