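"""Synthetic weather, ensemble forecasts and canopy seasons.

This module generates inputs with the statistical structure of the study
conditions the package targets: a network of Mediterranean automatic weather
stations, a limited-area ensemble forecast system whose raw temperature
carries a systematic cold bias of about -0.68 degC and noise that grows with
lead time, and maize canopy seasons whose LAI rises to about 5 at flowering
while the broadband albedo drifts from 0.15 to 0.20.

Everything is driven by :class:`numpy.random.Generator` seeds and is fully
deterministic for a fixed seed.  The generated frames use exactly the CSV
dialects consumed by the rest of the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from datetime import date as _date, timedelta

import numpy as np
import pandas as pd

from . import meteo
from .canopy import CanopyState, ClairParams, SensorSpec, forward_wdvi
from .meteo import SiteMeta

__all__ = [
    "SiteClimatology",
    "ForecastErrorModel",
    "DEFAULT_SENSOR",
    "DEFAULT_CLAIR",
    "default_climatologies",
    "gen_weather",
    "gen_forecasts",
    "gen_canopy_season",
]

#: Synthetic 3-band sensor (green/red/NIR) used by the canopy generator.
DEFAULT_SENSOR = SensorSpec(
    sensor_id="synthetic-3band",
    bands=(("green", 0.35), ("red", 0.30), ("nir", 0.35)),
    soil_line_slope=1.2,
)

DEFAULT_CLAIR = ClairParams(wdvi_inf=0.50, alpha_star=0.35)

# Station climatologies of an 18-station Mediterranean network (irrigation
# season means: elevation m, lat, lon, T degC, WS10 m/s, RH %, RS W/m2),
# patterned on the coastal-to-Apennine gradient of Campania, Southern Italy.
_STATION_ROWS = [
    ("aws01", 848, 40.65, 14.54, 20.3, 2.1, 72.3, 243.3),
    ("aws02", 631, 41.20, 15.14, 21.3, 3.0, 67.6, 264.1),
    ("aws03", 236, 41.12, 14.83, 22.8, 1.9, 68.5, 262.8),
    ("aws04", 9, 41.20, 13.84, 23.4, 1.9, 77.1, 265.3),
    ("aws05", 770, 40.86, 15.28, 20.8, 4.4, 69.5, 267.9),
    ("aws06", 1, 40.94, 14.02, 23.7, 2.5, 76.7, 268.5),
    ("aws07", 515, 40.84, 15.04, 20.2, 1.2, 71.5, 251.7),
    ("aws08", 552, 40.26, 15.66, 20.7, 1.5, 77.0, 256.9),
    ("aws09", 88, 40.79, 14.16, 25.7, 3.2, 74.9, 276.3),
    ("aws10", 660, 40.56, 15.24, 21.4, 4.0, 66.8, 256.4),
    ("aws11", 62, 41.43, 13.88, 23.4, 1.2, 76.0, 240.3),
    ("aws12", 750, 41.42, 15.04, 20.6, 4.2, 70.3, 266.4),
    ("aws13", 31, 41.02, 14.34, 25.8, 1.9, 67.1, 255.9),
    ("aws14", 167, 41.25, 14.47, 23.7, 1.9, 70.9, 260.2),
    ("aws15", 13, 40.64, 14.84, 26.0, 2.1, 65.5, 261.6),
    ("aws16", 413, 40.13, 15.46, 23.2, 2.6, 71.5, 260.8),
    ("aws17", 117, 41.34, 14.33, 22.9, 1.1, 67.0, 254.4),
    ("aws18", 64, 40.61, 14.98, 24.7, 1.3, 63.3, 263.7),
]


@dataclass(frozen=True)
class SiteClimatology:
    """Irrigation-season climatology and anomaly model of one station.

    Daily anomalies follow an AR(1) process per variable around a seasonal
    harmonic (for temperature) or the climatological mean.
    """

    site: SiteMeta
    mean_t: float  # degC
    mean_ws10: float  # m s-1
    mean_rh: float  # %
    mean_rs: float  # W m-2
    amp_t: float = 3.0  # seasonal harmonic amplitude of T, degC
    ar1: float = 0.7  # anomaly persistence, all variables
    sd_t: float = 1.5  # daily anomaly innovation sd, degC
    sd_rh: float = 6.0  # %
    sd_ws_frac: float = 0.25  # fraction of mean_ws10
    sd_rs_ratio: float = 0.10  # sd of the clearness-ratio anomaly
    diurnal_range_mean: float = 10.0  # Tmax - Tmin, degC
    diurnal_range_sd: float = 2.0

    def __post_init__(self) -> None:
        if not 30.0 <= self.mean_rh <= 95.0:
            raise ValueError("mean_rh outside [30, 95]")
        if not 0.0 <= self.ar1 < 1.0:
            raise ValueError("ar1 outside [0, 1)")


def default_climatologies(n_sites: int = 18) -> list[SiteClimatology]:
    """The default 18-station network (or its first ``n_sites`` stations)."""
    clims = []
    for sid, elev, lat, lon, t, ws, rh, rs in _STATION_ROWS[:n_sites]:
        clims.append(
            SiteClimatology(
                site=SiteMeta(site_id=sid, latitude=lat, longitude=lon,
                              elevation=elev),
                mean_t=t, mean_ws10=ws, mean_rh=rh, mean_rs=rs,
            )
        )
    return clims


@dataclass(frozen=True)
class ForecastErrorModel:
    """Additive error model of the synthetic ensemble forecast system.

    Member value = truth + systematic bias + shared daily forecast error
    (sd growing linearly with lead) + member dispersion.  Defaults inject
    the -0.68 degC systematic temperature bias of a raw limited-area
    ensemble against station observations; other variables are unbiased.
    """

    bias: dict = field(
        default_factory=lambda: {"T": -0.68, "RH": 0.0, "WS10": 0.0,
                                 "RS": 0.0, "P": 0.0}
    )
    noise_sd: dict = field(
        default_factory=lambda: {"T": 1.2, "RH": 8.0, "WS10": 0.7,
                                 "RS": 30.0, "P": 0.2}
    )
    member_sd: dict = field(
        default_factory=lambda: {"T": 0.8, "RH": 5.0, "WS10": 0.5,
                                 "RS": 20.0, "P": 0.1}
    )
    lead_growth: float = 0.2  # fractional sd growth per extra lead day
    members: int = 16

    def __post_init__(self) -> None:
        if self.members < 2:
            raise ValueError("at least 2 ensemble members required")
        if any(v < 0 for v in self.noise_sd.values()) or any(
            v < 0 for v in self.member_sd.values()
        ):
            raise ValueError("noise sds must be >= 0")

    def zeroed(self) -> "ForecastErrorModel":
        """A copy with no bias and no noise (forecast == truth)."""
        return replace(
            self,
            bias={k: 0.0 for k in self.bias},
            noise_sd={k: 0.0 for k in self.noise_sd},
            member_sd={k: 0.0 for k in self.member_sd},
        )


def _ar1(rng: np.random.Generator, n: int, phi: float, sd: float) -> np.ndarray:
    """Stationary AR(1) anomaly series with innovation sd ``sd``."""
    if sd == 0.0 or n == 0:
        return np.zeros(n)
    x = np.empty(n)
    marginal = sd / np.sqrt(1.0 - phi**2)
    x[0] = rng.normal(0.0, marginal)
    eps = rng.normal(0.0, sd, size=n - 1)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i - 1]
    return x


def gen_weather(
    clim: SiteClimatology,
    start: _date,
    end: _date,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Generate a daily observed-weather series for one station.

    Temperature follows the seasonal harmonic plus AR(1) anomalies, centred
    so the long-run mean over the requested range equals the climatological
    mean; shortwave radiation is a clearness ratio times the clear-sky cap,
    so it can never exceed the cap.  Columns match the weather CSV dialect.
    """
    if end < start:
        raise ValueError("empty date range")
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    dates = pd.date_range(start, end, freq="D")
    n = len(dates)
    doy = dates.dayofyear.to_numpy()

    harmonic = np.cos(2.0 * np.pi * (doy - 205) / 365.0)
    harmonic = harmonic - harmonic.mean()  # zero-mean over the range
    t_mean = clim.mean_t + clim.amp_t * harmonic + _ar1(
        rng, n, clim.ar1, clim.sd_t
    )
    half_range = 0.5 * np.clip(
        rng.normal(clim.diurnal_range_mean, clim.diurnal_range_sd, size=n),
        2.0, 20.0,
    )
    rh = np.clip(
        clim.mean_rh + _ar1(rng, n, clim.ar1, clim.sd_rh), 25.0, 98.0
    )
    ws = np.clip(
        clim.mean_ws10
        + _ar1(rng, n, clim.ar1, clim.sd_ws_frac * clim.mean_ws10),
        0.2, None,
    )
    ra = meteo.extraterrestrial_radiation(clim.site.latitude, doy)
    cap_wm2 = meteo.clear_sky_radiation(ra, clim.site.elevation) / meteo.WM2_TO_MJ_DAY
    target_ratio = np.clip(clim.mean_rs / max(cap_wm2.mean(), 1e-9), 0.15, 0.95)
    ratio = np.clip(
        target_ratio + _ar1(rng, n, clim.ar1, clim.sd_rs_ratio), 0.15, 1.0
    )
    rs = ratio * cap_wm2

    return pd.DataFrame(
        {
            "site_id": clim.site.site_id,
            "date": [d.date() for d in dates],
            "t_max": t_mean + half_range,
            "t_min": t_mean - half_range,
            "t_mean": t_mean,
            "rh_mean": rh,
            "ws10": ws,
            "rs_wm2": rs,
            "pressure_kpa": float(meteo.barometric_pressure(clim.site.elevation)),
        }
    )


# 3-hourly shapes of the diurnal cycle (8 steps per day).  The temperature
# shape has mean 0, max +1 and min -1, so the stepwise profile preserves the
# daily mean and extremes exactly; the radiation weights have mean 1.
_T_SHAPE = np.array([-1.0, -0.8, -0.3, 0.5, 1.0, 0.9, 0.3, -0.6])
_RS_SHAPE = np.array([0.0, 0.0, 0.9, 2.1, 2.6, 1.7, 0.7, 0.0])


def _truth_steps(weather: pd.DataFrame, variable: str) -> np.ndarray:
    """3-hourly truth profile per day, shape (n_days, 8)."""
    if variable == "T":
        t = weather["t_mean"].to_numpy()[:, None]
        half = 0.5 * (weather["t_max"] - weather["t_min"]).to_numpy()[:, None]
        return t + half * _T_SHAPE
    if variable == "RS":
        return weather["rs_wm2"].to_numpy()[:, None] * _RS_SHAPE
    col = {"RH": "rh_mean", "WS10": "ws10", "P": "pressure_kpa"}[variable]
    return np.repeat(weather[col].to_numpy()[:, None], 8, axis=1)


_NONNEG = {"RS", "WS10"}


def gen_forecasts(
    truth: pd.DataFrame,
    model: ForecastErrorModel,
    seed: int | np.random.Generator,
    issue_dates=None,
    leads: range = range(1, 6),
    variables=("T", "RH", "WS10", "RS", "P"),
    as_long: bool = False,
):
    """Generate an ensemble forecast set against a daily truth series.

    Returns the member-level values reduced to daily per-site forecasts
    (median across members per 3-hourly step, then mean of the eight steps;
    daily temperature extremes are the max/min of the stepwise medians).
    With ``as_long=True`` additionally returns the member-level long-format
    frame for use with :func:`etcast.nwp.reduce_daily`.

    Issue dates default to every truth day whose lead-1..5 valid days are
    all inside the truth range.
    """
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    truth = truth.sort_values("date").reset_index(drop=True)
    dates = pd.to_datetime(truth["date"])
    date_index = {d.date(): i for i, d in enumerate(dates)}
    max_lead = max(leads)
    if issue_dates is None:
        issue_dates = [
            d.date() for d in dates
            if (d + pd.Timedelta(days=max_lead)).date() in date_index
        ]
    issue_idx = []
    for d in issue_dates:
        for l in leads:
            if d + timedelta(days=l) not in date_index:
                raise ValueError(f"truth does not cover {d} + {l} days")
        issue_idx.append([date_index[d + timedelta(days=l)] for l in leads])
    issue_idx = np.array(issue_idx)  # (n_issue, n_leads)
    n_issue, n_leads = issue_idx.shape
    m = model.members
    site_id = truth["site_id"].iloc[0]

    reduced = {
        "site_id": np.repeat(site_id, n_issue * n_leads),
        "issue_date": np.repeat(issue_dates, n_leads),
        "lead_days": np.tile(list(leads), n_issue),
    }
    long_rows = {}
    lead_arr = np.array(list(leads), dtype=float)
    sd_scale = 1.0 + model.lead_growth * (lead_arr - 1.0)

    for var in variables:
        steps = _truth_steps(truth, var)  # (n_days, 8)
        base = steps[issue_idx]  # (n_issue, n_leads, 8)
        shared = rng.normal(
            0.0, 1.0, size=(n_issue, n_leads)
        ) * (model.noise_sd[var] * sd_scale)
        member = rng.normal(
            0.0, model.member_sd[var], size=(n_issue, n_leads, m)
        )
        values = (
            base[:, :, None, :]
            + model.bias[var]
            + shared[:, :, None, None]
            + member[:, :, :, None]
        )  # (n_issue, n_leads, m, 8)
        if var in _NONNEG:
            values = np.maximum(values, 0.0)
        elif var == "RH":
            values = np.clip(values, 0.0, 100.0)
        med = np.median(values, axis=2)  # (n_issue, n_leads, 8)
        if var == "T":
            reduced["t_mean"] = med.mean(axis=2).ravel()
            reduced["t_max"] = med.max(axis=2).ravel()
            reduced["t_min"] = med.min(axis=2).ravel()
        else:
            col = {"RH": "rh_mean", "WS10": "ws10", "RS": "rs_wm2",
                   "P": "pressure_kpa"}[var]
            reduced[col] = med.mean(axis=2).ravel()
        if as_long:
            long_rows[var] = values

    reduced_df = pd.DataFrame(reduced)
    for col in ("t_mean", "t_max", "t_min", "rh_mean", "ws10", "rs_wm2",
                "pressure_kpa"):
        if col not in reduced_df.columns:
            reduced_df[col] = np.nan
    if not as_long:
        return reduced_df

    records = []
    for var, values in long_rows.items():
        for i, d0 in enumerate(issue_dates):
            for j, l in enumerate(leads):
                valid_day = pd.Timestamp(d0) + pd.Timedelta(days=int(l))
                for k in range(m):
                    for s in range(8):
                        records.append(
                            (
                                site_id,
                                pd.Timestamp(d0),
                                k + 1,
                                var,
                                valid_day + pd.Timedelta(hours=3 * s),
                                values[i, j, k, s],
                            )
                        )
    long_df = pd.DataFrame(
        records,
        columns=["site_id", "issue_time", "member_id", "variable",
                 "valid_time", "value"],
    )
    return reduced_df, long_df


def gen_canopy_season(
    field_id: str,
    start: _date,
    end: _date,
    flowering: _date,
    lai_max: float = 5.0,
    albedo_range: tuple = (0.15, 0.20),
    clair: ClairParams = DEFAULT_CLAIR,
    sensor: SensorSpec = DEFAULT_SENSOR,
    sampling_interval: int = 7,
    rise_rate: float = 0.15,  # logistic rate, day-1
    decline_rate: float = 0.01,  # fractional LAI loss per day after flowering
    lai_floor: float = 0.2,
):
    """Generate a maize-like canopy season sampled at satellite revisits.

    LAI rises along a logistic curve normalized to hit ``lai_max`` exactly
    on the flowering date, then declines linearly (senescence); albedo is
    linear in LAI between the early-season and full-canopy values.  Band
    reflectances are produced by the forward CLAIR map (red reflectance
    decays with canopy closure; NIR is set so the weighted difference index
    matches exactly), so LAI retrieval round-trips to machine precision.

    Returns
    -------
    (states, reflectance) : list of :class:`CanopyState` and a DataFrame in
        the reflectance CSV dialect.
    """
    if lai_max <= 0.0:
        raise ValueError("lai_max must be positive")
    lo, hi = albedo_range
    if not lo < hi:
        raise ValueError("albedo_range must be increasing")
    if not start <= flowering <= end:
        raise ValueError("flowering must fall inside the season")
    sample_dates = []
    d = start
    while d <= end:
        sample_dates.append(d)
        d += timedelta(days=sampling_interval)

    t = np.array([(d - start).days for d in sample_dates], dtype=float)
    t_flower = float((flowering - start).days)
    t_mid = t_flower - 25.0

    def logistic(x):
        return 1.0 / (1.0 + np.exp(-rise_rate * (x - t_mid)))

    f0, f1 = logistic(0.0), logistic(t_flower)
    rise = lai_max * (logistic(t) - f0) / (f1 - f0)
    decline = lai_max * (1.0 - decline_rate * (t - t_flower))
    lai = np.where(t <= t_flower, rise, decline)
    lai = np.clip(lai, lai_floor, lai_max)

    albedo = lo + (hi - lo) * lai / lai_max
    wdvi = forward_wdvi(lai, clair)
    rho_red = 0.02 + 0.23 * np.exp(-0.6 * lai)
    rho_nir = wdvi + sensor.soil_line_slope * rho_red

    states = [
        CanopyState(date=d, lai=float(l), albedo=float(a))
        for d, l, a in zip(sample_dates, lai, albedo)
    ]
    reflectance = pd.DataFrame(
        {
            "field_id": field_id,
            "date": sample_dates,
            "sensor_id": sensor.sensor_id,
            "rho_red": rho_red,
            "rho_nir": rho_nir,
        }
    )
    return states, reflectance
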