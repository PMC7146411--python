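"""Crop-coefficient computation and ETc forecasting.

The crop coefficient is computed analytically as the ratio of the one-step
crop Penman-Monteith estimate to the reference estimate, both driven by the
weather observed on the forecast issue day t0:

    Kc(t0) = ETc-PM,obs(t0) / ET0-PM,obs(t0)

Canopy parameters inside Kc are updated whenever a new multispectral
retrieval arrives (weekly to fortnightly) and held constant in between,
while the weather part refreshes daily.

ETc forecasts at leads of 1-5 days are issued by two paths:

* HS — the proposed temperature-only path, Kc(t0) times the locally
  calibrated Hargreaves-Samani ET0 driven by bias-corrected forecast
  temperature;
* PM — the comparison path, the one-step Penman-Monteith evaluated directly
  on the full set of forecast weather variables with the same held canopy.

Daily values are accumulated to the 1-, 3- and 5-day horizons relevant for
irrigation scheduling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from datetime import date as _date
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import et, meteo
from .canopy import CanopyState, hold_canopy
from .meteo import SiteMeta, WeatherDaily

__all__ = [
    "KcRecord",
    "EtcForecast",
    "HORIZONS",
    "MIN_ET0_FOR_KC",
    "crop_coefficient",
    "forecast_etc",
    "accumulate",
]

#: Accumulation horizons (days) reported for irrigation scheduling.
HORIZONS = (1, 3, 5)

#: ET0 floor (mm day-1) below which the Kc ratio is considered undefined.
MIN_ET0_FOR_KC = 0.1


@dataclass(frozen=True)
class KcRecord:
    """An analytically computed crop coefficient for one field and day."""

    field_id: str
    site_id: str
    date: _date
    kc: float
    canopy_date: _date

    def __post_init__(self) -> None:
        if not (np.isfinite(self.kc) and self.kc > 0.0):
            raise ValueError("kc must be finite and positive")
        if self.canopy_date > self.date:
            raise ValueError("canopy_date must not postdate the Kc date")


@dataclass
class EtcForecast:
    """ETc forecast for one field, site and issue date over leads 1-5."""

    field_id: str
    site_id: str
    issue_date: _date
    etc_hs: dict = field(default_factory=dict)  # lead -> mm day-1
    etc_pm: dict = field(default_factory=dict)  # lead -> mm day-1 (optional)
    accumulated_hs: dict = field(default_factory=dict)  # horizon -> mm
    accumulated_pm: dict = field(default_factory=dict)


def crop_coefficient(
    wx_t0: WeatherDaily,
    canopy: CanopyState | Sequence[CanopyState],
    site: SiteMeta,
    field_id: str = "",
    h_c: float = et.DEFAULT_CROP_HEIGHT,
    r_s: float | None = None,
) -> KcRecord:
    """Analytic crop coefficient from day-t0 weather and the held canopy.

    ``canopy`` may be a single state or a dated series, in which case the
    state in force at t0 is selected by forward fill.  ``r_s`` overrides the
    LAI-derived surface resistance (e.g. the reference-crop 70 s m-1).
    """
    if not isinstance(canopy, CanopyState):
        canopy = hold_canopy(list(canopy), wx_t0.date)
    et0 = et.et0_penman_monteith(wx_t0, site).et
    if et0 < MIN_ET0_FOR_KC:
        raise ValueError(
            f"ET0 = {et0:.3f} mm day-1 below {MIN_ET0_FOR_KC}: Kc undefined"
        )
    etc = et.etc_penman_monteith(wx_t0, canopy, site, h_c=h_c, r_s=r_s).et
    return KcRecord(
        field_id=field_id,
        site_id=site.site_id,
        date=wx_t0.date,
        kc=etc / et0,
        canopy_date=canopy.date,
    )


def accumulate(daily: Mapping[int, float] | Sequence[float]) -> dict:
    """Partial sums of per-lead daily values at the 1/3/5-day horizons."""
    if not isinstance(daily, Mapping):
        daily = {lead: v for lead, v in enumerate(daily, start=1)}
    missing = [l for l in range(1, max(HORIZONS) + 1) if l not in daily]
    if missing:
        raise ValueError(f"missing leads {missing}")
    return {h: float(sum(daily[l] for l in range(1, h + 1))) for h in HORIZONS}


def forecast_etc(
    kc: KcRecord,
    forecast: pd.DataFrame,
    site: SiteMeta,
    canopy: CanopyState,
    k_hs: float = 1.0,
    method: str = "both",
    h_c: float = et.DEFAULT_CROP_HEIGHT,
) -> EtcForecast:
    """Issue an ETc forecast for one field from one reduced daily forecast.

    Parameters
    ----------
    kc : crop coefficient at the issue date t0.
    forecast : reduced daily forecast rows for this site and t0 (one row per
        lead 1..5, columns as produced by :func:`etcast.nwp.reduce_daily`);
        temperature is expected to be bias-corrected already.
    canopy : the canopy state held at t0 (used by the PM path).
    k_hs : locally calibrated Hargreaves-Samani scaling factor (HS path).
    method : "HS", "PM" or "both".
    """
    if method not in {"HS", "PM", "both"}:
        raise ValueError(f"unknown method {method!r}")
    fc = forecast.sort_values("lead_days")
    issue = pd.Timestamp(kc.date)
    if not (pd.to_datetime(fc["issue_date"]) == issue).all():
        raise ValueError("forecast issue_date does not match the Kc date")
    leads = fc["lead_days"].to_numpy()
    if sorted(leads) != list(range(1, 6)):
        raise ValueError(f"expected leads 1..5, got {sorted(leads)}")

    out = EtcForecast(
        field_id=kc.field_id, site_id=kc.site_id, issue_date=kc.date
    )
    valid_doy = np.array(
        [(issue + pd.Timedelta(days=int(l))).dayofyear for l in leads]
    )
    if method in {"HS", "both"}:
        for col in ("t_mean", "t_max", "t_min"):
            if fc[col].isna().any():
                raise ValueError(f"missing forecast {col} for the HS path")
        ra = meteo.extraterrestrial_radiation(site.latitude, valid_doy)
        et0_hs = et.et0_hs_values(
            fc["t_mean"].to_numpy(), fc["t_max"].to_numpy(),
            fc["t_min"].to_numpy(), ra, k_hs,
        )
        out.etc_hs = {int(l): float(kc.kc * v) for l, v in zip(leads, et0_hs)}
        out.accumulated_hs = accumulate(out.etc_hs)
    if method in {"PM", "both"}:
        for col in ("t_mean", "t_max", "t_min", "rh_mean", "ws10", "rs_wm2"):
            if fc[col].isna().any():
                raise ValueError(f"missing forecast {col} for the PM path")
        pressure = fc["pressure_kpa"].to_numpy()
        if np.isnan(pressure).all():
            pressure = None
        etc_pm = et.etc_pm_values(
            fc["t_max"].to_numpy(), fc["t_min"].to_numpy(),
            fc["rh_mean"].to_numpy(), fc["ws10"].to_numpy(),
            fc["rs_wm2"].to_numpy(), site.latitude, site.elevation,
            valid_doy, canopy.lai, canopy.albedo, h_c=h_c,
            pressure=pressure, t_mean=fc["t_mean"].to_numpy(),
        )
        out.etc_pm = {int(l): float(v) for l, v in zip(leads, etc_pm)}
        out.accumulated_pm = accumulate(out.etc_pm)
    return out
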