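"""Daily evapotranspiration estimators.

Three estimators share the primitives from :mod:`etcast.meteo`:

* ``et0_penman_monteith`` — FAO-56 reference evapotranspiration of the
  hypothetical grass crop (albedo 0.23, fixed canopy resistances folded into
  the familiar 900/(T+273) and 0.34*u2 coefficients).
* ``etc_penman_monteith`` — the one-step crop form: the full Penman-Monteith
  combination equation with the crop's own broadband albedo in the net
  radiation and resistances derived from crop height and LAI,

      ETc = 86400/lambda * [Delta*(Rn - G) + rho*cp*(es - ea)/ra]
                          / [Delta + gamma*(1 + rs/ra)]

  with the bracketed flux evaluated in W m-2 and converted to mm day-1.
* ``et0_hargreaves`` — the temperature-only Hargreaves-Samani equation with a
  locally calibrated scaling factor kHS.

All array functions broadcast; record-level wrappers operate on
:class:`~etcast.meteo.WeatherDaily` / :class:`~etcast.canopy.CanopyState`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from datetime import date as _date

import numpy as np

from . import meteo
from .canopy import CanopyState
from .meteo import SiteMeta, WeatherDaily

__all__ = [
    "EtValue",
    "ResistancePair",
    "VON_KARMAN",
    "DEFAULT_CROP_HEIGHT",
    "REFERENCE_ALBEDO",
    "CALM_WIND_FLOOR",
    "aerodynamic_resistance",
    "surface_resistance",
    "et0_pm_values",
    "etc_pm_values",
    "et0_hs_values",
    "et0_penman_monteith",
    "etc_penman_monteith",
    "et0_hargreaves",
]

VON_KARMAN = 0.41
#: Default crop height (m); sensitivity of ETc in 0.1-0.6 m is negligible.
DEFAULT_CROP_HEIGHT = 0.4
REFERENCE_ALBEDO = 0.23
#: Floor applied to 2 m wind in the resistance equations (Eq. diverges at 0).
CALM_WIND_FLOOR = 0.1


@dataclass(frozen=True)
class ResistancePair:
    """Aerodynamic and surface resistances (s m-1)."""

    r_a: float
    r_s: float

    def __post_init__(self) -> None:
        if self.r_a <= 0.0:
            raise ValueError("r_a must be positive")
        if self.r_s < 50.0:
            raise ValueError("r_s below the 50 s m-1 closed-canopy floor")


@dataclass(frozen=True)
class EtValue:
    """A daily evapotranspiration estimate, mm day-1."""

    date: _date
    et: float
    method: str  # ET0-PM | ETc-PM | ET0-HS | ETc-HS

    def __post_init__(self) -> None:
        if self.et < 0.0:
            raise ValueError("et must be >= 0")
        if self.method not in {"ET0-PM", "ETc-PM", "ET0-HS", "ETc-HS"}:
            raise ValueError(f"unknown method {self.method!r}")


def aerodynamic_resistance(h_c, ws2):
    """Aerodynamic resistance r_a (s m-1) for a crop of height h_c (m).

    Logarithmic-profile form with measurement heights at 2 m, zero-plane
    displacement 2/3 h_c, momentum roughness 0.123 h_c and heat roughness one
    tenth of that.  ws2 = 0 is a calm-wind error; callers substitute
    :data:`CALM_WIND_FLOOR`.
    """
    h_c = np.asarray(h_c, dtype=float)
    ws2 = np.asarray(ws2, dtype=float)
    if np.any((h_c <= 0.0) | (h_c >= 3.0)):
        raise ValueError("h_c must be in (0, 3) m so that 2 - (2/3) h_c > 0")
    if np.any(ws2 <= 0.0):
        raise ValueError("calm wind: ws2 must be positive (apply a floor)")
    z_minus_d = 2.0 - (2.0 / 3.0) * h_c
    ra = (
        np.log(z_minus_d / (0.123 * h_c))
        * np.log(z_minus_d / (0.0123 * h_c))
        / (VON_KARMAN**2 * ws2)
    )
    return ra if ra.ndim else float(ra)


def surface_resistance(lai):
    """Canopy surface resistance r_s (s m-1): 200/LAI up to LAI = 4, then 50.

    Continuous at LAI = 4 (200/4 = 50).  LAI <= 0 is a degenerate
    no-transpiration case and raises.
    """
    lai = np.asarray(lai, dtype=float)
    if np.any(lai <= 0.0):
        raise ValueError("lai must be positive for surface resistance")
    rs = np.where(lai <= 4.0, 200.0 / lai, 50.0)
    return rs if rs.ndim else float(rs)


def _clamp_nonneg(et, what):
    et = np.asarray(et, dtype=float)
    if np.any(et < 0.0):
        warnings.warn(f"negative {what} clamped to 0", stacklevel=3)
    out = np.maximum(et, 0.0)
    return out if out.ndim else float(out)


def et0_pm_values(
    t_max, t_min, rh_mean, ws10, rs_wm2, latitude, elevation, day_of_year,
    pressure=None, t_mean=None,
):
    """FAO-56 reference evapotranspiration ET0 (mm day-1), vectorized.

    ``rs_wm2`` is the daily mean shortwave in W m-2; wind at 10 m is
    converted to 2 m internally; soil heat flux is zero at the daily scale.
    """
    t_max = np.asarray(t_max, dtype=float)
    t_min = np.asarray(t_min, dtype=float)
    if t_mean is None:
        t_mean = 0.5 * (t_max + t_min)
    e_s, e_a, delta = meteo.vapor_pressures(t_max, t_min, rh_mean)
    consts = meteo.air_constants(elevation, t_mean, pressure)
    gamma = consts["gamma"]
    u2 = meteo.wind_2m_from_10m(ws10)
    ra = meteo.extraterrestrial_radiation(latitude, day_of_year)
    rn = meteo.net_radiation(
        rs_wm2, REFERENCE_ALBEDO, t_max, t_min, e_a, ra, elevation
    )
    num = 0.408 * delta * rn + gamma * 900.0 / (t_mean + 273.0) * u2 * (e_s - e_a)
    den = delta + gamma * (1.0 + 0.34 * u2)
    return _clamp_nonneg(num / den, "ET0-PM")


def etc_pm_values(
    t_max, t_min, rh_mean, ws10, rs_wm2, latitude, elevation, day_of_year,
    lai, albedo, h_c=DEFAULT_CROP_HEIGHT, pressure=None, t_mean=None,
    r_s=None,
):
    """One-step crop Penman-Monteith ETc (mm day-1), vectorized.

    Canopy albedo enters the net radiation; LAI sets the surface resistance
    (``r_s`` may override it, e.g. to force the reference-crop 70 s m-1);
    crop height sets the aerodynamic resistance.  The combination equation is
    evaluated with all flux terms in W m-2, then converted to water depth via
    86400 / (lambda * 1e6).
    """
    t_max = np.asarray(t_max, dtype=float)
    t_min = np.asarray(t_min, dtype=float)
    if t_mean is None:
        t_mean = 0.5 * (t_max + t_min)
    e_s, e_a, delta = meteo.vapor_pressures(t_max, t_min, rh_mean)
    consts = meteo.air_constants(elevation, t_mean, pressure)
    gamma = consts["gamma"]
    rho = consts["rho_air"]
    cp_j = consts["c_p"] * 1e6  # MJ kg-1 K-1 -> J kg-1 K-1
    u2 = np.maximum(meteo.wind_2m_from_10m(ws10), CALM_WIND_FLOOR)
    ra_sol = meteo.extraterrestrial_radiation(latitude, day_of_year)
    rn = meteo.net_radiation(rs_wm2, albedo, t_max, t_min, e_a, ra_sol, elevation)
    rn_w = rn / meteo.WM2_TO_MJ_DAY  # MJ m-2 day-1 -> W m-2
    r_a = aerodynamic_resistance(h_c, u2)
    if r_s is None:
        r_s = surface_resistance(lai)
    bracket = (delta * rn_w + rho * cp_j * (e_s - e_a) / r_a) / (
        delta + gamma * (1.0 + np.asarray(r_s, dtype=float) / r_a)
    )
    etc = 86400.0 * bracket / (meteo.LATENT_HEAT * 1e6)
    return _clamp_nonneg(etc, "ETc-PM")


def et0_hs_values(t_mean, t_max, t_min, ra, k_hs=1.0):
    """Hargreaves-Samani reference evapotranspiration (mm day-1), vectorized.

    ET0-HS = kHS * 0.0023 * (T + 17.8) * sqrt(Tmax - Tmin) * 0.408 * Ra,
    clamped at zero for T below -17.8 degC.
    """
    t_max = np.asarray(t_max, dtype=float)
    t_min = np.asarray(t_min, dtype=float)
    if np.any(t_max < t_min):
        raise ValueError("t_max < t_min")
    ra = np.asarray(ra, dtype=float)
    if np.any(ra < 0.0):
        raise ValueError("ra must be >= 0")
    if np.any(np.asarray(k_hs, dtype=float) <= 0.0):
        raise ValueError("k_hs must be positive")
    t_mean = np.asarray(t_mean, dtype=float)
    et = k_hs * 0.0023 * (t_mean + 17.8) * np.sqrt(t_max - t_min) * 0.408 * ra
    return _clamp_nonneg(et, "ET0-HS")


# --- record-level wrappers -------------------------------------------------

def et0_penman_monteith(wx: WeatherDaily, site: SiteMeta) -> EtValue:
    """Reference ET0 for one observed day at a site."""
    et = et0_pm_values(
        wx.t_max, wx.t_min, wx.rh_mean, wx.ws10, wx.rs,
        site.latitude, site.elevation, wx.date.timetuple().tm_yday,
        pressure=wx.pressure, t_mean=wx.t_mean,
    )
    return EtValue(date=wx.date, et=float(et), method="ET0-PM")


def etc_penman_monteith(
    wx: WeatherDaily,
    canopy: CanopyState,
    site: SiteMeta,
    h_c: float = DEFAULT_CROP_HEIGHT,
    r_s: float | None = None,
) -> EtValue:
    """One-step crop ETc for one observed day, given the held canopy state."""
    if r_s is None and canopy.lai <= 0.0:
        raise ValueError("canopy.lai must be positive (no-transpiration case)")
    et = etc_pm_values(
        wx.t_max, wx.t_min, wx.rh_mean, wx.ws10, wx.rs,
        site.latitude, site.elevation, wx.date.timetuple().tm_yday,
        canopy.lai if canopy.lai > 0 else 1.0, canopy.albedo,
        h_c=h_c, pressure=wx.pressure, t_mean=wx.t_mean, r_s=r_s,
    )
    return EtValue(date=wx.date, et=float(et), method="ETc-PM")


def et0_hargreaves(
    t_mean: float, t_max: float, t_min: float, ra: float, k_hs: float,
    date: _date | None = None,
) -> EtValue:
    """Hargreaves-Samani ET0 for one day (temperature and Ra only)."""
    et = et0_hs_values(t_mean, t_max, t_min, ra, k_hs)
    return EtValue(date=date or _date(2000, 1, 1), et=float(et), method="ET0-HS")
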