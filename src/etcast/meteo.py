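"""Psychrometric and radiation primitives for daily evapotranspiration models.

All formulas follow the FAO-56 daily conventions: vapour pressures in kPa,
radiation fluxes in MJ m-2 day-1, temperatures in degrees Celsius, wind speed
in m s-1.  Incoming shortwave radiation is *stored* in W m-2 at the data
interface (that is what automatic weather stations report) and converted to
MJ m-2 day-1 in exactly one place (:data:`WM2_TO_MJ_DAY`).

Every function accepts scalars or numpy arrays and broadcasts element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date as _date
from typing import Optional

import numpy as np

__all__ = [
    "SiteMeta",
    "WeatherDaily",
    "PsychroBundle",
    "WM2_TO_MJ_DAY",
    "WIND_PROFILE_FACTOR",
    "LATENT_HEAT",
    "SPECIFIC_HEAT_AIR",
    "STEFAN_BOLTZMANN_DAY",
    "sat_vapor_pressure",
    "vapor_pressures",
    "slope_vapor_pressure",
    "barometric_pressure",
    "air_constants",
    "wind_2m_from_10m",
    "extraterrestrial_radiation",
    "clear_sky_radiation",
    "net_radiation",
]

#: W m-2 (daily mean) -> MJ m-2 day-1.  86400 s / 1e6.
WM2_TO_MJ_DAY = 0.0864

#: Latent heat of vaporization, MJ kg-1 (FAO-56 fixed value).
LATENT_HEAT = 2.45

#: Specific heat of moist air at constant pressure, MJ kg-1 degC-1.
SPECIFIC_HEAT_AIR = 1.013e-3

#: Stefan-Boltzmann constant on a daily basis, MJ K-4 m-2 day-1.
STEFAN_BOLTZMANN_DAY = 4.903e-9

#: Logarithmic-profile conversion of 10 m wind to the 2 m reference height:
#: u2 = uz * 4.87 / ln(67.8 z - 5.42) with z = 10 m.  Evaluates to ~0.748,
#: i.e. the familiar "about 0.75" multiplier.
WIND_PROFILE_FACTOR = 4.87 / np.log(67.8 * 10.0 - 5.42)

#: Solar constant, MJ m-2 min-1.
_GSC = 0.0820


@dataclass(frozen=True)
class SiteMeta:
    """A weather station or field location."""

    site_id: str
    latitude: float  # degrees north
    longitude: float  # degrees east
    elevation: float  # m a.s.l.

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude {self.latitude} outside [-90, 90]")
        if not self.elevation > -430.0:
            raise ValueError(f"elevation {self.elevation} below -430 m")


@dataclass
class WeatherDaily:
    """One day of observed surface weather at a site.

    ``rs`` is the daily mean incoming shortwave radiation in W m-2 (as AWS
    report it); conversion to MJ m-2 day-1 happens inside the radiation
    routines.  ``t_mean`` defaults to the average of the daily extremes when
    not supplied.
    """

    date: _date
    t_max: float  # degC
    t_min: float  # degC
    rh_mean: float  # % in [0, 100]
    ws10: float  # m s-1 at 10 m
    rs: float  # W m-2, daily mean
    t_mean: Optional[float] = None  # degC
    pressure: Optional[float] = None  # kPa

    def __post_init__(self) -> None:
        if self.t_min > self.t_max:
            raise ValueError(f"t_min {self.t_min} > t_max {self.t_max}")
        if self.t_mean is None:
            self.t_mean = 0.5 * (self.t_max + self.t_min)
        if not self.t_min - 1e-9 <= self.t_mean <= self.t_max + 1e-9:
            raise ValueError("t_mean outside [t_min, t_max]")
        if not 0.0 <= self.rh_mean <= 100.0:
            raise ValueError(f"rh_mean {self.rh_mean} outside [0, 100]")
        if self.ws10 < 0.0:
            raise ValueError("negative wind speed")
        if self.rs < 0.0:
            raise ValueError("negative shortwave radiation")


@dataclass(frozen=True)
class PsychroBundle:
    """Derived psychrometric state for one day."""

    e_s: float  # kPa
    e_a: float  # kPa
    delta: float  # kPa degC-1
    gamma: float  # kPa degC-1
    lam: float  # MJ kg-1
    rho_air: float  # kg m-3
    c_p: float  # MJ kg-1 degC-1
    pressure: float  # kPa


def sat_vapor_pressure(t):
    """Saturation vapour pressure e0(T) in kPa at air temperature T (degC)."""
    t = np.asarray(t, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def slope_vapor_pressure(t_mean):
    """Slope of the saturation vapour-pressure curve (kPa degC-1) at T."""
    t_mean = np.asarray(t_mean, dtype=float)
    return 4098.0 * sat_vapor_pressure(t_mean) / (t_mean + 237.3) ** 2


def vapor_pressures(t_max, t_min, rh_mean):
    """Saturation and actual vapour pressure plus the curve slope.

    e_s is the mean of the saturation pressures at the daily extremes; e_a
    scales e_s by the mean relative humidity; the slope is evaluated at the
    mean of the extremes.

    Returns
    -------
    (e_s, e_a, delta) : kPa, kPa, kPa degC-1
    """
    t_max = np.asarray(t_max, dtype=float)
    t_min = np.asarray(t_min, dtype=float)
    rh_mean = np.asarray(rh_mean, dtype=float)
    if np.any(t_min > t_max):
        raise ValueError("t_min > t_max")
    if np.any((rh_mean < 0.0) | (rh_mean > 100.0)):
        raise ValueError("rh_mean outside [0, 100]")
    e_s = 0.5 * (sat_vapor_pressure(t_max) + sat_vapor_pressure(t_min))
    e_a = rh_mean / 100.0 * e_s
    delta = slope_vapor_pressure(0.5 * (t_max + t_min))
    return e_s, e_a, delta


def barometric_pressure(elevation):
    """Standard-atmosphere barometric pressure (kPa) at elevation z (m)."""
    elevation = np.asarray(elevation, dtype=float)
    return 101.3 * ((293.0 - 0.0065 * elevation) / 293.0) ** 5.26


def air_constants(elevation, t_mean, pressure=None):
    """Pressure-dependent air properties.

    Parameters
    ----------
    elevation : m a.s.l.; used for the barometric estimate of pressure when
        the station does not report it.
    t_mean : degC, used for the air density.
    pressure : kPa, optional measured value overriding the estimate.

    Returns
    -------
    dict with ``pressure`` (kPa), ``gamma`` (kPa degC-1), ``lam`` (MJ kg-1),
    ``rho_air`` (kg m-3) and ``c_p`` (MJ kg-1 degC-1).
    """
    elevation = np.asarray(elevation, dtype=float)
    t_mean = np.asarray(t_mean, dtype=float)
    if not (np.all(np.isfinite(elevation)) and np.all(np.isfinite(t_mean))):
        raise ValueError("non-finite input")
    if pressure is None:
        pressure = barometric_pressure(elevation)
    else:
        pressure = np.asarray(pressure, dtype=float)
        if not np.all(np.isfinite(pressure)):
            raise ValueError("non-finite pressure")
    gamma = 0.000665 * pressure
    # Ideal-gas density at the virtual temperature 1.01 (T + 273).
    rho_air = 3.486 * pressure / (1.01 * (t_mean + 273.0))
    return {
        "pressure": pressure,
        "gamma": gamma,
        "lam": LATENT_HEAT,
        "rho_air": rho_air,
        "c_p": SPECIFIC_HEAT_AIR,
    }


def psychro_bundle(wx: WeatherDaily, site: SiteMeta) -> PsychroBundle:
    """Assemble the full psychrometric state for one observation day."""
    e_s, e_a, delta = vapor_pressures(wx.t_max, wx.t_min, wx.rh_mean)
    consts = air_constants(site.elevation, wx.t_mean, wx.pressure)
    return PsychroBundle(
        e_s=float(e_s),
        e_a=float(e_a),
        delta=float(delta),
        gamma=float(consts["gamma"]),
        lam=consts["lam"],
        rho_air=float(consts["rho_air"]),
        c_p=consts["c_p"],
        pressure=float(consts["pressure"]),
    )


def wind_2m_from_10m(ws10):
    """Convert 10 m wind speed to the 2 m reference height (factor ~0.75)."""
    ws10 = np.asarray(ws10, dtype=float)
    if np.any(ws10 < 0.0):
        raise ValueError("negative wind speed")
    return WIND_PROFILE_FACTOR * ws10


def extraterrestrial_radiation(latitude, day_of_year):
    """Daily extraterrestrial radiation Ra (MJ m-2 day-1).

    Solar geometry: inverse relative Earth-Sun distance, solar declination
    and sunset hour angle.  The sunset-angle argument is clamped to [-1, 1],
    so polar night yields exactly zero.
    """
    latitude = np.asarray(latitude, dtype=float)
    day_of_year = np.asarray(day_of_year)
    if np.any(np.abs(latitude) > 90.0):
        raise ValueError("latitude outside [-90, 90]")
    if np.any((day_of_year < 1) | (day_of_year > 366)):
        raise ValueError("day_of_year outside 1..366")
    j = np.asarray(day_of_year, dtype=float)
    phi = np.deg2rad(latitude)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi / 365.0 * j)
    decl = 0.409 * np.sin(2.0 * np.pi / 365.0 * j - 1.39)
    cos_ws = np.clip(-np.tan(phi) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(cos_ws)
    ra = (24.0 * 60.0 / np.pi) * _GSC * dr * (
        ws * np.sin(phi) * np.sin(decl) + np.cos(phi) * np.cos(decl) * np.sin(ws)
    )
    return np.maximum(ra, 0.0)


def clear_sky_radiation(ra, elevation):
    """Clear-sky shortwave radiation Rso (MJ m-2 day-1)."""
    ra = np.asarray(ra, dtype=float)
    elevation = np.asarray(elevation, dtype=float)
    return (0.75 + 2e-5 * elevation) * ra


def net_radiation(rs_wm2, albedo, t_max, t_min, e_a, ra, elevation):
    """Daily net radiation Rn (MJ m-2 day-1) at a surface of given albedo.

    Net shortwave is ``(1 - albedo) * Rs``.  Net longwave follows the FAO-56
    emissivity/cloudiness formulation, with the relative shortwave ratio
    Rs/Rso clamped to [0.3, 1.0] (and treated as 1 when Ra is zero) so the
    longwave loss stays physical on overcast or polar-night days.

    Parameters are in interface units: ``rs_wm2`` in W m-2; the result is in
    MJ m-2 day-1.
    """
    rs_wm2 = np.asarray(rs_wm2, dtype=float)
    albedo = np.asarray(albedo, dtype=float)
    if np.any((albedo < 0.0) | (albedo >= 1.0)):
        raise ValueError("albedo outside [0, 1)")
    if np.any(rs_wm2 < 0.0):
        raise ValueError("negative shortwave radiation")
    rs = rs_wm2 * WM2_TO_MJ_DAY
    rso = clear_sky_radiation(ra, elevation)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(rso > 0.0, rs / np.where(rso > 0.0, rso, 1.0), 1.0)
    ratio = np.clip(ratio, 0.3, 1.0)
    tmax_k4 = (np.asarray(t_max, dtype=float) + 273.16) ** 4
    tmin_k4 = (np.asarray(t_min, dtype=float) + 273.16) ** 4
    e_a = np.asarray(e_a, dtype=float)
    rnl = (
        STEFAN_BOLTZMANN_DAY
        * 0.5 * (tmax_k4 + tmin_k4)
        * (0.34 - 0.14 * np.sqrt(np.maximum(e_a, 0.0)))
        * (1.35 * ratio - 0.35)
    )
    return (1.0 - albedo) * rs - rnl
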