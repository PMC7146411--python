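"""Canopy parameter retrieval from multispectral surface reflectance.

Two canopy parameters drive the one-step crop Penman-Monteith equation:
broadband albedo, approximated as an irradiance-weighted sum of band
reflectances, and leaf area index (LAI), inverted from the weighted
difference vegetation index (WDVI) with the CLAIR model

    LAI = -(1/a*) * ln(1 - WDVI / WDVI_inf),      WDVI = rho_nir - C * rho_red

where ``a*`` is an extinction/scattering coefficient (0.35 for the maize
fields this package was designed around), ``WDVI_inf`` the asymptotic WDVI of
a closed canopy and ``C`` the soil-line slope (ratio of NIR to red soil
reflectance).  Between satellite passes the latest retrieval is held constant
(step function), as operational advisory services do.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from datetime import date as _date
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "SensorSpec",
    "ClairParams",
    "CanopyState",
    "SaturationError",
    "broadband_albedo",
    "wdvi",
    "retrieve_lai",
    "forward_wdvi",
    "hold_canopy",
]


class SaturationError(ValueError):
    """Raised when WDVI >= WDVI_inf: reflectance inconsistent with CLAIR."""


@dataclass(frozen=True)
class SensorSpec:
    """Band weights and soil line of a multispectral sensor.

    ``bands`` maps band id to the broadband weight (fraction of solar
    irradiance in that band); weights are normalized on construction.
    """

    sensor_id: str
    bands: tuple  # of (band_id, weight)
    soil_line_slope: float = 1.2

    def __post_init__(self) -> None:
        weights = np.array([w for _, w in self.bands], dtype=float)
        if np.any(weights < 0.0):
            raise ValueError("negative band weight")
        total = weights.sum()
        if total <= 0.0:
            raise ValueError("band weights sum to zero")
        if self.soil_line_slope <= 0.0:
            raise ValueError("soil_line_slope must be positive")
        object.__setattr__(
            self,
            "bands",
            tuple((b, float(w / total)) for (b, _), w in zip(self.bands, weights)),
        )


@dataclass(frozen=True)
class ClairParams:
    """CLAIR inversion parameters."""

    wdvi_inf: float
    alpha_star: float = 0.35

    def __post_init__(self) -> None:
        if self.alpha_star <= 0.0:
            raise ValueError("alpha_star must be positive")
        if not 0.0 < self.wdvi_inf <= 1.0:
            raise ValueError("wdvi_inf must be in (0, 1]")


@dataclass(frozen=True)
class CanopyState:
    """Dated LAI / albedo pair for a field."""

    date: _date
    lai: float  # m2 m-2
    albedo: float

    def __post_init__(self) -> None:
        if self.lai < 0.0:
            raise ValueError("lai must be >= 0")
        if not 0.0 < self.albedo < 1.0:
            raise ValueError("albedo must be in (0, 1)")


def broadband_albedo(reflectances: Mapping[str, float], spec: SensorSpec) -> float:
    """Irradiance-weighted broadband albedo from per-band reflectances."""
    total = 0.0
    for band_id, weight in spec.bands:
        if band_id not in reflectances:
            raise KeyError(f"band {band_id!r} missing from reflectances")
        rho = float(reflectances[band_id])
        if not 0.0 <= rho <= 1.0:
            raise ValueError(f"reflectance {rho} for band {band_id!r} outside [0, 1]")
        total += rho * weight
    return total


def wdvi(rho_red, rho_nir, spec: SensorSpec):
    """Weighted difference vegetation index: rho_nir - C * rho_red."""
    rho_red = np.asarray(rho_red, dtype=float)
    rho_nir = np.asarray(rho_nir, dtype=float)
    if np.any((rho_red < 0) | (rho_red > 1) | (rho_nir < 0) | (rho_nir > 1)):
        raise ValueError("reflectance outside [0, 1]")
    return rho_nir - spec.soil_line_slope * rho_red


def retrieve_lai(rho_red, rho_nir, spec: SensorSpec, params: ClairParams):
    """Invert CLAIR to LAI (m2 m-2).

    Negative WDVI (bare or wet soil) clamps to LAI = 0; WDVI at or above the
    asymptote raises :class:`SaturationError`.
    """
    w = wdvi(rho_red, rho_nir, spec)
    if np.any(np.asarray(w) >= params.wdvi_inf):
        raise SaturationError(
            f"WDVI >= WDVI_inf ({params.wdvi_inf}): reflectance inconsistent "
            "with the CLAIR asymptote"
        )
    w = np.maximum(w, 0.0)
    lai = -np.log(1.0 - w / params.wdvi_inf) / params.alpha_star
    return lai if lai.ndim else float(lai)


def forward_wdvi(lai, params: ClairParams):
    """Forward CLAIR map: WDVI of a canopy with the given LAI."""
    lai = np.asarray(lai, dtype=float)
    if np.any(lai < 0.0):
        raise ValueError("lai must be >= 0")
    return params.wdvi_inf * (1.0 - np.exp(-params.alpha_star * lai))


def hold_canopy(series: Sequence[CanopyState], query_date: _date) -> CanopyState:
    """Latest canopy state at or before ``query_date`` (forward fill).

    The series must be non-empty with strictly increasing dates; querying
    before the first retrieval is an error.
    """
    if not series:
        raise ValueError("empty canopy series")
    dates = [s.date for s in series]
    if any(b <= a for a, b in zip(dates, dates[1:])):
        raise ValueError("canopy dates must be strictly increasing")
    if query_date < dates[0]:
        raise ValueError(
            f"query date {query_date} precedes first canopy observation {dates[0]}"
        )
    idx = bisect.bisect_right(dates, query_date) - 1
    return series[idx]
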