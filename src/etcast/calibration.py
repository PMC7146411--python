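"""Local calibration of the Hargreaves-Samani scaling factor.

The Hargreaves-Samani equation is linear in its scaling factor kHS, so
minimizing the sum of squared differences between ET0-HS and the
Penman-Monteith reference ET0 over a calibration period has the closed-form
solution of a least-squares fit through the origin:

    kHS = sum(h_i * p_i) / sum(h_i^2)

with h the unit-kHS Hargreaves-Samani series and p the Penman-Monteith
series.  Calibration conventionally uses the irrigation season (June 1 to
September 30) over several past years.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KhsFit", "calibrate_khs", "DEFAULT_MIN_DAYS"]

DEFAULT_MIN_DAYS = 30


@dataclass(frozen=True)
class KhsFit:
    """A fitted Hargreaves-Samani scaling factor for one site."""

    site_id: str
    k_hs: float
    rmse_cal: float  # mm day-1 at the fitted k over the calibration sample
    n_days: int
    reference_period: tuple | None = None

    def __post_init__(self) -> None:
        if self.k_hs <= 0.0:
            raise ValueError("k_hs must be positive")


def calibrate_khs(
    et0_hs_unit,
    et0_pm,
    site_id: str = "",
    reference_period: tuple | None = None,
    min_days: int = DEFAULT_MIN_DAYS,
) -> KhsFit:
    """Fit kHS by least squares of kHS*h against the Penman-Monteith series.

    Parameters
    ----------
    et0_hs_unit : Hargreaves-Samani ET0 computed with kHS = 1 (mm day-1).
    et0_pm : paired Penman-Monteith reference ET0 (mm day-1).

    Non-finite pairs are dropped pairwise before fitting.
    """
    h = np.asarray(et0_hs_unit, dtype=float)
    p = np.asarray(et0_pm, dtype=float)
    if h.shape != p.shape:
        raise ValueError("series length mismatch")
    mask = np.isfinite(h) & np.isfinite(p)
    h, p = h[mask], p[mask]
    n = h.size
    if n < min_days:
        raise ValueError(f"only {n} paired days; need >= {min_days}")
    denom = float(np.sum(h * h))
    if denom == 0.0:
        raise ValueError("all-zero Hargreaves-Samani series")
    k = float(np.sum(h * p)) / denom
    rmse = float(np.sqrt(np.mean((k * h - p) ** 2)))
    return KhsFit(
        site_id=site_id,
        k_hs=k,
        rmse_cal=rmse,
        n_days=int(n),
        reference_period=reference_period,
    )
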