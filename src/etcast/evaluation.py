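"""Forecast verification: BIAS and RMSE against the best estimate.

Forecasts (weather variables, daily ETc, or ETc accumulated over 1/3/5-day
horizons) are verified against the corresponding quantity derived from
ground observations.  For ETc the verification truth ("best estimate") is
the one-step crop Penman-Monteith estimate computed from observed weather.

    BIAS = mean(forecast - observed)
    RMSE = sqrt(mean((forecast - observed)^2))

Distribution summaries across sites follow the box-plot convention with
quartiles, Tukey fences at 1.5 IQR, and whiskers at the most extreme
non-outlier values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SkillRecord",
    "DistributionSummary",
    "bias_rmse",
    "summarize_over_sites",
]


@dataclass(frozen=True)
class SkillRecord:
    """BIAS/RMSE for one site and one target at one lead or horizon."""

    site_id: str
    target: str
    lead_or_horizon: int
    bias: float
    rmse: float
    n: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if self.rmse < abs(self.bias) - 1e-12:
            raise ValueError("rmse < |bias| is impossible")


@dataclass(frozen=True)
class DistributionSummary:
    """Box-plot summary of a set of values (e.g. one index over sites)."""

    p25: float
    p50: float
    p75: float
    mean: float
    whisker_lo: float
    whisker_hi: float
    outliers: tuple = field(default_factory=tuple)


def bias_rmse(forecast, best_estimate) -> tuple[float, float, int]:
    """Mean error and root-mean-square error of paired series.

    Pairs with a missing (non-finite) value on either side are dropped
    pairwise; an empty pairing is an error.
    """
    f = np.asarray(forecast, dtype=float)
    o = np.asarray(best_estimate, dtype=float)
    if f.shape != o.shape:
        raise ValueError("paired series must have equal length")
    mask = np.isfinite(f) & np.isfinite(o)
    f, o = f[mask], o[mask]
    if f.size == 0:
        raise ValueError("no valid pairs")
    err = f - o
    return float(err.mean()), float(np.sqrt(np.mean(err**2))), int(f.size)


def summarize_over_sites(
    records: Sequence[SkillRecord] | Sequence[float], index: str = "rmse"
) -> DistributionSummary:
    """Box-plot summary of one skill index across sites.

    ``records`` may be SkillRecords (the ``index`` attribute is extracted)
    or raw numbers.  Quartiles use linear interpolation between order
    statistics; values beyond p75 + 1.5 IQR or below p25 - 1.5 IQR are
    outliers and the whiskers stop at the most extreme non-outliers.
    """
    if len(records) == 0:
        raise ValueError("empty input")
    if isinstance(records[0], SkillRecord):
        values = np.array([getattr(r, index) for r in records], dtype=float)
    else:
        values = np.asarray(records, dtype=float)
    p25, p50, p75 = np.percentile(values, [25, 50, 75])
    iqr = p75 - p25
    lo_fence, hi_fence = p25 - 1.5 * iqr, p75 + 1.5 * iqr
    inliers = values[(values >= lo_fence) & (values <= hi_fence)]
    outliers = values[(values < lo_fence) | (values > hi_fence)]
    return DistributionSummary(
        p25=float(p25),
        p50=float(p50),
        p75=float(p75),
        mean=float(values.mean()),
        whisker_lo=float(inliers.min()),
        whisker_hi=float(inliers.max()),
        outliers=tuple(sorted(float(v) for v in outliers)),
    )
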