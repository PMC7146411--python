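"""Reduction of raw ensemble NWP output to daily per-site forecasts.

The workflow mirrors operational practice with a limited-area ensemble
system (3-hourly output, leads 1-5 days, ~16 members):

1. horizontally interpolate the three grid nodes nearest a station to the
   station location (triangle-based bilinear / barycentric weights);
2. per 3-hourly step, take the ensemble **median** across members;
3. per lead day, average the eight 3-hourly medians into daily values
   (daily temperature extremes are the max/min of the eight medians);
4. remove the mean forecast-minus-observation bias estimated on a reference
   period, per site and lead time.  By default only the temperature columns
   are corrected: temperature is the one variable whose systematic error a
   mean-bias correction removes reliably at every site.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .meteo import SiteMeta

__all__ = [
    "DAILY_COLUMNS",
    "TEMPERATURE_COLUMNS",
    "BiasTable",
    "interpolate_to_site",
    "reduce_daily_array",
    "reduce_daily",
    "fit_mean_bias",
    "apply_bias_correction",
]

#: Daily per-variable columns of a reduced site forecast frame.
DAILY_COLUMNS = (
    "t_mean", "t_max", "t_min", "rh_mean", "ws10", "rs_wm2", "pressure_kpa",
)
#: Columns touched by the default (temperature-only) bias correction.
TEMPERATURE_COLUMNS = ("t_mean", "t_max", "t_min")

#: Mapping from raw NWP variable codes to daily column conventions.
_VARIABLE_MAP = {
    "T": "t_mean",
    "RH": "rh_mean",
    "WS10": "ws10",
    "RS": "rs_wm2",
    "P": "pressure_kpa",
}


@dataclass
class BiasTable:
    """Mean forecast biases keyed by (site_id, variable/column, lead)."""

    entries: dict = field(default_factory=dict)
    reference_period: tuple | None = None

    def get(self, site_id: str, variable: str, lead: int):
        return self.entries.get((site_id, variable, int(lead)))

    def to_json(self, path) -> None:
        payload = {
            "reference_period": [str(p) for p in self.reference_period]
            if self.reference_period
            else None,
            "entries": {
                f"{s}|{v}|{l}": b for (s, v, l), b in sorted(self.entries.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "BiasTable":
        with open(path) as fh:
            payload = json.load(fh)
        entries = {}
        for key, bias in payload["entries"].items():
            site, var, lead = key.rsplit("|", 2)
            entries[(site, var, int(lead))] = float(bias)
        ref = payload.get("reference_period")
        return cls(entries=entries, reference_period=tuple(ref) if ref else None)


def interpolate_to_site(
    node_values: Sequence[tuple[tuple[float, float], float]], site: SiteMeta
) -> float:
    """Interpolate the three nearest grid nodes to the station location.

    Barycentric (triangle-based bilinear) weights in a local planar frame
    about the site.  A site outside the triangle is projected onto the
    nearest edge; collinear nodes fall back to inverse-distance weighting.

    Parameters
    ----------
    node_values : three ((lat, lon), value) pairs.
    """
    if len(node_values) != 3:
        raise ValueError("exactly three grid nodes required")
    lat0, lon0 = site.latitude, site.longitude
    coslat = np.cos(np.deg2rad(lat0))
    pts = np.array(
        [[(lon - lon0) * coslat, lat - lat0] for (lat, lon), _ in node_values]
    )
    vals = np.array([v for _, v in node_values], dtype=float)
    # barycentric weights of the origin (the site) wrt the triangle
    t = np.column_stack([pts[0] - pts[2], pts[1] - pts[2]])
    det = np.linalg.det(t)
    area_scale = max(np.abs(pts).max(), 1e-12)
    if abs(det) < 1e-12 * area_scale**2:
        warnings.warn("collinear grid nodes: falling back to inverse-distance")
        d = np.maximum(np.linalg.norm(pts, axis=1), 1e-12)
        if np.any(d < 1e-9):
            return float(vals[int(np.argmin(d))])
        w = 1.0 / d
        return float(np.sum(w * vals) / np.sum(w))
    w12 = np.linalg.solve(t, -pts[2])
    weights = np.array([w12[0], w12[1], 1.0 - w12.sum()])
    if np.all(weights >= -1e-12):
        weights = np.clip(weights, 0.0, None)
        return float(np.sum(weights / weights.sum() * vals))
    # outside the triangle: project onto the nearest edge segment
    best = None
    for i, j in ((0, 1), (1, 2), (0, 2)):
        a, b = pts[i], pts[j]
        ab = b - a
        tproj = np.clip(np.dot(-a, ab) / np.dot(ab, ab), 0.0, 1.0)
        p = a + tproj * ab
        dist = np.linalg.norm(p)
        if best is None or dist < best[0]:
            best = (dist, vals[i] * (1.0 - tproj) + vals[j] * tproj)
    return float(best[1])


def reduce_daily_array(values: np.ndarray, kind: str = "mean") -> np.ndarray:
    """Median-over-members then daily aggregate of 3-hourly ensemble values.

    ``values`` has shape (..., M members, 8 steps).  ``kind`` selects the
    daily aggregate of the eight stepwise medians: "mean", "max" or "min".
    """
    if values.shape[-1] != 8:
        raise ValueError("expected 8 three-hourly steps per day")
    if values.shape[-2] < 1:
        raise ValueError("at least one ensemble member required")
    med = np.median(values, axis=-2)
    if kind == "mean":
        return med.mean(axis=-1)
    if kind == "max":
        return med.max(axis=-1)
    if kind == "min":
        return med.min(axis=-1)
    raise ValueError(f"unknown daily aggregate {kind!r}")


def reduce_daily(
    long_df: pd.DataFrame, member_first: bool = False
) -> pd.DataFrame:
    """Reduce a long-format ensemble forecast frame to daily site values.

    Input columns: ``site_id, issue_time, member_id, variable, valid_time,
    value`` with variables in {T, RH, WS10, RS, P}.  Output: one row per
    (site_id, issue_date, lead_days) with the columns of
    :data:`DAILY_COLUMNS`; temperature also yields daily max/min of the
    stepwise ensemble medians.  Days with fewer than eight steps for a
    variable are dropped (flagged invalid).

    ``member_first=True`` swaps the reduction order (daily mean per member,
    then median across members) — an alternative convention kept behind this
    switch.
    """
    df = long_df.copy()
    df["issue_time"] = pd.to_datetime(df["issue_time"])
    df["valid_time"] = pd.to_datetime(df["valid_time"])
    df["issue_date"] = df["issue_time"].dt.normalize()
    df["valid_date"] = df["valid_time"].dt.normalize()
    df["lead_days"] = (df["valid_date"] - df["issue_date"]).dt.days
    df = df[df["lead_days"] >= 1]

    keys = ["site_id", "issue_date", "lead_days", "variable"]
    if member_first:
        per_member = df.groupby(keys + ["member_id"]).agg(
            value=("value", "mean"), n_steps=("value", "size")
        )
        per_member = per_member[per_member["n_steps"] == 8]
        daily = per_member.groupby(keys)["value"].median().rename("mean")
        vmax = per_member.groupby(keys)["value"].max().rename("max")
        vmin = per_member.groupby(keys)["value"].min().rename("min")
        agg = pd.concat([daily, vmax, vmin], axis=1).reset_index()
    else:
        med = (
            df.groupby(keys + ["valid_time"])["value"].median().rename("med")
        ).reset_index()
        g = med.groupby(keys)["med"]
        agg = g.agg(["mean", "max", "min", "size"]).reset_index()
        agg = agg[agg["size"] == 8].drop(columns="size")

    rows = []
    for (site, issue, lead), grp in agg.groupby(
        ["site_id", "issue_date", "lead_days"]
    ):
        row = {
            "site_id": site,
            "issue_date": issue.date(),
            "lead_days": int(lead),
        }
        for _, r in grp.iterrows():
            col = _VARIABLE_MAP.get(r["variable"])
            if col is None:
                raise ValueError(f"unknown forecast variable {r['variable']!r}")
            row[col] = r["mean"]
            if r["variable"] == "T":
                row["t_max"] = r["max"]
                row["t_min"] = r["min"]
        rows.append(row)
    out = pd.DataFrame(rows)
    for col in DAILY_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    return out.sort_values(["site_id", "issue_date", "lead_days"]).reset_index(
        drop=True
    )


def fit_mean_bias(
    forecasts: pd.DataFrame,
    obs: pd.DataFrame,
    variables: Iterable[str] = TEMPERATURE_COLUMNS,
    reference_period: tuple | None = None,
    min_pairs: int = 30,
) -> BiasTable:
    """Mean forecast-minus-observation bias per (site, variable, lead).

    ``forecasts`` is a reduced daily frame (see :func:`reduce_daily`);
    ``obs`` has columns ``site_id, date`` plus the same variable columns.
    Pairs with a missing value on either side are dropped; fewer than
    ``min_pairs`` valid pairs for a (site, lead) is an error.
    """
    fc = forecasts.copy()
    fc["valid_date"] = pd.to_datetime(fc["issue_date"]) + pd.to_timedelta(
        fc["lead_days"], unit="D"
    )
    ob = obs.copy()
    ob["valid_date"] = pd.to_datetime(ob["date"])
    if reference_period is not None:
        start, end = pd.Timestamp(reference_period[0]), pd.Timestamp(
            reference_period[1]
        )
        fc = fc[(fc["valid_date"] >= start) & (fc["valid_date"] <= end)]
        ob = ob[(ob["valid_date"] >= start) & (ob["valid_date"] <= end)]
    variables = list(variables)
    merged = fc.merge(
        ob[["site_id", "valid_date"] + variables],
        on=["site_id", "valid_date"],
        suffixes=("_fc", "_obs"),
    )
    table = BiasTable(reference_period=reference_period)
    for (site, lead), grp in merged.groupby(["site_id", "lead_days"]):
        for var in variables:
            diff = (grp[f"{var}_fc"] - grp[f"{var}_obs"]).dropna()
            if len(diff) < min_pairs:
                raise ValueError(
                    f"only {len(diff)} paired days for {site} lead {lead} "
                    f"({var}); need >= {min_pairs}"
                )
            table.entries[(site, var, int(lead))] = float(diff.mean())
    return table


def apply_bias_correction(
    forecasts: pd.DataFrame, table: BiasTable, strict: bool = False
) -> pd.DataFrame:
    """Subtract fitted mean biases from a reduced daily forecast frame.

    Only (site, variable, lead) combinations present in the table are
    touched; a missing entry passes the value through with a warning
    (``strict=True`` raises instead).
    """
    out = forecasts.copy()
    corrected_vars = sorted({v for (_, v, _) in table.entries})
    missing = set()
    for idx, row in out.iterrows():
        for var in corrected_vars:
            bias = table.get(row["site_id"], var, row["lead_days"])
            if bias is None:
                missing.add((row["site_id"], var, int(row["lead_days"])))
                continue
            out.at[idx, var] = row[var] - bias
    if missing:
        msg = f"no bias entry for {sorted(missing)[:3]}... pass-through"
        if strict:
            raise KeyError(msg)
        warnings.warn(msg)
    return out
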