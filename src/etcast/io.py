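"""CSV/JSON dialects shared by the pipeline commands.

All dates are ISO-8601 calendar days.  Readers validate the column schema
and report unknown or missing columns by name.
"""

from __future__ import annotations

import json
from datetime import date as _date

import pandas as pd

from .calibration import KhsFit
from .canopy import CanopyState
from .meteo import SiteMeta

__all__ = [
    "SchemaError",
    "WEATHER_COLUMNS",
    "read_sites",
    "read_weather",
    "read_canopy_direct",
    "read_canopy_reflectance",
    "read_forecast_long",
    "read_forecast_daily",
    "write_khs",
    "read_khs",
    "canopy_states_to_frame",
]

WEATHER_COLUMNS = (
    "site_id", "date", "t_max", "t_min", "t_mean", "rh_mean", "ws10",
    "rs_wm2", "pressure_kpa",
)
SITE_COLUMNS = ("site_id", "lat", "lon", "elev_m")
CANOPY_DIRECT_COLUMNS = ("field_id", "date", "lai", "albedo")
CANOPY_REFLECTANCE_COLUMNS = ("field_id", "date", "sensor_id", "rho_red", "rho_nir")
FORECAST_LONG_COLUMNS = (
    "site_id", "issue_time", "member_id", "variable", "valid_time", "value",
)
FORECAST_DAILY_COLUMNS = (
    "site_id", "issue_date", "lead_days", "t_mean", "t_max", "t_min",
    "rh_mean", "ws10", "rs_wm2", "pressure_kpa",
)


class SchemaError(ValueError):
    """A CSV does not match the expected column schema."""


def _check_schema(df: pd.DataFrame, required, optional=(), what="file"):
    missing = [c for c in required if c not in df.columns]
    unknown = [c for c in df.columns if c not in (*required, *optional)]
    if missing:
        raise SchemaError(f"{what}: missing column(s) {missing}")
    if unknown:
        raise SchemaError(f"{what}: unknown column(s) {unknown}")


def read_sites(path) -> dict[str, SiteMeta]:
    df = pd.read_csv(path, dtype={"site_id": str})
    _check_schema(df, SITE_COLUMNS, what="site CSV")
    return {
        r.site_id: SiteMeta(
            site_id=r.site_id, latitude=r.lat, longitude=r.lon, elevation=r.elev_m
        )
        for r in df.itertuples()
    }


def read_weather(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str}, parse_dates=["date"])
    _check_schema(
        df, [c for c in WEATHER_COLUMNS if c not in ("t_mean", "pressure_kpa")],
        optional=("t_mean", "pressure_kpa"), what="weather CSV",
    )
    if "t_mean" not in df.columns:
        df["t_mean"] = 0.5 * (df["t_max"] + df["t_min"])
    else:
        df["t_mean"] = df["t_mean"].fillna(0.5 * (df["t_max"] + df["t_min"]))
    if "pressure_kpa" not in df.columns:
        df["pressure_kpa"] = float("nan")
    df["date"] = df["date"].dt.date
    bad = df.index[df["t_min"] > df["t_max"]].tolist()
    if bad:
        raise SchemaError(f"weather CSV: t_min > t_max at row(s) {bad[:5]}")
    return df[list(WEATHER_COLUMNS)]


def read_canopy_direct(path) -> dict[str, list[CanopyState]]:
    df = pd.read_csv(path, dtype={"field_id": str}, parse_dates=["date"])
    _check_schema(df, CANOPY_DIRECT_COLUMNS, what="canopy CSV")
    out: dict[str, list[CanopyState]] = {}
    for field_id, grp in df.groupby("field_id"):
        grp = grp.sort_values("date")
        out[field_id] = [
            CanopyState(date=r.date.date(), lai=r.lai, albedo=r.albedo)
            for r in grp.itertuples()
        ]
    return out


def read_canopy_reflectance(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"field_id": str, "sensor_id": str},
                     parse_dates=["date"])
    extra = [c for c in df.columns if c.startswith("rho_")]
    _check_schema(df, CANOPY_REFLECTANCE_COLUMNS, optional=extra,
                  what="reflectance CSV")
    df["date"] = df["date"].dt.date
    return df


def read_forecast_long(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str},
                     parse_dates=["issue_time", "valid_time"])
    _check_schema(df, FORECAST_LONG_COLUMNS, what="forecast CSV")
    return df


def read_forecast_daily(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str}, parse_dates=["issue_date"])
    _check_schema(df, FORECAST_DAILY_COLUMNS, what="daily forecast CSV")
    df["issue_date"] = df["issue_date"].dt.date
    return df


def write_khs(fits: dict[str, KhsFit], path) -> None:
    payload = {
        site: {
            "site_id": fit.site_id,
            "k_hs": fit.k_hs,
            "rmse_cal_mm": fit.rmse_cal,
            "n_days": fit.n_days,
            "period": list(fit.reference_period) if fit.reference_period else None,
        }
        for site, fit in sorted(fits.items())
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_khs(path) -> dict[str, KhsFit]:
    with open(path) as fh:
        payload = json.load(fh)
    return {
        site: KhsFit(
            site_id=rec["site_id"],
            k_hs=rec["k_hs"],
            rmse_cal=rec["rmse_cal_mm"],
            n_days=rec["n_days"],
            reference_period=tuple(rec["period"]) if rec.get("period") else None,
        )
        for site, rec in payload.items()
    }


def canopy_states_to_frame(states: dict[str, list[CanopyState]]) -> pd.DataFrame:
    rows = [
        {"field_id": fid, "date": s.date, "lai": s.lai, "albedo": s.albedo}
        for fid, series in states.items()
        for s in series
    ]
    return pd.DataFrame(rows, columns=list(CANOPY_DIRECT_COLUMNS))
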