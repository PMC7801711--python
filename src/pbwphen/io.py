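"""Delimited-text readers/writers for weather, trap and event tables.

All tables are plain CSV with ISO-8601 dates.  Weather comes either at
daily resolution (``site,date,tmin,tmax``; the ``site`` column optional)
or as monthly means (``site,year,month,tmin,tmax``) which are expanded to
constant daily values within each month and flagged as
``monthly-resolution`` in the frame's ``attrs``.
"""

from __future__ import annotations

import calendar
import warnings
from pathlib import Path
from typing import Iterable

import pandas as pd

from .degreedays import validate_weather
from .errors import ValidationError
from .phenology import TrapSeries

__all__ = ["read_weather", "write_weather", "read_traps", "write_traps"]

DEFAULT_SITE = "site0"


def _read_csv(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"no such file: {path}")
    try:
        return pd.read_csv(path)
    except Exception as exc:  # surface parser line info
        raise ValidationError(f"cannot parse {path}: {exc}") from exc


def _expand_monthly(df: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for i, row in df.iterrows():
        try:
            year, month = int(row["year"]), int(row["month"])
            ndays = calendar.monthrange(year, month)[1]
        except Exception as exc:
            raise ValidationError(f"bad year/month on data row {i + 1}: {exc}") from exc
        dates = pd.date_range(f"{year}-{month:02d}-01", periods=ndays, freq="D")
        rows.append(
            pd.DataFrame(
                {
                    "site": row.get("site", DEFAULT_SITE),
                    "date": dates,
                    "tmin": float(row["tmin"]),
                    "tmax": float(row["tmax"]),
                }
            )
        )
    out = pd.concat(rows, ignore_index=True)
    out.attrs["resolution"] = "monthly"
    return out


def read_weather(path) -> dict[str, pd.DataFrame]:
    """Read a daily or monthly weather file, returning one frame per site.

    Frames are validated (tmin <= tmax, unique dates) and sorted; monthly
    files are expanded to daily and carry ``attrs['resolution'] ==
    'monthly'``.
    """
    df = _read_csv(path)
    cols = set(df.columns)
    if {"year", "month", "tmin", "tmax"} <= cols:
        df = _expand_monthly(df)
    elif {"date", "tmin", "tmax"} <= cols:
        if "site" not in cols:
            df = df.assign(site=DEFAULT_SITE)
    else:
        raise ValidationError(
            f"{path}: expected header date,tmin,tmax or year,month,tmin,tmax "
            f"(optionally with site); got {sorted(cols)}"
        )
    bad = pd.to_datetime(df["date"], errors="coerce").isna()
    if bad.any():
        lines = (df.index[bad] + 2).tolist()  # +2: header + 1-based
        raise ValidationError(f"{path}: unparseable dates on line(s) {lines[:5]}")
    resolution = df.attrs.get("resolution", "daily")
    out = {}
    for site, sub in df.groupby("site"):
        frame = validate_weather(sub[["date", "tmin", "tmax"]])
        frame.attrs["resolution"] = resolution
        out[str(site)] = frame
    return out


def write_weather(weather: pd.DataFrame, path, site: str | None = None) -> None:
    w = validate_weather(weather)
    if site is not None:
        w.insert(0, "site", site)
    w_out = w.copy()
    w_out["date"] = w_out["date"].dt.strftime("%Y-%m-%d")
    w_out.to_csv(path, index=False, float_format="%.2f")


def _season_year(dates: pd.Series) -> pd.Series:
    """Season label: cropping seasons run ~June-March, windowed April-March."""
    return dates.dt.year.where(dates.dt.month >= 4, dates.dt.year - 1)


def read_traps(path) -> list[TrapSeries]:
    """Read trap catches grouped by site and July-June season.

    Catches spanning a new year stay in one group (seasons are windowed
    April-March); negative catches are a validation error; an empty file
    returns an empty list with a warning.
    """
    df = _read_csv(path)
    if df.empty:
        warnings.warn(f"{path}: empty trap file", stacklevel=2)
        return []
    if missing := {"date", "mean_catch"} - set(df.columns):
        raise ValidationError(f"{path}: trap file missing columns {sorted(missing)}")
    if "site" not in df.columns:
        df = df.assign(site=DEFAULT_SITE)
    df["date"] = pd.to_datetime(df["date"])
    if (df["mean_catch"] < 0).any():
        lines = (df.index[df["mean_catch"] < 0] + 2).tolist()
        raise ValidationError(f"{path}: negative catches on line(s) {lines[:5]}")
    df["season"] = _season_year(df["date"])
    out = []
    for (site, season), sub in df.groupby(["site", "season"], sort=True):
        out.append(
            TrapSeries(
                site=str(site),
                data=sub[["date", "mean_catch"]].reset_index(drop=True),
                season=int(season),
            )
        )
    return out


def write_traps(series_list: Iterable[TrapSeries], path) -> None:
    frames = []
    for s in series_list:
        frame = s.data.copy()
        frame.insert(0, "site", s.site)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    out["date"] = out["date"].dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False, float_format="%.3f")
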