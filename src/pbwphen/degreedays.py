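"""Daily degree-day computation and accumulation.

The diurnal temperature course is modelled as one full sine period per
calendar day, built from that day's own minimum and maximum::

    T(theta) = m + a * sin(theta),   m = (tmax + tmin) / 2,  a = (tmax - tmin) / 2

Degree-days for the day are the time-average of the development-effective
temperature ``max(0, min(T, utt) - ltt)`` — i.e. heat between a lower
developmental threshold (LTT) and an upper threshold (UTT), with a
*horizontal* upper cutoff: above the UTT development proceeds at its maximal
rate rather than stopping, so the area above the UTT is clipped flat, not
subtracted.  The integral has a closed form with six cases depending on how
the day's temperature span straddles the thresholds.

A simple daily-average method is provided as a baseline for comparison.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import (
    RangeCoverageError,
    TargetUnreachableError,
    ValidationError,
    WeatherGapError,
)

__all__ = [
    "ThresholdPair",
    "SineDayGeometry",
    "sine_day_geometry",
    "single_sine_dd",
    "simple_average_dd",
    "validate_weather",
    "accumulate_dd",
    "dd_to_date",
]

HALF_PI = np.pi / 2.0


@dataclass(frozen=True)
class ThresholdPair:
    """Lower/upper developmental temperature thresholds in degrees Celsius."""

    ltt: float
    utt: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ltt) or not np.isfinite(self.utt):
            raise ValidationError("thresholds must be finite")
        if not self.ltt < self.utt:
            raise ValidationError(f"lower threshold must be below upper ({self.ltt} >= {self.utt})")

    @property
    def span(self) -> float:
        """Maximum attainable degree-days in one day, ``utt - ltt``."""
        return self.utt - self.ltt


@dataclass(frozen=True)
class SineDayGeometry:
    """Geometry of one day's sine curve relative to a threshold pair.

    ``theta1``/``theta2`` are the angles (in the rising half-cycle,
    ``[-pi/2, pi/2]``) at which the curve crosses the lower and upper
    threshold; ``nan`` when the curve never crosses that threshold.
    """

    m: float
    a: float
    theta1: float
    theta2: float


def _check_temps(tmin, tmax) -> tuple[np.ndarray, np.ndarray]:
    tmin = np.asarray(tmin, dtype=float)
    tmax = np.asarray(tmax, dtype=float)
    if not (np.all(np.isfinite(tmin)) and np.all(np.isfinite(tmax))):
        raise ValidationError("temperatures must be finite")
    if np.any(tmin > tmax):
        raise ValidationError("tmin exceeds tmax")
    return tmin, tmax


def sine_day_geometry(tmin: float, tmax: float, thresholds: ThresholdPair) -> SineDayGeometry:
    """Midpoint, amplitude and threshold crossing angles for a single day."""
    tmin, tmax = _check_temps(tmin, tmax)
    m = float((tmax + tmin) / 2.0)
    a = float((tmax - tmin) / 2.0)
    theta1 = theta2 = float("nan")
    if a > 0.0:
        if tmin < thresholds.ltt <= tmax:
            theta1 = float(np.arcsin((thresholds.ltt - m) / a))
        if tmin < thresholds.utt <= tmax:
            theta2 = float(np.arcsin((thresholds.utt - m) / a))
    return SineDayGeometry(m=m, a=a, theta1=theta1, theta2=theta2)


def single_sine_dd(tmin, tmax, thresholds: ThresholdPair):
    """Degree-days for one day by the single-sine method, horizontal cutoff.

    Accepts scalars or arrays (broadcast elementwise).  The six closed-form
    cases depend on the position of ``[tmin, tmax]`` relative to the
    thresholds ``L < U``; boundary days (``tmin == tmax`` or temperatures
    exactly at a threshold) fall through the same ``<=`` / ``>=`` case
    boundaries, so the result is continuous in its arguments.
    """
    tmin, tmax = _check_temps(tmin, tmax)
    scalar = tmin.ndim == 0 and tmax.ndim == 0
    tmin, tmax = np.atleast_1d(tmin), np.atleast_1d(tmax)
    tmin, tmax = np.broadcast_arrays(tmin, tmax)

    L, U = thresholds.ltt, thresholds.utt
    m = (tmax + tmin) / 2.0
    a = (tmax - tmin) / 2.0

    below = tmax <= L                     # (i) whole day below LTT
    above = tmin >= U                     # (ii) whole day at/above UTT
    inside = ~below & ~above & (tmin >= L) & (tmax <= U)    # (iii)
    low_cut = ~below & ~above & (tmin < L) & (tmax <= U)    # (iv)
    high_cut = ~below & ~above & (tmin >= L) & (tmax > U)   # (v)
    both_cut = ~below & ~above & (tmin < L) & (tmax > U)    # (vi)

    # crossing angles; a > 0 wherever theta is consumed (cases iv-vi imply
    # tmax > tmin because the interval straddles a threshold strictly)
    safe_a = np.where(a > 0, a, 1.0)
    with np.errstate(invalid="ignore"):
        th1 = np.arcsin(np.clip((L - m) / safe_a, -1.0, 1.0))
        th2 = np.arcsin(np.clip((U - m) / safe_a, -1.0, 1.0))

    dd = np.zeros_like(m)
    dd[above] = U - L
    dd[inside] = (m - L)[inside]
    if np.any(low_cut):
        i = low_cut
        dd[i] = ((m[i] - L) * (HALF_PI - th1[i]) + a[i] * np.cos(th1[i])) / np.pi
    if np.any(high_cut):
        i = high_cut
        dd[i] = (
            (m[i] - L) * (th2[i] + HALF_PI)
            + (U - L) * (HALF_PI - th2[i])
            - a[i] * np.cos(th2[i])
        ) / np.pi
    if np.any(both_cut):
        i = both_cut
        dd[i] = (
            (m[i] - L) * (th2[i] - th1[i])
            + a[i] * (np.cos(th1[i]) - np.cos(th2[i]))
            + (U - L) * (HALF_PI - th2[i])
        ) / np.pi

    dd = np.clip(dd, 0.0, U - L)
    return float(dd[0]) if scalar else dd


def simple_average_dd(tmin, tmax, thresholds: ThresholdPair):
    """Baseline daily degree-days: clamp the (tmin+tmax)/2 average between thresholds."""
    tmin, tmax = _check_temps(tmin, tmax)
    mid = (tmin + tmax) / 2.0
    dd = np.maximum(0.0, np.minimum(mid, thresholds.utt) - thresholds.ltt)
    return float(dd) if np.ndim(dd) == 0 else dd


_METHODS = {"single_sine": single_sine_dd, "simple_average": simple_average_dd}


def validate_weather(weather: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalise a daily weather table.

    Expects columns ``date``, ``tmin``, ``tmax``; returns a copy sorted by
    date with ``date`` as normalised Timestamps.  Raises ValidationError on
    duplicate dates, non-finite temperatures or tmin > tmax.
    """
    required = {"date", "tmin", "tmax"}
    missing = required - set(weather.columns)
    if missing:
        raise ValidationError(f"weather table missing columns: {sorted(missing)}")
    out = weather.copy()
    out["date"] = pd.to_datetime(out["date"]).dt.normalize()
    out = out.sort_values("date").reset_index(drop=True)
    if out["date"].duplicated().any():
        dups = out.loc[out["date"].duplicated(), "date"].dt.date.unique()
        raise ValidationError(f"duplicate weather dates: {list(dups)[:5]}")
    t = out[["tmin", "tmax"]].to_numpy(dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValidationError("non-finite temperatures in weather table")
    bad = out["tmin"] > out["tmax"]
    if bad.any():
        dates = out.loc[bad, "date"].dt.strftime("%Y-%m-%d").tolist()
        raise ValidationError(f"tmin > tmax on dates: {dates[:5]}")
    return out


def _fill_gaps(weather: pd.DataFrame, full_index: pd.DatetimeIndex, max_gap: int) -> pd.DataFrame:
    """Linearly interpolate tmin/tmax across gaps of at most ``max_gap`` days."""
    idx = weather.set_index("date").reindex(full_index)
    missing = idx["tmin"].isna()
    # identify runs of consecutive missing days
    run_id = (missing != missing.shift()).cumsum()
    for _, run in idx[missing].groupby(run_id[missing]):
        if len(run) > max_gap:
            raise WeatherGapError(list(run.index))
    idx[["tmin", "tmax"]] = idx[["tmin", "tmax"]].interpolate(method="time", limit_area="inside")
    if idx[["tmin", "tmax"]].isna().any().any():
        raise WeatherGapError(list(idx.index[idx["tmin"].isna()]))
    return idx.reset_index(names="date")


def accumulate_dd(
    weather: pd.DataFrame,
    thresholds: ThresholdPair,
    start_date,
    end_date,
    method: str = "single_sine",
    fill_gaps_max: int | None = None,
) -> pd.DataFrame:
    """Daily and cumulative degree-days over the closed interval [start, end].

    Returns a DataFrame with columns ``date``, ``dd``, ``cum_dd``.  Missing
    days inside the interval raise :class:`WeatherGapError` unless
    ``fill_gaps_max`` allows linear interpolation across short gaps (which is
    then recorded in ``result.attrs['gap_filled']``).
    """
    if method not in _METHODS:
        raise ValidationError(f"unknown method {method!r}; expected one of {sorted(_METHODS)}")
    start = pd.Timestamp(start_date).normalize()
    end = pd.Timestamp(end_date).normalize()
    if start > end:
        raise ValidationError(f"start_date {start.date()} after end_date {end.date()}")

    w = validate_weather(weather)
    if w.empty or start < w["date"].iloc[0] or end > w["date"].iloc[-1]:
        raise RangeCoverageError(
            f"weather covers {w['date'].iloc[0].date() if len(w) else '<empty>'}"
            f"..{w['date'].iloc[-1].date() if len(w) else ''}, requested {start.date()}..{end.date()}"
        )
    w = w[(w["date"] >= start) & (w["date"] <= end)]
    full = pd.date_range(start, end, freq="D")
    gap_filled = False
    if len(w) < len(full):
        if fill_gaps_max is None:
            present = pd.DatetimeIndex(w["date"])
            raise WeatherGapError(list(full.difference(present)))
        w = _fill_gaps(w, full, fill_gaps_max)
        gap_filled = True

    dd = _METHODS[method](w["tmin"].to_numpy(), w["tmax"].to_numpy(), thresholds)
    trace = pd.DataFrame({"date": full, "dd": dd, "cum_dd": np.cumsum(dd)})
    trace.attrs["method"] = method
    trace.attrs["thresholds"] = (thresholds.ltt, thresholds.utt)
    trace.attrs["gap_filled"] = gap_filled
    if "resolution" in weather.attrs:
        trace.attrs["resolution"] = weather.attrs["resolution"]
    return trace


def dd_to_date(
    weather: pd.DataFrame,
    thresholds: ThresholdPair,
    start_date,
    target_dd: float,
    method: str = "single_sine",
    fill_gaps_max: int | None = None,
) -> pd.Timestamp:
    """Earliest date whose cumulative DD from ``start_date`` reaches ``target_dd``.

    Whole-day resolution, no intra-day interpolation: the returned date ``d``
    satisfies ``cum(d-1) < target <= cum(d)`` (with ``cum`` the inclusive
    cumulative trace), and ``target_dd == 0`` maps to the start date.
    """
    if target_dd < 0:
        raise ValidationError("target_dd must be non-negative")
    w = validate_weather(weather)
    if w.empty:
        raise RangeCoverageError("empty weather series")
    trace = accumulate_dd(
        w, thresholds, start_date, w["date"].iloc[-1], method=method, fill_gaps_max=fill_gaps_max
    )
    cum = trace["cum_dd"].to_numpy()
    hit = np.searchsorted(cum, target_dd, side="left")
    if target_dd == 0:
        return trace["date"].iloc[0]
    if hit >= len(cum):
        raise TargetUnreachableError(target_dd, cum[-1], trace["date"].iloc[-1])
    return trace["date"].iloc[hit]
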