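"""Field calibration of developmental thresholds by CV minimisation.

Degree-days accumulated over a repeated phenological event (here: one
pink bollworm generation, delimited by successive pheromone-trap catch
peaks) should be constant across years when computed with the species'
true developmental thresholds; wrong thresholds let the year-to-year
weather leak into the totals.  The calibration therefore evaluates a grid
of candidate (LTT, UTT) pairs and selects the pair minimising the
coefficient of variation (CV) of the event degree-day totals.

Two event kinds enter the procedure:

* ``jan1_to_emergence`` — 1 January to the beginning of moth emergence;
* ``emergence_to_next_peak`` / ``peak_to_peak`` — successive trap-catch
  peaks, i.e. one in-field generation.

The two between-peak kinds measure the same biological quantity (one
generation) and are pooled for the primary ranking; the jan1 kind breaks
ties, then the lower LTT.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .degreedays import ThresholdPair, single_sine_dd, validate_weather
from .errors import (
    ConfigurationError,
    InsufficientDataError,
    RangeCoverageError,
    ValidationError,
)

__all__ = [
    "EVENT_KINDS",
    "BETWEEN_PEAK_KINDS",
    "CalibrationEvent",
    "CalibrationResult",
    "cv_percent",
    "event_dd_table",
    "calibrate_thresholds",
]

EVENT_KINDS = ("jan1_to_emergence", "emergence_to_next_peak", "peak_to_peak")
BETWEEN_PEAK_KINDS = ("emergence_to_next_peak", "peak_to_peak")

RANKING_RULE = (
    "minimise the sum of the two event-kind CVs (pooled between-peak CV + "
    "jan1_to_emergence CV); ties broken by lower between-peak CV, then lower LTT"
)


@dataclass(frozen=True)
class CalibrationEvent:
    """One phenological interval in one year, bounded by calendar dates."""

    year: int
    event_kind: str
    start_date: pd.Timestamp
    end_date: pd.Timestamp

    def __post_init__(self) -> None:
        if self.event_kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.event_kind!r}")
        start = pd.Timestamp(self.start_date).normalize()
        end = pd.Timestamp(self.end_date).normalize()
        object.__setattr__(self, "start_date", start)
        object.__setattr__(self, "end_date", end)
        if not start < end:
            raise ValidationError(f"event start {start.date()} not before end {end.date()}")


@dataclass
class CalibrationResult:
    """Full CV grid plus the selected threshold pair."""

    grid: pd.DataFrame
    best: ThresholdPair
    ranking_rule: str = RANKING_RULE


def cv_percent(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 * sample sd (n-1) / mean."""
    arr = np.asarray(list(values), dtype=float)
    if arr.size < 2:
        raise InsufficientDataError(f"CV needs at least 2 values, got {arr.size}")
    mean = arr.mean()
    if mean <= 0:
        raise ValidationError(f"CV undefined for non-positive mean ({mean:.3g})")
    return float(100.0 * arr.std(ddof=1) / mean)


def _year_arrays(weather_by_year: Mapping[int, pd.DataFrame]) -> dict[int, tuple]:
    """Pre-extract (dates, tmin, tmax) numpy arrays per year for fast grid scans."""
    out = {}
    for year, wdf in weather_by_year.items():
        w = validate_weather(wdf)
        dates = w["date"].to_numpy(dtype="datetime64[D]")
        if len(dates) > 1 and np.any(np.diff(dates).astype(int) != 1):
            gaps = dates[:-1][np.diff(dates).astype(int) != 1]
            raise RangeCoverageError(f"weather for year {year} has gaps after {gaps[:3]}")
        out[year] = (dates, w["tmin"].to_numpy(), w["tmax"].to_numpy())
    return out


def event_dd_table(
    weather_by_year: Mapping[int, pd.DataFrame],
    events: Iterable[CalibrationEvent],
    thresholds: ThresholdPair,
) -> pd.DataFrame:
    """Single-sine DD accumulated over each event's closed date interval.

    Returns a tidy table (year, event_kind, start_date, end_date, dd) that
    preserves year labels for grouping by kind.
    """
    return _event_dd_table(_year_arrays(weather_by_year), list(events), thresholds)


def _event_dd_table(year_arrays, events, thresholds) -> pd.DataFrame:
    cum_by_year = {}
    for year, (dates, tmin, tmax) in year_arrays.items():
        dd = single_sine_dd(tmin, tmax, thresholds)
        cum_by_year[year] = (dates, np.concatenate([[0.0], np.cumsum(dd)]))

    rows = []
    for ev in events:
        if ev.year not in cum_by_year:
            raise RangeCoverageError(f"no weather for year {ev.year} (event {ev.event_kind})")
        dates, cum0 = cum_by_year[ev.year]
        s = np.datetime64(ev.start_date.date())
        e = np.datetime64(ev.end_date.date())
        i = np.searchsorted(dates, s)
        j = np.searchsorted(dates, e)
        if i >= len(dates) or dates[i] != s or j >= len(dates) or dates[j] != e:
            raise RangeCoverageError(
                f"event {ev.event_kind} {ev.start_date.date()}..{ev.end_date.date()} "
                f"not covered by weather for year {ev.year}"
            )
        rows.append(
            {
                "year": ev.year,
                "event_kind": ev.event_kind,
                "start_date": ev.start_date,
                "end_date": ev.end_date,
                "dd": cum0[j + 1] - cum0[i],  # closed interval [start, end]
            }
        )
    return pd.DataFrame(rows)


def calibrate_thresholds(
    weather_by_year: Mapping[int, pd.DataFrame],
    events: Iterable[CalibrationEvent],
    ltt_grid: Sequence[float],
    utt_grid: Sequence[float],
) -> CalibrationResult:
    """Evaluate the full LTT x UTT cross product and select the lowest-CV pair.

    Invalid pairs (ltt >= utt) are skipped with a warning.  Each grid cell
    records per-kind CVs and means; the ranking follows :data:`RANKING_RULE`.
    """
    ltt_grid = list(ltt_grid)
    utt_grid = list(utt_grid)
    if not ltt_grid or not utt_grid:
        raise ConfigurationError("empty threshold grid")
    events = list(events)
    year_arrays = _year_arrays(weather_by_year)

    rows = []
    for ltt in ltt_grid:
        for utt in utt_grid:
            if not ltt < utt:
                warnings.warn(f"skipping invalid threshold pair ({ltt}, {utt})", stacklevel=2)
                continue
            pair = ThresholdPair(ltt, utt)
            table = _event_dd_table(year_arrays, events, pair)
            cell = {"ltt": ltt, "utt": utt}
            between = table[table["event_kind"].isin(BETWEEN_PEAK_KINDS)]["dd"]
            cell["n_between"] = len(between)
            cell["mean_dd_between"] = between.mean() if len(between) else np.nan
            cell["cv_between"] = cv_percent(between) if len(between) >= 2 else np.nan
            for kind in EVENT_KINDS:
                vals = table.loc[table["event_kind"] == kind, "dd"]
                cell[f"n_{kind}"] = len(vals)
                cell[f"mean_dd_{kind}"] = vals.mean() if len(vals) else np.nan
                cell[f"cv_{kind}"] = cv_percent(vals) if len(vals) >= 2 else np.nan
            rows.append(cell)

    if not rows:
        raise ConfigurationError("all threshold pairs in the grid were invalid")
    grid = pd.DataFrame(rows)

    between = grid["cv_between"].fillna(np.inf)
    jan1 = grid["cv_jan1_to_emergence"]
    # a grid run without jan1 events ranks on the between-peak CV alone
    score = between + (jan1 if jan1.notna().all() else 0.0)
    ranked = grid.assign(_score=score, _tie=between).sort_values(
        ["_score", "_tie", "ltt"], kind="mergesort"
    )
    best_row = ranked.iloc[0]
    best = ThresholdPair(float(best_row["ltt"]), float(best_row["utt"]))
    return CalibrationResult(grid=grid, best=best)


def grid_report(result: CalibrationResult, value: str = "cv_between") -> pd.DataFrame:
    """Pivot the calibration grid into an LTT-by-UTT matrix of one statistic."""
    return result.grid.pivot(index="ltt", columns="utt", values=value)
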