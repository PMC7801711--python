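"""Trap-series phenology: emergence, peaks, biofix and generation events.

Weekly pheromone-trap catches of male moths index adult activity.  The
module extracts the observables the degree-day analysis runs on:

* the emergence date (first survey with a minimum mean catch),
* catch peaks (local maxima of the smoothed weekly series),
* a crop-phenology biofix (two weeks before the first rosette flower,
  i.e. roughly when the eggs producing the first in-field generation were
  laid on susceptible squares), and
* the chain of in-field generations, delimited by successive peaks whose
  degree-day spacing matches the species' thermal constant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .degreedays import ThresholdPair, accumulate_dd
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "TrapSeries",
    "CropPhenologyRules",
    "GenerationConfig",
    "GenerationEvent",
    "FilterResult",
    "filter_site_year",
    "emergence_date",
    "detect_peaks",
    "biofix_from_crop",
    "estimate_generations",
    "generations_to_peak",
]


@dataclass
class TrapSeries:
    """Weekly mean male-moth catches per trap for one site-year."""

    site: str
    data: pd.DataFrame  # columns: date, mean_catch
    n_traps: int | None = None
    season: int | None = None  # season label = year the cropping season starts in

    def __post_init__(self) -> None:
        df = self.data.copy()
        required = {"date", "mean_catch"}
        if missing := required - set(df.columns):
            raise ValidationError(f"trap series missing columns: {sorted(missing)}")
        df["date"] = pd.to_datetime(df["date"]).dt.normalize()
        df = df.sort_values("date").reset_index(drop=True)
        if df["date"].duplicated().any():
            raise ValidationError(f"duplicate trap observation dates for site {self.site}")
        if (df["mean_catch"] < 0).any():
            raise ValidationError(f"negative trap catches for site {self.site}")
        self.data = df
        if self.season is None and len(df):
            # cropping seasons run ~June-March; anchor the window in April so
            # early-June surveys and post-new-year catches share one label
            first = df["date"].iloc[0]
            self.season = int(first.year if first.month >= 4 else first.year - 1)


@dataclass(frozen=True)
class CropPhenologyRules:
    """Cotton phenology timings (days) used to anchor the biofix.

    Defaults are field observations: the first just-visible square appears
    43-45 days after sowing (DAS); squares are most susceptible to
    oviposition at 8-10 days old; a square infested then becomes a rosette
    flower 12-14 days later.  The biofix for first-generation degree-day
    accumulation is 14 days before the first rosette flower.
    """

    das_first_square: tuple[int, int] = (43, 45)
    square_susceptible_age: tuple[int, int] = (8, 10)
    square_to_flower_days: tuple[int, int] = (12, 14)
    biofix_offset_days: int = -14

    def __post_init__(self) -> None:
        for name in ("das_first_square", "square_susceptible_age", "square_to_flower_days"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} must be a positive day range, got {(lo, hi)}")
        if self.biofix_offset_days >= 0:
            raise ValidationError("biofix_offset_days must be negative (biofix precedes rosette)")


@dataclass(frozen=True)
class GenerationConfig:
    """Thermal parameters of one pink bollworm generation.

    ``generation_dd`` is the laboratory egg-to-adult thermal constant;
    a between-peak accumulation within ``acceptance_center ± acceptance_band``
    is accepted as one completed in-field generation.
    """

    generation_dd: float = 503.62
    acceptance_center: float = 500.00
    acceptance_band: float = 10.00
    emergence_min_catch: float = 2.0

    def __post_init__(self) -> None:
        if self.generation_dd <= 0 or self.acceptance_band <= 0 or self.acceptance_center <= 0:
            raise ValidationError("generation parameters must be positive")


@dataclass(frozen=True)
class GenerationEvent:
    """One link of the generation chain between two trap-catch peaks."""

    index: int
    start_peak_date: pd.Timestamp
    end_peak_date: pd.Timestamp
    dd: float
    days: int
    accepted: bool
    overlapping: bool


@dataclass
class FilterResult:
    passed: bool
    violations: list[int] = field(default_factory=list)
    emergence: pd.Timestamp | None = None

    def __bool__(self) -> bool:
        return self.passed


def _candidate_emergence(series: TrapSeries, min_catch: float, july_cutoff: bool) -> pd.Timestamp | None:
    df = series.data
    mask = df["mean_catch"] >= min_catch
    if july_cutoff and len(df):
        season = series.season if series.season is not None else df["date"].iloc[0].year
        mask &= df["date"] >= pd.Timestamp(int(season), 7, 1)
    hits = df.loc[mask, "date"]
    return hits.iloc[0] if len(hits) else None


def filter_site_year(series: TrapSeries, min_catch: float = 2.0) -> FilterResult:
    """Classify a site-year against the four data-inclusion criteria.

    (1) every observation at/after the emergence date has a mean catch of at
    least ``min_catch``; (2) at least one zero-catch survey precedes the
    emergence date; (3) the insect appears on more than one survey date;
    (4) at least one survey falls within the two weeks before emergence.
    A series with no qualifying emergence observation fails criterion (1).
    """
    if series.data.empty:
        raise ValidationError("empty trap series")
    df = series.data
    violations: list[int] = []
    emergence = _candidate_emergence(series, min_catch, july_cutoff=True)
    if emergence is None:
        violations.append(1)
        if not (df["mean_catch"] > 0).sum() > 1:
            violations.append(3)
        return FilterResult(False, violations, None)

    after = df[df["date"] >= emergence]
    if (after["mean_catch"] < min_catch).any():
        violations.append(1)
    before = df[df["date"] < emergence]
    if not (before["mean_catch"] == 0).any():
        violations.append(2)
    if not (df["mean_catch"] > 0).sum() > 1:
        violations.append(3)
    window = before[before["date"] >= emergence - pd.Timedelta(days=14)]
    if window.empty:
        violations.append(4)
    return FilterResult(not violations, violations, emergence)


def emergence_date(series: TrapSeries, config: GenerationConfig = GenerationConfig()) -> pd.Timestamp:
    """First survey date with mean catch >= the emergence minimum.

    Dates before 1 July of the season year are excluded: pre-July catches
    are rare and not used as emergence proxies.
    """
    hit = _candidate_emergence(series, config.emergence_min_catch, july_cutoff=True)
    if hit is None:
        raise InsufficientDataError(
            f"no observation with catch >= {config.emergence_min_catch} for site {series.site}"
        )
    return hit


def detect_peaks(
    series: TrapSeries,
    min_prominence: float = 2.0,
    min_separation_days: int = 21,
    smooth_window: int = 3,
) -> list[pd.Timestamp]:
    """Dates of trap-catch peaks: smoothed strict local maxima.

    A centred moving average (window in observations) suppresses sampling
    noise; peaks need a prominence of at least ``min_prominence`` moths and
    a pairwise calendar separation of ``min_separation_days`` (higher peaks
    win).  An endpoint qualifies only when it exceeds its single neighbour
    by the prominence margin.
    """
    df = series.data
    if len(df) < 3:
        raise InsufficientDataError("peak detection needs at least 3 observations")
    y = df["mean_catch"].to_numpy(dtype=float)
    if smooth_window and smooth_window > 1:
        y = pd.Series(y).rolling(smooth_window, center=True, min_periods=1).mean().to_numpy()
    dates = df["date"].reset_index(drop=True)

    idx, _ = find_peaks(y, prominence=min_prominence)
    idx = list(idx)
    if y[0] - y[1] >= min_prominence:
        idx.insert(0, 0)
    if y[-1] - y[-2] >= min_prominence:
        idx.append(len(y) - 1)

    # enforce calendar separation, keeping the higher peak
    order = sorted(idx, key=lambda i: -y[i])
    kept: list[int] = []
    for i in order:
        if all(abs((dates[i] - dates[j]).days) >= min_separation_days for j in kept):
            kept.append(i)
    return [dates[i] for i in sorted(kept)]


@dataclass(frozen=True)
class BiofixResult:
    biofix: pd.Timestamp
    first_square: tuple[pd.Timestamp, pd.Timestamp]
    susceptible_square: tuple[pd.Timestamp, pd.Timestamp]
    first_flower: tuple[pd.Timestamp, pd.Timestamp]


def biofix_from_crop(
    sowing_date,
    first_rosette_date,
    rules: CropPhenologyRules = CropPhenologyRules(),
) -> BiofixResult:
    """Biofix date (offset before the first rosette flower) plus predicted crop milestones.

    The milestone windows (first square, most-susceptible square, first
    flower) are date ranges implied by the rules, returned for
    cross-checking the observed rosette date against crop development.
    """
    sowing = pd.Timestamp(sowing_date).normalize()
    rosette = pd.Timestamp(first_rosette_date).normalize()
    if not rosette > sowing:
        raise ValidationError("first rosette date must fall after sowing")

    def window(start_lo, start_hi, offset):
        lo, hi = offset
        return (start_lo + pd.Timedelta(days=lo), start_hi + pd.Timedelta(days=hi))

    square = window(sowing, sowing, rules.das_first_square)
    susceptible = window(*square, rules.square_susceptible_age)
    flower = window(*susceptible, rules.square_to_flower_days)
    biofix = rosette + pd.Timedelta(days=rules.biofix_offset_days)
    if biofix <= sowing:
        raise ValidationError(
            f"biofix {biofix.date()} not after sowing {sowing.date()}; dates inconsistent"
        )
    return BiofixResult(biofix, square, susceptible, flower)


def estimate_generations(
    weather: pd.DataFrame,
    thresholds: ThresholdPair,
    biofix,
    peaks: Sequence[pd.Timestamp],
    config: GenerationConfig = GenerationConfig(),
) -> list[GenerationEvent]:
    """Walk the peak chain from the biofix, delimiting in-field generations.

    From each anchor (the biofix, then the previous generation's peak) the
    subsequent peak whose degree-day distance is nearest the thermal
    constant becomes the next generation boundary; it is *accepted* when the
    span falls within the acceptance band.  Peaks the chain skips are
    emitted as ``overlapping`` events (intermittent peaks from continuously
    emerging moths).  If every remaining peak is closer than one acceptance
    band below the band centre, none can delimit a full generation: they are
    all emitted as overlapping and the chain stops.

    Degree-day spans are start-exclusive (``cum[end] - cum[start]``), so
    consecutive events tile the season without double counting days.
    """
    biofix = pd.Timestamp(biofix).normalize()
    peaks = sorted(pd.Timestamp(p).normalize() for p in peaks)
    peaks = [p for p in peaks if p > biofix]
    if not peaks:
        warnings.warn("no trap-catch peaks after the biofix; no generations estimated", stacklevel=2)
        return []

    trace = accumulate_dd(weather, thresholds, biofix, peaks[-1])
    cum = dict(zip(trace["date"], trace["cum_dd"]))
    lower_edge = config.acceptance_center - config.acceptance_band

    events: list[GenerationEvent] = []
    anchor, anchor_dd = biofix, cum[biofix]
    remaining = [(p, cum[p]) for p in peaks]
    gen_index = 0
    while remaining:
        deltas = [p_dd - anchor_dd for _, p_dd in remaining]
        if max(deltas) < lower_edge:
            # nothing left spans a full generation: all intermittent
            for (p, p_dd), delta in zip(remaining, deltas):
                events.append(
                    GenerationEvent(
                        index=gen_index + 1,
                        start_peak_date=anchor,
                        end_peak_date=p,
                        dd=float(delta),
                        days=(p - anchor).days,
                        accepted=False,
                        overlapping=True,
                    )
                )
            break
        choice = int(np.argmin([abs(d - config.generation_dd) for d in deltas]))
        gen_index += 1
        for k in range(choice):
            p, p_dd = remaining[k]
            events.append(
                GenerationEvent(
                    index=gen_index,
                    start_peak_date=anchor,
                    end_peak_date=p,
                    dd=float(p_dd - anchor_dd),
                    days=(p - anchor).days,
                    accepted=abs((p_dd - anchor_dd) - config.acceptance_center)
                    <= config.acceptance_band,
                    overlapping=True,
                )
            )
        p, p_dd = remaining[choice]
        events.append(
            GenerationEvent(
                index=gen_index,
                start_peak_date=anchor,
                end_peak_date=p,
                dd=float(p_dd - anchor_dd),
                days=(p - anchor).days,
                accepted=abs((p_dd - anchor_dd) - config.acceptance_center) <= config.acceptance_band,
                overlapping=False,
            )
        )
        anchor, anchor_dd = p, p_dd
        remaining = remaining[choice + 1 :]
    return events


def generations_to_peak(peak_gdd: float, per_generation_dd: float) -> int:
    """Whole generations completed within ``peak_gdd`` thermal units."""
    if peak_gdd <= 0 or per_generation_dd <= 0:
        raise ValidationError("degree-day inputs must be positive")
    return int(np.floor(peak_gdd / per_generation_dd))


def generation_table(events: Sequence[GenerationEvent]) -> pd.DataFrame:
    """Tabular report of a generation chain."""
    return pd.DataFrame(
        [
            {
                "index": e.index,
                "start_peak": e.start_peak_date.date(),
                "end_peak": e.end_peak_date.date(),
                "dd": round(e.dd, 2),
                "days": e.days,
                "accepted": e.accepted,
                "overlapping": e.overlapping,
            }
            for e in events
        ]
    )
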