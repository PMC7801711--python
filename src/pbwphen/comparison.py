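"""Leave-one-out comparison of degree-days vs ordinal date as phenology predictors.

For every site with at least three survey years, each year's peak moth
catch is predicted from the *other* years two ways: (a) the mean ordinal
date of the peak, and (b) the mean degree-day accumulation
(emergence → peak) converted back to a calendar date using that year's own
weather.  The absolute date error of each predictor is compared per
site-year, and a 1-df chi-square goodness-of-fit test against a 50:50 null
asks whether one predictor wins more site-years than chance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .degreedays import ThresholdPair, dd_to_date
from .errors import InsufficientDataError, TargetUnreachableError, ValidationError

__all__ = [
    "PeakRecord",
    "ComparisonRecord",
    "loo_means",
    "compare_site_year",
    "chisq_gof_1df",
    "site_summary",
]

MIN_YEARS = 3  # inclusion rule: sites need >= 3 survey years


@dataclass(frozen=True)
class PeakRecord:
    """Observed peak moth catch for one site-year."""

    site: str
    year: int
    emergence_date: pd.Timestamp
    peak_date: pd.Timestamp
    peak_gdd: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "emergence_date", pd.Timestamp(self.emergence_date).normalize())
        object.__setattr__(self, "peak_date", pd.Timestamp(self.peak_date).normalize())
        if self.emergence_date > self.peak_date:
            raise ValidationError(f"emergence after peak for {self.site} {self.year}")
        if self.peak_gdd < 0:
            raise ValidationError("peak_gdd must be non-negative")


@dataclass(frozen=True)
class ComparisonRecord:
    site: str
    year: int
    observed_date: pd.Timestamp
    loo_mean_date_error: float
    loo_mean_gdd_as_date_error: float
    winner: str  # "gdd" | "date" | "tie"


def loo_means(values_by_year: Mapping[int, float]) -> dict[int, float]:
    """For each year, the mean of all *other* years' values."""
    years = list(values_by_year)
    if len(years) < MIN_YEARS:
        raise InsufficientDataError(
            f"leave-one-out means need >= {MIN_YEARS} years, got {len(years)}"
        )
    vals = np.array([float(values_by_year[y]) for y in years])
    total = vals.sum()
    return {y: float((total - v) / (len(vals) - 1)) for y, v in zip(years, vals)}


def _ordinal(date: pd.Timestamp, season_year: int) -> float:
    """Day-of-season relative to 1 January of the season's starting year.

    Seasons at southern sites run past the new year, so the ordinal keeps
    counting (367, 368, ...) rather than wrapping.
    """
    return float((date - pd.Timestamp(season_year, 1, 1)).days + 1)


def compare_site_year(
    records: Sequence[PeakRecord],
    weather_by_year: Mapping[tuple[str, int] | int, pd.DataFrame],
    thresholds: ThresholdPair,
) -> list[ComparisonRecord]:
    """Per site-year leave-one-out errors for the date and GDD predictors.

    ``weather_by_year`` maps ``(site, year)`` (or plain ``year`` for a
    single-site analysis) to that season's daily weather; it is needed to
    convert the left-out-mean GDD back onto the calendar.  Records whose GDD
    target cannot be reached within the year's weather are excluded with a
    warning.
    """
    out: list[ComparisonRecord] = []
    for site in sorted({r.site for r in records}):
        site_records = sorted((r for r in records if r.site == site), key=lambda r: r.year)
        date_loo = loo_means({r.year: _ordinal(r.peak_date, r.year) for r in site_records})
        gdd_loo = loo_means({r.year: r.peak_gdd for r in site_records})
        for rec in site_records:
            key = (site, rec.year) if (site, rec.year) in weather_by_year else rec.year
            weather = weather_by_year[key]
            date_err = abs(_ordinal(rec.peak_date, rec.year) - date_loo[rec.year])
            try:
                predicted = dd_to_date(
                    weather, thresholds, rec.emergence_date, gdd_loo[rec.year]
                )
            except TargetUnreachableError as exc:
                warnings.warn(
                    f"{site} {rec.year}: mean GDD not reachable ({exc}); record excluded",
                    stacklevel=2,
                )
                continue
            gdd_err = abs((rec.peak_date - predicted).days)
            if gdd_err < date_err:
                winner = "gdd"
            elif date_err < gdd_err:
                winner = "date"
            else:
                winner = "tie"
            out.append(
                ComparisonRecord(site, rec.year, rec.peak_date, date_err, gdd_err, winner)
            )
    return out


def chisq_gof_1df(n_a: int, n_b: int) -> tuple[float, float]:
    """Pearson goodness-of-fit of two counts against an equal split.

    ``chi2 = (n_a - E)^2/E + (n_b - E)^2/E`` with ``E = (n_a + n_b)/2``;
    no continuity correction; p from the 1-df chi-square distribution.
    """
    if n_a < 0 or n_b < 0:
        raise ValidationError("counts must be non-negative")
    total = n_a + n_b
    if total == 0:
        raise ValidationError("chi-square undefined for zero total count")
    expected = total / 2.0
    chi2 = (n_a - expected) ** 2 / expected + (n_b - expected) ** 2 / expected
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def site_summary(comparisons: Sequence[ComparisonRecord]) -> pd.DataFrame:
    """Per-site winner counts with the chi-square test, plus an overall row."""
    rows = []
    df = pd.DataFrame(
        [{"site": c.site, "winner": c.winner} for c in comparisons]
    )
    if df.empty:
        return pd.DataFrame(columns=["site", "n_gdd_better", "n_date_better", "n_tie", "chi2", "p"])
    groups = list(df.groupby("site")) + [("all", df)]
    for site, sub in groups:
        n_gdd = int((sub["winner"] == "gdd").sum())
        n_date = int((sub["winner"] == "date").sum())
        n_tie = int((sub["winner"] == "tie").sum())
        if n_gdd + n_date > 0:
            chi2, p = chisq_gof_1df(n_gdd, n_date)
        else:
            chi2, p = np.nan, np.nan
        rows.append(
            {
                "site": site,
                "n_gdd_better": n_gdd,
                "n_date_better": n_date,
                "n_tie": n_tie,
                "chi2": chi2,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
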