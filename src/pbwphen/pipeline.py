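"""End-to-end composition: trap series -> peak records -> comparison/forecast.

Thin orchestration over the stage modules so the analysis drivers, the CLI
and the tests all run the exact same pipeline.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .comparison import MIN_YEARS, PeakRecord, compare_site_year, site_summary
from .degreedays import ThresholdPair, accumulate_dd
from .errors import InsufficientDataError
from .forecast import AnnualSeries, fit_forecast_last, residual_in_days
from .phenology import (
    GenerationConfig,
    TrapSeries,
    detect_peaks,
    emergence_date,
    filter_site_year,
)

__all__ = [
    "extract_peak_records",
    "run_comparison",
    "forecast_peak_tables",
]


def extract_peak_records(
    traps: Mapping[tuple[str, int], TrapSeries],
    weather: Mapping[tuple[str, int], pd.DataFrame],
    thresholds: ThresholdPair,
    config: GenerationConfig = GenerationConfig(),
    apply_filter: bool = True,
    **peak_kwargs,
) -> tuple[list[PeakRecord], list[tuple[str, int, list[int]]]]:
    """Peak records (emergence, seasonal-maximum peak, emergence->peak GDD) per site-year.

    Site-years failing the four inclusion criteria are returned separately
    with their violated criteria.  The seasonal peak is the highest detected
    peak of the smoothed series.
    """
    records: list[PeakRecord] = []
    rejected: list[tuple[str, int, list[int]]] = []
    for (site, year), series in traps.items():
        if apply_filter:
            verdict = filter_site_year(series, min_catch=config.emergence_min_catch)
            if not verdict:
                rejected.append((site, year, verdict.violations))
                continue
        try:
            emergence = emergence_date(series, config)
            peaks = detect_peaks(series, **peak_kwargs)
        except InsufficientDataError:
            rejected.append((site, year, []))
            continue
        peaks = [p for p in peaks if p >= emergence]
        if not peaks:
            rejected.append((site, year, []))
            continue
        lookup = series.data.set_index("date")["mean_catch"]
        peak = max(peaks, key=lambda p: lookup.loc[p])
        trace = accumulate_dd(weather[(site, year)], thresholds, emergence, peak)
        records.append(
            PeakRecord(
                site=site,
                year=year,
                emergence_date=emergence,
                peak_date=peak,
                peak_gdd=float(trace["cum_dd"].iloc[-1]),
            )
        )
    return records, rejected


def run_comparison(
    records: Sequence[PeakRecord],
    weather: Mapping[tuple[str, int], pd.DataFrame],
    thresholds: ThresholdPair,
) -> pd.DataFrame:
    """Leave-one-out predictor comparison, dropping sites below the year minimum."""
    by_site: dict[str, list[PeakRecord]] = {}
    for r in records:
        by_site.setdefault(r.site, []).append(r)
    usable: list[PeakRecord] = []
    for site, recs in by_site.items():
        if len(recs) < MIN_YEARS:
            warnings.warn(
                f"site {site}: only {len(recs)} usable years (< {MIN_YEARS}); excluded",
                stacklevel=2,
            )
            continue
        usable.extend(recs)
    if not usable:
        raise InsufficientDataError("no site with enough years for the comparison")
    comparisons = compare_site_year(usable, weather, thresholds)
    return site_summary(comparisons)


def forecast_peak_tables(
    records: Sequence[PeakRecord],
    weather: Mapping[tuple[str, int], pd.DataFrame],
    thresholds: ThresholdPair,
) -> pd.DataFrame:
    """Hold-out-last-year forecasts of peak GDD and peak date per site.

    For the GDD track the predicted accumulation is converted back to a
    calendar date with the held-out year's own weather, so both tracks
    report residuals in days (alongside the GDD residual).
    """
    from .degreedays import dd_to_date
    from .errors import TargetUnreachableError

    by_site: dict[str, list[PeakRecord]] = {}
    for r in records:
        by_site.setdefault(r.site, []).append(r)

    rows = []
    for site, recs in sorted(by_site.items()):
        recs = sorted(recs, key=lambda r: r.year)
        if len(recs) < MIN_YEARS:
            continue
        years = tuple(r.year for r in recs)
        last = recs[-1]

        gdd_fc = fit_forecast_last(
            AnnualSeries(site, years, tuple(r.peak_gdd for r in recs))
        )
        ordinals = tuple(
            float((r.peak_date - pd.Timestamp(r.year, 1, 1)).days + 1) for r in recs
        )
        date_fc = fit_forecast_last(AnnualSeries(site, years, ordinals))
        predicted_date = pd.Timestamp(last.year, 1, 1) + pd.Timedelta(
            days=int(round(date_fc.predicted)) - 1
        )
        try:
            gdd_as_date = dd_to_date(
                weather[(site, last.year)], thresholds, last.emergence_date, gdd_fc.predicted
            )
            gdd_day_resid = residual_in_days(last.peak_date, gdd_as_date)
        except TargetUnreachableError:
            gdd_as_date, gdd_day_resid = pd.NaT, np.nan
        rows.append(
            {
                "site": site,
                "observed_gdd": last.peak_gdd,
                "predicted_gdd": gdd_fc.predicted,
                "residual_gdd": gdd_fc.residual,
                "gdd_model": "".join(map(str, gdd_fc.model_order)),
                "observed_date": last.peak_date.date(),
                "predicted_date": predicted_date.date(),
                "residual_days_date": residual_in_days(last.peak_date, predicted_date),
                "date_from_gdd": gdd_as_date.date() if gdd_as_date is not pd.NaT else None,
                "residual_days_gdd": gdd_day_resid,
                "date_model": "".join(map(str, date_fc.model_order)),
                "fallback": gdd_fc.fallback_used or date_fc.fallback_used,
            }
        )
    return pd.DataFrame(rows)
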