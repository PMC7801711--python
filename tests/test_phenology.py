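"""Trap-series phenology: inclusion filter, emergence, peaks, biofix, generations."""

import warnings

import numpy as np
import pandas as pd
import pytest

from pbwphen import (
    CropPhenologyRules,
    GenerationConfig,
    InsufficientDataError,
    ThresholdPair,
    TrapSeries,
    ValidationError,
    biofix_from_crop,
    detect_peaks,
    emergence_date,
    estimate_generations,
    filter_site_year,
    generations_to_peak,
)

from .conftest import constant_weather

T = ThresholdPair(13.0, 34.0)


def weekly_series(start, catches, site="s"):
    dates = pd.date_range(start, periods=len(catches), freq="7D")
    return TrapSeries(site=site, data=pd.DataFrame({"date": dates, "mean_catch": catches}))


class TestFilter:
    def test_clean_series_passes(self):
        s = weekly_series("2015-07-01", [0, 0, 3, 5, 4, 6, 8])
        verdict = filter_site_year(s)
        assert verdict.passed and verdict.violations == []
        assert verdict.emergence == pd.Timestamp("2015-07-15")

    def test_no_prior_absence_fails_criterion_2(self):
        s = weekly_series("2015-07-01", [1, 3, 5, 4, 6])
        verdict = filter_site_year(s)
        assert not verdict.passed and 2 in verdict.violations

    def test_single_positive_survey_fails_criterion_3(self):
        s = weekly_series("2015-07-01", [0, 0, 5, 0, 0])
        verdict = filter_site_year(s)
        assert not verdict.passed and 3 in verdict.violations

    def test_low_catch_after_emergence_fails_criterion_1(self):
        s = weekly_series("2015-07-01", [0, 0, 4, 1, 6, 7])
        verdict = filter_site_year(s)
        assert not verdict.passed and 1 in verdict.violations

    def test_no_survey_shortly_before_emergence_fails_criterion_4(self):
        dates = [pd.Timestamp("2015-07-01"), pd.Timestamp("2015-09-01"),
                 pd.Timestamp("2015-09-08"), pd.Timestamp("2015-09-15")]
        s = TrapSeries("s", pd.DataFrame({"date": dates, "mean_catch": [0, 4, 5, 6]}))
        verdict = filter_site_year(s)
        assert not verdict.passed and 4 in verdict.violations


class TestEmergence:
    def test_first_date_reaching_two_moths(self):
        s = weekly_series("2015-07-01", [0, 1, 3, 5])
        assert emergence_date(s) == pd.Timestamp("2015-07-15")

    def test_all_below_threshold_not_found(self):
        s = weekly_series("2015-07-01", [0, 1, 1, 1])
        with pytest.raises(InsufficientDataError):
            emergence_date(s)

    def test_pre_july_occurrences_excluded(self):
        s = weekly_series("2015-06-24", [5, 0, 4, 6])  # 24 Jun qualifies but is pre-July
        assert emergence_date(s) == pd.Timestamp("2015-07-08")


class TestDetectPeaks:
    def test_single_triangular_pulse_apex(self):
        s = weekly_series("2015-07-01", [0, 2, 6, 12, 6, 2, 0])
        assert detect_peaks(s) == [pd.Timestamp("2015-07-22")]

    def test_two_pulses_in_order(self):
        catches = [0, 2, 10, 2, 0, 0, 0, 0, 3, 14, 3, 0]
        s = weekly_series("2015-07-01", catches)
        peaks = detect_peaks(s)
        assert peaks == [pd.Timestamp("2015-07-15"), pd.Timestamp("2015-09-02")]

    def test_close_secondary_peak_suppressed(self):
        # second bump 14 days after a higher one: below the separation floor
        catches = [0, 2, 12, 4, 10, 2, 0, 0, 0]
        s = weekly_series("2015-07-01", catches, site="x")
        peaks = detect_peaks(s, smooth_window=1)
        assert peaks == [pd.Timestamp("2015-07-15")]

    def test_recovers_planted_pulses_across_seeds(self):
        from pbwphen import SITE_PRESETS, TrapSimSpec, dd_to_date, simulate_trap_catches, simulate_weather

        hits = total = 0
        for seed in range(50):
            w = simulate_weather(SITE_PRESETS["nagpur"], "2018-01-01", 460, 1000 + seed)
            biofix = dd_to_date(w, T, "2018-01-01", 3073.55)
            spec = TrapSimSpec(biofix_date=biofix, n_generations=4, seed=1000 + seed)
            series, truth = simulate_trap_catches(w, T, spec)
            peaks = detect_peaks(series)
            for d in truth.loc[truth["kind"] == "main", "true_peak_date"]:
                total += 1
                if min(abs((p - d).days) for p in peaks) <= 8:
                    hits += 1
        assert hits / total >= 0.90


class TestBiofix:
    def test_two_weeks_before_rosette(self):
        res = biofix_from_crop("2018-06-23", "2018-08-26")
        assert res.biofix == pd.Timestamp("2018-08-12")

    def test_offset_applied_to_rosette(self):
        sowing = pd.Timestamp("2019-07-01")
        res = biofix_from_crop(sowing, sowing + pd.Timedelta(days=70))
        assert res.biofix == sowing + pd.Timedelta(days=56)

    def test_milestone_chain_from_rules(self):
        res = biofix_from_crop("2018-06-23", "2018-08-26")
        assert res.first_square == (pd.Timestamp("2018-08-05"), pd.Timestamp("2018-08-07"))
        assert res.susceptible_square == (pd.Timestamp("2018-08-13"), pd.Timestamp("2018-08-17"))
        assert res.first_flower == (pd.Timestamp("2018-08-25"), pd.Timestamp("2018-08-31"))

    def test_inconsistent_dates_rejected(self):
        with pytest.raises(ValidationError):
            biofix_from_crop("2018-08-26", "2018-06-23")
        with pytest.raises(ValidationError):
            CropPhenologyRules(biofix_offset_days=3)


class TestEstimateGenerations:
    def test_exactly_spaced_peaks_all_accepted(self, flat_weather):
        # 10 DD/day: peaks every 50 days span 500 DD each
        biofix = pd.Timestamp("2020-03-01")
        peaks = [biofix + pd.Timedelta(days=50 * k) for k in (1, 2, 3)]
        events = estimate_generations(flat_weather, T, biofix, peaks)
        assert [e.accepted for e in events] == [True, True, True]
        assert [e.overlapping for e in events] == [False, False, False]
        assert all(e.dd == pytest.approx(500.0) for e in events)
        assert [e.days for e in events] == [50, 50, 50]

    def test_single_distant_peak_not_accepted(self, flat_weather):
        biofix = pd.Timestamp("2020-03-01")
        events = estimate_generations(flat_weather, T, biofix, [biofix + pd.Timedelta(days=70)])
        assert len(events) == 1
        assert events[0].dd == pytest.approx(700.0)
        assert not events[0].accepted and not events[0].overlapping

    def test_trailing_premature_peak_is_overlapping(self, flat_weather):
        biofix = pd.Timestamp("2020-03-01")
        peaks = [biofix + pd.Timedelta(days=50), biofix + pd.Timedelta(days=75)]
        events = estimate_generations(flat_weather, T, biofix, peaks)
        assert [e.overlapping for e in events] == [False, True]
        assert events[0].accepted and not events[1].accepted

    def test_intermittent_peaks_marked_overlapping(self, flat_weather):
        biofix = pd.Timestamp("2020-01-15")
        days = [50, 75, 100, 150]  # mains at 50/100/150, intermittent at 75
        peaks = [biofix + pd.Timedelta(days=d) for d in days]
        events = estimate_generations(flat_weather, T, biofix, peaks)
        by_end = {e.end_peak_date: e for e in events}
        assert by_end[biofix + pd.Timedelta(days=75)].overlapping
        mains = [e for e in events if not e.overlapping]
        assert [e.days for e in mains] == [50, 50, 50]
        assert all(e.accepted for e in mains)

    def test_no_peaks_after_biofix_warns_empty(self, flat_weather):
        with pytest.warns(UserWarning):
            events = estimate_generations(flat_weather, T, "2020-06-01", ["2020-05-01"])
        assert events == []

    def test_deterministic_and_idempotent(self, flat_weather):
        biofix = pd.Timestamp("2020-03-01")
        peaks = [biofix + pd.Timedelta(days=d) for d in (50, 100, 160)]
        first = estimate_generations(flat_weather, T, biofix, peaks)
        second = estimate_generations(flat_weather, T, biofix, peaks)
        assert first == second

    def test_day_span_varies_with_temperature_but_dd_does_not(self):
        # one generation takes longer in a cool regime at ~equal DD
        warm = constant_weather("2020-03-01", 200, 20.0, 30.0)  # 12 DD/day
        cool = constant_weather("2020-03-01", 200, 16.0, 24.0)  # 7 DD/day
        config = GenerationConfig()
        warm_events = estimate_generations(
            warm, T, "2020-03-01", [pd.Timestamp("2020-03-01") + pd.Timedelta(days=42)], config
        )
        cool_events = estimate_generations(
            cool, T, "2020-03-01", [pd.Timestamp("2020-03-01") + pd.Timedelta(days=72)], config
        )
        assert abs(warm_events[0].dd - cool_events[0].dd) <= config.acceptance_band
        assert cool_events[0].days - warm_events[0].days >= 5


class TestGenerationsToPeak:
    @pytest.mark.parametrize(
        "gdd, per_gen, expected",
        [
            (1519.50, 504.05, 3),  # three generations to the seasonal peak
            (503.62, 503.62, 1),
            (1000.0, 503.62, 1),
        ],
    )
    def test_floor_of_thermal_ratio(self, gdd, per_gen, expected):
        assert generations_to_peak(gdd, per_gen) == expected

    def test_inverse_use_gives_per_generation_dd(self):
        # season totals of 1501.8 and 1553.45 over three generations
        assert 1501.8 / 3 == pytest.approx(500.60, abs=0.005)
        assert 1553.45 / 3 == pytest.approx(517.82, abs=0.005)

    def test_rejects_non_positive(self):
        with pytest.raises(ValidationError):
            generations_to_peak(0.0, 503.62)
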