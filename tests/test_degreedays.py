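"""Degree-day engine: closed-form cases, accumulation and date inversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbwphen import (
    RangeCoverageError,
    TargetUnreachableError,
    ThresholdPair,
    ValidationError,
    WeatherGapError,
    accumulate_dd,
    dd_to_date,
    simple_average_dd,
    single_sine_dd,
)

from .conftest import constant_weather, sine_dd_quadrature

T = ThresholdPair(13.0, 34.0)


class TestSingleSine:
    @pytest.mark.parametrize(
        "tmin, tmax, expected",
        [
            (20.0, 26.0, 10.0),  # whole day between thresholds: midpoint - L
            (35.0, 40.0, 21.0),  # whole day above the upper cutoff: U - L
            (5.0, 12.0, 0.0),  # whole day below the lower threshold
            (10.0, 30.0, 7.500904),  # lower threshold intercepted (oracle value)
            (12.0, 38.0, 11.406894),  # both thresholds intercepted (oracle value)
        ],
    )
    def test_case_contract(self, tmin, tmax, expected):
        assert single_sine_dd(tmin, tmax, T) == pytest.approx(expected, abs=1e-5)

    def test_matches_quadrature_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(300):
            tmin = rng.uniform(-5, 45)
            tmax = tmin + rng.uniform(0, 25)
            ltt = rng.uniform(5, 20)
            utt = ltt + rng.uniform(5, 25)
            closed = single_sine_dd(tmin, tmax, ThresholdPair(ltt, utt))
            assert closed == pytest.approx(
                sine_dd_quadrature(tmin, tmax, ltt, utt), abs=1e-6
            )

    def test_constant_day_uses_case_lookup(self):
        assert single_sine_dd(20.0, 20.0, T) == pytest.approx(7.0)
        assert single_sine_dd(40.0, 40.0, T) == pytest.approx(21.0)
        assert single_sine_dd(5.0, 5.0, T) == 0.0

    def test_vectorised_matches_scalar(self):
        tmin = np.array([10.0, 20.0, 35.0])
        tmax = np.array([30.0, 26.0, 40.0])
        out = single_sine_dd(tmin, tmax, T)
        assert out == pytest.approx([single_sine_dd(a, b, T) for a, b in zip(tmin, tmax)])

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            single_sine_dd(30.0, 10.0, T)
        with pytest.raises(ValidationError):
            ThresholdPair(34.0, 13.0)

    @settings(max_examples=150, derandomize=True)
    @given(
        tmin=st.floats(-5, 45),
        span=st.floats(0, 25),
        ltt=st.floats(5, 20),
        lspan=st.floats(0.5, 25),
    )
    def test_bounds_and_threshold_monotonicity(self, tmin, span, ltt, lspan):
        tmax = tmin + span
        utt = ltt + lspan
        dd = single_sine_dd(tmin, tmax, ThresholdPair(ltt, utt))
        assert 0.0 <= dd <= utt - ltt + 1e-12
        # non-increasing in the lower threshold, non-decreasing in the upper
        assert single_sine_dd(tmin, tmax, ThresholdPair(ltt - 1.0, utt)) >= dd - 1e-9
        assert single_sine_dd(tmin, tmax, ThresholdPair(ltt, utt + 1.0)) >= dd - 1e-9

    @settings(max_examples=100, derandomize=True)
    @given(tmin=st.floats(10, 33.9))
    def test_continuity_across_upper_cutoff(self, tmin):
        lo = single_sine_dd(tmin, 34.0 - 1e-6, T)
        hi = single_sine_dd(tmin, 34.0 + 1e-6, T)
        assert abs(hi - lo) < 1e-4

    def test_agrees_with_averaging_inside_thresholds(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            tmin = rng.uniform(13, 30)
            tmax = rng.uniform(tmin, 34)
            assert single_sine_dd(tmin, tmax, T) == pytest.approx(
                simple_average_dd(tmin, tmax, T), abs=1e-12
            )


class TestSimpleAverage:
    @pytest.mark.parametrize(
        "tmin, tmax, expected",
        [(20, 26, 10.0), (35, 40, 21.0), (10, 30, 7.0), (5, 12, 0.0)],
    )
    def test_clamped_midpoint(self, tmin, tmax, expected):
        assert simple_average_dd(tmin, tmax, T) == pytest.approx(expected)


class TestAccumulate:
    def test_totals_and_cumulative(self):
        w = constant_weather("2020-06-01", 3, 20, 26)
        trace = accumulate_dd(w, T, "2020-06-01", "2020-06-03")
        assert trace["cum_dd"].iloc[-1] == pytest.approx(30.0)
        assert np.all(np.diff(trace["cum_dd"]) >= 0)
        assert trace["cum_dd"].to_numpy() == pytest.approx(
            np.cumsum(trace["dd"].to_numpy())
        )

    def test_single_day_equals_daily_value(self):
        w = constant_weather("2020-06-01", 5, 10, 30)
        trace = accumulate_dd(w, T, "2020-06-02", "2020-06-02")
        assert trace["cum_dd"].iloc[-1] == pytest.approx(single_sine_dd(10, 30, T))

    def test_year_total_matches_per_day_oracle(self):
        from pbwphen import SITE_PRESETS, simulate_weather

        w = simulate_weather(SITE_PRESETS["nagpur"], "2015-01-01", 365, seed=5)
        trace = accumulate_dd(w, T, "2015-01-01", "2015-12-31")
        oracle = sum(
            sine_dd_quadrature(a, b, T.ltt, T.utt)
            for a, b in zip(w["tmin"], w["tmax"])
        )
        assert trace["cum_dd"].iloc[-1] == pytest.approx(oracle, abs=1e-4)

    def test_gap_raises_with_missing_dates(self):
        w = constant_weather("2020-06-01", 10, 20, 26)
        w = w[w["date"] != pd.Timestamp("2020-06-05")]
        with pytest.raises(WeatherGapError) as err:
            accumulate_dd(w, T, "2020-06-01", "2020-06-10")
        assert pd.Timestamp("2020-06-05") in err.value.missing_dates

    def test_short_gap_interpolated_behind_flag(self):
        w = constant_weather("2020-06-01", 10, 20, 26)
        w = w[w["date"] != pd.Timestamp("2020-06-05")]
        trace = accumulate_dd(w, T, "2020-06-01", "2020-06-10", fill_gaps_max=3)
        assert trace.attrs["gap_filled"]
        assert trace["cum_dd"].iloc[-1] == pytest.approx(100.0)

    def test_uncovered_range_raises(self):
        w = constant_weather("2020-06-01", 10, 20, 26)
        with pytest.raises(RangeCoverageError):
            accumulate_dd(w, T, "2020-05-01", "2020-06-05")


class TestDdToDate:
    def test_zero_target_is_start(self, flat_weather):
        assert dd_to_date(flat_weather, T, "2020-03-01", 0.0) == pd.Timestamp("2020-03-01")

    def test_ceiling_behaviour(self, flat_weather):
        # 10 DD/day: 25 DD is first reached at the end of day 3
        assert dd_to_date(flat_weather, T, "2020-03-01", 25.0) == pd.Timestamp("2020-03-03")

    def test_unreachable_target_reports_total(self, flat_weather):
        with pytest.raises(TargetUnreachableError) as err:
            dd_to_date(flat_weather, T, "2020-01-01", 1e6)
        assert err.value.total_dd == pytest.approx(3660.0)

    def test_round_trip_against_trace(self):
        from pbwphen import SITE_PRESETS, simulate_weather

        w = simulate_weather(SITE_PRESETS["surat"], "2016-01-01", 365, seed=9)
        trace = accumulate_dd(w, T, "2016-01-01", w["date"].iloc[-1])
        cum = trace.set_index("date")["cum_dd"]
        rng = np.random.default_rng(1)
        for target in rng.uniform(50, cum.iloc[-1], 25):
            d = dd_to_date(w, T, "2016-01-01", target)
            assert cum.loc[d] >= target
            prev = d - pd.Timedelta(days=1)
            if prev >= trace["date"].iloc[0]:
                assert cum.loc[prev] < target
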