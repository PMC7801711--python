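"""Synthetic weather/trap generator: determinism, climatology and ground truth."""

import numpy as np
import pandas as pd
import pytest

from pbwphen import (
    ConfigurationError,
    SITE_PRESETS,
    SiteClimateSpec,
    ThresholdPair,
    TrapSimSpec,
    accumulate_dd,
    calibration_scenario,
    dd_to_date,
    detect_peaks,
    scenario_suite,
    simulate_trap_catches,
    simulate_weather,
)

T = ThresholdPair(13.0, 34.0)


class TestSimulateWeather:
    def test_noiseless_flat_climate_is_constant(self):
        spec = SiteClimateSpec(
            "flat", 25.0, 0.0, noise_sd=0.0, interannual_sd=0.0, spell_sd=0.0
        )
        w = simulate_weather(spec, "2020-01-01", 30, seed=0)
        assert w["tmin"].nunique() == 1 and w["tmax"].nunique() == 1
        assert w["tmax"].iloc[0] - w["tmin"].iloc[0] == pytest.approx(spec.diurnal_range)

    def test_deterministic_under_fixed_seed(self):
        a = simulate_weather(SITE_PRESETS["surat"], "2020-01-01", 100, seed=5)
        b = simulate_weather(SITE_PRESETS["surat"], "2020-01-01", 100, seed=5)
        pd.testing.assert_frame_equal(a, b)
        c = simulate_weather(SITE_PRESETS["surat"], "2020-01-01", 100, seed=6)
        assert not a["tmin"].equals(c["tmin"])

    def test_annual_mean_matches_preset(self):
        means = []
        for seed in range(20):
            w = simulate_weather(SITE_PRESETS["nagpur"], "2015-01-01", 365, seed=seed)
            means.append(((w["tmin"] + w["tmax"]) / 2).mean())
        assert np.mean(means) == pytest.approx(26.9, abs=0.5)

    def test_tmin_never_exceeds_tmax(self):
        w = simulate_weather(SITE_PRESETS["faridkot"], "2015-01-01", 365, seed=3)
        assert (w["tmin"] <= w["tmax"]).all()


class TestSimulateTrapCatches:
    def _nagpur_season(self, seed, **kwargs):
        w = simulate_weather(SITE_PRESETS["nagpur"], "2018-01-01", 460, seed)
        biofix = dd_to_date(w, T, "2018-01-01", 3073.55)
        spec = TrapSimSpec(biofix_date=biofix, seed=seed, **kwargs)
        series, truth = simulate_trap_catches(w, T, spec)
        return w, biofix, series, truth

    def test_planted_peaks_spaced_one_thermal_constant(self):
        w, biofix, series, truth = self._nagpur_season(21, n_generations=4)
        mains = truth[truth["kind"] == "main"].sort_values("pulse_index")
        dds = mains["true_dd_since_biofix"].to_numpy()
        spacings = np.diff(np.concatenate([[0.0], dds]))
        # exact up to one day's accumulation at the peak date
        daily_max = accumulate_dd(w, T, biofix, mains["true_peak_date"].iloc[-1])["dd"].max()
        assert np.all(np.abs(spacings - 503.62) <= daily_max)

    def test_dense_low_noise_sampling_recovers_exact_peaks(self):
        w, biofix, series, truth = self._nagpur_season(
            3,
            n_generations=3,
            survey_interval_days=1,
            n_traps=400,
            overdispersion=0.0,
        )
        peaks = detect_peaks(series, min_separation_days=25)
        for d in truth.loc[truth["kind"] == "main", "true_peak_date"]:
            assert min(abs((p - d).days) for p in peaks) <= 1

    def test_reproducible_and_seed_sensitive(self):
        _, _, a, _ = self._nagpur_season(10)
        _, _, b, _ = self._nagpur_season(10)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_catches_zero_before_overwintered_flight(self):
        _, biofix, series, _ = self._nagpur_season(10, survey_lead_days=60)
        early = series.data[series.data["date"] < biofix - pd.Timedelta(days=45)]
        assert (early["mean_catch"] == 0).all()


class TestScenarioSuite:
    def test_byte_identical_regeneration(self):
        a = scenario_suite(["nagpur", "surat"], 2, seed=7)
        b = scenario_suite(["nagpur", "surat"], 2, seed=7)
        assert a.site_years() == b.site_years()
        for key in a.site_years():
            pd.testing.assert_frame_equal(a.weather[key], b.weather[key])
            pd.testing.assert_frame_equal(a.traps[key].data, b.traps[key].data)

    def test_minimum_years_for_inclusion_rule(self):
        bundle = scenario_suite(["nagpur"], 3, seed=1)
        assert len(bundle.site_years()) == 3

    def test_unknown_preset_rejected(self):
        with pytest.raises(ConfigurationError):
            scenario_suite(["atlantis"], 3, seed=1)

    def test_thermal_constancy_across_climates(self):
        # inter-peak DD is climate-invariant; inter-peak day counts are not
        spans = {}
        for site in ("surat", "dharwad"):
            w = simulate_weather(SITE_PRESETS[site], "2015-01-01", 460, seed=42)
            biofix = dd_to_date(w, T, "2015-01-01", 3073.55)
            spec = TrapSimSpec(biofix_date=biofix, n_generations=3, seed=42)
            _, truth = simulate_trap_catches(w, T, spec)
            mains = truth[truth["kind"] == "main"].sort_values("pulse_index")
            dd = np.diff(np.concatenate([[0.0], mains["true_dd_since_biofix"].to_numpy()]))
            dates = np.array(
                [biofix] + list(mains["true_peak_date"]), dtype="datetime64[D]"
            )
            days = np.diff(dates).astype(int)
            spans[site] = (dd, days)
        for dd, _ in spans.values():
            assert np.all(np.abs(dd - 503.62) <= 10.0)
        assert np.mean(spans["dharwad"][1]) - np.mean(spans["surat"][1]) >= 5


class TestCalibrationScenario:
    def test_reproducible(self):
        w1, e1 = calibration_scenario(n_years=2, seed=5)
        w2, e2 = calibration_scenario(n_years=2, seed=5)
        assert e1 == e2
        for y in w1:
            pd.testing.assert_frame_equal(w1[y], w2[y])

    def test_event_layout(self):
        _, events = calibration_scenario(n_years=3, seed=0, n_peaks=4)
        kinds = [e.event_kind for e in events if e.year == 2012]
        assert kinds == [
            "jan1_to_emergence",
            "emergence_to_next_peak",
            "peak_to_peak",
            "peak_to_peak",
            "peak_to_peak",
        ]
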