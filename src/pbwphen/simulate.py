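"""Synthetic weather and trap-catch generator with known ground truth.

No raw survey or station weather data are distributed with this package,
so every pipeline stage is exercised on synthetic site-years that encode
the mechanism the analysis is meant to detect: *moth generations are
spaced by a fixed thermal interval*, not a fixed calendar interval.

Weather is a sinusoidal seasonal cycle around each site's mean annual
temperature with a fixed diurnal range, day-to-day Gaussian noise and a
season-level inter-annual anomaly.  Trap catches are a train of pulses
that are Gaussian *in thermal time* (degree-days from a biofix) — so a
warm season compresses the calendar spacing of peaks while their
degree-day spacing stays put — with geometric late-season amplitude
growth, an overwintered-emergence pulse before the biofix, a low baseline
of continuous emergence, and negative-binomial observation noise averaged
over the traps at a site.  A calendar-time pulse axis is available as the
null alternative (peaks pinned to dates regardless of temperature).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .degreedays import ThresholdPair, accumulate_dd, dd_to_date, single_sine_dd
from .errors import ConfigurationError, RangeCoverageError, ValidationError
from .phenology import TrapSeries

__all__ = [
    "SiteClimateSpec",
    "TrapSimSpec",
    "SITE_PRESETS",
    "simulate_weather",
    "simulate_trap_catches",
    "scenario_suite",
    "calibration_scenario",
    "ScenarioBundle",
]

DEFAULT_THRESHOLDS = ThresholdPair(13.0, 34.0)
GENERATION_DD = 503.62
#: mean Jan-1 -> emergence accumulation observed over eight Nagpur years
EMERGENCE_DD_FROM_JAN1 = 3073.55


@dataclass(frozen=True)
class SiteClimateSpec:
    """Sinusoidal seasonal climate for one site.

    ``mean_annual_temp`` values come from published station descriptions of
    the ten survey sites; amplitude, phase, diurnal range and noise levels
    are fixed from Indian station climatology (see docs/methods.md).
    """

    name: str
    mean_annual_temp: float
    seasonal_amplitude: float
    phase_day: int = 135  # day of year of the warmest day
    diurnal_range: float = 12.0
    noise_sd: float = 1.5
    interannual_sd: float = 0.6
    #: autocorrelated warm/cool spells: AR(1) anomaly on the daily mean
    spell_sd: float = 1.0
    spell_corr_days: float = 15.0

    def __post_init__(self) -> None:
        if self.diurnal_range <= 0:
            raise ValidationError("diurnal_range must be positive")
        if min(self.noise_sd, self.seasonal_amplitude, self.interannual_sd, self.spell_sd) < 0:
            raise ValidationError("noise/amplitude parameters must be >= 0")
        if self.spell_corr_days <= 0:
            raise ValidationError("spell_corr_days must be positive")


SITE_PRESETS: dict[str, SiteClimateSpec] = {
    s.name: s
    for s in [
        # north zone: strong seasonality, wide diurnal range
        SiteClimateSpec("faridkot", 24.1, 9.5, 165, 13.0, 1.8),
        SiteClimateSpec("sriganganagar", 24.9, 10.0, 165, 14.0, 1.8),
        # central zone (coolest weeks around mid-December)
        SiteClimateSpec("junagadh", 25.7, 5.0, 150, 12.0, 1.5),
        SiteClimateSpec("surat", 27.2, 4.5, 150, 10.0, 1.5),
        SiteClimateSpec("nagpur", 26.9, 6.5, 150, 12.5, 1.8),
        SiteClimateSpec("rahuri", 25.9, 5.5, 150, 13.0, 1.5),
        # south zone: damped seasonality
        SiteClimateSpec("dharwad", 24.3, 3.5, 140, 11.0, 1.5),
        SiteClimateSpec("raichur", 27.7, 4.0, 140, 11.5, 1.5),
        SiteClimateSpec("lam", 28.5, 4.5, 140, 10.5, 1.5),
        SiteClimateSpec("nandyal", 28.4, 4.5, 140, 11.0, 1.5),
    ]
}


@dataclass(frozen=True)
class TrapSimSpec:
    """Parameters of one simulated trap-catch season.

    ``pulse_axis`` chooses the mechanism: ``"thermal"`` places generation
    pulses every ``generation_dd`` degree-days after the biofix;
    ``"calendar"`` pins them every ``calendar_interval_days`` calendar days
    (temperature-independent null).  Amplitudes grow geometrically to mimic
    the late-season build-up of catches; observation noise is
    negative-binomial per trap (``overdispersion`` is the inverse size, 0
    recovering Poisson) and the reported value is the mean over ``n_traps``.
    """

    biofix_date: pd.Timestamp
    generation_dd: float = GENERATION_DD
    n_generations: int = 4
    pulse_sd_dd: float = 60.0
    base_amplitude: float = 8.0
    growth_factor: float = 1.8
    overdispersion: float = 0.2
    survey_interval_days: int = 7
    seed: int = 0
    n_traps: int = 30
    baseline_catch: float = 3.0
    overwinter_lead_days: int = 21
    overwinter_sd_days: float = 10.0
    overwinter_amplitude: float = 8.0
    survey_lead_days: int = 45
    intermittent_offsets_dd: tuple[float, ...] = ()
    intermittent_amp_frac: float = 0.5
    pulse_axis: str = "thermal"
    calendar_interval_days: float = 45.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "biofix_date", pd.Timestamp(self.biofix_date).normalize())
        if min(self.generation_dd, self.pulse_sd_dd, self.base_amplitude) <= 0:
            raise ValidationError("pulse parameters must be positive")
        if self.growth_factor < 1:
            raise ValidationError("growth_factor must be >= 1")
        if self.overdispersion < 0:
            raise ValidationError("overdispersion must be >= 0")
        if self.n_generations < 1 or self.survey_interval_days < 1 or self.n_traps < 1:
            raise ValidationError("n_generations, survey_interval_days, n_traps must be >= 1")
        if self.pulse_axis not in ("thermal", "calendar"):
            raise ValidationError(f"unknown pulse_axis {self.pulse_axis!r}")


def simulate_weather(
    spec: SiteClimateSpec,
    start_date,
    n_days: int,
    seed: int,
) -> pd.DataFrame:
    """Daily tmin/tmax for ``n_days`` from ``start_date``.

    Daily mean follows ``mean + amplitude * cos(2 pi (doy - phase)/365)``
    plus a season-level anomaly (sd ``interannual_sd``) and an AR(1)
    warm/cool-spell anomaly (stationary sd ``spell_sd``, correlation time
    ``spell_corr_days``); tmin/tmax sit half a diurnal range below/above
    with independent Gaussian noise, re-ordered if noise inverts them.
    Fully reproducible for a fixed seed.
    """
    if n_days < 1:
        raise ValidationError("n_days must be >= 1")
    rng = np.random.default_rng(seed)
    start = pd.Timestamp(start_date).normalize()
    dates = pd.date_range(start, periods=n_days, freq="D")
    doy = dates.day_of_year.to_numpy(dtype=float)
    season_anomaly = rng.normal(0.0, spec.interannual_sd) if spec.interannual_sd > 0 else 0.0
    spell = np.zeros(n_days)
    if spec.spell_sd > 0:
        rho = np.exp(-1.0 / spec.spell_corr_days)
        innov = rng.normal(0.0, spec.spell_sd * np.sqrt(1 - rho**2), n_days)
        spell[0] = rng.normal(0.0, spec.spell_sd)
        for i in range(1, n_days):
            spell[i] = rho * spell[i - 1] + innov[i]
    tbar = (
        spec.mean_annual_temp
        + season_anomaly
        + spell
        + spec.seasonal_amplitude * np.cos(2 * np.pi * (doy - spec.phase_day) / 365.0)
    )
    eps_min = rng.normal(0.0, spec.noise_sd, n_days) if spec.noise_sd > 0 else 0.0
    eps_max = rng.normal(0.0, spec.noise_sd, n_days) if spec.noise_sd > 0 else 0.0
    tmin = tbar - spec.diurnal_range / 2.0 + eps_min
    tmax = tbar + spec.diurnal_range / 2.0 + eps_max
    lo, hi = np.minimum(tmin, tmax), np.maximum(tmin, tmax)
    return pd.DataFrame({"date": dates, "tmin": lo, "tmax": hi})


def _thermal_time(weather: pd.DataFrame, thresholds: ThresholdPair, biofix: pd.Timestamp):
    """Cumulative DD signed around the biofix (0 at end of biofix day)."""
    w = weather.sort_values("date").reset_index(drop=True)
    dd = single_sine_dd(w["tmin"].to_numpy(), w["tmax"].to_numpy(), thresholds)
    cum = np.cumsum(dd)
    dates = pd.DatetimeIndex(w["date"])
    if biofix not in dates:
        raise RangeCoverageError(f"biofix {biofix.date()} outside weather coverage")
    offset = cum[dates.get_loc(biofix)]
    return dates, cum - offset


def simulate_trap_catches(
    weather: pd.DataFrame,
    thresholds: ThresholdPair,
    spec: TrapSimSpec,
    site: str = "synthetic",
) -> tuple[TrapSeries, pd.DataFrame]:
    """A weekly trap-catch series plus its ground-truth peak table.

    Returns ``(series, truth)`` where ``truth`` has one row per planted
    pulse: ``pulse_index``, ``kind`` (main / intermittent / overwintered),
    ``true_peak_date`` (calendar argmax of the pulse) and
    ``true_dd_since_biofix``.
    """
    biofix = spec.biofix_date
    dates, dd_axis = _thermal_time(weather, thresholds, biofix)
    days_axis = (dates - biofix).days.to_numpy(dtype=float)

    g = spec.generation_dd
    if spec.pulse_axis == "thermal":
        axis, width = dd_axis, spec.pulse_sd_dd
        step = g
    else:
        # calendar null: same pulse structure pinned to days since biofix
        axis, width = days_axis, spec.pulse_sd_dd / 10.0
        step = spec.calendar_interval_days

    # main generations form a chain: each pulse is centred one generation
    # interval past the *previous pulse's realised peak day*, exactly as the
    # insect (and the peak-to-peak accumulation rule) propagates
    main_centers: list[float] = []
    anchor = 0.0
    for _ in range(spec.n_generations):
        center = anchor + step
        peak_i = int(np.argmin(np.abs(axis - center)))
        main_centers.append(center)
        anchor = float(axis[peak_i])
    # intermittent pulses sit between chain peaks: an offset of (k + f)*step
    # is placed f*step past the k-th realised main peak
    centers: list[tuple[float, str, int]] = [
        (c, "main", k + 1) for k, c in enumerate(main_centers)
    ]
    for i, off in enumerate(spec.intermittent_offsets_dd):
        frac_pos = off / g if spec.pulse_axis == "thermal" else off / g  # position in generations
        k = int(np.floor(frac_pos))
        rel = (frac_pos - k) * step
        if 1 <= k <= len(main_centers):
            peak_i = int(np.argmin(np.abs(axis - main_centers[k - 1])))
            base_pos = float(axis[peak_i])
        else:
            base_pos = 0.0
        centers.append((base_pos + rel, "intermittent", -i - 1))

    expected = np.zeros_like(axis)
    truth_rows = []
    last_center_pos = 0.0
    for center, kind, k in centers:
        if kind == "main":
            amp = spec.base_amplitude * spec.growth_factor ** (abs(k) - 1)
        else:
            # intermittent amplitude follows the seasonal build-up at its position
            amp = (
                spec.intermittent_amp_frac
                * spec.base_amplitude
                * spec.growth_factor ** (center / step - 1.0)
            )
        expected += amp * np.exp(-((axis - center) ** 2) / (2 * width**2))
        peak_i = int(np.argmin(np.abs(axis - center)))
        truth_rows.append(
            {
                "pulse_index": k,
                "kind": kind,
                "true_peak_date": dates[peak_i],
                "true_dd_since_biofix": float(dd_axis[peak_i]),
            }
        )
        last_center_pos = max(last_center_pos, center)

    # overwintered emergence pulse, calendar-anchored ahead of the biofix
    ow_center = -float(spec.overwinter_lead_days)
    expected += spec.overwinter_amplitude * np.exp(
        -((days_axis - ow_center) ** 2) / (2 * spec.overwinter_sd_days**2)
    )
    # true pest absence before the overwintered flight begins: surveys
    # before diapause emergence record zeros, not a Gaussian tail
    expected[days_axis < ow_center - 2.0 * spec.overwinter_sd_days] = 0.0
    ow_i = int(np.argmin(np.abs(days_axis - ow_center)))
    truth_rows.append(
        {
            "pulse_index": 0,
            "kind": "overwintered",
            "true_peak_date": dates[ow_i],
            "true_dd_since_biofix": float(dd_axis[ow_i]),
        }
    )

    # continuous low-level emergence between overwintered flight and last pulse
    season_end_pos = last_center_pos + 3.5 * width
    active = (days_axis >= ow_center) & (axis <= season_end_pos)
    expected = expected + np.where(active, spec.baseline_catch, 0.0)

    first_survey = biofix - pd.Timedelta(days=spec.survey_lead_days)
    if first_survey < dates[0]:
        raise RangeCoverageError(
            f"weather starts {dates[0].date()}, surveys need {first_survey.date()}"
        )
    survey_mask = np.zeros(len(dates), dtype=bool)
    i0 = pd.DatetimeIndex(dates).get_loc(first_survey)
    end_i = int(np.searchsorted(axis, season_end_pos))  # surveys stop with the season
    survey_mask[i0:end_i:spec.survey_interval_days] = True

    rng = np.random.default_rng(spec.seed)
    mu = expected[survey_mask]
    if spec.overdispersion > 0:
        size = 1.0 / spec.overdispersion
        p = size / (size + np.maximum(mu, 1e-12))
        draws = rng.negative_binomial(size, np.clip(p, 1e-12, 1.0), (spec.n_traps, len(mu)))
    else:
        draws = rng.poisson(np.maximum(mu, 0.0), (spec.n_traps, len(mu)))
    counts = draws.mean(axis=0)

    series = TrapSeries(
        site=site,
        data=pd.DataFrame({"date": dates[survey_mask], "mean_catch": counts}),
        n_traps=spec.n_traps,
    )
    truth = (
        pd.DataFrame(truth_rows)
        .sort_values("pulse_index", key=lambda s: s.abs())
        .reset_index(drop=True)
    )
    return series, truth


@dataclass
class ScenarioBundle:
    """Multi-site multi-year synthetic fixture with its ground truth."""

    mode: str
    thresholds: ThresholdPair
    weather: dict[tuple[str, int], pd.DataFrame] = field(default_factory=dict)
    traps: dict[tuple[str, int], TrapSeries] = field(default_factory=dict)
    truth: dict[tuple[str, int], pd.DataFrame] = field(default_factory=dict)
    biofix: dict[tuple[str, int], pd.Timestamp] = field(default_factory=dict)

    def site_years(self) -> list[tuple[str, int]]:
        return sorted(self.weather)


def scenario_suite(
    names: Sequence[str],
    years: int,
    seed: int,
    mode: str = "thermal",
    thresholds: ThresholdPair = DEFAULT_THRESHOLDS,
    n_generations: int = 3,
    start_year: int = 2010,
    spec_overrides: Mapping[str, object] | None = None,
) -> ScenarioBundle:
    """Weather + trap series + truth for ``names`` x ``years`` site-years.

    ``mode="thermal"`` anchors each season's biofix at a fixed degree-day
    accumulation from 1 January (so peak *dates* shift with the weather);
    ``mode="calendar"`` pins the biofix and pulses to calendar dates.
    Regeneration with the same arguments is byte-identical.
    """
    if mode not in ("thermal", "calendar"):
        raise ConfigurationError(f"unknown scenario mode {mode!r}")
    unknown = [n for n in names if n not in SITE_PRESETS]
    if unknown:
        raise ConfigurationError(f"unknown site presets: {unknown}")
    if years < 1:
        raise ConfigurationError("years must be >= 1")

    bundle = ScenarioBundle(mode=mode, thresholds=thresholds)
    root = np.random.SeedSequence(seed)
    for si, name in enumerate(names):
        preset = SITE_PRESETS[name]
        for yi in range(years):
            year = start_year + yi
            child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(si, yi))
            w_seed, t_seed = (int(s) for s in child.generate_state(2) % (2**31))
            weather = simulate_weather(preset, pd.Timestamp(year, 1, 1), 460, w_seed)
            if mode == "thermal":
                biofix = dd_to_date(
                    weather, thresholds, pd.Timestamp(year, 1, 1), EMERGENCE_DD_FROM_JAN1
                )
            else:
                biofix = pd.Timestamp(year, 8, 12)
            spec = TrapSimSpec(
                biofix_date=biofix,
                n_generations=n_generations,
                seed=t_seed,
                pulse_axis=mode,
                **(dict(spec_overrides) if spec_overrides else {}),
            )
            series, truth = simulate_trap_catches(weather, thresholds, spec, site=name)
            key = (name, year)
            bundle.weather[key] = weather
            bundle.traps[key] = series
            bundle.truth[key] = truth
            bundle.biofix[key] = biofix
    return bundle


def calibration_scenario(
    n_years: int = 8,
    seed: int = 0,
    site: str = "nagpur",
    thresholds: ThresholdPair = DEFAULT_THRESHOLDS,
    emergence_dd: float = EMERGENCE_DD_FROM_JAN1,
    generation_dd: float = GENERATION_DD,
    n_peaks: int = 4,
    start_year: int = 2012,
):
    """Weather plus event windows for the CV-grid threshold calibration.

    For each synthetic year, the emergence date and ``n_peaks`` successive
    peak dates are placed on the calendar so that, *under the true
    thresholds*, the spans accumulate exactly the target degree-days (up to
    whole-day resolution): 1 January -> emergence hits ``emergence_dd`` and
    each peak-to-peak interval hits ``generation_dd``.  Any other threshold
    pair lets seasonal position and year-to-year weather variation into the
    totals, which is precisely the signal the CV criterion keys on.

    Returns ``(weather_by_year, events)`` ready for
    :func:`pbwphen.calibration.calibrate_thresholds`.
    """
    from .calibration import CalibrationEvent

    if site not in SITE_PRESETS:
        raise ConfigurationError(f"unknown site preset {site!r}")
    preset = SITE_PRESETS[site]
    root = np.random.SeedSequence(seed)
    weather_by_year: dict[int, pd.DataFrame] = {}
    events: list[CalibrationEvent] = []
    for yi in range(n_years):
        year = start_year + yi
        child = np.random.SeedSequence(entropy=root.entropy, spawn_key=(yi,))
        w_seed = int(child.generate_state(1)[0] % (2**31))
        jan1 = pd.Timestamp(year, 1, 1)
        weather = simulate_weather(preset, jan1, 460, w_seed)
        weather_by_year[year] = weather

        # place each endpoint on the *nearest* day to its DD target, so the
        # day-resolution error is centred on zero rather than always positive
        trace = accumulate_dd(weather, thresholds, jan1, weather["date"].iloc[-1])
        cum = trace["cum_dd"].to_numpy()

        def nearest_date(target: float) -> pd.Timestamp:
            i = int(np.argmin(np.abs(cum - target)))
            return trace["date"].iloc[i]

        emergence = nearest_date(emergence_dd)
        events.append(CalibrationEvent(year, "jan1_to_emergence", jan1, emergence))
        prev = emergence
        prev_cum = float(cum[trace["date"].searchsorted(emergence)])
        for k in range(1, n_peaks + 1):
            # chain targeting: each peak sits one thermal constant past the
            # previous peak's *actual* accumulation, so every span carries a
            # single nearest-day rounding error
            peak = nearest_date(prev_cum + generation_dd)
            kind = "emergence_to_next_peak" if k == 1 else "peak_to_peak"
            # start the day after the previous peak so the closed interval
            # tiles exactly one generation of accumulation
            events.append(CalibrationEvent(year, kind, prev + pd.Timedelta(days=1), peak))
            prev = peak
            prev_cum = float(cum[trace["date"].searchsorted(peak)])
    return weather_by_year, events
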