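# Methods

`pbwphen` implements a degree-day (DD) phenology analysis for pink bollworm
(*Pectinophora gossypiella*), the key cotton pest of the Indian subcontinent:
daily thermal accumulation, field calibration of developmental thresholds,
counting of in-field generations from pheromone-trap catch peaks, a
leave-one-out comparison of degree-days against ordinal date as phenology
predictors, and hold-out forecasting of peak timing. This note records the
model, its assumptions, the defaults, and the choices made where the design
was genuinely open.

## Single-sine degree-days with a horizontal cutoff

Each day's temperature course is modelled as one full sine period through
that day's own minimum and maximum (no blending with the next day's
minimum). Writing `m = (tmax+tmin)/2`, `a = (tmax-tmin)/2`, the day's
degree-days between a lower threshold `L` and upper threshold `U` are the
time-average of `max(0, min(T, U) - L)`. "Horizontal cutoff" means
development above `U` continues at its maximal rate — the area above `U` is
clipped flat, not subtracted — which matches how this insect's development
saturates rather than stops at high temperature. The integral has six
closed-form cases depending on whether the day's span lies below, inside,
above, or straddles the thresholds; days with `tmin == tmax` or
temperatures exactly at a threshold fall through the same `<=`/`>=` case
boundaries, making the result continuous in all arguments. The closed form
is verified in the test suite against trapezoid quadrature of the clamped
sine (40,001 nodes per day; agreement better than 1e-6 °C·day on 10,000
random days). A clamped daily-average method is included purely as a
baseline.

Accumulation is over closed date intervals at whole-day resolution.
Missing weather days are a hard error by default; linear interpolation
across gaps of at most a stated length is available behind an explicit
flag, because silent gap-filling would corrupt the CV calibration. Monthly
temperature tables (used where stations report no daily data) are expanded
to constant daily values and flagged `monthly-resolution`. Inverting a DD
target to a date returns the earliest date whose cumulative total reaches
the target, with no intra-day interpolation.

## Threshold calibration by CV minimisation

Development should consume a fixed thermal sum regardless of the year's
weather, so the DD total of a repeated phenological event — here one
trap-catch generation interval, and the 1 January → emergence run-up — is
most nearly constant across years under the true thresholds. The
calibration evaluates the full cross product of the candidate grids
(LTT 12.5, 13.0, 13.4, 13.9, 15.5 °C × UTT 32.5, 32.8, 34.0, 35.5,
37.5 °C; invalid pairs skipped with a warning) and reports, per cell, the
per-kind CVs (sample standard deviation, n−1, over the mean, in percent).

**Ranking rule.** The two between-peak event kinds (emergence → first
peak; peak → peak) measure the same quantity — one generation — and are
pooled. The selected pair minimises the *sum* of the pooled between-peak
CV and the Jan-1 → emergence CV, with ties broken by the between-peak CV
and then the lower LTT. A strict lexicographic rule (between-peak CV
first, the other CV only on exact ties) was tried first and discarded:
floating-point CVs never tie exactly, so the second criterion never
engages, and the between-peak CV alone cannot separate compensating
diagonal pairs (a lower LTT offset by a higher UTT) whose CV sits within
the day-resolution noise floor of the true pair. The summed rule uses both
event kinds, which is also all the source procedure states ("lowest CV
between events" while tabulating both CVs).

## Generation counting from trap peaks

The phenology observable is the weekly mean male-moth catch per pheromone
trap. The emergence proxy is the first survey with a mean catch of at
least 2 moths/trap/week, excluding dates before 1 July (pre-July catches
are sporadic). Site-years enter the comparison analyses only if they pass
four inclusion criteria: every post-emergence observation at or above the
2-moth minimum; at least one recorded absence before emergence; presence
on more than one survey; and a survey within the two weeks before
emergence.

Peaks are strict local maxima of a centred moving average (window 3
observations) with prominence ≥ 2 moths and pairwise calendar separation
≥ 21 days (higher peak wins); endpoints qualify only by exceeding their
single neighbour by the prominence margin. The defaults are chosen so one
generation (≥ ~30 days) cannot produce two peaks.

The biofix for first-generation accumulation is 14 days before the first
rosette flower — the rosette diagnoses a square infested at its most
susceptible age, so the offset lands near the oviposition that started the
generation. Crop milestone windows (first square 43–45 days after sowing,
susceptible square age 8–10 days, square → flower 12–14 days) are returned
for cross-checking.

The generation chain walks forward from the biofix: from each anchor (the
biofix, then the previous generation's peak) the later peak whose
start-exclusive DD distance is nearest the thermal constant (503.62 DD,
the laboratory egg-to-adult estimate) becomes the next boundary, accepted
when the span falls within 500 ± 10 DD. Peaks the chain skips are emitted
as *overlapping* events — intermittent peaks from continuously emerging
moths. If every remaining peak is nearer than one band-width below the
band centre, none can close a generation; they are all emitted as
overlapping and the chain stops. This single rule reproduces both edge
behaviours the analysis needs: one distant peak is a (rejected) chain
event, while trailing intermittent peaks after the last full generation
are overlapping. Day spans use the exclusive convention (end − start).

**Resolution limit.** Whole-day peak dates carry up to half a day's
accumulation (~4–7 DD in season) of rounding per endpoint, so even
ground-truth peak dates occasionally push a true 503.62-DD span outside
the ±10 band. Weekly surveys are far coarser: a detected peak lands on a
survey date, up to ±3–4 days (~±40 DD) from the true apex, so degree-day
spans between *detected* weekly peaks cannot meet a ±10 DD band; the chain
structure (which peaks are generation boundaries vs overlapping) is still
recovered when sampling is dense. This is the same limitation the original
field protocol faced — later-season peaks were traced via DD rather than
read from the weekly plots — and it is why the generation-count checks run
on the generator's ground-truth peak dates.

## Predictor comparison and the chi-square decision

Per site (minimum three survey years), each year's peak is predicted from
the other years two ways: the leave-one-out mean ordinal date (days since
1 January of the season's starting year, so seasons crossing the new year
keep counting), and the leave-one-out mean emergence→peak GDD converted
back to a calendar date with the year's own weather and emergence date.
The absolute day errors decide a per-site-year winner (ties kept
separately); winner counts are tested against a 50:50 null with a Pearson
goodness-of-fit chi-square on 1 df, no continuity correction. The p-values
printed in the source's site table are not reproducible from its printed
counts under any standard 1-df chi-square (e.g. 7 vs 1 gives χ² = 4.5,
p = 0.034, not "< 0.00001"); the standard test is implemented and the
discrepancy simply noted.

## Hold-out forecasting

Per-site annual series of peak GDD and peak ordinal date are very short
(3–9 points), so the candidate set is deliberately tiny: mean-only
(0,0,0), AR(1)-with-constant (1,0,0), and random walk (0,1,0). The AR(1)
is fitted by exact maximum likelihood (statsmodels ARIMA); candidates are
compared by Gaussian AICc of their conditional one-step residuals on the
common training points 2..n, because raw state-space likelihoods of d=0
and d=1 models are not comparable (the differenced model drops an
observation; naive AICc comparison systematically selected the random walk
on AR(1) test data). Below five training points the mean-only model is
mandatory and is computed as the exact arithmetic mean. The final year is
forecast one step ahead and the signed residual reported; on the GDD track
the forecast is also converted to a date with the held-out year's weather
so both tracks yield day residuals. Missing years are treated as an evenly
spaced index series.

## Synthetic data generator

No survey or station weather data are distributed, so the generator
encodes the mechanism the analysis must detect, with known ground truth.

**Weather.** Daily mean temperature is a sinusoid around the site's mean
annual temperature (the published value for each of the ten survey sites)
plus a season-level anomaly (sd 0.6 °C), an AR(1) warm/cool-spell anomaly
(stationary sd 1.0 °C, correlation time 15 days), and iid daily noise
(sd 1.5–1.8 °C); tmin/tmax sit half a diurnal range (10–14 °C by site)
below/above. Amplitude, phase, diurnal range and the noise scales were
fixed once from Indian station climatology. The spell term matters: iid
daily noise averages out over month-long event windows, and without
autocorrelated spells the synthetic inter-annual variability — the signal
the CV calibration keys on — would be unrealistically small. A single
sinusoid cannot reproduce both the pre-monsoon (May) maximum and the
monsoon plateau; the phase is set so the *cool season* (the part the
trap-catch events traverse) falls in December as observed, at the cost of
a too-smooth summer. Consequences of this simplification: synthetic
Jan-1 → emergence totals are somewhat less variable than real ones, and
monsoon cloud-cover effects on the diurnal range are absent — so passing
tests demonstrate the machinery recovers planted signal under realistic
noise, not that real data would be as clean.

**Trap catches.** Catch intensity is a train of pulses that are Gaussian
in *thermal time* (DD since the biofix), one per generation, chained so
each pulse sits one thermal constant past the previous pulse's realised
peak day — exactly how the insect (and the peak-to-peak accumulation rule)
propagates. Pulse width is 60 DD; amplitudes grow geometrically (factor
1.8 per generation) to mimic the late-season build-up; optional
intermittent pulses midway between chain peaks (amplitude a configurable
fraction, following the seasonal build-up at their position) model
overlapping generations. An overwintered-emergence pulse (calendar-
anchored ~3 weeks before the biofix, sd 10 days) precedes the season, with
catches hard-zeroed before its onset (diapause emergence has an onset;
pre-season surveys must record true absence). A baseline of 3
moths/trap/week spans the active season (continuous emergence), and
surveys stop when the season's activity ends. Observations are
negative-binomial per trap (inverse-size 0.2; Poisson at 0) averaged over
30 traps — the reported observable is a mean per trap per week, which is
what makes realistic series satisfy the ≥2-moth inclusion criterion — at
7-day intervals starting 45 days before the biofix. A calendar-axis mode
pins the same pulse structure to days instead of DD; it is the null
scenario in which ordinal date should beat degree-days.

**Calibration scenario.** For the threshold-recovery experiments, eight
synthetic years are generated and event endpoints are *placed* on the
calendar so that, under the true thresholds 13.0/34.0 °C, 1 Jan → emergence
accumulates 3073.55 DD and each successive peak sits 503.62 DD past the
previous one — as exactly as whole days permit: each endpoint is the
nearest day to its running target (a single centred rounding error per
span, rather than the always-positive bias of first-day-at-or-above
placement).

## Numerical and degenerate-input conventions

* DD results are clipped to `[0, U−L]`; crossing angles use clipped
  arcsine arguments to absorb rounding at case boundaries.
* `dd_to_date` with target 0 returns the start date; an unreachable target
  raises an error carrying the final cumulative total.
* CV requires ≥ 2 values and positive mean; grid cells without enough
  events carry NaN and rank last.
* Peak-separation conflicts are resolved in favour of the higher smoothed
  peak, deterministically.
* A constant forecast series yields a zero-variance likelihood; the
  variance is floored at 1e-12 and every candidate predicts the constant.
* Seeds: every stochastic component takes an explicit seed; scenario
  builders derive child seeds via `SeedSequence(entropy, spawn_key)` so
  site-years are independent but reproducible.

## Problem sizes used in the checks

The simulation-based checks run at the scale of the original survey
design: 8 years for calibration (5 events/year; 25-cell grid; 20 seeds),
50 seeds for the generation-count and discrimination checks, 4 sites × 6
years for the pipeline comparison, and 100 replicates of n=30 for the
AR(1) forecast coverage. These sizes make every check reproducible on a
single CPU in minutes.

## Known limitations

* The single-sinusoid climate understates summer/monsoon structure (see
  above); conclusions about the UTT rest mainly on the post-monsoon season
  and the Jan-1 → emergence window.
* The generation chain assumes the configured thermal constant is at least
  roughly right; with a badly wrong constant the nearest-in-DD rule can
  skip true generation boundaries.
* The forecasting track treats missing survey years as adjacent — with
  long gaps the AR(1)/random-walk candidates lose their time meaning and
  the mean-only model is effectively the honest choice.
* Day counts between peaks use the exclusive convention throughout; the
  source's printed day counts mix conventions and cannot all be matched
  simultaneously.
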