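# Methods

This document records what `noctograph` computes, the assumptions built
into each step, how the synthetic validation data are generated, and the
numerical and statistical choices made — including where the package
deliberately deviates from common defaults and why.

## 1. Units of analysis

Two day conventions coexist and are used deliberately:

- **Animal-night** (local noon → following local noon): the unit for
  activity *timing*.  A nocturnal bout spanning midnight is never split
  across rows.  A night is labeled by the date of its opening noon, so an
  offset at 05:00 belongs to the previous calendar date's night.
- **Calendar day** (midnight → midnight): the unit for *activity level*
  (mean daily ODBA), so that it aligns one-to-one with daily weather
  covariates.

All timestamps are naive local standard time.  The package assumes no DST
transition within a deployment; the onset/offset plausibility windows are
civil clock times.

## 2. ODBA

Per axis, the static (gravitational) component is estimated by a centered
running mean and subtracted; ODBA is the sum of absolute residuals over
the three axes.  Choices:

- **Window by rate**: 5 s at 1 Hz (5 samples) and 3 s at 10 Hz (30
  samples, made odd → 31 so the centered window is symmetric).  Window
  length in samples is `round(window_s × rate_hz)`, forced odd by adding
  one sample.
- **Edges shrink**: near the record boundaries the window truncates
  rather than padding, so output length equals input length and no
  synthetic data are invented.
- **Gaps are explicit**: a missing sample is NaN on all axes at its grid
  position.  The running mean skips NaNs (mean over the finite samples in
  the window); ODBA at a missing sample is NaN.

Invariances that follow (and are tested): a static trace reads exactly
zero; constant per-axis offsets (device re-orientation) change nothing;
scaling all axes scales ODBA linearly.

Mixed 1 Hz / 10 Hz deployments are reconciled by `compare_rates`:
decimate the 10 Hz trace (every 10th sample), compute ODBA at each rate
with its own window, aggregate hourly, and regress 1 Hz on 10 Hz.  Slope
near 1 with r² near 1 indicates both rates measure the same activity
signal.  The slope is expected slightly below 1 (the 1 Hz stream with a
5 s window removes a little more of the movement band than the 10 Hz
stream with a 3 s window); the acceptance band is [0.9, 1.1].

Hourly/daily aggregates require ≥ 80% finite-sample coverage; periods
below that are NaN rather than a biased mean.

## 3. Civil twilight

Civil dawn/dusk are the times the sun's geometric center crosses −6°
elevation (zenith 96°), computed from NOAA-style series for the equation
of time and solar declination, with the hour-angle inversion seeded at
solar noon and refined in a second pass.  No atmospheric refraction is
applied: civil twilight is defined geometrically.

Polar behavior is typed, not silent: when the sun never crosses −6° on a
date (midnight sun / polar night), `NoTwilightError` is raised.  A site
is constructible at any |latitude| < 90; `Site.twilight_guaranteed`
(|latitude| < 66.5°) tells whether every date has civil twilight.

Validation uses an *independently implemented* ephemeris — the Michalsky
(1988, Solar Energy 40:227–235) low-precision solar position with a
minute-grid + bisection crossing search, sharing no code with the
implementation — and agrees within 2 minutes on all 366 dates of 2016 at
the study site (observed maximum deviation ≈ 0.05 min).  A geometry
sanity check: at the equator on an equinox the sun descends at ~0.25°/min,
so civil dusk falls ~24 min after 18:00 solar time.

## 4. Activity onset/offset detection

The detector reproduces the classic actogram-based procedure:

1. average per-sample ODBA into 1-min clock bins (empty bins = missing);
2. smooth with a Gaussian kernel, SD 5 min, truncated at ±4 SD and
   renormalized over non-missing bins (missing bins stay missing);
3. threshold at the **median of the animal's whole smoothed deployment
   record** (per-night medians are available as an option but are less
   stable);
4. within each noon-to-noon night, find above-threshold runs lasting at
   least 30 min; the night's **principal bout** is the longest such run
   (earliest on ties);
5. the onset candidate is the upward crossing opening the principal run
   and the offset candidate the downward crossing closing it (first
   below-threshold bin after the run), refined by **hysteresis**: the
   bout is confirmed where the smoothed signal reaches the midpoint
   between the threshold and the run's median level, and the reported
   crossing is the nearest near-threshold bin (threshold + 0.15 × span)
   before/after confirmation.

Two design choices deserve explanation:

- **Principal run, not first/last crossing.**  Real records contain brief
  in-den movement (posture shifts, grooming) during the rest phase.  A
  cluster of such bursts can exceed the record-median threshold for over
  30 minutes, and a first-crossing rule then reports an "onset" hours
  before the animal actually emerges.  Anchoring both events to the
  night's dominant sustained run makes the detector report the main
  activity phase — which is what an observer marks on an actogram.
- **Hysteresis refinement.**  Bursts immediately adjacent to the true
  onset can merge with the bout into one above-threshold run, pulling the
  run-edge crossing early by tens of minutes.  Requiring confirmation at
  the mid-level and stepping back only to the nearest near-threshold bin
  skips such merged preambles.  A clean bout rises monotonically through
  both marks, so unmerged nights are unchanged to within a minute or two.
  The refinement introduces a small systematic delay (the low mark sits
  slightly above the threshold); on ground-truthed nights the net onset
  error is a few minutes — see the recovery figures below.

A detection is *withheld with a flag*, never an error, when: no qualifying
run exists (`no_detection` — the known failure mode on low or ultradian
activity), the candidate falls outside its plausibility window (onsets
15:00–23:00, offsets 01:00–09:00, inclusive), or night coverage is below
80% (`low_coverage`).  Bout duration (offset − onset, decimal hours) is
reported only for nights with both events and no flags.

Snow rule: nights whose date has snow cover ≥ 8 cm (inclusive) are
excluded from timing analyses with a `snow_excluded` flag; a night with
*missing* snow data is excluded conservatively (`snow_unresolved`).
Excluded nights remain available — exclusion is a partition, not a
deletion — and activity-level analyses keep them.

Ground-truth recovery (200 synthetic nights, onsets uniform 17:00–21:00,
offsets 03:00–07:00, consolidated bouts over a bursty rest background):
onset median |error| ≈ 2.5 min, p95 ≤ 9 min; offset median ≈ 3.5 min,
p95 ≈ 4 min; bout-duration median error ≈ 6 min; all detections inside
their windows.  The acceptance contract is median ≤ 5 min, p95 ≤ 15 min,
duration median ≤ 10 min.

## 5. Weather covariates

Input is a 5-min cadence series (temp °C, wind m/s, precip mm, snow cm).

- **Daily**: temperature and wind means over the calendar day (≥ 80%
  coverage, else NaN), `precip_sqrt` = √(daily total mm) — rain volumes
  are strongly right-skewed — and the snow category split at 8 cm
  (inclusive).  Snow is taken as the first reading of the day (the source
  reports one value per day replicated across the grid).
- **Twilight windows**: means over [t − 2.5 h, t + 2.5 h] with inclusive
  endpoints (61 records at 5-min cadence) — the conditions an animal
  experiences when deciding to leave or return to the den.  Windows
  truncated by the record report partial coverage, not an error.
- **Wind chill** enters models as the plain temperature × wind product.

## 6. Mixed models

`fit_lmm` fits a REML linear mixed model with crossed random intercepts
for individual and day of year (statsmodels `MixedLM`, a single grouping
with two variance components).  Responses: mean daily ODBA, onset
relative to dusk, offset relative to dawn (minutes; positive = after the
twilight), bout duration (h).  Fixed effects use Treatment coding with
study baselines winter / female / < 8 cm snow.

**Stage × weather guard.**  Each seasonal stage is one block of calendar
time with its own weather, so stage and weather covariates are collinear
by construction.  A specification containing both raises
`SpecificationError` at specification time — the error is in the design,
not the data.

**Inference is large-sample Wald (z).**  Satterthwaite/Kenward–Roger
denominator degrees of freedom are not available in statsmodels; with
hundreds to thousands of observations per fit the normal approximation is
adequate, and parameter-recovery simulations show 95% CI coverage within
[0.90, 0.99] at the design's scale (20 animals × 120 days, 50
replicates).  Point estimates are cross-checked against R `lme4::lmer`
in the test suite (agreement to 1e-4).

**Optimization.**  The fit tries lbfgs, then cg, then powell, reporting
the optimizer's own convergence status; statsmodels' advisory
"boundary of parameter space" warnings are not treated as failures
(they fire even on fits with strictly positive variance components).
A variance component estimated at numerical zero is reported via the
`singular` flag, not raised.

**Post-hoc.**  Least-squares means are model predictions on a reference
grid (numeric covariates at their sample mean, other categorical factors
equally weighted).  Pairwise contrasts use the studentized-range (Tukey)
distribution with residual df approximated as n − rank(X); with k = 4
stages there are 6 pairs, tested at family-wise α = 0.05.  The residual
QQ diagnostic reports the probability-plot correlation (Blom plotting
positions) with an advisory flag below 0.99.

## 7. Synthetic data generator

The generator is the package's validation instrument; realism choices are
made so that passing recovery is meaningful, not easy:

- **Gravity** is a unit vector whose orientation performs a slow random
  walk (hourly knots, interpolated), so gravity compensation is
  non-trivial.
- **Dynamic noise** is AR(1) per axis with a 0.12 s correlation time (a
  realistic movement band).  Its amplitude is calibrated in closed form:
  the running-mean residual SD of unit-variance AR(1) noise is computed
  exactly from the autocovariance, and with E|N(0,σ)| = σ√(2/π) the
  per-axis σ is solved so realized active-state ODBA equals the target —
  no empirical tuning.  Realized intensity matches the target within a
  few percent (tested at 5%).
- **Bouts are trapezoids**, not square pulses: activity ramps linearly
  over 15 min after onset and before offset (emergence, initial
  grooming).  Instantaneous on/off is biologically implausible and
  interacts with the smoothing kernel to bias crossings early/late.
- **Rest is not silent**: in-den maintenance movement arrives as Poisson
  bursts (2.5/h, mean 4 min, lognormal amplitude around 45% of the bout
  level), making the record's activity distribution realistically
  bimodal-with-overlap and the record-median threshold meaningful.
- **Fragmentation**: with sex/stage-dependent probability a night's bout
  is broken by Poisson rest gaps; deep-snow winter nights are usually
  suppressed (probability 0.85, intensity × 0.25, heavy fragmentation).
- **Study layout**: four seasonal stages; stage- and sex-specific timing
  rules (minutes relative to civil dusk/dawn) and intensities; per-animal
  chronotype and per-night jitter; no male deployments during lactation
  (study design).  Weather has a seasonal temperature cycle (coldest
  mid-January), an afternoon-peak diurnal harmonic, AR noise, monsoon
  rain, and winter snow storms whose depths straddle the 8 cm boundary
  with linear melt.
- **Determinism**: every artifact is a pure function of (config, seed);
  per-animal generators are spawned from a `SeedSequence`, so the study
  is reproducible bit-for-bit.

For mixed-model validation a separate day-level generator draws from the
exact model the LMM assumes (baseline + stage effect + individual +
day-of-year + residual, four consecutive stage blocks), with effect sizes
on the scale of a female annual cycle (lactation − winter = 0.15 g).

## 8. Pipeline

`run_pipeline` executes simulate → odba → timing → weather → model from
one config (YAML or dict; unknown sections/keys are config errors raised
before anything runs).  Stage failures abort with the failing stage named
(`PipelineError`).  Filter bookkeeping (how many nights the window and
snow rules removed) is logged.  The run manifest records a config hash,
seed, package version, and per-stage output row counts.  Output tables
are written with fixed float formatting; identical (config, seed) yields
byte-identical tables.  Actogram PNGs are rendered for inspection but are
outside the determinism contract.

## 9. Limitations

- Inference is Wald/normal; for very small designs (few animals or days)
  CIs will be anti-conservative.  The Tukey step's residual-df
  approximation ignores the random-effects structure.
- The detector targets one principal activity phase per night.  Genuinely
  polyphasic or ultradian patterns yield `no_detection` flags by design;
  the hysteresis refinement also introduces a small (minutes-scale)
  systematic delay in onsets and advance in offsets.
- The snow rule trusts a single daily snow value; sub-daily snowfall
  dynamics are not modeled.
- Twilight times assume a fixed UTC offset (local standard time) and no
  refraction correction; civil twilight is geometric by definition, but
  sites using DST must pre-convert timestamps.
- The generator is a statistical emulation, not a biomechanical model; it
  validates the *pipeline's* recovery properties, and none of its
  parameter values should be read as field estimates for any species.
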