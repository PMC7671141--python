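"""Ground-truthed synthetic accelerometry, weather, and study layouts.

The generator emulates the statistical structure the analysis pipeline
assumes about a nocturnal, twilight-entrained mesocarnivore study:

* tri-axial traces = a slowly drifting gravity vector (so that gravity
  compensation is non-trivial) plus a band-limited dynamic component whose
  amplitude is calibrated so the ODBA module recovers a configured target;
* nightly activity consolidated between civil dusk and dawn, with stage-
  and sex-dependent onset/offset shifts relative to twilight and per-animal
  and per-night random variation;
* fragmented vs consolidated rhythms (intra-night rest gaps; consolidated
  nights during lactation) and bursty in-den "maintenance" movement during
  rest, so the record's activity distribution is realistically bimodal-with-
  overlap rather than an idealized clean square wave;
* a weather series (5-min cadence) with a seasonal temperature cycle,
  diurnal harmonic, wind, monsoon-season rain, and winter snow episodes
  whose depths cross the 8 cm analysis boundary — snow cover at or above
  8 cm suppresses and fragments activity on most such nights;
* the full deployment layout over the four seasonal stages, with no male
  deployments during lactation (study design).

Amplitude calibration uses the closed-form mean absolute deviation of a
Gaussian, ``E|N(0, s)| = s * sqrt(2/pi)``, combined with the exact variance
of an AR(1) sample about its centered running-window mean, so the realized
active-state ODBA matches the configured target without empirical tuning.

Every artifact is a pure function of (config, seed).
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .core import AccelTrace, ValidationError
from .odba import OdbaConfig
from .twilight import FLAGSTAFF, Site, twilight_table

GRAVITY_G = 1.0

#: Deployment windows of the four seasonal stages.
DEFAULT_STAGES: dict[str, tuple[str, str]] = {
    "winter": ("2015-11-13", "2015-12-30"),
    "mating": ("2016-02-29", "2016-03-22"),
    "lactation": ("2016-06-26", "2016-07-26"),
    "fattening": ("2016-08-18", "2016-09-18"),
}

#: True activity-timing rules, minutes relative to twilight
#: (onset vs civil dusk, offset vs civil dawn; positive = after).
DEFAULT_TIMING: dict[tuple[str, str], tuple[float, float]] = {
    ("female", "winter"): (51.0, -90.0),
    ("female", "mating"): (29.0, -31.0),
    ("female", "lactation"): (-58.0, 75.0),
    ("female", "fattening"): (-33.0, 16.0),
    ("male", "winter"): (-9.0, -100.0),
    ("male", "mating"): (4.5, 34.0),
    ("male", "fattening"): (-15.5, -17.0),
}

#: Mean active-state per-sample ODBA targets (g) by sex and stage.
DEFAULT_INTENSITY: dict[tuple[str, str], float] = {
    ("female", "winter"): 0.12,
    ("female", "mating"): 0.19,
    ("female", "lactation"): 0.45,
    ("female", "fattening"): 0.22,
    ("male", "winter"): 0.18,
    ("male", "mating"): 0.38,
    ("male", "fattening"): 0.16,
}

#: Probability a night's bout is fragmented by intra-night rest gaps.
DEFAULT_FRAGMENTATION: dict[tuple[str, str], float] = {
    ("female", "winter"): 0.45,
    ("female", "mating"): 0.40,
    ("female", "lactation"): 0.05,
    ("female", "fattening"): 0.15,
    ("male", "winter"): 0.50,
    ("male", "mating"): 0.40,
    ("male", "fattening"): 0.35,
}

DEFAULT_ANIMALS: tuple[tuple[str, str], ...] = (
    ("F01", "female"),
    ("F02", "female"),
    ("F03", "female"),
    ("F04", "female"),
    ("M01", "male"),
    ("M02", "male"),
    ("M03", "male"),
    ("M04", "male"),
)


@dataclasses.dataclass
class SimConfig:
    """Study-generator configuration; defaults are the desk-scale study.

    Timing SDs are in minutes; ``onset_jitter_sd_min`` is the per-night
    deviation of the true onset around its stage/sex rule and
    ``individual_timing_sd_min`` the per-animal chronotype offset.
    ``rest_odba_g`` is the quiescent per-sample ODBA target and the rest
    bursts model in-den maintenance movement (posture shifts, grooming).
    """

    site: Site = FLAGSTAFF
    animals: tuple[tuple[str, str], ...] = DEFAULT_ANIMALS
    stages: Mapping[str, tuple[str, str]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_STAGES)
    )
    days_per_stage: Optional[int] = 21
    rate_hz: float = 1.0
    timing_rules: Mapping[tuple[str, str], tuple[float, float]] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_TIMING)
    )
    intensity: Mapping[tuple[str, str], float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_INTENSITY)
    )
    fragmentation: Mapping[tuple[str, str], float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_FRAGMENTATION)
    )
    onset_jitter_sd_min: float = 20.0
    individual_timing_sd_min: float = 11.0
    daily_intensity_cv: float = 0.15
    individual_intensity_cv: float = 0.10
    rest_odba_g: float = 0.02
    rest_burst_rate_per_h: float = 2.5
    rest_burst_mean_min: float = 4.0
    rest_burst_amp_frac: float = 0.45
    frag_gap_rate_per_h: float = 1.2
    frag_gap_mean_min: float = 25.0
    bout_ramp_min: float = 15.0
    noise_corr_time_s: float = 0.12
    gravity_drift_rad_per_h: float = 0.15
    snow_storm_interval_days: float = 9.0
    snow_depth_range_cm: tuple[float, float] = (3.0, 25.0)
    snow_melt_cm_per_day: float = 1.5
    snow_suppress_prob: float = 0.85
    snow_intensity_factor: float = 0.25
    weather_noise_sd_c: float = 2.0
    wind_mean_ms: float = 3.0
    wind_noise_sd_ms: float = 1.5
    rain_day_prob_monsoon: float = 0.45
    rain_day_prob_other: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for (sex, stage), p in self.fragmentation.items():
            if not 0 <= p <= 1:
                raise ValidationError(f"fragmentation prob out of [0,1] for {(sex, stage)}")
        windows = sorted(
            (pd.Timestamp(a), pd.Timestamp(b)) for a, b in self.stages.values()
        )
        for (a1, b1), (a2, b2) in zip(windows, windows[1:]):
            if a2 <= b1:
                raise ValidationError("stage date ranges must not overlap")

    def stage_dates(self, stage: str) -> pd.DatetimeIndex:
        start, end = self.stages[stage]
        dates = pd.date_range(pd.Timestamp(start), pd.Timestamp(end))
        if self.days_per_stage is not None:
            dates = dates[: self.days_per_stage]
        return dates


# ---------------------------------------------------------------------------
# amplitude calibration


def ar1_residual_sd_factor(phi: float, window_samples: int) -> float:
    """SD of ``x_i - centered-window-mean`` for unit-variance AR(1) noise.

    Exact from the AR(1) autocovariance; this is the factor by which the
    running-mean gravity compensation shrinks the dynamic component, and
    hence what the amplitude calibration must divide out.
    """
    w = window_samples
    half = w // 2
    lags = np.arange(-half, half + 1)
    rho = phi ** np.abs(lags)
    cross = rho.sum() / w
    grid = phi ** np.abs(lags[:, None] - lags[None, :])
    within = grid.sum() / (w * w)
    var = 1.0 - 2.0 * cross + within
    return math.sqrt(max(var, 0.0))


def axis_noise_sd(target_odba_g: float, phi: float, window_samples: int) -> float:
    """Per-axis AR(1) stationary SD so expected ODBA equals the target.

    ODBA sums |residual| over three axes and ``E|N(0,s)| = s sqrt(2/pi)``,
    so ``target = 3 * sigma * f * sqrt(2/pi)`` with f the window factor.
    """
    f = ar1_residual_sd_factor(phi, window_samples)
    return target_odba_g / (3.0 * math.sqrt(2.0 / math.pi) * f)


def _unit_ar1(n: int, phi: float, rng: np.random.Generator) -> np.ndarray:
    eps = rng.standard_normal(n)
    if phi == 0.0:
        return eps
    innov_sd = math.sqrt(1.0 - phi * phi)
    out = _signal.lfilter([1.0], [1.0, -phi], eps * innov_sd)
    # discard transient bias at the start by rescaling the first samples
    out[0] = eps[0]
    return out


def _gravity(times_h: np.ndarray, rng: np.random.Generator, drift_rad_per_h: float):
    """Slowly drifting unit gravity vector (orientation random walk)."""
    knots_h = np.arange(0.0, times_h[-1] + 1.0, 1.0) if len(times_h) else np.array([0.0])
    theta = 0.4 + np.cumsum(rng.standard_normal(len(knots_h))) * drift_rad_per_h
    phi_ang = np.cumsum(rng.standard_normal(len(knots_h))) * drift_rad_per_h
    th = np.interp(times_h, knots_h, theta)
    ph = np.interp(times_h, knots_h, phi_ang)
    return (
        GRAVITY_G * np.sin(th) * np.cos(ph),
        GRAVITY_G * np.sin(th) * np.sin(ph),
        GRAVITY_G * np.cos(th),
    )


# ---------------------------------------------------------------------------
# trace simulation


def _apply_bout(
    target: np.ndarray,
    times_ns: np.ndarray,
    onset: pd.Timestamp,
    offset: pd.Timestamp,
    intensity: float,
    rest: float,
    ramp_min: float,
    rate_hz: float,
) -> None:
    """Write one activity bout into ``target`` with linear edge ramps.

    Activity builds from the resting level to full intensity over
    ``ramp_min`` minutes after the true onset (den emergence, initial
    grooming) and decays symmetrically before the true offset, so bouts
    are trapezoids rather than idealized square pulses.
    """
    i0 = int(np.searchsorted(times_ns, onset.value))
    i1 = int(np.searchsorted(times_ns, offset.value))
    if i1 <= i0:
        return
    target[i0:i1] = intensity
    ramp = min(int(ramp_min * 60 * rate_hz), (i1 - i0) // 2)
    if ramp > 1:
        target[i0 : i0 + ramp] = np.linspace(rest, intensity, ramp)
        target[i1 - ramp : i1] = np.linspace(intensity, rest, ramp)


def _poisson_intervals(
    span_start: pd.Timestamp,
    span_end: pd.Timestamp,
    rate_per_h: float,
    mean_min: float,
    rng: np.random.Generator,
) -> list[tuple[pd.Timestamp, pd.Timestamp]]:
    hours = (span_end - span_start).total_seconds() / 3600.0
    if hours <= 0:
        return []
    n = rng.poisson(rate_per_h * hours)
    out = []
    for _ in range(n):
        start = span_start + pd.Timedelta(hours=float(rng.uniform(0, hours)))
        dur = pd.Timedelta(minutes=float(rng.exponential(mean_min)))
        out.append((start, min(start + dur, span_end)))
    return out


def simulate_trace(
    config: SimConfig,
    animal_id: str,
    sex: str,
    dates: pd.DatetimeIndex,
    stage: str,
    rng: np.random.Generator,
    snow_by_date: Optional[Mapping[pd.Timestamp, float]] = None,
) -> tuple[AccelTrace, pd.DataFrame]:
    """One animal-deployment trace plus its ground-truth night schedule.

    ``dates`` are the night dates (noon boundaries); the trace spans noon
    of the first date to noon after the last.  Returns the trace and a
    truth table with one row per night: true onset/offset, intensity,
    fragmentation and snow-suppression indicators.
    """
    if len(dates) == 0:
        raise ValidationError("empty date range")
    key = (sex, stage)
    if key not in config.timing_rules:
        raise ValidationError(f"no timing rule for {key} (study design)")
    onset_rule, offset_rule = config.timing_rules[key]
    base_intensity = config.intensity[key]
    frag_prob = config.fragmentation[key]

    twi = twilight_table(
        config.site, dates[0], dates[-1] + pd.Timedelta(days=1)
    )

    rate = config.rate_hz
    start = dates[0] + pd.Timedelta(hours=12)
    n = int(round(len(dates) * 86400 * rate))
    step_ns = int(round(1e9 / rate))
    times_ns = start.value + np.arange(n, dtype=np.int64) * step_ns

    ind_timing = rng.normal(0.0, config.individual_timing_sd_min)
    ind_intensity = math.exp(
        rng.normal(0.0, config.individual_intensity_cv)
        - 0.5 * config.individual_intensity_cv**2
    )

    # Target per-sample ODBA for every sample, built night by night.
    target = np.full(n, config.rest_odba_g)
    truth_rows = []
    for night_date in dates:
        dusk = twi.dusk(night_date)
        dawn = twi.dawn(night_date + pd.Timedelta(days=1))
        onset = dusk + pd.Timedelta(
            minutes=onset_rule + ind_timing + rng.normal(0, config.onset_jitter_sd_min)
        )
        offset = dawn + pd.Timedelta(
            minutes=offset_rule + ind_timing + rng.normal(0, config.onset_jitter_sd_min)
        )
        night_start = night_date + pd.Timedelta(hours=12)
        night_end = night_start + pd.Timedelta(days=1)
        onset = max(onset, night_start + pd.Timedelta(hours=1))
        offset = min(offset, night_end - pd.Timedelta(hours=1))
        if offset <= onset:
            offset = onset + pd.Timedelta(hours=4)

        snow_cm = np.nan
        if snow_by_date is not None:
            snow_cm = float(snow_by_date.get(night_date.normalize(), np.nan))
        suppressed = (
            np.isfinite(snow_cm)
            and snow_cm >= 8.0
            and rng.uniform() < config.snow_suppress_prob
        )
        night_intensity = (
            base_intensity
            * ind_intensity
            * math.exp(
                rng.normal(0.0, config.daily_intensity_cv)
                - 0.5 * config.daily_intensity_cv**2
            )
        )
        gap_rate = config.frag_gap_rate_per_h
        gap_mean = config.frag_gap_mean_min
        fragmented = rng.uniform() < frag_prob
        if suppressed:
            night_intensity *= config.snow_intensity_factor
            fragmented = True
            gap_rate *= 4.0
            gap_mean *= 2.0

        _apply_bout(
            target, times_ns, onset, offset, night_intensity,
            config.rest_odba_g, config.bout_ramp_min, rate,
        )
        if fragmented:
            for g0, g1 in _poisson_intervals(onset, offset, gap_rate, gap_mean, rng):
                j0 = int(np.searchsorted(times_ns, g0.value))
                j1 = int(np.searchsorted(times_ns, g1.value))
                target[j0:j1] = config.rest_odba_g
        # In-den maintenance bursts during the rest spans of this night.
        for span in ((night_start, onset), (offset, night_end)):
            for b0, b1 in _poisson_intervals(
                span[0], span[1], config.rest_burst_rate_per_h,
                config.rest_burst_mean_min, rng,
            ):
                j0 = int(np.searchsorted(times_ns, b0.value))
                j1 = int(np.searchsorted(times_ns, b1.value))
                amp = (
                    config.rest_burst_amp_frac
                    * base_intensity
                    * math.exp(rng.normal(0.0, 0.4))
                )
                target[j0:j1] = np.maximum(target[j0:j1], amp)
        truth_rows.append(
            {
                "animal_id": animal_id,
                "sex": sex,
                "stage": stage,
                "night_date": night_date.normalize(),
                "true_onset": onset,
                "true_offset": offset,
                "intensity_g": night_intensity,
                "fragmented": bool(fragmented),
                "snow_suppressed": bool(suppressed),
                "snow_cm": snow_cm,
            }
        )

    phi = math.exp(-1.0 / (rate * config.noise_corr_time_s))
    window = OdbaConfig().window_samples(rate)
    sd_scale = axis_noise_sd(1.0, phi, window)  # per unit target
    sigma = target * sd_scale

    times_h = (times_ns - times_ns[0]) / 3.6e12
    gx, gy, gz = _gravity(times_h, rng, config.gravity_drift_rad_per_h)
    x = gx + _unit_ar1(n, phi, rng) * sigma
    y = gy + _unit_ar1(n, phi, rng) * sigma
    z = gz + _unit_ar1(n, phi, rng) * sigma

    trace = AccelTrace(
        animal_id=animal_id, sex=sex, start=start, rate_hz=rate, x=x, y=y, z=z
    )
    return trace, pd.DataFrame(truth_rows)


def simulate_detection_nights(
    n_nights: int,
    rng: np.random.Generator,
    config: SimConfig | None = None,
    onset_clock_range: tuple[float, float] = (17.0, 21.0),
    offset_clock_range: tuple[float, float] = (3.0, 7.0),
    intensity_g: float = 0.30,
) -> tuple[AccelTrace, pd.DataFrame]:
    """Detector-recovery harness: nights with clock-uniform true events.

    True onsets are uniform in ``onset_clock_range`` (hours, evening of the
    night date) and offsets uniform in ``offset_clock_range`` (next
    morning).  Bouts are consolidated (no fragmentation), on top of the
    generator's usual rest background, so recovery error reflects the
    detector, not scheduling ambiguity.
    """
    config = config or SimConfig()
    rate = config.rate_hz
    start = pd.Timestamp("2016-01-01 12:00")
    n = int(round(n_nights * 86400 * rate))
    step_ns = int(round(1e9 / rate))
    times_ns = start.value + np.arange(n, dtype=np.int64) * step_ns

    target = np.full(n, config.rest_odba_g)
    rows = []
    for k in range(n_nights):
        night_date = (start + pd.Timedelta(days=k)).normalize()
        onset = night_date + pd.Timedelta(hours=float(rng.uniform(*onset_clock_range)))
        offset = (
            night_date
            + pd.Timedelta(days=1)
            + pd.Timedelta(hours=float(rng.uniform(*offset_clock_range)))
        )
        _apply_bout(
            target, times_ns, onset, offset, intensity_g,
            config.rest_odba_g, config.bout_ramp_min, rate,
        )
        night_start = night_date + pd.Timedelta(hours=12)
        for span in ((night_start, onset), (offset, night_start + pd.Timedelta(days=1))):
            for b0, b1 in _poisson_intervals(
                span[0], span[1], config.rest_burst_rate_per_h,
                config.rest_burst_mean_min, rng,
            ):
                j0 = int(np.searchsorted(times_ns, b0.value))
                j1 = int(np.searchsorted(times_ns, b1.value))
                amp = config.rest_burst_amp_frac * intensity_g * math.exp(
                    rng.normal(0.0, 0.4)
                )
                target[j0:j1] = np.maximum(target[j0:j1], amp)
        rows.append(
            {"night_date": night_date, "true_onset": onset, "true_offset": offset}
        )

    phi = math.exp(-1.0 / (rate * config.noise_corr_time_s))
    window = OdbaConfig().window_samples(rate)
    sigma = target * axis_noise_sd(1.0, phi, window)
    times_h = (times_ns - times_ns[0]) / 3.6e12
    gx, gy, gz = _gravity(times_h, rng, config.gravity_drift_rad_per_h)
    trace = AccelTrace(
        animal_id="SIM",
        sex="female",
        start=start,
        rate_hz=rate,
        x=gx + _unit_ar1(n, phi, rng) * sigma,
        y=gy + _unit_ar1(n, phi, rng) * sigma,
        z=gz + _unit_ar1(n, phi, rng) * sigma,
    )
    return trace, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# weather simulation


def simulate_weather(
    config: SimConfig,
    start,
    end,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """5-min weather series over [start, end] inclusive of the last day.

    Temperature = seasonal sinusoid (coldest mid-January) + afternoon-peak
    diurnal harmonic + AR noise; wind is a truncated AR series around
    ``wind_mean_ms``; rain falls on random monsoon-season days in short
    afternoon events; winter snow storms arrive as a Poisson process with
    uniform depths across the 8 cm boundary, then melt linearly.
    """
    start = pd.Timestamp(start).normalize()
    end = pd.Timestamp(end).normalize() + pd.Timedelta(days=1) - CADENCE
    idx = pd.date_range(start, end, freq=CADENCE)
    doy = idx.dayofyear.to_numpy()
    hour = idx.hour.to_numpy() + idx.minute.to_numpy() / 60.0

    seasonal = 9.5 - 9.5 * np.cos(2 * np.pi * (doy - 15) / 365.25)
    diurnal = 5.5 * np.cos(2 * np.pi * (hour - 15.0) / 24.0)
    temp_noise = (
        _unit_ar1(len(idx), 0.97, rng) * config.weather_noise_sd_c
        if config.weather_noise_sd_c > 0
        else 0.0
    )
    temp = seasonal + diurnal + temp_noise

    wind_noise = (
        _unit_ar1(len(idx), 0.95, rng) * config.wind_noise_sd_ms
        if config.wind_noise_sd_ms > 0
        else 0.0
    )
    wind = np.maximum(config.wind_mean_ms + wind_noise, 0.0)

    precip = np.zeros(len(idx))
    days = pd.date_range(start.normalize(), end.normalize())
    for day in days:
        monsoon = day.month in (7, 8, 9)
        p = config.rain_day_prob_monsoon if monsoon else config.rain_day_prob_other
        if rng.uniform() < p:
            t0 = day + pd.Timedelta(hours=float(rng.uniform(12, 20)))
            dur = pd.Timedelta(hours=float(rng.uniform(0.5, 3.0)))
            total_mm = float(rng.gamma(2.0, 3.0))
            mask = (idx >= t0) & (idx < t0 + dur)
            if mask.any():
                precip[mask] = total_mm / mask.sum()

    snow_daily = {}
    storms = []
    for day in days:
        if day.month in (11, 12, 1, 2, 3):
            if rng.uniform() < 1.0 / config.snow_storm_interval_days:
                depth = float(rng.uniform(*config.snow_depth_range_cm))
                storms.append((day, depth))
        depth_today = 0.0
        for d0, depth in storms:
            age = (day - d0).days
            if age >= 0:
                depth_today += max(depth - config.snow_melt_cm_per_day * age, 0.0)
        snow_daily[day] = depth_today
    snow = np.array([snow_daily[d] for d in idx.normalize()])

    return pd.DataFrame(
        {"temp_c": temp, "wind_ms": wind, "precip_mm": precip, "snow_cm": snow},
        index=idx,
    )


CADENCE = pd.Timedelta(minutes=5)


# ---------------------------------------------------------------------------
# full study


@dataclasses.dataclass
class StudyBundle:
    """Everything a pipeline run consumes, plus the generating truth."""

    config: SimConfig
    traces: list[AccelTrace]
    deployments: pd.DataFrame  # animal_id, sex, stage, start, n_days
    truth: pd.DataFrame
    weather: pd.DataFrame
    twilight: object  # core.TwilightTable


def simulate_study(config: SimConfig | None = None) -> StudyBundle:
    """Simulate the full deployment layout.

    Honors the study structure: every animal is deployed in every stage
    except that males are absent from the lactation stage.  Deterministic:
    identical (config, seed) reproduces the bundle bit-for-bit.
    """
    config = config or SimConfig()
    seed_seq = np.random.SeedSequence(config.seed)
    weather_rng, *animal_seqs = [
        np.random.default_rng(s) for s in seed_seq.spawn(1 + len(config.animals))
    ]

    all_dates = []
    for stage in config.stages:
        all_dates.append(config.stage_dates(stage))
    span_start = min(d[0] for d in all_dates)
    span_end = max(d[-1] for d in all_dates) + pd.Timedelta(days=1)

    weather = simulate_weather(config, span_start, span_end, weather_rng)
    snow_by_date = (
        weather["snow_cm"].groupby(weather.index.normalize()).first().to_dict()
    )
    twi = twilight_table(config.site, span_start, span_end + pd.Timedelta(days=1))

    traces: list[AccelTrace] = []
    truth_frames = []
    deployments = []
    for (animal_id, sex), rng in zip(config.animals, animal_seqs):
        for stage in config.stages:
            if stage == "lactation" and sex == "male":
                continue
            dates = config.stage_dates(stage)
            trace, truth = simulate_trace(
                config, animal_id, sex, dates, stage, rng, snow_by_date
            )
            traces.append(trace)
            truth_frames.append(truth)
            deployments.append(
                {
                    "animal_id": animal_id,
                    "sex": sex,
                    "stage": stage,
                    "start": trace.start,
                    "n_days": len(dates),
                }
            )
    return StudyBundle(
        config=config,
        traces=traces,
        deployments=pd.DataFrame(deployments),
        truth=pd.concat(truth_frames, ignore_index=True),
        weather=weather,
        twilight=twi,
    )


# ---------------------------------------------------------------------------
# day-level generator for mixed-model recovery


DEFAULT_STAGE_EFFECTS = {
    "winter": 0.0,
    "mating": 0.028,
    "lactation": 0.15,
    "fattening": 0.04,
}


def simulate_day_records(
    rng: np.random.Generator,
    n_animals: int = 20,
    n_days: int = 120,
    baseline: float = 0.10,
    stage_effects: Mapping[str, float] = None,
    sd_individual: float = 0.032,
    sd_day: float = 0.010,
    sd_resid: float = 0.032,
) -> pd.DataFrame:
    """Day-level records from the exact generative model the LMM assumes.

    ``mean_daily_odba = baseline + stage effect + individual intercept +
    day-of-year intercept + Gaussian residual``; days are split into four
    consecutive stage blocks.  Effect magnitudes default to the scale of a
    female annual-cycle stage model (lactation-winter contrast 0.15 g).
    Used for parameter-recovery and coverage checks.
    """
    stage_effects = dict(stage_effects or DEFAULT_STAGE_EFFECTS)
    stages = list(stage_effects)
    block = n_days // len(stages)
    dates = pd.date_range("2016-01-01", periods=n_days)
    a = rng.normal(0.0, sd_individual, n_animals)
    d = rng.normal(0.0, sd_day, n_days)
    rows = []
    for i in range(n_animals):
        for t in range(n_days):
            stage = stages[min(t // block, len(stages) - 1)]
            rows.append(
                {
                    "animal_id": f"A{i:02d}",
                    "date": dates[t],
                    "day_of_year": int(dates[t].dayofyear),
                    "sex": "female",
                    "stage": stage,
                    "mean_daily_odba": baseline
                    + stage_effects[stage]
                    + a[i]
                    + d[t]
                    + rng.normal(0.0, sd_resid),
                }
            )
    return pd.DataFrame(rows)
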