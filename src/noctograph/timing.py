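"""Activity onset/offset detection, plausibility filters, and actograms.

The detector re-creates the classic chronobiology onset/offset procedure:
per-sample ODBA is averaged into short clock bins, smoothed with a Gaussian
kernel (SD 5 min by default), and compared against a threshold equal to the
median of the animal's whole smoothed deployment record.  Within each
noon-to-noon night, the activity onset is the first upward threshold
crossing that stays above threshold for a sustained period, and the offset
is the last downward crossing preceded by a sustained above-threshold run.
The sustained-run requirement (default 30 min) makes the procedure's known
failure mode on low or ultradian (fragmented, sub-daily) activity explicit:
such nights simply yield no detection, which is reported as a flag, never
an error.

Two plausibility filters mirror standard practice for a nocturnal species:
onsets must fall between 15:00 and 23:00 and offsets between 01:00 and
09:00 local clock time; out-of-window candidates are flagged and dropped.
Days with snow cover at or above 8 cm are excluded from timing analyses
(they remain usable for activity-level analyses).

Relative timing follows the convention that positive values mean the event
occurred *after* its reference twilight (onset vs civil dusk, offset vs
civil dawn).
"""

from __future__ import annotations

import dataclasses
import datetime as dt
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    DAY_BOUNDARY,
    FLAG_LOW_COVERAGE,
    FLAG_NO_DETECTION,
    FLAG_OFFSET_OUT_OF_WINDOW,
    FLAG_ONSET_OUT_OF_WINDOW,
    FLAG_SNOW_EXCLUDED,
    FLAG_SNOW_UNRESOLVED,
    ActivityDay,
    OdbaSeries,
    TwilightTable,
    ValidationError,
    night_of,
)

#: Kernel support half-width in standard deviations.
KERNEL_TRUNCATION_SD = 4.0


@dataclasses.dataclass
class DetectorConfig:
    """Detector parameters.

    kernel_sd_min
        Gaussian smoothing SD in minutes (default 5).
    threshold_rule
        ``"median_of_record"``: threshold is the median of the animal's
        whole smoothed deployment record (the stable choice; per-night
        medians are available via ``"median_of_night"``).
    onset_window / offset_window
        Inclusive clock intervals of plausible detections.
    min_sustained_min
        Minutes a crossing must stay above threshold to qualify.
    hysteresis_frac
        Fraction of the (active level - threshold) span used as the
        near-threshold anchor when refining crossings within the principal
        run; guards against brief pre/post-bout movement that merges with
        the main bout into one above-threshold run.
    """

    kernel_sd_min: float = 5.0
    threshold_rule: str = "median_of_record"
    onset_window: tuple[dt.time, dt.time] = (dt.time(15, 0), dt.time(23, 0))
    offset_window: tuple[dt.time, dt.time] = (dt.time(1, 0), dt.time(9, 0))
    min_sustained_min: float = 30.0
    bin_min: int = 1
    min_night_coverage: float = 0.8
    day_boundary: dt.time = DAY_BOUNDARY
    hysteresis_frac: float = 0.15

    def __post_init__(self) -> None:
        if self.kernel_sd_min <= 0:
            raise ValidationError("kernel_sd_min must be positive")
        if self.threshold_rule not in ("median_of_record", "median_of_night"):
            raise ValidationError(f"unknown threshold rule {self.threshold_rule!r}")
        if 60 % self.bin_min != 0:
            raise ValidationError("bin_min must divide 60")


@dataclasses.dataclass
class DetectionResult:
    onset: Optional[pd.Timestamp]
    offset: Optional[pd.Timestamp]
    flags: frozenset


@dataclasses.dataclass
class ActogramMatrix:
    """Raster of mean ODBA: one row per noon-to-noon day, columns are
    time-of-day bins.  In a 48 h double plot the right half of row i equals
    the left half of row i+1 exactly (the final row's right half is NaN-
    padded).  Missing bins are NaN, distinct from zero activity."""

    night_dates: pd.DatetimeIndex
    bin_min: int
    values: np.ndarray
    double_plot: bool


def binned_activity(series: OdbaSeries, bin_min: int = 1) -> pd.Series:
    """Mean per-sample ODBA per clock bin; empty bins are NaN (missing)."""
    if 60 % bin_min != 0:
        raise ValidationError("bin_min must divide 60")
    s = series.as_series()
    binned = s.resample(f"{bin_min}min").mean()
    binned.name = "activity"
    return binned


def gaussian_kernel(sd_bins: float) -> np.ndarray:
    half = int(np.ceil(KERNEL_TRUNCATION_SD * sd_bins))
    k = np.exp(-0.5 * (np.arange(-half, half + 1) / sd_bins) ** 2)
    return k / k.sum()


def smooth_gaussian(activity: pd.Series, sd_min: float = 5.0) -> pd.Series:
    """Gaussian smoothing truncated at +/-4 SD, renormalized over the
    non-missing weights.  Bins that are missing in the input stay missing."""
    if sd_min <= 0:
        raise ValidationError("sd_min must be positive")
    values = activity.to_numpy(dtype=float)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValidationError("cannot smooth an all-missing record")
    step_min = (activity.index[1] - activity.index[0]).total_seconds() / 60.0 if len(activity) > 1 else 1.0
    kernel = gaussian_kernel(sd_min / step_min)
    num = np.convolve(np.where(finite, values, 0.0), kernel, mode="same")
    den = np.convolve(finite.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = np.where(den > 0, num / den, np.nan)
    smoothed[~finite] = np.nan
    return pd.Series(smoothed, index=activity.index, name="smoothed")


def record_threshold(smoothed: pd.Series, rule: str = "median_of_record") -> float:
    """Detection threshold: the median of the smoothed record."""
    values = smoothed.to_numpy(dtype=float)
    if not np.isfinite(values).any():
        raise ValidationError("threshold of an all-missing record")
    return float(np.nanmedian(values))


def _in_window(ts: pd.Timestamp, window: tuple[dt.time, dt.time]) -> bool:
    t = ts.time()
    lo, hi = window
    return lo <= t <= hi


def _runs_above(above: np.ndarray) -> list[tuple[int, int]]:
    """(start, stop) index pairs of maximal runs of True; stop exclusive."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], above, [False])).astype(int)))
    return list(zip(idx[::2], idx[1::2]))


def detect_onset_offset(
    smoothed_night: pd.Series,
    threshold: float,
    config: DetectorConfig | None = None,
) -> DetectionResult:
    """Detect onset and offset within one noon-to-noon night.

    The night's *principal bout* is the longest above-threshold run
    lasting at least ``min_sustained_min`` (ties: the earliest run).  The
    onset candidate is the upward crossing opening that run and the offset
    candidate the downward crossing closing it, refined by hysteresis (see
    ``DetectorConfig.hysteresis_frac``): the bout is confirmed at the
    midpoint between the threshold and the run's median level, and the
    reported crossing is the nearest near-threshold bin before/after
    confirmation.  Anchoring events to the principal run — rather than to
    the first/last qualifying crossing of the night — keeps brief in-den
    movement bouts during the rest phase from masquerading as activity
    onset or offset.  Candidates outside the plausibility windows are
    flagged and withheld; a night with no qualifying run is flagged
    ``no_detection``.
    """
    config = config or DetectorConfig()
    values = smoothed_night.to_numpy(dtype=float)
    finite = np.isfinite(values)
    n = len(values)
    flags: set[str] = set()
    if n == 0 or finite.mean() < config.min_night_coverage:
        return DetectionResult(None, None, frozenset({FLAG_LOW_COVERAGE, FLAG_NO_DETECTION}))
    step_min = (
        (smoothed_night.index[1] - smoothed_night.index[0]).total_seconds() / 60.0
        if n > 1
        else 1.0
    )
    min_bins = int(np.ceil(config.min_sustained_min / step_min))
    above = finite & (values > threshold)
    runs = [(s, e) for (s, e) in _runs_above(above) if e - s >= min_bins]

    onset = offset = None
    if not runs:
        flags.add(FLAG_NO_DETECTION)
        return DetectionResult(None, None, frozenset(flags))
    # Principal bout: longest qualifying run; earliest wins a tie.
    main = max(runs, key=lambda r: r[1] - r[0])

    # Hysteresis refinement within the principal run.  Brief movement just
    # before (or after) the bout can merge with it into one above-threshold
    # run, pulling the run-edge crossing away from the bout proper.  The
    # bout is confirmed where the signal reaches the midpoint between the
    # threshold and the run's typical active level; the reported crossing
    # is then the nearest near-threshold bin before/after confirmation.
    # A clean bout rises monotonically through both marks, so this leaves
    # unmerged nights essentially unchanged.
    run_vals = values[main[0] : main[1]]
    active = float(np.median(run_vals))
    confirm = threshold + 0.5 * (active - threshold)
    low_mark = threshold + config.hysteresis_frac * (active - threshold)

    # A run touching the first bin has no upward crossing inside the night;
    # one touching the last bin has no downward crossing.
    if main[0] > 0:
        conf_rel = np.flatnonzero(run_vals >= confirm)
        onset_idx = main[0]
        if conf_rel.size:
            lead = values[main[0] : main[0] + conf_rel[0] + 1]
            below = np.flatnonzero(lead <= low_mark)
            if below.size:
                onset_idx = main[0] + int(below[-1])
        cand = smoothed_night.index[onset_idx]
        if _in_window(cand, config.onset_window):
            onset = cand
        else:
            flags.add(FLAG_ONSET_OUT_OF_WINDOW)
    if main[1] < n:
        conf_rel = np.flatnonzero(run_vals >= confirm)
        # Default crossing time = first bin below threshold after the run.
        offset_idx = main[1]
        if conf_rel.size:
            tail = values[main[0] + conf_rel[-1] : main[1] + 1]
            below = np.flatnonzero(tail <= low_mark)
            if below.size:
                offset_idx = main[0] + int(conf_rel[-1]) + int(below[0])
        cand = smoothed_night.index[offset_idx]
        if _in_window(cand, config.offset_window):
            offset = cand
        else:
            flags.add(FLAG_OFFSET_OUT_OF_WINDOW)
    if onset is None and offset is None and not flags:
        flags.add(FLAG_NO_DETECTION)
    return DetectionResult(onset, offset, frozenset(flags))


def bout_duration(onset: pd.Timestamp, offset: pd.Timestamp) -> float:
    """Offset minus onset in decimal hours, spanning midnight correctly."""
    if onset is None or offset is None:
        raise ValidationError("bout duration requires both onset and offset")
    delta_h = (pd.Timestamp(offset) - pd.Timestamp(onset)).total_seconds() / 3600.0
    if delta_h <= 0:
        raise ValidationError(f"offset {offset} does not follow onset {onset}")
    return delta_h


def relative_to_twilight(event: pd.Timestamp, twilight: pd.Timestamp) -> float:
    """Signed minutes; positive when the event occurs after its twilight."""
    return (pd.Timestamp(event) - pd.Timestamp(twilight)).total_seconds() / 60.0


def activity_days(
    series: OdbaSeries,
    twilight: TwilightTable,
    config: DetectorConfig | None = None,
) -> list[ActivityDay]:
    """Run the detector over a whole deployment, night by night.

    Bins and smooths the full record, takes the record-level threshold,
    then detects per noon-to-noon night and derives bout durations and
    twilight-relative times.  Onset is referenced to the night date's civil
    dusk, offset to the following date's civil dawn.
    """
    config = config or DetectorConfig()
    binned = binned_activity(series, config.bin_min)
    smoothed = smooth_gaussian(binned, config.kernel_sd_min)
    if config.threshold_rule == "median_of_record":
        threshold = record_threshold(smoothed)
    nights = night_of(smoothed.index, config.day_boundary)
    out: list[ActivityDay] = []
    for night_date in nights.unique().sort_values():
        night = smoothed[nights == night_date]
        if config.threshold_rule == "median_of_night":
            vals = night.to_numpy(dtype=float)
            if not np.isfinite(vals).any():
                out.append(
                    ActivityDay(
                        animal_id=series.animal_id,
                        night_date=night_date,
                        flags={FLAG_LOW_COVERAGE, FLAG_NO_DETECTION},
                    )
                )
                continue
            threshold = float(np.nanmedian(vals))
        det = detect_onset_offset(night, threshold, config)
        duration = None
        onset_rel = offset_rel = None
        if det.onset is not None:
            try:
                onset_rel = relative_to_twilight(det.onset, twilight.dusk(night_date))
            except KeyError:
                pass
        if det.offset is not None:
            try:
                offset_rel = relative_to_twilight(
                    det.offset, twilight.dawn(night_date + pd.Timedelta(days=1))
                )
            except KeyError:
                pass
        if det.onset is not None and det.offset is not None and not det.flags:
            duration = bout_duration(det.onset, det.offset)
        out.append(
            ActivityDay(
                animal_id=series.animal_id,
                night_date=night_date,
                onset=det.onset,
                offset=det.offset,
                duration_h=duration,
                onset_rel_dusk_min=onset_rel,
                offset_rel_dawn_min=offset_rel,
                flags=det.flags,
            )
        )
    return out


def exclude_snow_days(
    days: Sequence[ActivityDay],
    snow_by_date: Mapping[pd.Timestamp, float] | pd.Series,
    threshold_cm: float = 8.0,
) -> list[ActivityDay]:
    """Flag and drop nights with snow cover at or above ``threshold_cm``.

    The boundary is inclusive (>= 8 cm).  A night whose snow value is
    missing is excluded conservatively with a ``snow_unresolved`` flag.
    Returns the retained days; use :func:`partition_snow_days` when the
    excluded days are needed for bookkeeping.
    """
    retained, _ = partition_snow_days(days, snow_by_date, threshold_cm)
    return retained


def partition_snow_days(
    days: Sequence[ActivityDay],
    snow_by_date: Mapping[pd.Timestamp, float] | pd.Series,
    threshold_cm: float = 8.0,
) -> tuple[list[ActivityDay], list[ActivityDay]]:
    """(retained, excluded) nights under the snow-cover rule."""
    if isinstance(snow_by_date, pd.Series):
        snow_lookup = {pd.Timestamp(k).normalize(): v for k, v in snow_by_date.items()}
    else:
        snow_lookup = {pd.Timestamp(k).normalize(): v for k, v in snow_by_date.items()}
    retained: list[ActivityDay] = []
    excluded: list[ActivityDay] = []
    for d in days:
        snow = snow_lookup.get(d.night_date, np.nan)
        if not np.isfinite(snow):
            excluded.append(dataclasses.replace(d, flags=d.flags | {FLAG_SNOW_UNRESOLVED}))
        elif snow >= threshold_cm:
            excluded.append(dataclasses.replace(d, flags=d.flags | {FLAG_SNOW_EXCLUDED}))
        else:
            retained.append(d)
    return retained, excluded


def filter_window(days: Sequence[ActivityDay]) -> list[ActivityDay]:
    """Drop nights already flagged by the clock-window plausibility filter."""
    return [
        d
        for d in days
        if not ({FLAG_ONSET_OUT_OF_WINDOW, FLAG_OFFSET_OUT_OF_WINDOW} & d.flags)
    ]


def build_actogram(
    series: OdbaSeries, bin_min: int = 10, double_plot: bool = True
) -> ActogramMatrix:
    """Raster of binned activity, optionally double-plotted over 48 h."""
    binned = binned_activity(series, bin_min)
    nights = night_of(binned.index, DAY_BOUNDARY)
    night_dates = nights.unique().sort_values()
    bins_per_day = 1440 // bin_min
    mat = np.full((len(night_dates), bins_per_day), np.nan)
    boundary = pd.Timedelta(hours=DAY_BOUNDARY.hour, minutes=DAY_BOUNDARY.minute)
    for i, nd in enumerate(night_dates):
        sel = binned[nights == nd]
        cols = (
            ((sel.index - (nd + boundary)).total_seconds() / 60.0) // bin_min
        ).astype(int)
        mat[i, cols] = sel.to_numpy()
    if double_plot:
        right = np.vstack([mat[1:], np.full((1, bins_per_day), np.nan)])
        mat = np.hstack([mat, right])
    return ActogramMatrix(
        night_dates=pd.DatetimeIndex(night_dates),
        bin_min=bin_min,
        values=mat,
        double_plot=double_plot,
    )


def plot_actogram(matrix: ActogramMatrix, path=None, title: str = ""):
    """Render an actogram raster; returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    hours = matrix.values.shape[1] * matrix.bin_min / 60.0
    fig, ax = plt.subplots(figsize=(8, max(2, 0.18 * len(matrix.night_dates))))
    masked = np.ma.masked_invalid(matrix.values)
    cmap = plt.cm.Greys.copy()
    cmap.set_bad("lightsteelblue")
    ax.imshow(
        masked,
        aspect="auto",
        interpolation="nearest",
        cmap=cmap,
        extent=(0, hours, len(matrix.night_dates), 0),
    )
    ax.set_xlabel("hours since local noon")
    ax.set_ylabel("day")
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
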