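import numpy as np
import pandas as pd
import pytest

from noctograph.core import (
    FLAG_LOW_COVERAGE,
    FLAG_NO_DETECTION,
    FLAG_ONSET_OUT_OF_WINDOW,
    FLAG_SNOW_EXCLUDED,
    FLAG_SNOW_UNRESOLVED,
    ActivityDay,
    OdbaSeries,
    ValidationError,
)
from noctograph.timing import (
    DetectorConfig,
    binned_activity,
    bout_duration,
    build_actogram,
    detect_onset_offset,
    exclude_snow_days,
    filter_window,
    partition_snow_days,
    relative_to_twilight,
    smooth_gaussian,
)


def minute_series(values, start="2016-05-01 12:00"):
    idx = pd.date_range(start, periods=len(values), freq="1min")
    return pd.Series(np.asarray(values, dtype=float), index=idx)


def square_night(onset_min, offset_min, rest=0.02, active=0.30, n=1440):
    """One noon-to-noon night of minute bins with a rectangular bout."""
    v = np.full(n, rest)
    v[onset_min:offset_min] = active
    return minute_series(v)


def test_binned_activity_matches_groupby(rng, make_trace):
    from noctograph.odba import compute_odba

    n = 2 * 3600
    series = compute_odba(make_trace(*rng.normal(0, 0.2, (3, n))))
    binned = binned_activity(series, 5)
    s = series.as_series()
    expected = s.groupby(s.index.floor("5min")).mean()
    np.testing.assert_allclose(binned.dropna().to_numpy(), expected.to_numpy(), atol=1e-12)


def test_smoothing_preserves_constant():
    s = minute_series(np.full(600, 0.17))
    out = smooth_gaussian(s, 5.0)
    np.testing.assert_allclose(out.to_numpy(), 0.17, atol=1e-12)


def test_smoothing_impulse_mass_and_symmetry():
    v = np.zeros(601)
    v[300] = 1.0
    out = smooth_gaussian(minute_series(v), 5.0).to_numpy()
    assert out.sum() == pytest.approx(1.0, abs=1e-9)
    np.testing.assert_allclose(out, out[::-1], atol=1e-12)
    assert out.argmax() == 300


def test_smoothing_keeps_missing_missing():
    v = np.full(200, 0.1)
    v[80:90] = np.nan
    out = smooth_gaussian(minute_series(v), 5.0)
    assert out.iloc[80:90].isna().all()
    # renormalization over present bins keeps the level unbiased nearby
    np.testing.assert_allclose(out.iloc[95:105].to_numpy(), 0.1, atol=1e-12)


def test_smoothing_all_missing_raises():
    with pytest.raises(ValidationError):
        smooth_gaussian(minute_series(np.full(50, np.nan)), 5.0)


def test_detect_square_wave_recovers_edges():
    # bout 20:00 -> 04:00 (bins 480..960 of a noon-anchored night)
    night = smooth_gaussian(square_night(480, 960), 5.0)
    det = detect_onset_offset(night, threshold=0.16)
    assert det.flags == frozenset()
    assert abs((det.onset - pd.Timestamp("2016-05-01 20:00")).total_seconds()) <= 300
    assert abs((det.offset - pd.Timestamp("2016-05-02 04:00")).total_seconds()) <= 300


def test_detect_out_of_window_flagged_not_errored():
    # onset 14:30 is before the 15:00 window opens
    night = smooth_gaussian(square_night(150, 960), 5.0)
    det = detect_onset_offset(night, threshold=0.16)
    assert det.onset is None
    assert FLAG_ONSET_OUT_OF_WINDOW in det.flags
    assert det.offset is not None  # offset at 04:00 is still plausible


def test_detect_nothing_above_threshold():
    night = smooth_gaussian(square_night(480, 960, active=0.02), 5.0)
    det = detect_onset_offset(night, threshold=0.16)
    assert det.onset is None and det.offset is None
    assert FLAG_NO_DETECTION in det.flags


def test_detect_short_bursts_do_not_qualify():
    v = np.full(1440, 0.02)
    v[600:615] = 0.5  # 15 min < the 30-min sustained requirement
    det = detect_onset_offset(smooth_gaussian(minute_series(v), 5.0), 0.16)
    assert FLAG_NO_DETECTION in det.flags


def test_detect_principal_run_ignores_stray_rest_burst():
    v = np.full(1440, 0.02)
    v[120:160] = 0.5  # 40-min in-den burst at 14:00, before the real bout
    v[480:960] = 0.30
    det = detect_onset_offset(smooth_gaussian(minute_series(v), 5.0), 0.16)
    assert det.onset is not None
    assert abs((det.onset - pd.Timestamp("2016-05-01 20:00")).total_seconds()) <= 300


def test_detect_low_coverage_flag():
    v = np.full(1440, np.nan)
    v[:100] = 0.02
    idx = pd.date_range("2016-05-01 12:00", periods=1440, freq="1min")
    det = detect_onset_offset(pd.Series(v, index=idx), 0.16)
    assert FLAG_LOW_COVERAGE in det.flags


def test_bout_duration_examples():
    assert bout_duration(
        pd.Timestamp("2016-05-01 20:00"), pd.Timestamp("2016-05-02 06:00")
    ) == pytest.approx(10.0)
    assert bout_duration(
        pd.Timestamp("2016-05-01 19:12"), pd.Timestamp("2016-05-02 06:48")
    ) == pytest.approx(11.6)
    with pytest.raises(ValidationError):
        bout_duration(pd.Timestamp("2016-05-02 06:00"), pd.Timestamp("2016-05-01 20:00"))
    with pytest.raises(ValidationError):
        bout_duration(None, pd.Timestamp("2016-05-01 20:00"))


def test_relative_to_twilight_sign_convention():
    dusk = pd.Timestamp("2016-05-01 19:30")
    assert relative_to_twilight(pd.Timestamp("2016-05-01 20:00"), dusk) == 30.0
    assert relative_to_twilight(pd.Timestamp("2016-05-01 19:00"), dusk) == -30.0


def _days(n, start="2016-11-01"):
    dates = pd.date_range(start, periods=n)
    return [ActivityDay(animal_id="A", night_date=d) for d in dates]


def test_snow_filter_hand_counts():
    days = _days(23)
    snow = pd.Series(2.0, index=pd.date_range("2016-11-01", periods=23))
    # four deep-snow days, one exactly at the inclusive 8 cm boundary
    snow.iloc[3] = 8.0
    snow.iloc[4] = 12.0
    snow.iloc[10] = 25.0
    snow.iloc[11] = 9.5
    retained, excluded = partition_snow_days(days, snow)
    assert len(retained) == 19
    assert len(excluded) == 4
    assert all(FLAG_SNOW_EXCLUDED in d.flags for d in excluded)
    assert len(exclude_snow_days(days, snow)) == 19


def test_snow_boundary_is_inclusive_and_7p9_retained():
    days = _days(2)
    snow = pd.Series(
        [8.0, 7.9], index=pd.date_range("2016-11-01", periods=2)
    )
    retained, excluded = partition_snow_days(days, snow)
    assert [d.night_date for d in excluded] == [pd.Timestamp("2016-11-01")]
    assert [d.night_date for d in retained] == [pd.Timestamp("2016-11-02")]


def test_missing_snow_is_conservatively_excluded():
    days = _days(3)
    snow = pd.Series(
        [2.0, np.nan, 2.0], index=pd.date_range("2016-11-01", periods=3)
    )
    retained, excluded = partition_snow_days(days, snow)
    assert len(retained) == 2
    assert len(excluded) == 1
    assert FLAG_SNOW_UNRESOLVED in excluded[0].flags


def test_snow_filter_idempotent():
    days = _days(23)
    snow = pd.Series(2.0, index=pd.date_range("2016-11-01", periods=23))
    snow.iloc[5] = 20.0
    once = exclude_snow_days(days, snow)
    twice = exclude_snow_days(once, snow)
    assert [d.night_date for d in once] == [d.night_date for d in twice]


def test_filter_window_drops_flagged():
    good = ActivityDay(animal_id="A", night_date="2016-11-01")
    bad = ActivityDay(
        animal_id="A", night_date="2016-11-02", flags={FLAG_ONSET_OUT_OF_WINDOW}
    )
    assert filter_window([good, bad]) == [good]


def test_actogram_double_plot_overlap_identity(rng, make_trace):
    from noctograph.odba import compute_odba

    n = 3 * 86400
    series = compute_odba(make_trace(*rng.normal(0, 0.2, (3, n)), start="2016-05-01 12:00"))
    mat = build_actogram(series, bin_min=10, double_plot=True)
    half = mat.values.shape[1] // 2
    # right half of row i == left half of row i+1
    np.testing.assert_array_equal(mat.values[:-1, half:], mat.values[1:, :half])
    assert np.isnan(mat.values[-1, half:]).all()


def test_end_to_end_activity_days_on_synthetic_nights(rng):
    from noctograph.odba import compute_odba
    from noctograph.synthetic import SimConfig, simulate_detection_nights
    from noctograph.twilight import FLAGSTAFF, twilight_table

    trace, truth = simulate_detection_nights(4, rng, SimConfig())
    series = compute_odba(trace)
    twi = twilight_table(FLAGSTAFF, "2016-01-01", "2016-01-06")
    from noctograph.timing import activity_days

    days = activity_days(series, twi)
    by_date = {d.night_date: d for d in days}
    hits = 0
    for _, row in truth.iterrows():
        d = by_date[row["night_date"]]
        if d.onset is not None:
            assert abs((d.onset - row["true_onset"]).total_seconds()) <= 1800
            hits += 1
    assert hits >= 2
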