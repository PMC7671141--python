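import numpy as np
import pandas as pd
import pytest

from noctograph.core import ValidationError
from noctograph.odba import (
    ConfigurationError,
    OdbaConfig,
    aggregate,
    compare_rates,
    compute_odba,
    decimate_to_1hz,
    running_mean,
)


def odba_oracle(x, y, z, window_samples):
    """Brute-force per-sample ODBA: explicit loops, edge shrink, NaN skip."""
    n = len(x)
    half = window_samples // 2
    out = np.zeros(n)
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        for axis in (x, y, z):
            seg = np.asarray(axis[lo:hi], dtype=float)
            seg = seg[np.isfinite(seg)]
            out[i] += abs(axis[i] - seg.mean()) if seg.size else np.nan
    return out


def test_window_samples_rates():
    cfg = OdbaConfig()
    assert cfg.window_samples(1.0) == 5  # 5 s at 1 Hz
    assert cfg.window_samples(10.0) == 31  # 3 s at 10 Hz, made odd
    with pytest.raises(ConfigurationError):
        cfg.window_samples(25.0)


def test_running_mean_simple_interior_and_edges():
    out = running_mean([0.0, 0.0, 3.0, 0.0, 0.0], 3)
    np.testing.assert_allclose(out, [0.0, 1.0, 1.0, 1.0, 0.0])


def test_running_mean_rejects_even_window_and_empty():
    with pytest.raises(ValidationError):
        running_mean([1.0, 2.0], 2)
    with pytest.raises(ValidationError):
        running_mean([], 3)


def test_single_spike_worked_example(make_trace):
    """A lone 1 g spike on one axis inside a 5-sample window: the residual
    at the spike is 1 - 1/5 = 0.8 and 0.2 at each in-window neighbor."""
    x = np.zeros(11)
    x[5] = 1.0
    trace = make_trace(x, np.zeros(11), np.zeros(11))
    odba = compute_odba(trace).per_sample
    assert odba[5] == pytest.approx(0.8)
    for j in (3, 4, 6, 7):
        assert odba[j] == pytest.approx(0.2)
    assert odba[0] == pytest.approx(0.0)


def test_static_trace_gives_zero(make_trace):
    n = 500
    trace = make_trace(np.full(n, 0.31), np.full(n, -0.42), np.full(n, 0.86))
    odba = compute_odba(trace).per_sample
    np.testing.assert_allclose(odba, 0.0, atol=1e-15)


def test_static_offset_invariance(make_trace, rng):
    """Adding a constant (re-orienting gravity) never changes ODBA."""
    n = 400
    x, y, z = rng.normal(0, 0.2, (3, n))
    base = compute_odba(make_trace(x, y, z)).per_sample
    shifted = compute_odba(make_trace(x + 0.7, y - 1.2, z + 0.05)).per_sample
    np.testing.assert_allclose(base, shifted, atol=1e-12)


def test_scale_equivariance(make_trace, rng):
    n = 300
    x, y, z = rng.normal(0, 0.2, (3, n))
    base = compute_odba(make_trace(x, y, z)).per_sample
    scaled = compute_odba(make_trace(3 * x, 3 * y, 3 * z)).per_sample
    np.testing.assert_allclose(scaled, 3 * base, rtol=1e-10, atol=1e-12)


def test_oracle_equivalence_with_gaps(make_trace, rng):
    n = 240
    x, y, z = rng.normal(0, 0.3, (3, n))
    x[50:60] = np.nan
    y[50:60] = np.nan
    z[50:60] = np.nan
    trace = make_trace(x, y, z)
    odba = compute_odba(trace).per_sample
    expected = odba_oracle(x, y, z, 5)
    expected[50:60] = np.nan  # missing samples stay missing
    np.testing.assert_allclose(odba, expected, atol=1e-12)
    assert np.isnan(odba[50:60]).all()


def test_aggregate_matches_groupby_oracle(make_trace, rng):
    n = 3 * 3600
    trace = make_trace(*rng.normal(0, 0.2, (3, n)))
    series = compute_odba(trace)
    hourly = aggregate(series, "hourly")
    s = series.as_series()
    expected = s.groupby(s.index.floor("h")).mean()
    np.testing.assert_allclose(hourly.to_numpy(), expected.to_numpy(), atol=1e-12)
    assert series.hourly is hourly


def test_aggregate_coverage_policy(make_trace, rng):
    n = 2 * 3600
    x, y, z = rng.normal(0, 0.2, (3, n))
    x[3600 + 1000 :] = np.nan  # second hour has < 80% coverage
    y[3600 + 1000 :] = np.nan
    z[3600 + 1000 :] = np.nan
    hourly = aggregate(compute_odba(make_trace(x, y, z)), "hourly")
    assert np.isfinite(hourly.iloc[0])
    assert np.isnan(hourly.iloc[1])


def test_decimate_keeps_every_tenth(make_trace, rng):
    n = 1000
    trace = make_trace(*rng.normal(0, 0.2, (3, n)), rate_hz=10.0)
    deci = decimate_to_1hz(trace)
    assert deci.rate_hz == 1.0
    np.testing.assert_array_equal(deci.x, trace.x[::10])
    with pytest.raises(ValidationError):
        decimate_to_1hz(deci)


def test_compare_rates_degenerate_on_constant(make_trace):
    n = 3 * 36000
    trace = make_trace(np.zeros(n), np.zeros(n), np.ones(n), rate_hz=10.0)
    out = compare_rates(trace)
    assert out["degenerate"] is True


def test_compare_rates_requires_two_hours(make_trace, rng):
    n = 36000  # one hour at 10 Hz
    trace = make_trace(*rng.normal(0, 0.2, (3, n)), rate_hz=10.0)
    with pytest.raises(ValidationError):
        compare_rates(trace)
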