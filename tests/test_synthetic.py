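import numpy as np
import pandas as pd
import pytest

from noctograph.core import ValidationError
from noctograph.odba import OdbaConfig, compute_odba
from noctograph.synthetic import (
    DEFAULT_ANIMALS,
    SimConfig,
    ar1_residual_sd_factor,
    axis_noise_sd,
    simulate_day_records,
    simulate_detection_nights,
    simulate_study,
    simulate_trace,
    simulate_weather,
)

TINY = SimConfig(animals=DEFAULT_ANIMALS[:2] + DEFAULT_ANIMALS[4:5], days_per_stage=2)


def test_study_is_deterministic():
    b1 = simulate_study(TINY)
    b2 = simulate_study(TINY)
    assert len(b1.traces) == len(b2.traces)
    for t1, t2 in zip(b1.traces, b2.traces):
        np.testing.assert_array_equal(t1.x, t2.x)
        np.testing.assert_array_equal(t1.z, t2.z)
    pd.testing.assert_frame_equal(b1.truth, b2.truth)
    pd.testing.assert_frame_equal(b1.weather, b2.weather)


def test_different_seed_changes_data():
    import dataclasses

    b1 = simulate_study(TINY)
    b2 = simulate_study(dataclasses.replace(TINY, seed=1))
    assert not np.array_equal(b1.traces[0].x, b2.traces[0].x)


def test_no_male_lactation_deployments():
    bundle = simulate_study(TINY)
    dep = bundle.deployments
    assert ((dep["sex"] == "male") & (dep["stage"] == "lactation")).sum() == 0
    # females are deployed in all four stages, males in three
    assert set(dep[dep["sex"] == "female"]["stage"]) == {
        "winter", "mating", "lactation", "fattening",
    }
    assert set(dep[dep["sex"] == "male"]["stage"]) == {
        "winter", "mating", "fattening",
    }


def test_truth_rows_one_per_night():
    bundle = simulate_study(TINY)
    dep = bundle.deployments
    assert len(bundle.truth) == int(dep["n_days"].sum())
    assert (bundle.truth["true_onset"] < bundle.truth["true_offset"]).all()


def test_no_timing_rule_for_lactating_males():
    cfg = SimConfig()
    rng = np.random.default_rng(0)
    with pytest.raises(ValidationError):
        simulate_trace(
            cfg, "M99", "male", pd.date_range("2016-06-26", periods=2), "lactation", rng
        )


def test_intensity_calibration_closed_form(rng):
    """Realized active-state mean ODBA matches the configured target."""
    target = 0.30
    trace, truth = simulate_detection_nights(
        2, rng, SimConfig(), intensity_g=target
    )
    odba = compute_odba(trace)
    s = odba.as_series()
    # measure well inside the bouts, away from ramps and edges
    vals = []
    for _, row in truth.iterrows():
        sel = s[
            (s.index >= row["true_onset"] + pd.Timedelta(minutes=30))
            & (s.index <= row["true_offset"] - pd.Timedelta(minutes=30))
        ]
        vals.append(sel.mean())
    realized = float(np.mean(vals))
    assert realized == pytest.approx(target, rel=0.05)


def test_ar1_factor_matches_monte_carlo():
    phi, w = 0.5, 5
    factor = ar1_residual_sd_factor(phi, w)
    rng = np.random.default_rng(0)
    # Monte Carlo the residual SD about the centered window mean
    from scipy.signal import lfilter

    eps = rng.standard_normal(400_000) * np.sqrt(1 - phi * phi)
    x = lfilter([1.0], [1.0, -phi], eps)
    kernel = np.ones(w) / w
    mean = np.convolve(x, kernel, mode="same")
    resid_sd = np.std((x - mean)[w : -w])
    assert resid_sd == pytest.approx(factor, rel=0.01)
    # and the calibration inverts it
    assert axis_noise_sd(1.0, phi, w) * 3 * np.sqrt(2 / np.pi) * factor == pytest.approx(1.0)


def test_weather_shape_and_snow_season():
    cfg = SimConfig()
    rng = np.random.default_rng(3)
    w = simulate_weather(cfg, "2015-11-13", "2016-09-18", rng)
    assert (w.index[1] - w.index[0]) == pd.Timedelta(minutes=5)
    assert {"temp_c", "wind_ms", "precip_mm", "snow_cm"} <= set(w.columns)
    assert (w["snow_cm"] >= 0).all() and (w["precip_mm"] >= 0).all()
    snowy = w[w["snow_cm"] > 0]
    assert set(snowy.index.month) <= {11, 12, 1, 2, 3, 4}
    # summer is warmer than winter
    assert w.loc["2016-07", "temp_c"].mean() > w.loc["2015-12", "temp_c"].mean() + 10


def test_weather_zero_noise_recovers_sinusoid():
    import dataclasses

    cfg = dataclasses.replace(
        SimConfig(),
        weather_noise_sd_c=0.0,
        wind_noise_sd_ms=0.0,
        rain_day_prob_monsoon=0.0,
        rain_day_prob_other=0.0,
    )
    rng = np.random.default_rng(0)
    w = simulate_weather(cfg, "2016-06-01", "2016-06-02", rng)
    doy = w.index.dayofyear.to_numpy()
    hour = w.index.hour.to_numpy() + w.index.minute.to_numpy() / 60.0
    expected = (
        9.5 - 9.5 * np.cos(2 * np.pi * (doy - 15) / 365.25)
        + 5.5 * np.cos(2 * np.pi * (hour - 15.0) / 24.0)
    )
    np.testing.assert_allclose(w["temp_c"].to_numpy(), expected, atol=1e-9)
    np.testing.assert_allclose(w["wind_ms"].to_numpy(), cfg.wind_mean_ms)
    assert w["precip_mm"].sum() == 0.0


def test_day_records_design(rng):
    df = simulate_day_records(rng, n_animals=5, n_days=40)
    assert len(df) == 5 * 40
    assert df["animal_id"].nunique() == 5
    assert list(df["stage"].unique()) == ["winter", "mating", "lactation", "fattening"]
    # stage blocks are consecutive in time
    first_day = df.groupby("stage")["date"].min().sort_values()
    assert list(first_day.index) == ["winter", "mating", "lactation", "fattening"]
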