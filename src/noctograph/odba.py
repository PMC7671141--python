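"""Overall dynamic body acceleration (ODBA).

ODBA is the classic biologging proxy for movement-related energy
expenditure: on each axis the slowly varying (static, gravitational)
component is estimated by a running mean and subtracted, and the absolute
residuals are summed over the three axes,

    ODBA_i = |x_i - xbar_i| + |y_i - ybar_i| + |z_i - zbar_i|,

with the running-mean window chosen by sampling rate: 5 s at 1 Hz, 3 s at
10 Hz.  The window is centered and shrinks at the record edges so output
length equals input length.

Because devices in a mixed deployment may record at either rate,
:func:`compare_rates` re-creates the standard consistency check: decimate a
10 Hz trace to 1 Hz, compute ODBA at each rate with its own window, and
regress 1 Hz hourly means on 10 Hz hourly means; near-identity (slope ~ 1,
r^2 ~ 1) indicates the two rates measure the same activity signal.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .core import AccelTrace, OdbaSeries, ValidationError


class ConfigurationError(ValueError):
    """ODBA configuration does not cover the trace's sampling rate."""


@dataclasses.dataclass
class OdbaConfig:
    """Rate-dependent running-mean windows.

    The window length in samples is ``round(window_s * rate_hz)``, made odd
    (by adding one sample) so the centered window is symmetric.
    """

    window_s_by_rate: Mapping[float, float] = dataclasses.field(
        default_factory=lambda: {1.0: 5.0, 10.0: 3.0}
    )
    window_alignment: str = "centered"
    edge_policy: str = "shrink"

    def window_samples(self, rate_hz: float) -> int:
        try:
            window_s = self.window_s_by_rate[rate_hz]
        except KeyError:
            raise ConfigurationError(
                f"no running-mean window configured for rate {rate_hz} Hz"
            ) from None
        n = int(round(window_s * rate_hz))
        n = max(n, 1)
        if n % 2 == 0:
            n += 1
        return n


def running_mean(signal, window_samples: int) -> np.ndarray:
    """Centered running mean with edge shrink; NaNs are skipped.

    Element i is the mean of the finite samples within the centered window,
    truncated at the record boundaries.  Output has the input's length.
    """
    signal = np.asarray(signal, dtype=float)
    if signal.size == 0:
        raise ValidationError("running_mean of an empty signal")
    if window_samples < 1 or window_samples % 2 == 0:
        raise ValidationError(
            f"window must be an odd positive sample count, got {window_samples}"
        )
    if window_samples == 1:
        return signal.copy()
    finite = np.isfinite(signal)
    vals = np.where(finite, signal, 0.0)
    kernel = np.ones(window_samples)
    sums = np.convolve(vals, kernel, mode="same")
    counts = np.convolve(finite.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(counts > 0, sums / counts, np.nan)
    return out


def compute_odba(trace: AccelTrace, config: OdbaConfig | None = None) -> OdbaSeries:
    """Gravity-compensate each axis and sum absolute residuals."""
    config = config or OdbaConfig()
    w = config.window_samples(trace.rate_hz)
    per_sample = np.zeros(trace.n_samples)
    for axis in (trace.x, trace.y, trace.z):
        per_sample = per_sample + np.abs(axis - running_mean(axis, w))
    per_sample[trace.missing_mask()] = np.nan
    return OdbaSeries(
        animal_id=trace.animal_id,
        start=trace.start,
        rate_hz=trace.rate_hz,
        window_s=w / trace.rate_hz,
        per_sample=per_sample,
    )


def aggregate(
    series: OdbaSeries,
    level: str,
    min_coverage: float = 0.8,
) -> pd.Series:
    """Mean per-sample ODBA per clock hour or calendar day.

    Periods with fewer than ``min_coverage`` of their expected finite
    samples get NaN (flagged-missing) rather than a biased mean.  The
    result is also cached on the series (``hourly`` / ``daily``).
    """
    if level not in ("hourly", "daily"):
        raise ValidationError(f"level must be 'hourly' or 'daily', got {level!r}")
    s = series.as_series()
    if level == "hourly":
        keys = s.index.floor("h")
        expected = 3600 * series.rate_hz
    else:
        keys = s.index.normalize()
        expected = 86400 * series.rate_hz
    grouped = s.groupby(keys)
    means = grouped.mean()
    coverage = grouped.count() / expected
    means[coverage < min_coverage] = np.nan
    means.index.name = "hour" if level == "hourly" else "date"
    if level == "hourly":
        series.hourly = means
    else:
        series.daily = means
    return means


def decimate_to_1hz(trace: AccelTrace) -> AccelTrace:
    """Instantaneous subsampling: keep every 10th sample of a 10 Hz trace."""
    if trace.rate_hz != 10:
        raise ValidationError("decimation expects a 10 Hz trace")
    return AccelTrace(
        animal_id=trace.animal_id,
        sex=trace.sex,
        start=trace.start,
        rate_hz=1.0,
        x=trace.x[::10],
        y=trace.y[::10],
        z=trace.z[::10],
    )


def compare_rates(
    trace_10hz: AccelTrace, config: OdbaConfig | None = None
) -> dict:
    """1 Hz vs 10 Hz hourly-ODBA equivalence check.

    Returns ``{"intercept", "slope", "r2", "n_hours", "degenerate"}`` from
    an OLS regression of the 1 Hz (decimated) hourly means on the 10 Hz
    hourly means.  Zero variance in the predictor is reported as a
    degenerate regression rather than an exception.
    """
    config = config or OdbaConfig()
    if trace_10hz.rate_hz != 10:
        raise ValidationError("compare_rates expects a 10 Hz trace")
    odba_10 = compute_odba(trace_10hz, config)
    odba_1 = compute_odba(decimate_to_1hz(trace_10hz), config)
    hourly_10 = aggregate(odba_10, "hourly")
    hourly_1 = aggregate(odba_1, "hourly")
    joined = pd.concat(
        {"hz10": hourly_10, "hz1": hourly_1}, axis=1, join="inner"
    ).dropna()
    if len(joined) < 2:
        raise ValidationError(
            f"regression needs at least 2 complete hourly pairs, got {len(joined)}"
        )
    x = joined["hz10"].to_numpy()
    y = joined["hz1"].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {
            "intercept": np.nan,
            "slope": np.nan,
            "r2": np.nan,
            "n_hours": len(joined),
            "degenerate": True,
        }
    fit = stats.linregress(x, y)
    return {
        "intercept": float(fit.intercept),
        "slope": float(fit.slope),
        "r2": float(fit.rvalue**2),
        "n_hours": len(joined),
        "degenerate": False,
    }
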