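import numpy as np
import pandas as pd
import pytest

from noctograph import AccelTrace


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_trace():
    def _make(x, y, z, rate_hz=1.0, start="2016-01-01 00:00:00",
              animal_id="T1", sex="female"):
        return AccelTrace(
            animal_id=animal_id,
            sex=sex,
            start=pd.Timestamp(start),
            rate_hz=rate_hz,
            x=np.asarray(x, dtype=float),
            y=np.asarray(y, dtype=float),
            z=np.asarray(z, dtype=float),
        )

    return _make
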