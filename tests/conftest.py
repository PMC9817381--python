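import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from actirhythm import SarimaSpec, MinuteSeries

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from actirhythm.synthetic import DEFAULT_PROFILE, simulate_hourly_series


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)


@pytest.fixture
def model22_spec():
    """The study's most frequently selected structure: (1,1,1)(0,1,1)[24]."""
    return SarimaSpec(1, 1, 1, 0, 1, 1, 24)


@pytest.fixture
def model22_weights():
    return {"ar1": 0.4, "ma1": 0.3, "sma1": 0.5}


@pytest.fixture
def hourly_series(model22_spec, model22_weights):
    """One 165-point hourly series with known generating weights (no clip)."""
    return simulate_hourly_series(
        model22_spec, model22_weights, DEFAULT_PROFILE, 5.0, 165, seed=11,
        clip_negative=False,
    )


def make_minute_series(met, participant_id="P001", start="2022-01-02 00:00"):
    return MinuteSeries(participant_id, pd.Timestamp(start), np.asarray(met, dtype=float))


@pytest.fixture
def minute_series_factory():
    return make_minute_series
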