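import numpy as np
import pytest

from fhrv.preprocessing import RRSeries


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


def make_series(rr_ms, ga_weeks=30.0, recording_id="test"):
    """RRSeries from interval values alone; onsets rebuilt by cumulation."""
    rr = np.asarray(rr_ms, dtype=float)
    onsets = np.cumsum(rr) / 1000.0
    return RRSeries(onsets, rr, ga_weeks=ga_weeks, recording_id=recording_id)


@pytest.fixture
def constant_series():
    return make_series([400.0] * 300)
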