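import numpy as np
import pytest

from microdyn.core import ParcelTimeSeries
from microdyn.synthetic import SequenceParams, make_state_maps


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def uniform_params():
    """Seven states, uniform syntax, 100 ms dwells, 250 Hz."""
    k = 7
    T = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(T, 0.0)
    return SequenceParams(transition_matrix=T, dwell_mean=100.0, duration_s=600.0, fs=250.0)


@pytest.fixture
def small_maps():
    return make_state_maps(3, 20, max_abs_corr=0.5, seed=7)


@pytest.fixture
def small_scan(rng):
    return ParcelTimeSeries(data=rng.standard_normal((8, 2000)), fs=250.0, scan_id="s0")
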