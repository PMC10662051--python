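import numpy as np
import pytest

from tugsim import AnnealConfig, SimConfig, Track, ddb_params, kif16b_params


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def kif():
    return kif16b_params()


@pytest.fixture
def ddb():
    return ddb_params()


@pytest.fixture
def sim_config():
    return SimConfig()


@pytest.fixture
def anneal_config():
    return AnnealConfig()


def linear_track(v_nm_s=800.0, duration=10.0, dt=0.1, x0=0.0, track_id="lin"):
    t = dt * np.arange(int(round(duration / dt)) + 1)
    return Track(track_id, t, x0 + v_nm_s * t)


@pytest.fixture
def make_linear_track():
    return linear_track
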