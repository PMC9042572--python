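import numpy as np
import pytest

from hpadyn import TimeSeries


@pytest.fixture
def grid_12h():
    return np.arange(0.0, 721.0, 10.0)


def make_ts(v, name="x", units="dimensionless", dt=10.0, t0=0.0):
    v = np.asarray(v, dtype=float)
    t = t0 + dt * np.arange(len(v))
    return TimeSeries(name, t, v, units, dt)


@pytest.fixture
def gauss_pulses(grid_12h):
    """Three equal Gaussian bumps 180 min apart on a 12-h grid."""
    centers = np.array([120.0, 300.0, 480.0])
    v = np.exp(-0.5 * ((grid_12h[:, None] - centers) / 15.0) ** 2).sum(axis=1)
    return make_ts(v)
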