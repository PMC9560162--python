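import numpy as np
import pytest

from segclock.circstats import PulseTrain
from segclock.signal import Timeseries
from segclock.synthdata import default_period_modulation, fitted_params


@pytest.fixture(scope="session")
def ref_params():
    """The reference fitted oscillator (lambda=0.5, s*=5.6, eps=0.4)."""
    return fitted_params()


@pytest.fixture(scope="session")
def ref_modulation(ref_params):
    """Default intrinsic-period modulation T_osc(T_zeit)."""
    return default_period_modulation(ref_params)


@pytest.fixture()
def cosine_ts():
    """Pure 140-min cosine sampled every 10 min over 1500 min."""
    t = np.arange(0.0, 1500.0, 10.0)
    return Timeseries("cos140", t, np.cos(2 * np.pi * t / 140.0))


def make_ts(y_of_t, t_end=1500.0, dt=10.0, sample_id="ts"):
    t = np.arange(0.0, t_end, dt)
    return Timeseries(sample_id, t, y_of_t(t))


@pytest.fixture()
def pulses_170():
    return PulseTrain(t_first=100.0, T_zeit=170.0, n_pulses=9, strength=0.4)
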