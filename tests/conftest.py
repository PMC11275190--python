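import numpy as np
import pytest

from protospike import ConditionSpec, Trace


@pytest.fixture
def simple_spec():
    """A small, clean condition: no drift, no noise, moderate spikes."""
    return ConditionSpec(
        label="test", amp_mean=1.0, amp_sd=0.2, amp_skew=0.8,
        amp_min=0.4, amp_max=1.8, isi_mean=100.0, isi_sd=20.0,
        isi_min=50.0, isi_max=160.0, drift_amplitude=0.0,
        noise_sd=0.0, sample_interval=1.0, seed=7)


@pytest.fixture
def sparse_spec():
    """Spikes far apart relative to the pulse width (realistic duty cycle)."""
    return ConditionSpec(
        label="sparse", amp_mean=1.0, amp_sd=0.2, amp_skew=0.8,
        amp_min=0.4, amp_max=1.8, isi_mean=1000.0, isi_sd=150.0,
        isi_min=500.0, isi_max=1600.0, drift_amplitude=0.0,
        noise_sd=0.0, sample_interval=1.0, seed=7)


@pytest.fixture
def flat_trace():
    return Trace(np.zeros(500), dt=1.0, unit="mV")


def make_trace(values, dt=1.0, unit="mV", label=""):
    return Trace(np.asarray(values, dtype=float), dt=dt, unit=unit, label=label)
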