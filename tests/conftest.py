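import numpy as np
import pytest

from abquant.simulate import ConditionEpoch, SimulationConfig
from abquant.traces import DffTrace


@pytest.fixture
def quiet_config():
    """Noise- and drift-free simulation settings for deterministic oracles."""
    return SimulationConfig(noise_sd=0.0, drift_amplitude=0.0)


@pytest.fixture
def application_schedule():
    """Baseline / application / washout epochs with 5x rate suppression."""
    return (
        ConditionEpoch("baseline", 0.0, 60.0, 1.0),
        ConditionEpoch("application", 60.0, 120.0, 0.2),
        ConditionEpoch("washout", 120.0, 180.0, 1.0),
    )


def make_dff(values, sampling_rate=40.0, channel="calcium", f0=1.0):
    """Wrap a plain array as a DffTrace for detection-level tests."""
    return DffTrace(np.asarray(values, dtype=float), sampling_rate, f0=f0,
                    f0_mode="trace-percentile", channel=channel)


def kernel_signal(t, event_times, amplitude, rise=0.05, decay=0.5):
    """Linear-rise / exponential-decay transient kernel, summed over events."""
    out = np.zeros_like(t)
    for te in np.atleast_1d(event_times):
        dt = t - te
        rising = (dt >= 0) & (dt < rise)
        out[rising] += amplitude * dt[rising] / rise
        tail = dt >= rise
        out[tail] += amplitude * np.exp(-(dt[tail] - rise) / decay)
    return out
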