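import numpy as np
import pytest

from atriopv.pressure import CompositePressureCycle
from atriopv.simulate import PatientParams, WaveformParams, af_waveform
from atriopv.volume import CompositeVolumeCycle


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def quiet_waveform():
    """Deterministic, noise-free regular-rhythm waveform settings."""
    return WaveformParams(noise_sd=0.0, resp_amp=0.0, powerline_amp=0.0, rr_cv=0.0)


@pytest.fixture
def af_params():
    return af_waveform()


@pytest.fixture
def default_patient():
    return PatientParams()


def make_pressure_composite(values, sample_rate=1000.0, n_cycles=10, rr=None):
    """Composite with uniform support, for feature/loop tests."""
    values = np.asarray(values, dtype=float)
    rr = values.size / sample_rate if rr is None else rr
    return CompositePressureCycle(
        sample_rate=sample_rate,
        values=values,
        support_counts=np.full(values.size, n_cycles, dtype=int),
        rr_lengths=np.full(n_cycles, rr),
    )


def make_volume_composite(values, cycle_length=1.0):
    values = np.asarray(values, dtype=float)
    return CompositeVolumeCycle(
        phase_grid=np.arange(values.size) / values.size,
        values=values,
        n_beats=3,
        mean_cycle_length=cycle_length,
    )
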