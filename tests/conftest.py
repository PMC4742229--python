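"""Shared fixtures: nominal simulations and synthetic waveform builders."""

import numpy as np
import pytest

from vfpop.model import GlottalFlowSeries, ParameterSet, SimConfig, simulate
from vfpop.measures import VoiceMeasures


@pytest.fixture(scope="session")
def nominal_params() -> np.ndarray:
    return ParameterSet.nominal().to_array()


@pytest.fixture(scope="session")
def nominal_result(nominal_params):
    """One nominal simulation, shared across tests."""
    return simulate(nominal_params)


def make_flow(u: np.ndarray, dt: float) -> GlottalFlowSeries:
    return GlottalFlowSeries(t=np.arange(u.size) * dt, u=np.asarray(u, float), dt=dt)


def half_sine_flow(freq_khz: float = 0.125, dt: float = 0.05,
                   duration: float = 1000.0, amplitude: float = 1.0,
                   ) -> GlottalFlowSeries:
    """Rectified-sine pulse train: closed half the cycle, sinusoidal pulse."""
    t = np.arange(int(duration / dt)) * dt
    return make_flow(amplitude * np.maximum(0.0, np.sin(2 * np.pi * freq_khz * t)), dt)


def triangle_flow(rise_ms: float = 2.0, fall_ms: float = 1.0,
                  period_ms: float = 8.0, dt: float = 0.01,
                  duration: float = 800.0) -> GlottalFlowSeries:
    """Triangular pulses (linear rise then fall, closed the rest of the cycle)."""
    t = np.arange(int(duration / dt)) * dt
    ph = t % period_ms
    u = np.where(ph < rise_ms, ph / rise_ms,
                 np.where(ph < rise_ms + fall_ms,
                          1.0 - (ph - rise_ms) / fall_ms, 0.0))
    return make_flow(u, dt)


def harmonic_flow(amps: dict[int, float], freq_khz: float = 0.125,
                  dt: float = 0.05, duration: float = 800.0,
                  offset: float | None = None) -> GlottalFlowSeries:
    """Sum of harmonics plus a DC offset keeping the signal non-negative."""
    t = np.arange(int(duration / dt)) * dt
    u = np.zeros_like(t)
    for n, a in amps.items():
        u += a * np.cos(2 * np.pi * n * freq_khz * t)
    if offset is None:
        offset = 1.05 * np.abs(u).max() + 0.1
    return make_flow(u + offset, dt)


def stub_measures(**overrides) -> VoiceMeasures:
    """Oscillating measures with every bounded field mid-range."""
    base = dict(f0=150.0, mean_flow=200.0, ac_flow=300.0, max_flow=500.0,
                mfdr=400.0, hrf=-10.0, h1h2=5.0, oq=0.6, sq=1.5,
                oscillating=True)
    base.update(overrides)
    return VoiceMeasures(**base)
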