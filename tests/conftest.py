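"""Shared fixtures: generator objects reused across test modules.

Session-scoped fixtures cache the more expensive simulations (kHz photon
traces) so the suite stays fast; everything is seeded and deterministic.
"""

import numpy as np
import pytest

from voltscope import synthgen
from voltscope.types import Trace


@pytest.fixture(scope="session")
def model():
    """Default indicator forward model (no bleaching)."""
    return synthgen.default_force1s_model()


@pytest.fixture(scope="session")
def bright_model():
    """High-flux model for near-noiseless photon traces."""
    return synthgen.default_force1s_model(flux=600_000)


@pytest.fixture(scope="session")
def snr8_model():
    """Flux chosen so a single spike has shot-noise SNR ~ 8 at 7.1 kHz."""
    return synthgen.default_force1s_model(flux=170_000)


@pytest.fixture(scope="session")
def spont_recording(bright_model):
    """20-s spontaneous recording: (VoltageSim, dff Trace, 440-Hz photons)."""
    sim = synthgen.simulate_voltage("spontaneous", seed=3, duration_s=20,
                                    rate_hz=5.0)
    dff = synthgen.voltage_to_dff(sim, bright_model)
    ph440 = synthgen.emit_photons(dff, bright_model, 440.0, seed=5)
    return sim, dff, ph440


@pytest.fixture(scope="session")
def ulove_recording(snr8_model):
    """60-s spontaneous recording at 7.1 kHz, spike SNR ~ 8."""
    sim = synthgen.simulate_voltage("spontaneous", seed=11, duration_s=60,
                                    rate_hz=2.0)
    dff = synthgen.voltage_to_dff(sim, snr8_model)
    ph = synthgen.emit_photons(dff, snr8_model, 7142.9, seed=12)
    return sim, dff, ph


@pytest.fixture()
def gauss_spike_waveform():
    """A smooth positive transient (FWHM ~ 2.6 ms) sampled at 7.1 kHz."""
    fs = 7142.9
    t = np.arange(0, 0.02, 1 / fs)
    sigma = 0.0026 / (2 * np.sqrt(2 * np.log(2)))
    return Trace(np.exp(-0.5 * ((t - 0.01) / sigma) ** 2), fs)
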