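import numpy as np
import pytest
from dataclasses import replace

import mscmech as m


@pytest.fixture
def patch_geometry():
    """0.9 um curvature patch, the spheroplast patch-clamp scale."""
    return m.PatchGeometry(tip_radius=0.5, dome_radius=0.9,
                           curvature_radius=0.9)


@pytest.fixture
def nonvolt_mscCG():
    """MscCG-like channel without voltage coupling (detailed-balance limit)."""
    return replace(m.PRESETS["mscCG"], voltage_coupling=0.0)


@pytest.fixture
def simulate_sweep(patch_geometry):
    """Simulate one preset sweep: returns (trace, events)."""

    def _run(channels, seed, peak=-150.0, duration=8.0, voltage=30.0,
             sampling_rate=5000.0, noise_sd=0.5, kind="triangle", lead=0.5,
             filter_cutoff_hz=2000.0):
        if isinstance(channels, str):
            channels = m.get_preset(channels)
        protocol = m.build_protocol(kind, peak, duration, sampling_rate,
                                    lead=lead)
        noise = m.NoiseSpec(current_noise_sd=noise_sd, seed=seed)
        return m.simulate_recording(channels, protocol, patch_geometry,
                                    voltage, noise,
                                    filter_cutoff_hz=filter_cutoff_hz)

    return _run


def square_pulse_trace(amplitude=10.0, n=300, start=100, stop=200,
                       sampling_rate=1000.0):
    """Noiseless single square current pulse with a suction plateau."""
    t = np.arange(n) / sampling_rate
    current = np.zeros(n)
    current[start:stop] = amplitude
    pressure = np.zeros(n)
    pressure[n // 4:] = -50.0
    return m.RecordingTrace(time=t, current=current, pressure=pressure,
                            sampling_rate=sampling_rate, voltage=30.0)
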