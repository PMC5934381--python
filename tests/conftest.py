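import numpy as np
import pytest

from callprop.types import CallParameters, Waveform

FS = 44100.0


@pytest.fixture
def four_pulse_params() -> CallParameters:
    """Simple 4-pulse call: 0.1 s pulses, 0.1 s gaps, moderate modulation."""
    return CallParameters(
        dominant_frequency=2000.0,
        n_pulses=4,
        pulse_duration=0.1,
        inter_pulse_interval=0.1,
        modulation_depth=50.0,
        n_intra_pulse_modulations=5,
    )


@pytest.fixture
def deep_am_params() -> CallParameters:
    """Single long pulse with deep five-cycle modulation (depth measurement)."""
    return CallParameters(
        dominant_frequency=2200.0,
        n_pulses=1,
        pulse_duration=0.4,
        inter_pulse_interval=0.0,
        modulation_depth=80.0,
        n_intra_pulse_modulations=5,
    )


def make_tone(freq: float, duration: float, amplitude: float = 0.5, fs: float = FS) -> Waveform:
    t = np.arange(int(round(duration * fs))) / fs
    return Waveform(amplitude * np.sin(2.0 * np.pi * freq * t), fs)


def random_call_parameters(rng: np.random.Generator) -> CallParameters:
    """Draw a realistic pulsed-call parameter set for round-trip testing."""
    return CallParameters(
        dominant_frequency=float(rng.uniform(800.0, 4000.0)),
        n_pulses=int(rng.integers(1, 7)),
        pulse_duration=float(rng.uniform(0.03, 0.45)),
        inter_pulse_interval=float(rng.uniform(0.04, 0.3)),
        modulation_depth=float(rng.uniform(0.0, 85.0)),
        n_intra_pulse_modulations=int(rng.choice([0, 5])),
    )
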