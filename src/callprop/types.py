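"""Core value types: call parameter sets, waveforms, stimulus specs."""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Mapping

import numpy as np

DEFAULT_SAMPLE_RATE = 44100.0
#: Largest representable 16-bit peak after float -> PCM16 export.
PCM16_FULL_SCALE = 1.0 - 2.0 ** -15


@dataclass(frozen=True)
class CallParameters:
    """Per-locality synthesis/analysis parameter set for a pulsed advertisement call.

    ``call_duration`` may be omitted; it is then derived as
    ``n_pulses * pulse_duration + (n_pulses - 1) * inter_pulse_interval``.
    An explicitly supplied value must agree with that sum within 1 %.
    ``pulse_rate`` (pulses/s) is likewise derived as ``n_pulses / call_duration``
    when not given.
    """

    dominant_frequency: float
    n_pulses: int
    pulse_duration: float
    inter_pulse_interval: float
    modulation_depth: float = 0.0
    n_intra_pulse_modulations: int = 0
    call_duration: float | None = None
    pulse_rate: float | None = None
    locality_label: str = ""

    def __post_init__(self) -> None:
        if self.dominant_frequency <= 0:
            raise ValueError("dominant_frequency must be positive")
        if self.n_pulses < 1:
            raise ValueError("n_pulses must be >= 1")
        if self.pulse_duration <= 0:
            raise ValueError("pulse_duration must be positive")
        if self.inter_pulse_interval < 0:
            raise ValueError("inter_pulse_interval must be >= 0")
        if not 0.0 <= self.modulation_depth <= 100.0:
            raise ValueError("modulation_depth must lie in [0, 100]")
        if self.n_intra_pulse_modulations < 0:
            raise ValueError("n_intra_pulse_modulations must be >= 0")
        expected = self.expected_call_duration
        if self.call_duration is None:
            object.__setattr__(self, "call_duration", expected)
        elif abs(self.call_duration - expected) > 0.01 * expected:
            raise ValueError(
                f"call_duration {self.call_duration:g} s inconsistent with pulse "
                f"structure ({expected:g} s) beyond 1%"
            )
        if self.pulse_rate is None:
            object.__setattr__(self, "pulse_rate", self.n_pulses / self.call_duration)

    @property
    def expected_call_duration(self) -> float:
        return (
            self.n_pulses * self.pulse_duration
            + (self.n_pulses - 1) * self.inter_pulse_interval
        )

    def validate_for_rate(self, sample_rate: float) -> None:
        if self.dominant_frequency >= sample_rate / 2:
            raise ValueError(
                f"carrier {self.dominant_frequency:g} Hz at or above Nyquist "
                f"({sample_rate / 2:g} Hz)"
            )

    @classmethod
    def from_dict(cls, d: Mapping[str, Any], label: str = "") -> "CallParameters":
        known = {
            "dominant_frequency",
            "n_pulses",
            "pulse_duration",
            "inter_pulse_interval",
            "modulation_depth",
            "n_intra_pulse_modulations",
            "call_duration",
            "pulse_rate",
            "locality_label",
        }
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown CallParameters fields: {sorted(unknown)}")
        kwargs = dict(d)
        kwargs.setdefault("locality_label", label)
        return cls(**kwargs)

    def to_dict(self) -> dict[str, Any]:
        return {
            "dominant_frequency": self.dominant_frequency,
            "n_pulses": self.n_pulses,
            "pulse_duration": self.pulse_duration,
            "inter_pulse_interval": self.inter_pulse_interval,
            "modulation_depth": self.modulation_depth,
            "n_intra_pulse_modulations": self.n_intra_pulse_modulations,
            "call_duration": self.call_duration,
            "pulse_rate": self.pulse_rate,
            "locality_label": self.locality_label,
        }

    def with_label(self, label: str) -> "CallParameters":
        return replace(self, locality_label=label)


@dataclass(frozen=True)
class StimulusSpec:
    """Playback stimulus train: replicate count and inter-stimulus interval (s)."""

    n_replicates: int = 5
    inter_stimulus_interval: float = 6.0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.inter_stimulus_interval < 0:
            raise ValueError("inter_stimulus_interval must be >= 0")


@dataclass
class Waveform:
    """Mono audio with sample rate and optional onset annotations.

    ``samples`` are dimensionless amplitudes in [-1, 1]; ``annotations`` maps
    marker names (e.g. ``"pulse_onsets_s"``, ``"replicate_onsets_s"``) to arrays
    of onset times in seconds.
    """

    samples: np.ndarray
    sample_rate: float = DEFAULT_SAMPLE_RATE
    annotations: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise ValueError("Waveform is mono: samples must be 1-D")
        if self.samples.size < 1:
            raise ValueError("Waveform must contain at least one sample")
        if self.sample_rate <= 0:
            raise ValueError("sample_rate must be positive")
        if np.max(np.abs(self.samples)) > 1.0 + 1e-12:
            raise ValueError("samples exceed [-1, 1]")
        self.annotations = {
            k: np.asarray(v, dtype=np.float64) for k, v in self.annotations.items()
        }

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def nyquist(self) -> float:
        return self.sample_rate / 2.0

    def time_axis(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate

    def slice_seconds(self, start: float, stop: float) -> "Waveform":
        """Half-open slice [start, stop) in seconds (annotations dropped)."""
        i = max(int(round(start * self.sample_rate)), 0)
        j = min(int(round(stop * self.sample_rate)), self.samples.size)
        if j <= i:
            raise ValueError(f"empty slice [{start:g}, {stop:g}) s")
        return Waveform(self.samples[i:j], self.sample_rate)

    def rms(self) -> float:
        return float(np.sqrt(np.mean(np.square(self.samples))))
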