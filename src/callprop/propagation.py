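"""Parametric propagation model standing in for field transects.

A stimulus broadcast from a point source is re-recorded at fixed distances
(default 0.5, 2, 4, 8 and 16 m). Each channel applies, in order: geometric
(spherical-spreading) attenuation of 20*log10(d/d_ref) dB, habitat excess
attenuation linear in distance per frequency band, reverberant smearing by a
unit-sum exponential kernel, and stationary Gaussian background noise at a
calibrated level. A single calibration constant (digital RMS <-> dB SPL) is
shared by all channels of a transect, as with a common recorder calibrated by
a reference tone.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.signal import fftconvolve

from callprop.metrics import CalibrationReference
from callprop.types import Waveform

Band = tuple[tuple[float, float], float]  # ((f_lo, f_hi) Hz, coefficient dB/m)

DEFAULT_DISTANCES = (0.5, 2.0, 4.0, 8.0, 16.0)


@dataclass(frozen=True)
class TransectConfig:
    """One simulated transect: microphone distances and degradation parameters."""

    distances: tuple[float, ...] = DEFAULT_DISTANCES
    reference_distance: float = 0.5
    source_level_db: float = 90.0  # dB SPL of the call at the reference distance
    excess_attenuation: tuple[Band, ...] = ()
    reverb_decay_s: float = 0.0
    #: Diffuse-tail/direct energy ratio at the reference distance; it grows
    #: linearly with d/d_ref (the direct field decays geometrically, the
    #: reverberant field does not), so far microphones are more smeared.
    reverb_tail_to_direct: float = 0.05
    noise_level_db: float | None = 40.0  # None disables background noise
    lead_noise_s: float = 1.0  # noise-only segment prepended to each channel
    seed: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.distances, dtype=float)
        if d.size < 1 or np.any(np.diff(d) <= 0):
            raise ValueError("distances must be strictly ascending")
        if self.reference_distance <= 0 or d[0] < self.reference_distance:
            raise ValueError("all distances must be >= reference_distance > 0")
        if any(coef < 0 for _, coef in self.excess_attenuation):
            raise ValueError("excess attenuation coefficients must be >= 0")
        if self.reverb_decay_s < 0:
            raise ValueError("reverb_decay_s must be >= 0")
        if self.reverb_tail_to_direct < 0:
            raise ValueError("reverb_tail_to_direct must be >= 0")
        if self.lead_noise_s < 0:
            raise ValueError("lead_noise_s must be >= 0")


@dataclass
class TransectRecording:
    """Calibrated per-distance recordings of one transect.

    Each channel starts with a noise-only lead (span in ``noise_span_s``);
    replicate/pulse onset annotations on each Waveform are already shifted by
    the lead. The calibration maps digital RMS to dB SPL identically across
    channels.
    """

    recordings: dict[float, Waveform]
    calibration: CalibrationReference
    noise_span_s: tuple[float, float]
    config: TransectConfig
    stimulus_annotations: dict[str, np.ndarray] = field(default_factory=dict)

    def calibration_tone(self, duration_s: float = 1.0) -> Waveform:
        """Reference tone (1 kHz at the calibration level) for this transect."""
        fs = next(iter(self.recordings.values())).sample_rate
        t = np.arange(int(round(duration_s * fs))) / fs
        amp = self.calibration.tone_rms_digital * np.sqrt(2.0)
        if amp > 1.0:
            raise ValueError("calibration tone would clip; lower the source level")
        return Waveform(
            amp * np.sin(2.0 * np.pi * self.calibration.tone_frequency_hz * t), fs
        )


def geometric_attenuation_db(d: float, d_ref: float) -> float:
    """Spherical-spreading loss 20*log10(d/d_ref): 6 dB per doubling of distance."""
    if d_ref <= 0 or d < d_ref:
        raise ValueError("require d >= d_ref > 0")
    return 20.0 * np.log10(d / d_ref)


def _validate_bands(bands: Sequence[Band], nyquist: float) -> list[Band]:
    ordered = sorted(bands, key=lambda b: b[0][0])
    prev_hi = -np.inf
    for (lo, hi), coef in ordered:
        if not 0 <= lo < hi:
            raise ValueError(f"invalid band ({lo}, {hi})")
        if hi > nyquist + 1e-9:
            raise ValueError(f"band edge {hi:g} Hz above Nyquist {nyquist:g} Hz")
        if lo < prev_hi:
            raise ValueError("excess-attenuation bands overlap")
        prev_hi = hi
    return ordered


def apply_excess_attenuation(
    wave: Waveform, bands: Sequence[Band], d: float, d_ref: float
) -> Waveform:
    """Habitat filtering: per-band gain of -coefficient*(d - d_ref) dB.

    Implemented as a zero-phase piecewise-constant filter in the frequency
    domain, so pulse onsets are not shifted. Frequencies outside every band
    pass unchanged.
    """
    if d < d_ref:
        raise ValueError("require d >= d_ref")
    ordered = _validate_bands(bands, wave.nyquist)
    if not ordered or d == d_ref:
        return Waveform(wave.samples.copy(), wave.sample_rate, dict(wave.annotations))
    n = wave.samples.size
    freqs = np.fft.rfftfreq(n, 1.0 / wave.sample_rate)
    gains = np.ones_like(freqs)
    for (lo, hi), coef in ordered:
        gains[(freqs >= lo) & (freqs < hi)] = 10.0 ** (-coef * (d - d_ref) / 20.0)
    filtered = np.fft.irfft(np.fft.rfft(wave.samples) * gains, n=n)
    return Waveform(
        np.clip(filtered, -1.0, 1.0), wave.sample_rate, dict(wave.annotations)
    )


#: Default RNG seed for the diffuse reverberation tail, so a bare call of
#: apply_reverberation is deterministic; simulate_transect derives one habitat
#: kernel seed per transect from the config seed.
_REVERB_KERNEL_SEED = 987_654_321
#: Default diffuse-tail to direct-path energy ratio of the reverberation kernel.
_REVERB_TAIL_ENERGY = 0.25


def reverberation_kernel(
    decay: float,
    sample_rate: float,
    seed: int = _REVERB_KERNEL_SEED,
    tail_to_direct: float = _REVERB_TAIL_ENERGY,
) -> np.ndarray:
    """Synthetic impulse response: direct path + exponentially decaying diffuse tail.

    The tail is carrier-band noise under an ``exp(-t/decay)`` envelope (a smooth
    positive kernel of that shape would act as a sub-audio low-pass and erase
    the carrier instead of smearing the envelope). The kernel is normalized so
    that its transfer-function magnitude never exceeds one: no frequency gains
    energy, hence signal energy never increases through this stage.
    """
    if tail_to_direct < 0:
        raise ValueError("tail_to_direct must be >= 0")
    fs = sample_rate
    n = max(int(round(8.0 * decay * fs)), 2)
    rng = np.random.default_rng(seed)
    tail = rng.standard_normal(n) * np.exp(-np.arange(n) / (decay * fs))
    norm = np.linalg.norm(tail)
    tail *= np.sqrt(tail_to_direct) / norm if norm > 0 else 0.0
    kernel = tail
    kernel[0] += 1.0  # direct path
    # Evaluate |H| on a dense grid; small margin guards interpolation between bins.
    mag = np.abs(np.fft.rfft(kernel, n=8 * n))
    kernel /= 1.001 * float(np.max(mag))
    return kernel


def apply_reverberation(
    wave: Waveform,
    decay: float,
    seed: int = _REVERB_KERNEL_SEED,
    tail_to_direct: float = _REVERB_TAIL_ENERGY,
) -> Waveform:
    """Convolve with the exponential-decay reverberation kernel.

    ``decay`` is the tail time constant in seconds (0 disables). Reverberant
    smearing fills inter-pulse gaps and intra-pulse troughs, so measured
    modulation depth drops; the colored tail spectrum (comb-like fading) also
    lowers spectral cross-correlation against the clean reference. ``seed``
    selects the realization of the diffuse tail; the default gives one fixed
    kernel per (decay, sample rate). ``tail_to_direct`` sets the tail energy
    relative to the direct path.
    """
    if decay < 0:
        raise ValueError("decay must be >= 0")
    if decay == 0:
        return Waveform(wave.samples.copy(), wave.sample_rate, dict(wave.annotations))
    kernel = reverberation_kernel(decay, wave.sample_rate, seed, tail_to_direct)
    out = fftconvolve(wave.samples, kernel)[: wave.samples.size]
    return Waveform(np.clip(out, -1.0, 1.0), wave.sample_rate, dict(wave.annotations))


def add_noise(
    wave: Waveform,
    noise_level_db: float | None,
    calib: CalibrationReference,
    seed: int,
) -> Waveform:
    """Add stationary white Gaussian noise at a calibrated broadband SPL.

    Reproducible for a given seed; ``None`` level returns the input unchanged.
    Raises if the noisy signal would clip.
    """
    if noise_level_db is None:
        return Waveform(wave.samples.copy(), wave.sample_rate, dict(wave.annotations))
    rng = np.random.default_rng(seed)
    sigma = calib.rms_for_spl(noise_level_db)
    noisy = wave.samples + rng.normal(0.0, sigma, wave.samples.size)
    peak = float(np.max(np.abs(noisy)))
    if peak > 1.0:
        raise ValueError(f"noise addition clips (peak {peak:.3f}); lower the levels")
    return Waveform(noisy, wave.sample_rate, dict(wave.annotations))


def simulate_transect(stimulus: Waveform, config: TransectConfig) -> TransectRecording:
    """Record a stimulus train at every configured distance.

    The calibration constant is chosen so the first replicate of the stimulus
    measures ``source_level_db`` dB SPL at the reference distance. Each channel
    is the attenuated/filtered/reverberated stimulus preceded by a noise-only
    lead; annotations are shifted by the lead duration.
    """
    fs = stimulus.sample_rate
    ref_rms = _active_rms(stimulus)
    # Recorder gain: scale the whole transect so the 94-dB reference tone sits
    # at 0.9 digital peak — headroom against clipping; calibration absorbs it.
    tone_rms = 0.9 / np.sqrt(2.0)
    digital_gain = tone_rms / (
        ref_rms * 10.0 ** ((94.0 - config.source_level_db) / 20.0)
    )
    calib = CalibrationReference(tone_rms_digital=tone_rms)
    peak_near = float(np.max(np.abs(stimulus.samples))) * digital_gain
    if peak_near > 1.0:
        raise ValueError(
            f"source level {config.source_level_db:g} dB SPL overloads the recorder "
            "gain set by the 94-dB reference tone (nearest channel would clip)"
        )
    lead = np.zeros(int(round(config.lead_noise_s * fs)))
    lead_s = lead.size / fs
    seeds = np.random.SeedSequence(config.seed).generate_state(len(config.distances) + 1)
    habitat_seed = int(seeds[0]) % 2**31  # one reverberant habitat per transect
    recordings: dict[float, Waveform] = {}
    for i, d in enumerate(config.distances):
        gain = digital_gain * 10.0 ** (
            -geometric_attenuation_db(d, config.reference_distance) / 20.0
        )
        chan = Waveform(stimulus.samples * gain, fs, dict(stimulus.annotations))
        chan = apply_excess_attenuation(
            chan, config.excess_attenuation, d, config.reference_distance
        )
        chan = apply_reverberation(
            chan,
            config.reverb_decay_s,
            habitat_seed,
            config.reverb_tail_to_direct * d / config.reference_distance,
        )
        child_seed = seeds[i + 1]
        shifted = {k: v + lead_s for k, v in chan.annotations.items()}
        chan = Waveform(np.concatenate([lead, chan.samples]), fs, shifted)
        chan = add_noise(chan, config.noise_level_db, calib, int(child_seed) % 2**31)
        recordings[d] = chan
    return TransectRecording(
        recordings=recordings,
        calibration=calib,
        noise_span_s=(0.0, lead_s),
        config=config,
        stimulus_annotations={k: v + lead_s for k, v in stimulus.annotations.items()},
    )


def _active_rms(stimulus: Waveform) -> float:
    """RMS over the active (non-silent) portion of the stimulus.

    Silent inter-stimulus gaps would otherwise dilute the level the source
    calibration refers to.
    """
    peak = float(np.max(np.abs(stimulus.samples)))
    if peak <= 0:
        raise ValueError("silent stimulus cannot be broadcast")
    active = stimulus.samples[np.abs(stimulus.samples) > 0.01 * peak]
    return float(np.sqrt(np.mean(np.square(active))))
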