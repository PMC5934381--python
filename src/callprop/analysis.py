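"""Envelope-threshold call segmentation, the seven call variables, and the
covariate correction.

The measurement chain mirrors the classic automated routine for pulsed anuran
calls: the amplitude envelope is the modulus of the analytic signal (Hilbert
transform), an amplitude threshold relative to the envelope maximum yields a
presence/absence logical vector, runs of presence are pulses, pulses closer
than a call gap belong to one call, and from the segmentation the five temporal
variables (call duration, pulse count, mean pulse duration, mean inter-pulse
interval, pulse rate) plus modulation depth and dominant frequency are
extracted. Variables correlated with water temperature (temporal variables) or
snout-vent length (dominant frequency) are adjusted to the covariate grand mean
via ``Ycorr = Y - b*Xmeasured + b*Xmean``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.signal import get_window, hilbert
from scipy.stats import linregress

from callprop.types import Waveform

#: Default threshold on the envelope, as a fraction of its maximum.
DEFAULT_THRESHOLD_FRACTION = 0.1
#: Secondary (low) fraction used to refine pulse boundaries outward.
DEFAULT_REFINE_FRACTION = 0.01
#: Interior guard stripped from each pulse edge before measuring modulation
#: depth, slightly wider than the synthesis rise/fall gates.
DEFAULT_EDGE_GUARD_S = 0.0025
DEFAULT_FFT_LENGTH = 4096


@dataclass
class Envelope:
    """Amplitude envelope, optionally block-averaged.

    Smoothing averages the Hilbert modulus over non-overlapping windows of
    ``smoothing_window`` samples, so ``sample_rate_effective`` is the original
    rate divided by the window (one envelope point per block).
    """

    values: np.ndarray
    sample_rate_effective: float
    smoothing_window: int = 1

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 1 or self.values.size < 1:
            raise ValueError("envelope must be a non-empty 1-D sequence")
        if np.any(self.values < 0):
            raise ValueError("envelope values must be non-negative")

    def time_axis(self) -> np.ndarray:
        return np.arange(self.values.size) / self.sample_rate_effective


@dataclass
class CallSegmentation:
    """Detected call and pulse spans (seconds, half-open intervals)."""

    calls: list[tuple[float, float]]
    pulses: list[list[tuple[float, float]]]
    threshold_used: float

    @property
    def n_calls(self) -> int:
        return len(self.calls)


@dataclass
class CallFeatures:
    """The seven call variables for one call."""

    call_duration: float
    n_pulses: int
    mean_pulse_duration: float
    mean_inter_pulse_interval: float  # NaN for single-pulse calls
    pulse_rate: float
    modulation_depth: float
    dominant_frequency: float

    def as_dict(self) -> dict[str, float]:
        return {
            "call_duration": self.call_duration,
            "n_pulses": float(self.n_pulses),
            "mean_pulse_duration": self.mean_pulse_duration,
            "mean_inter_pulse_interval": self.mean_inter_pulse_interval,
            "pulse_rate": self.pulse_rate,
            "modulation_depth": self.modulation_depth,
            "dominant_frequency": self.dominant_frequency,
        }


@dataclass
class CorrectionModel:
    """Covariate-correction model: OLS slope, covariate grand mean, Pearson r/p."""

    b: float
    x_mean: float
    r: float
    p: float
    apply: bool


def compute_envelope(wave: Waveform, smoothing_window: int = 1) -> Envelope:
    """Hilbert-modulus envelope, block-averaged over non-overlapping windows.

    ``smoothing_window=1`` returns the raw modulus at full rate. A trailing
    partial block is discarded.
    """
    if smoothing_window < 1:
        raise ValueError("smoothing_window must be >= 1")
    n = wave.samples.size
    if smoothing_window > n:
        raise ValueError(
            f"smoothing_window {smoothing_window} longer than signal ({n} samples)"
        )
    env = np.abs(hilbert(wave.samples))
    if smoothing_window == 1:
        return Envelope(env, wave.sample_rate, 1)
    n_blocks = n // smoothing_window
    blocks = env[: n_blocks * smoothing_window].reshape(n_blocks, smoothing_window)
    return Envelope(
        blocks.mean(axis=1), wave.sample_rate / smoothing_window, smoothing_window
    )


def _runs_of_ones(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index runs where mask is True."""
    padded = np.concatenate(([0], mask.astype(np.int8), [0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    stops = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), stops.tolist()))


def _bridge_gaps(runs: list[tuple[int, int]], max_gap: int) -> list[tuple[int, int]]:
    if not runs or max_gap <= 0:
        return runs
    merged = [runs[0]]
    for start, stop in runs[1:]:
        if start - merged[-1][1] < max_gap:
            merged[-1] = (merged[-1][0], stop)
        else:
            merged.append((start, stop))
    return merged


def _refine_boundaries(
    runs: list[tuple[int, int]], values: np.ndarray, low: float
) -> list[tuple[int, int]]:
    """Extend each run outward to the crossing of a lower threshold.

    Thresholding at the detection fraction places boundaries partway up the
    pulse onset ramp; walking out to a low secondary threshold moves them back
    toward the true rise/fall feet. Extension never crosses a neighbouring run.
    """
    refined: list[tuple[int, int]] = []
    n = values.size
    for i, (start, stop) in enumerate(runs):
        left_limit = runs[i - 1][1] if i > 0 else 0
        right_limit = runs[i + 1][0] if i + 1 < len(runs) else n
        while start > left_limit and values[start - 1] >= low:
            start -= 1
        while stop < right_limit and values[stop] >= low:
            stop += 1
        refined.append((start, stop))
    return refined


def segment_calls(
    env: Envelope,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
    min_gap_pulse: float = 0.0,
    min_gap_call: float = 0.5,
    refine_fraction: float | None = DEFAULT_REFINE_FRACTION,
) -> CallSegmentation:
    """Threshold the envelope into pulses and group pulses into calls.

    The logical vector is ``env >= threshold_fraction * max(env)``; runs of
    presence are pulses. Gaps shorter than ``min_gap_pulse`` (s) are bridged
    (replacing manual correction of segmentation errors); consecutive pulses
    separated by less than ``min_gap_call`` (s) belong to one call. With
    ``refine_fraction`` set, pulse boundaries are extended outward to that
    lower fraction of the maximum.

    A silent envelope (or none above threshold) yields an empty segmentation.
    """
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must lie in (0, 1)")
    if min_gap_pulse < 0 or min_gap_call <= min_gap_pulse:
        raise ValueError("require min_gap_call > min_gap_pulse >= 0")
    if refine_fraction is not None and not 0.0 < refine_fraction <= threshold_fraction:
        raise ValueError("refine_fraction must lie in (0, threshold_fraction]")
    peak = float(np.max(env.values))
    if peak <= 0.0:
        return CallSegmentation([], [], threshold_fraction)
    rate = env.sample_rate_effective
    mask = env.values >= threshold_fraction * peak
    runs = _runs_of_ones(mask)
    if not runs:
        return CallSegmentation([], [], threshold_fraction)
    runs = _bridge_gaps(runs, int(math.ceil(min_gap_pulse * rate)))
    if refine_fraction is not None:
        runs = _refine_boundaries(runs, env.values, refine_fraction * peak)

    calls: list[tuple[float, float]] = []
    pulses: list[list[tuple[float, float]]] = []
    current: list[tuple[int, int]] = [runs[0]]
    for run in runs[1:]:
        gap_s = (run[0] - current[-1][1]) / rate
        if gap_s < min_gap_call:
            current.append(run)
        else:
            calls.append((current[0][0] / rate, current[-1][1] / rate))
            pulses.append([(a / rate, b / rate) for a, b in current])
            current = [run]
    calls.append((current[0][0] / rate, current[-1][1] / rate))
    pulses.append([(a / rate, b / rate) for a, b in current])
    return CallSegmentation(calls, pulses, threshold_fraction)


def envelope_modulation_depth(
    env: Envelope, span: tuple[float, float], edge_guard_s: float = 0.0
) -> float:
    """``100 * (max - min) / max`` of the envelope inside a pulse span.

    ``edge_guard_s`` strips the rise/fall feet at each edge so the depth
    reflects the intra-pulse modulation rather than the gating ramps.
    """
    rate = env.sample_rate_effective
    i = int(math.ceil((span[0] + edge_guard_s) * rate))
    j = int(math.floor((span[1] - edge_guard_s) * rate))
    if j - i < 2:
        # Guarded interior too short (e.g. very short pulse): fall back to the
        # ungated span.
        i = int(math.ceil(span[0] * rate))
        j = int(math.floor(span[1] * rate))
    seg = env.values[max(i, 0) : j]
    if seg.size < 1 or np.max(seg) <= 0:
        return float("nan")
    vmax = float(np.max(seg))
    vmin = float(np.min(seg))
    return 100.0 * (vmax - vmin) / vmax


def central_pulse_index(n_pulses: int) -> int:
    """0-based index of the central pulse: ceil(n/2) in 1-based terms."""
    return (n_pulses + 1) // 2 - 1


def dominant_frequency_of(
    wave: Waveform, span: tuple[float, float], fft_length: int = DEFAULT_FFT_LENGTH
) -> float:
    """Peak of the Hann-windowed magnitude spectrum of a span (zero-padded)."""
    seg = wave.slice_seconds(*span).samples
    nfft = max(fft_length, 1 << (seg.size - 1).bit_length())
    win = get_window("hann", seg.size)
    spectrum = np.abs(np.fft.rfft(seg * win, n=nfft))
    freqs = np.fft.rfftfreq(nfft, 1.0 / wave.sample_rate)
    return float(freqs[int(np.argmax(spectrum))])


def extract_features(
    wave: Waveform,
    seg: CallSegmentation,
    fft_length: int = DEFAULT_FFT_LENGTH,
    edge_guard_s: float = DEFAULT_EDGE_GUARD_S,
) -> list[CallFeatures]:
    """Measure the seven variables for every segmented call.

    Modulation depth and dominant frequency are measured on the central pulse
    (1-based index ``ceil(n/2)``); the dominant frequency comes from a
    Hann-windowed FFT zero-padded to at least ``fft_length`` points.
    """
    env = compute_envelope(wave, 1)
    out: list[CallFeatures] = []
    for span, pulse_spans in zip(seg.calls, seg.pulses):
        if not pulse_spans:
            raise ValueError("call without pulses")
        onsets = np.array([p[0] for p in pulse_spans])
        offsets = np.array([p[1] for p in pulse_spans])
        duration = float(offsets[-1] - onsets[0])
        if duration <= 0:
            raise ValueError(f"zero-duration call at {span[0]:g} s")
        n = len(pulse_spans)
        mean_pd = float(np.mean(offsets - onsets))
        mean_ipi = float(np.mean(onsets[1:] - offsets[:-1])) if n > 1 else float("nan")
        central = pulse_spans[central_pulse_index(n)]
        out.append(
            CallFeatures(
                call_duration=duration,
                n_pulses=n,
                mean_pulse_duration=mean_pd,
                mean_inter_pulse_interval=mean_ipi,
                pulse_rate=n / duration,
                modulation_depth=envelope_modulation_depth(env, central, edge_guard_s),
                dominant_frequency=dominant_frequency_of(wave, central, fft_length),
            )
        )
    return out


def fit_correction(y, x, alpha: float = 0.05) -> CorrectionModel:
    """OLS regression of a call variable on a covariate.

    Returns the slope ``b``, the covariate grand mean, Pearson ``r`` with its
    two-sided ``p``, and ``apply = (p < alpha)`` — only significantly
    correlated variables are corrected.
    """
    y = np.asarray(y, dtype=np.float64)
    x = np.asarray(x, dtype=np.float64)
    if y.shape != x.shape or y.ndim != 1:
        raise ValueError("y and x must be 1-D and paired")
    if y.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0:
        raise ValueError("covariate is constant; correction undefined")
    if np.ptp(y) == 0:
        # Degenerate flat response: slope 0, no correction.
        return CorrectionModel(0.0, float(np.mean(x)), 0.0, 1.0, False)
    fit = linregress(x, y)
    return CorrectionModel(
        b=float(fit.slope),
        x_mean=float(np.mean(x)),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        apply=bool(fit.pvalue < alpha),
    )


def correct_variable(y: float, model: CorrectionModel, x_measured: float) -> float:
    """Adjust a call variable to the covariate grand mean.

    ``Ycorr = Y - b*Xmeasured + b*Xmean``; the identity when the model was not
    significant (``apply`` False).
    """
    if not model.apply:
        return y
    return y - model.b * x_measured + model.b * model.x_mean
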