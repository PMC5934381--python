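"""Synthetic advertisement-call generation.

A call is a train of tone pulses: a sinusoidal carrier at the dominant
frequency, shaped by a raised-cosine intra-pulse amplitude modulator and short
cosine rise/fall gates, with silent inter-pulse intervals. Stimulus trains
repeat a call with a fixed inter-stimulus interval, mimicking the playback
protocol (five replicates, 6-s interval) used in transmission experiments.

The modulator is ``e(t) = 1 - (d/100) * (1 + cos(2*pi*k*t/T)) / 2`` with depth
``d`` percent, ``k`` intra-pulse modulation cycles and pulse duration ``T``:
minima sit at the pulse edges, the interior carries exactly ``k`` envelope
maxima, and ``100*(max-min)/max = d`` by construction. Synthesis is fully
deterministic.
"""

from __future__ import annotations

import numpy as np

from callprop.types import DEFAULT_SAMPLE_RATE, CallParameters, StimulusSpec, Waveform

#: Default peak amplitude of synthesized calls (headroom below PCM16 full scale).
DEFAULT_AMPLITUDE = 0.9
#: Cosine rise/fall gate duration at each pulse edge (s).
EDGE_RAMP_S = 0.002


def _edge_gate(n: int, sample_rate: float, ramp_s: float) -> np.ndarray:
    """Cosine rise/fall window; ramps shrink for pulses shorter than 2 ramps."""
    gate = np.ones(n)
    n_ramp = min(int(round(ramp_s * sample_rate)), n // 2)
    if n_ramp > 0:
        ramp = 0.5 * (1.0 - np.cos(np.pi * np.arange(n_ramp) / n_ramp))
        gate[:n_ramp] = ramp
        gate[-n_ramp:] = ramp[::-1]
    return gate


def synthesize_pulse(
    params: CallParameters,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    amplitude: float = DEFAULT_AMPLITUDE,
    ramp_s: float = EDGE_RAMP_S,
) -> Waveform:
    """One amplitude-modulated tone pulse.

    Parameters
    ----------
    params
        Carrier frequency, pulse duration, modulation depth (percent) and the
        number of intra-pulse modulation cycles are read from here.
    sample_rate
        Output rate in Hz; the carrier must lie below Nyquist.
    amplitude
        Peak amplitude of the pulse (dimensionless, < 1 for 16-bit headroom).
    ramp_s
        Rise/fall gate length at each edge.
    """
    params.validate_for_rate(sample_rate)
    if not 0 < amplitude <= 1.0 - 2.0 ** -15:
        raise ValueError("amplitude must lie in (0, 1 - 2^-15]")
    n = int(round(params.pulse_duration * sample_rate))
    if n < 2:
        raise ValueError("pulse_duration too short for the sample rate")
    t = np.arange(n) / sample_rate
    carrier = np.sin(2.0 * np.pi * params.dominant_frequency * t)
    d = params.modulation_depth / 100.0
    k = params.n_intra_pulse_modulations
    if k > 0 and d > 0:
        modulator = 1.0 - d * (1.0 + np.cos(2.0 * np.pi * k * t / params.pulse_duration)) / 2.0
    else:
        modulator = np.ones(n)
    gate = _edge_gate(n, sample_rate, ramp_s)
    samples = amplitude * carrier * modulator * gate
    return Waveform(
        samples,
        sample_rate,
        annotations={"pulse_onsets_s": np.array([0.0])},
    )


def synthesize_call(
    params: CallParameters,
    sample_rate: float = DEFAULT_SAMPLE_RATE,
    amplitude: float = DEFAULT_AMPLITUDE,
    ramp_s: float = EDGE_RAMP_S,
) -> Waveform:
    """Full call: ``n_pulses`` identical pulses separated by silent intervals.

    Pulse onset times are recorded in ``annotations["pulse_onsets_s"]``; the
    non-silent structure matches ``params.call_duration`` to within one sample
    per pulse boundary.
    """
    pulse = synthesize_pulse(params, sample_rate, amplitude, ramp_s)
    if params.n_pulses == 1:
        return pulse
    gap = np.zeros(int(round(params.inter_pulse_interval * sample_rate)))
    period = pulse.samples.size + gap.size
    pieces = []
    for i in range(params.n_pulses):
        pieces.append(pulse.samples)
        if i < params.n_pulses - 1:
            pieces.append(gap)
    onsets = np.arange(params.n_pulses) * period / sample_rate
    return Waveform(
        np.concatenate(pieces), sample_rate, annotations={"pulse_onsets_s": onsets}
    )


def build_stimulus_train(call: Waveform, spec: StimulusSpec) -> Waveform:
    """Playback train: replicate copies of a call separated by silence.

    Gaps are inserted between copies only (no leading/trailing silence).
    Replicate onsets are annotated, and per-replicate pulse onsets are tiled
    from the call's own annotations when present.
    """
    if spec.n_replicates == 1:
        return Waveform(
            call.samples.copy(),
            call.sample_rate,
            annotations={**call.annotations, "replicate_onsets_s": np.array([0.0])},
        )
    gap = np.zeros(int(round(spec.inter_stimulus_interval * call.sample_rate)))
    period_s = (call.samples.size + gap.size) / call.sample_rate
    pieces = []
    for i in range(spec.n_replicates):
        pieces.append(call.samples)
        if i < spec.n_replicates - 1:
            pieces.append(gap)
    onsets = np.arange(spec.n_replicates) * period_s
    annotations: dict[str, np.ndarray] = {"replicate_onsets_s": onsets}
    if "pulse_onsets_s" in call.annotations:
        annotations["pulse_onsets_s"] = np.concatenate(
            [call.annotations["pulse_onsets_s"] + o for o in onsets]
        )
    return Waveform(np.concatenate(pieces), call.sample_rate, annotations=annotations)
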