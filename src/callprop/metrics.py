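"""Attenuation and degradation statistics for transect recordings.

Recordings are calibrated against a 1-kHz reference tone at 94 dB SPL RMS.
Per replicate and distance the module measures: sound pressure level with
power-subtraction noise correction, transmitted modulation depth from a
400-point block-averaged Hilbert envelope, and spectral cross-correlation
(SCC) — the zero-lag Pearson correlation between mean power spectra (440-point
Hann windows, 0 % overlap: 100.227 Hz frequency and 9.977 ms temporal
resolution at 44.1 kHz) at the reference distance and farther distances.
SPL and modulation depth are standardized per transect and call origin by the
highest reference-distance value (SSPL on the linear amplitude scale, SMD on
the percentage scale), replicates are averaged, and local-versus-foreign
origin contrasts are evaluated with a within-transect permutation test.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd
from scipy.signal import welch

from callprop.analysis import (
    central_pulse_index,
    compute_envelope,
    dominant_frequency_of,
    envelope_modulation_depth,
)
from callprop.types import CallParameters, Waveform

if TYPE_CHECKING:  # pragma: no cover - typing only, avoids an import cycle
    from callprop.propagation import TransectRecording

#: Envelope smoothing used for transmitted modulation depth (samples).
DEPTH_SMOOTHING_WINDOW = 400
#: FFT window for mean power spectra (samples): 100.227 Hz bins at 44.1 kHz.
SPECTRUM_WINDOW_LENGTH = 440
#: Default upper frequency bound for SCC (call energy band).
DEFAULT_SCC_FMAX_HZ = 10_000.0

TABLE_COLUMNS = [
    "transect",
    "origin",
    "distance_m",
    "replicate",
    "spl_db",
    "modulation_depth_pct",
    "scc",
]


@dataclass(frozen=True)
class CalibrationReference:
    """Digital RMS <-> dB SPL mapping from a reference tone."""

    tone_rms_digital: float
    tone_level_db: float = 94.0
    tone_frequency_hz: float = 1000.0

    def __post_init__(self) -> None:
        if self.tone_rms_digital <= 0:
            raise ValueError("tone_rms_digital must be positive")

    def spl(self, segment: Waveform | float) -> float:
        """Calibrated SPL of a segment (or of a raw digital RMS value)."""
        rms = segment.rms() if isinstance(segment, Waveform) else float(segment)
        if rms <= 0:
            return float("-inf")
        return self.tone_level_db + 20.0 * math.log10(rms / self.tone_rms_digital)

    def rms_for_spl(self, level_db: float) -> float:
        return self.tone_rms_digital * 10.0 ** ((level_db - self.tone_level_db) / 20.0)


@dataclass
class MeanPowerSpectrum:
    """Average of per-window power spectra (non-overlapping Hann windows)."""

    frequencies: np.ndarray
    powers: np.ndarray
    bin_spacing: float
    window_length: int
    window_type: str = "hann"
    overlap: float = 0.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=np.float64)
        self.powers = np.asarray(self.powers, dtype=np.float64)
        if self.frequencies.shape != self.powers.shape:
            raise ValueError("frequency and power grids differ in length")
        if np.any(self.powers < 0):
            raise ValueError("band powers must be non-negative")


def calibrate(tone_segment: Waveform, tone_level_db: float = 94.0) -> CalibrationReference:
    """Build the digital-RMS-to-SPL map from a recorded calibration tone.

    The segment must be at least 0.1 s; its dominant frequency is checked
    against 1000 +/- 50 Hz (a mismatch warns but proceeds, covering re-use of
    the routine with a non-standard calibrator).
    """
    if tone_segment.duration < 0.1:
        raise ValueError("calibration tone must be at least 0.1 s")
    rms = tone_segment.rms()
    if rms <= 0:
        raise ValueError("silent calibration segment")
    f_peak = dominant_frequency_of(tone_segment, (0.0, tone_segment.duration))
    if abs(f_peak - 1000.0) > 50.0:
        warnings.warn(
            f"calibration tone peak at {f_peak:.0f} Hz, expected 1000 +/- 50 Hz",
            stacklevel=2,
        )
    return CalibrationReference(tone_rms_digital=rms, tone_level_db=tone_level_db)


def noise_corrected_spl(
    call_segment: Waveform, noise_segment: Waveform, calib: CalibrationReference
) -> float:
    """SPL of a call embedded in noise, by power subtraction.

    ``L = 10*log10(10^(Lmeas/10) - 10^(Lnoise/10))`` with both levels under the
    same calibration. Returns NaN (flagged missing) when the noise level
    reaches the measured level — the signal is below the noise floor.
    """
    l_meas = calib.spl(call_segment)
    l_noise = calib.spl(noise_segment)
    if l_noise >= l_meas:
        warnings.warn(
            f"noise level {l_noise:.1f} dB >= measured {l_meas:.1f} dB; "
            "flagging SPL as missing",
            stacklevel=2,
        )
        return float("nan")
    return 10.0 * math.log10(10.0 ** (l_meas / 10.0) - 10.0 ** (l_noise / 10.0))


def mean_power_spectrum(
    segment: Waveform, window_length: int = SPECTRUM_WINDOW_LENGTH
) -> MeanPowerSpectrum:
    """Mean power spectrum over non-overlapping Hann windows.

    With the default 440-point window at 44.1 kHz the bin spacing is
    44100/440 = 100.227 Hz and the window spans 9.977 ms. A trailing partial
    window is discarded.
    """
    n = segment.samples.size
    if n < window_length:
        raise ValueError(
            f"segment of {n} samples shorter than the {window_length}-point window"
        )
    freqs, powers = welch(
        segment.samples,
        fs=segment.sample_rate,
        window="hann",
        nperseg=window_length,
        noverlap=0,
        detrend=False,
        scaling="spectrum",
    )
    return MeanPowerSpectrum(
        frequencies=freqs,
        powers=powers,
        bin_spacing=segment.sample_rate / window_length,
        window_length=window_length,
    )


def scc(
    spec_ref: MeanPowerSpectrum,
    spec_far: MeanPowerSpectrum,
    fmax_hz: float | None = DEFAULT_SCC_FMAX_HZ,
    scale: str = "linear",
) -> float:
    """Zero-lag spectral cross-correlation between two mean power spectra.

    Pearson correlation of the band-power vectors, restricted to frequencies
    at or below ``fmax_hz`` (None for full band). ``scale`` selects linear
    power (default) or ``"db"``. Constant spectra have no defined correlation
    and yield NaN (flagged missing).
    """
    if spec_ref.frequencies.shape != spec_far.frequencies.shape or not np.allclose(
        spec_ref.frequencies, spec_far.frequencies
    ):
        raise ValueError("spectra are on different frequency grids")
    mask = (
        np.ones_like(spec_ref.frequencies, dtype=bool)
        if fmax_hz is None
        else spec_ref.frequencies <= fmax_hz
    )
    a = spec_ref.powers[mask]
    b = spec_far.powers[mask]
    if scale == "db":
        floor = 1e-30
        a = 10.0 * np.log10(np.maximum(a, floor))
        b = 10.0 * np.log10(np.maximum(b, floor))
    elif scale != "linear":
        raise ValueError("scale must be 'linear' or 'db'")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant spectrum: SCC undefined, flagged missing", stacklevel=2)
        return float("nan")
    a = a - a.mean()
    b = b - b.mean()
    return float(np.dot(a, b) / np.sqrt(np.dot(a, a) * np.dot(b, b)))


def transmitted_modulation_depth(
    segment: Waveform,
    smoothing_window: int = DEPTH_SMOOTHING_WINDOW,
    pulse_span_s: tuple[float, float] | None = None,
    threshold_fraction: float = 0.1,
    edge_guard_s: float = 0.0025,
) -> float:
    """Modulation depth of a transmitted call from the smoothed envelope.

    The envelope is the Hilbert modulus averaged over non-overlapping
    ``smoothing_window``-sample blocks (no overlap). Depth is
    ``100*(max-min)/max`` within the pulse: either an explicitly supplied span
    (seconds, relative to the segment) or, failing that, the central pulse
    found by thresholding the smoothed envelope.
    """
    if segment.samples.size < smoothing_window:
        raise ValueError("segment shorter than the smoothing window")
    env = compute_envelope(segment, smoothing_window)
    if pulse_span_s is None:
        from callprop.analysis import segment_calls  # local import, light dependency

        seg = segment_calls(
            env,
            threshold_fraction=threshold_fraction,
            min_gap_call=math.inf,
            refine_fraction=None,
        )
        if not seg.pulses or not seg.pulses[0]:
            raise ValueError("no pulse found above threshold in segment")
        pulses = seg.pulses[0]
        pulse_span_s = pulses[central_pulse_index(len(pulses))]
    return envelope_modulation_depth(env, pulse_span_s, edge_guard_s)


# ---------------------------------------------------------------------------
# Degradation table construction and summaries
# ---------------------------------------------------------------------------

def degradation_table(
    rec: "TransectRecording",
    params: CallParameters,
    transect_id: str,
    scc_fmax_hz: float | None = DEFAULT_SCC_FMAX_HZ,
    min_snr_db: float = 3.0,
) -> pd.DataFrame:
    """Score one transect recording of one call origin, per replicate/distance.

    For each replicate span (from the stimulus annotations) and distance:
    noise-corrected SPL over the call span, transmitted modulation depth of the
    central pulse, and SCC of the replicate's mean power spectrum against the
    same replicate at the reference distance. Replicates whose envelope SNR
    falls below ``min_snr_db`` are flagged missing (NaN), mirroring the visual
    screening of noisy segments.
    """
    calib = rec.calibration
    d_ref = rec.config.reference_distance
    onsets = rec.stimulus_annotations.get("replicate_onsets_s")
    if onsets is None:
        raise ValueError("recording lacks replicate onset annotations")
    call_len = params.call_duration
    central = central_pulse_index(params.n_pulses)
    pulse_rel_on = central * (params.pulse_duration + params.inter_pulse_interval)
    pulse_rel = (pulse_rel_on, pulse_rel_on + params.pulse_duration)
    # Allow the reverberant tail inside the analysis span.
    tail = 2.0 * rec.config.reverb_decay_s

    ref_wave = rec.recordings[d_ref]
    ref_spectra = [
        mean_power_spectrum(ref_wave.slice_seconds(o, o + call_len + tail))
        for o in onsets
    ]

    rows = []
    for d, wave in rec.recordings.items():
        noise_seg = None
        l_noise = float("-inf")
        if rec.noise_span_s[1] > rec.noise_span_s[0]:
            noise_seg = wave.slice_seconds(*rec.noise_span_s)
            l_noise = calib.spl(noise_seg)
        for r, onset in enumerate(onsets):
            span = (float(onset), float(onset) + call_len + tail)
            call_seg = wave.slice_seconds(*span)
            l_meas = calib.spl(call_seg)
            if l_meas - l_noise < min_snr_db:
                spl = md = s = float("nan")
            else:
                spl = (
                    noise_corrected_spl(call_seg, noise_seg, calib)
                    if noise_seg is not None
                    else l_meas
                )
                md = transmitted_modulation_depth(call_seg, pulse_span_s=pulse_rel)
                s = scc(ref_spectra[r], mean_power_spectrum(call_seg), fmax_hz=scc_fmax_hz)
            rows.append(
                {
                    "transect": transect_id,
                    "origin": params.locality_label,
                    "distance_m": d,
                    "replicate": r,
                    "spl_db": spl,
                    "modulation_depth_pct": md,
                    "scc": s,
                }
            )
    return pd.DataFrame(rows, columns=TABLE_COLUMNS)


def standardize_by_origin(
    table: pd.DataFrame, reference_distance: float | None = None
) -> pd.DataFrame:
    """Add SSPL and SMD columns, standardized per (transect, origin).

    The divisor is the highest value of that origin at the shortest distance
    of its transect (or an explicit ``reference_distance``). SPL is
    standardized on the linear amplitude scale —
    ``SSPL = 10^((SPL - SPL_ref_max)/20)`` — so pure spherical spreading gives
    ``SSPL = d_ref/d``; modulation depth is a percentage and is divided
    directly. Groups lacking reference-distance rows are dropped with a
    warning. Exactly one row per group has SSPL = 1.
    """
    out_groups = []
    for (transect, origin), grp in table.groupby(["transect", "origin"], sort=True):
        d_ref = reference_distance
        if d_ref is None:
            d_ref = float(grp["distance_m"].min())
        ref_rows = grp[np.isclose(grp["distance_m"], d_ref)]
        if ref_rows.empty or ref_rows["spl_db"].isna().all():
            warnings.warn(
                f"group ({transect}, {origin}) lacks usable reference-distance rows; "
                "dropped from standardization",
                stacklevel=2,
            )
            continue
        grp = grp.copy()
        spl_ref_max = ref_rows["spl_db"].max()
        md_ref_max = ref_rows["modulation_depth_pct"].max()
        grp["sspl"] = 10.0 ** ((grp["spl_db"] - spl_ref_max) / 20.0)
        grp["smd"] = (
            grp["modulation_depth_pct"] / md_ref_max if md_ref_max > 0 else np.nan
        )
        out_groups.append(grp)
    if not out_groups:
        raise ValueError("no group contained reference-distance rows")
    return pd.concat(out_groups, ignore_index=True)


def average_replicates(table: pd.DataFrame) -> pd.DataFrame:
    """Mean of every metric over replicates within (transect, origin, distance).

    Flagged-missing (NaN) replicates are excluded from each mean; a cell with
    no valid replicate stays missing.
    """
    if "replicate" not in table.columns:
        raise ValueError("table lacks a replicate column")
    value_cols = [
        c
        for c in table.columns
        if c not in ("transect", "origin", "distance_m", "replicate")
    ]
    return (
        table.groupby(["transect", "origin", "distance_m"], sort=True)[value_cols]
        .mean()
        .reset_index()
    )


def local_vs_foreign_summary(
    table: pd.DataFrame,
    locality: str,
    n_permutations: int = 10_000,
    seed: int = 0,
    metrics: Sequence[str] = ("sspl", "smd", "scc"),
) -> pd.DataFrame:
    """Contrast local against foreign call origins, per distance and overall.

    For each metric the contrast is ``mean(local) - mean(foreign)`` over
    transects. Significance comes from a permutation test that reassigns the
    "local" origin label uniformly among the origins within each transect
    (transects are the exchangeable blocks), recomputing the contrast each
    time; the two-sided p-value is ``(1 + #{|T*| >= |T|}) / (n + 1)``.
    """
    metrics = [m for m in metrics if m in table.columns]
    if not metrics:
        raise ValueError("none of the requested metric columns are present")
    origins = sorted(table["origin"].unique())
    if locality not in origins:
        raise ValueError(f"locality {locality!r} absent from the table")
    if len(origins) < 2:
        raise ValueError("need at least one foreign origin for a contrast")
    transects = sorted(table["transect"].unique())
    distances = sorted(table["distance_m"].unique())
    n_t, n_o, n_d = len(transects), len(origins), len(distances)

    # Dense value array V[t, o, d, m]; missing combinations stay NaN.
    v = np.full((n_t, n_o, n_d, len(metrics)), np.nan)
    t_idx = {t: i for i, t in enumerate(transects)}
    o_idx = {o: i for i, o in enumerate(origins)}
    d_idx = {d: i for i, d in enumerate(distances)}
    for _, row in table.iterrows():
        v[t_idx[row["transect"]], o_idx[row["origin"]], d_idx[row["distance_m"]]] = [
            row[m] for m in metrics
        ]

    local = o_idx[locality]

    def contrasts(local_per_transect: np.ndarray) -> np.ndarray:
        """(n_d + 1, n_metrics) contrast array: per distance then overall."""
        sel = local_per_transect[:, None, None, None] == np.arange(n_o)[None, :, None, None]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # empty-slice means
            loc = np.nanmean(np.where(sel, v, np.nan), axis=(0, 1))
            frn = np.nanmean(np.where(~sel, v, np.nan), axis=(0, 1))
            per_distance = loc - frn
            overall = np.nanmean(loc, axis=0) - np.nanmean(frn, axis=0)
        return np.vstack([per_distance, overall])

    observed = contrasts(np.full(n_t, local))
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, n_o, size=(n_permutations, n_t))
    exceed = np.zeros_like(observed)
    for perm in draws:
        exceed += np.abs(contrasts(perm)) >= np.abs(observed) - 1e-12
    pvals = (1.0 + exceed) / (n_permutations + 1.0)

    rows = []
    labels = [*(f"{d:g}" for d in distances), "overall"]
    for i, label in enumerate(labels):
        for j, m in enumerate(metrics):
            rows.append(
                {
                    "metric": m,
                    "distance_m": label,
                    "contrast": observed[i, j],
                    "p_value": pvals[i, j],
                    "n_local_transects": n_t,
                    "n_foreign_origins": n_o - 1,
                }
            )
    return pd.DataFrame(rows)
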