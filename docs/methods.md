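# Methods

This note documents the models, measurement conventions and design choices
behind `callprop`, in the order the pipeline applies them.

## Call model and synthesis

A call is `n_pulses` identical tone pulses separated by silent inter-pulse
intervals. One pulse is a sinusoidal carrier at the dominant frequency `f0`
shaped by two envelopes:

- an intra-pulse raised-cosine modulator
  `e(t) = 1 − (d/100)·(1 + cos(2πkt/T))/2`, with depth `d` (percent), `k`
  modulation cycles and pulse duration `T`. The phase is chosen so the minima
  sit at the pulse edges: the interior then carries exactly `k` envelope
  maxima (matching how intra-pulse modulations are counted on an oscillogram)
  and `100·(max − min)/max = d` holds exactly by construction;
- a 2-ms cosine rise/fall gate at each edge, to avoid spectral splatter. Depth
  is therefore always measured on the pulse interior, excluding a 2.5-ms guard.

Peak amplitude defaults to 0.9, leaving headroom below 16-bit full scale
(`1 − 2⁻¹⁵`). Stimulus trains repeat the call with gaps between copies only;
the field playback protocol corresponds to 5 replicates at a 6-s
inter-stimulus interval. Synthesis is deterministic: identical parameters give
bit-identical samples. Audio is mono PCM-16 WAV at 44.1 kHz; foreign-rate
inputs are carried with their own rate rather than resampled.

The shipped locality presets are *illustrative*. They describe a plausible
Pleurodema-thaul-like call — carrier near 2 kHz, five intra-pulse modulations,
deeper modulation in northern than southern populations, pulse durations of a
few hundred milliseconds — chosen once so examples and fixtures run; they are
not field measurements, and real analyses should supply their own parameter
sets via config. Pulse durations of 0.2–0.4 s keep the intra-pulse modulation
rate (k/T ≈ 12–25 Hz) well below the 9-ms envelope-smoothing window used by
the degradation metrics, so design depth is recoverable after transmission.

## Segmentation and the seven variables

The envelope is `|hilbert(x)|`, optionally block-averaged over non-overlapping
windows (`smoothing_window` samples; window 1, the default for feature
analysis, is the raw modulus). Segmentation thresholds the envelope at
`threshold_fraction` (default 0.1) of its maximum; runs of presence are
pulses. Two gap parameters replace the manual correction step of
interactive workflows: gaps shorter than `min_gap_pulse` are bridged (healing
spurious splits when deep modulation grazes the threshold), and pulses closer
than `min_gap_call` (default 0.5 s) belong to one call. Because a plain
threshold crossing lands partway up the 2-ms onset ramp, boundaries are
refined outward to a 1 %-of-maximum crossing (`refine_fraction`); this moves
boundaries only, never changes pulse counts, and brings onset errors below
~0.5 ms. All spans are half-open `[onset, offset)` in seconds.

Feature definitions: call duration = last offset − first onset; mean
inter-pulse interval = mean offset→next-onset gap (missing for single-pulse
calls); pulse rate = `n_pulses / call_duration` (the alternative, the inverse
mean inter-onset interval, is deliberately not the default); the central pulse
is index `⌈n/2⌉` (1-based). Dominant frequency is the argmax of the
Hann-windowed magnitude spectrum of the central pulse, zero-padded to at least
4096 points (≈10.8 Hz bins at 44.1 kHz). Modulation depth uses the raw
envelope within the central pulse interior.

The covariate correction `Y_corr = Y − b·X_measured + b·X_mean` uses the OLS
slope of the variable on the covariate and the covariate grand mean; it is
applied only when the Pearson correlation is significant at α = 0.05
(temporal variables vs. water temperature; dominant frequency vs. snout–vent
length). The correction is affine in `Y` with unit slope and is the identity
when the variable is measured at the covariate mean.

## Propagation model

The transect simulator is a parametric forward model with four stages per
microphone distance `d`:

1. **Spherical spreading**: gain `−20·log10(d/d_ref)` dB, i.e. 6.02 dB per
   doubling (reference distance 0.5 m by default).
2. **Excess attenuation**: per frequency band, `−c·(d − d_ref)` dB with
   coefficient `c` in dB/m, applied as a zero-phase piecewise-constant filter
   in the frequency domain so pulse onsets are not shifted. Bands must not
   overlap; uncovered frequencies pass unchanged.
3. **Reverberation**: convolution with a synthetic impulse response — a
   direct-path delta plus carrier-band noise under an `exp(−t/decay)`
   envelope. A smooth *positive* kernel of that shape would act as a sub-audio
   low-pass (−3 dB near `1/(2π·decay)` ≈ 8 Hz for decay = 20 ms) and erase a
   2-kHz carrier rather than smear its envelope, which is why the tail must
   itself be carrier-band. The kernel is normalized so `max|H(f)| ≤ 1`: no
   frequency gains energy, hence signal energy never increases through this
   stage. One kernel (seeded from the transect seed) is shared by all
   distances of a transect — the habitat — while the tail/direct energy ratio
   grows linearly with `d/d_ref` (default 0.05 at the reference), because the
   direct field decays geometrically and the diffuse field does not. Distant
   microphones are therefore more smeared: modulation depth erodes and the
   comb-like tail spectrum lowers SCC. For shallowly modulated calls the
   multipath speckle can also *raise* measured depth at intermediate
   distances; non-monotone SMD transects are expected behaviour, not a defect.
4. **Background noise**: stationary white Gaussian noise at a calibrated
   broadband SPL (default 40 dB), seeded per channel from the transect seed.

The whole transect shares one digital gain, chosen so the 94-dB reference
tone sits at 0.9 digital peak; a source level that would overload that gain at
the nearest microphone raises an error. Each channel is preceded by a 1-s
noise-only lead whose span is recorded in the sidecar markers. The free
parameters the field study does not pin down — source level (90 dB SPL at
0.5 m), noise level, band coefficients — are config values; absolute levels
cancel in the standardized metrics.

What the simulator does **not** model: ray tracing, ground effect,
meteorology, vegetation scattering, receiver directivity, time-varying
channels. Passing tests on simulated transects therefore demonstrates the
correctness of the measurement chain and the qualitative degradation axes
(attenuation, envelope smearing, spectral change), not quantitative agreement
with any particular habitat.

## Degradation statistics

Calibration maps digital RMS to SPL via a 1-kHz, 94-dB RMS tone:
`SPL(x) = 94 + 20·log10(rms(x)/rms_tone)`. A tone deviating more than ±50 Hz
from 1 kHz warns but proceeds. SPL of a call embedded in noise is corrected by
power subtraction using a contiguous noise-only segment; when the noise level
reaches the measured level the value is flagged missing (NaN), never zero.
Replicates whose level clears the noise floor by less than 3 dB are likewise
flagged — the automated stand-in for visually discarding contaminated
segments. SPL integrates over each replicate's call span (from the sidecar
markers) plus twice the reverberation time constant, not fixed windows.

Mean power spectra average non-overlapping 440-point Hann periodograms
(44100/440 = 100.227 Hz bins, 9.977-ms windows; trailing partial window
discarded). SCC is the Pearson correlation of the two linear band-power
vectors at zero lag, restricted to 0–10 kHz by default (the call energy band);
a dB-scale variant and full-band option exist. For a narrowband pulsed call
the linear-scale SCC is dominated by the carrier peak and stays near 1 unless
the filtering cuts across the occupied band — a property of the statistic, not
an implementation artifact. Constant spectra have no defined correlation and
are flagged missing. Transmitted modulation depth uses the 400-point
block-averaged envelope and the same `(max − min)/max` formula within the
(known or auto-detected central) pulse.

Standardization divides by the highest value of the same transect × origin at
the reference distance. SPL is standardized on the **linear amplitude scale**,
`SSPL = 10^((SPL − SPL_ref_max)/20)`, so that pure spherical spreading yields
`SSPL = d_ref/d` exactly; modulation depth, already a linear percentage, is
divided directly. Exactly one row per group gets SSPL = 1. Replicate averages
skip flagged values; a cell with no valid replicate stays missing.

## Local-versus-foreign contrast

The field analysis fits mixed-effects models with transect as a random
intercept; that machinery (REML, Kenward–Roger, outlier loops, transforms) is
deliberately out of scope. In its place the package reports, per metric,
distance and overall, the descriptive contrast `mean(local) − mean(foreign)`
with a permutation p-value: the "local" origin label is reassigned uniformly
among the origins within each transect (transects are the exchangeable
blocks), the contrast is recomputed, and
`p = (1 + #{|T*| ≥ |T|})/(n_perm + 1)` two-sided. Under a true null the
p-values are uniform on the `1/(n_perm+1)` grid; the test suite verifies
uniformity by Kolmogorov–Smirnov over 200 simulated null datasets. Missing
cells are skipped by nan-aware means.

## Numerical and reproducibility choices

- Seeds: one config seed fans out deterministically (`numpy.random
  .SeedSequence`) to per-stage, per-transect, per-channel children, all below
  2³¹; two runs from the same config are byte-identical.
- Degenerate inputs are rejected loudly (empty envelopes, constant covariates,
  overlapping bands, carriers at or above Nyquist, silent calibration tones);
  empty segmentations (nothing above threshold) are a valid result, not an
  error.
- Problem sizes in the test suite and acceptance script (calls of 2–6 pulses,
  2–3 replicates, 2–3 transects per site, 99–2000 permutations, 100 round-trip
  parameter draws, 200 null datasets) were chosen as the smallest sizes at
  which every property under test is well-resolved.
- Round-trip fidelity is guaranteed for modulation depths up to ~85 %; at 90 %
  and beyond the envelope minima graze the 10 % detection threshold and pulse
  splitting must be healed via `min_gap_pulse` (the analyzer exposes it; the
  fixture analyses use 20 ms).

## Known limitations

- The propagation model is phenomenological; coefficients are not derived from
  vegetation or meteorology.
- SCC on linear powers is insensitive to uniform attenuation of a narrowband
  call's whole energy band (use the dB variant for that question).
- The covariate correction assumes a single pooled OLS slope across
  localities, as in the classic workflow; no per-locality slopes.
- No GUI, no manual segmentation editing; severely clipped or non-mono
  recordings are rejected rather than repaired.
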