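# callprop

Synthesis, propagation simulation and degradation analysis of pulsed anuran
advertisement calls.

`callprop` is a desk-scale implementation of the full measurement chain used in
playback transect studies of frog acoustic communication (e.g. the four-eyed
frog *Pleurodema thaul*, whose advertisement call is a train of
amplitude-modulated pulses). It is aimed at bioacousticians who want a
reproducible, scriptable version of that chain: generating per-locality
synthetic stimuli, measuring calls automatically, simulating (or ingesting)
calibrated transect recordings, and scoring how much a call attenuates and
degrades as it travels.

## What it computes

**Call measurement.** The amplitude envelope is the modulus of the analytic
signal, `e(t) = |x(t) + i·H[x](t)|` (Hilbert transform). An amplitude threshold
relative to the envelope maximum yields a presence/absence vector whose runs
are pulses; pulses are grouped into calls. From the segmentation come the seven
standard call variables: call duration, number of pulses, mean pulse duration,
mean inter-pulse interval, pulse rate, modulation depth
`100·(max − min)/max` of the envelope within the central pulse, and dominant
frequency (FFT peak of the central pulse). Variables correlated with water
temperature (temporal variables) or snout–vent length (dominant frequency) are
adjusted to the covariate grand mean:

    Y_corr = Y − b·X_measured + b·X_mean

with `b` the OLS slope, applied only when the Pearson correlation is
significant (α = 0.05).

**Propagation.** A point source in free field loses
`20·log10(d/d_ref)` dB — 6 dB per doubling of distance ("spherical
spreading"). The transect simulator adds habitat excess attenuation (dB/m per
frequency band), reverberant smearing (direct path plus an exponentially
decaying diffuse tail whose energy grows with distance), and calibrated
Gaussian background noise, and records at 0.5, 2, 4, 8 and 16 m.

**Degradation statistics.** Recordings are calibrated against a 1-kHz,
94-dB-SPL RMS reference tone. Per replicate and distance:

- **SPL**, noise-corrected by power subtraction
  `L = 10·log10(10^(L_meas/10) − 10^(L_noise/10))` using a contiguous
  noise-only segment;
- **modulation depth** from the Hilbert envelope averaged over non-overlapping
  400-sample windows;
- **SCC**, the zero-lag Pearson correlation between mean power spectra
  (440-point Hann windows, 0 % overlap → 100.227 Hz frequency and 9.977 ms
  temporal resolution at 44.1 kHz) at the reference and the farther distance.

SPL and modulation depth are standardized per transect and call origin by the
highest value at the shortest distance (**SSPL**, on the linear amplitude
scale, so pure spherical spreading gives `SSPL = d_ref/d`; **SMD** on the
percentage scale), replicates are averaged, and local-versus-foreign origin
contrasts are evaluated with a within-transect permutation test.

## Worked example

```bash
callprop run --config examples/demo_config.yaml --outdir out
```

runs the whole chain for two illustrative localities (the parameter presets are
documented as illustrative, not field values): synthesis of five-replicate
stimulus trains, three simulated transects per site, degradation scoring,
standardization, replicate averaging and the permutation contrast. It prints

```
pipeline complete: {'stimuli': 2, 'degradation_rows': 300, 'summary_rows': 36}
```

and writes `degradation_table.csv`, `degradation_averaged.csv`,
`local_vs_foreign.csv` and `manifest.json` into `out/`. The averaged table for
one transect looks like:

```
transect origin  distance_m  spl_db  modulation_depth_pct    scc   sspl    smd
norte/T1  norte         0.5 86.4407               84.7121 1.0000 0.9902 0.9999
norte/T1  norte         2.0 72.4222               81.6777 1.0000 0.1972 0.9641
norte/T1  norte         4.0 64.7183               80.1337 1.0000 0.0812 0.9459
norte/T1  norte         8.0 56.0206               77.8111 1.0000 0.0298 0.9185
norte/T1  norte        16.0 45.3251               64.3402 1.0000 0.0087 0.7595
```

Reading the rows: SPL falls faster than the spherical-spreading prediction
(`SSPL = 0.25, 0.125, …` would be pure geometry; excess attenuation and the
growing reverberant field steepen it), modulation depth erodes as reverberation
fills the envelope troughs (SMD down to 0.76 at 16 m), and the spectrum stays
nearly intact for this narrowband call (SCC ≈ 1). A row flagged `NaN` means the
replicate fell below the noise-floor screening margin and was excluded, as
noisy segments are discarded in field practice. `local_vs_foreign.csv` then
reports, per site, metric and distance, the mean local-minus-foreign contrast
with its permutation p-value.

Individual stages are available as `callprop synth`, `analyze`, `simulate`,
`degrade`, `summarize` and `fixtures`, and as plain library functions
(`callprop.synthesize_call`, `callprop.segment_calls`,
`callprop.simulate_transect`, `callprop.degradation_table`, …).

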