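# Demo pipeline configuration: two illustrative localities, five-microphone
# transects, field-protocol stimulus trains (5 replicates, 6-s interval).
# Locality parameter values are illustrative, not field measurements.
seed: 7
outdir: callprop_out
localities:
  norte:
    dominant_frequency: 2200.0
    n_pulses: 3
    pulse_duration: 0.4
    inter_pulse_interval: 0.2
    modulation_depth: 90.0
    n_intra_pulse_modulations: 5
  sur:
    dominant_frequency: 2000.0
    n_pulses: 4
    pulse_duration: 0.3
    inter_pulse_interval: 0.2
    modulation_depth: 60.0
    n_intra_pulse_modulations: 5
stimulus:
  n_replicates: 5
  inter_stimulus_interval: 6.0
transect:
  distances: [0.5, 2.0, 4.0, 8.0, 16.0]
  reference_distance: 0.5
  source_level_db: 90.0
  excess_attenuation:
    - [[2000.0, 4000.0], 0.5]
    - [[4000.0, 10000.0], 1.5]
  reverb_decay_s: 0.02
  noise_level_db: 42.0
  lead_noise_s: 1.0
n_transects: 3
permutations: 999
write_wavs: false
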