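"""Illustrative locality parameter presets.

These are NOT measured field values for any real population: the source study
prints its per-locality call parameters only graphically. The presets are
plausible values for a Pleurodema-thaul-like pulsed call (carrier near 2 kHz,
five intra-pulse modulations, deeper modulation in northern than southern
populations) and exist so the pipeline, fixtures and examples run out of the
box. Users supply their own parameter sets via config for real analyses.
"""

from callprop.types import CallParameters

ILLUSTRATIVE_LOCALITIES: dict[str, CallParameters] = {
    "norte": CallParameters(
        dominant_frequency=2200.0,
        n_pulses=3,
        pulse_duration=0.4,
        inter_pulse_interval=0.2,
        modulation_depth=90.0,
        n_intra_pulse_modulations=5,
        locality_label="norte",
    ),
    "centro": CallParameters(
        dominant_frequency=2600.0,
        n_pulses=3,
        pulse_duration=0.35,
        inter_pulse_interval=0.25,
        modulation_depth=85.0,
        n_intra_pulse_modulations=5,
        locality_label="centro",
    ),
    "sur": CallParameters(
        dominant_frequency=2000.0,
        n_pulses=4,
        pulse_duration=0.3,
        inter_pulse_interval=0.2,
        modulation_depth=60.0,
        n_intra_pulse_modulations=5,
        locality_label="sur",
    ),
}
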