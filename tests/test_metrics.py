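"""Calibration, SPL, spectra, SCC, standardization and permutation contrasts."""

import numpy as np
import pandas as pd
import pytest

from callprop.metrics import (
    CalibrationReference,
    MeanPowerSpectrum,
    average_replicates,
    calibrate,
    local_vs_foreign_summary,
    mean_power_spectrum,
    noise_corrected_spl,
    scc,
    standardize_by_origin,
    transmitted_modulation_depth,
)
from callprop.synthesis import synthesize_pulse
from callprop.types import Waveform

from conftest import FS, make_tone


class TestCalibration:
    def test_tone_rms_maps_to_94_db(self):
        tone = make_tone(1000.0, 0.5, amplitude=0.5)
        calib = calibrate(tone)
        assert calib.spl(tone) == pytest.approx(94.0, abs=1e-9)

    def test_halved_rms_is_six_db_down(self):
        tone = make_tone(1000.0, 0.5, amplitude=0.5)
        calib = calibrate(tone)
        half = Waveform(tone.samples * 0.5, FS)
        assert calib.spl(half) == pytest.approx(94.0 + 20.0 * np.log10(0.5), abs=1e-9)
        assert calib.spl(half) == pytest.approx(87.98, abs=0.005)

    def test_tenfold_rms_is_plus_20_db(self):
        calib = CalibrationReference(tone_rms_digital=0.01)
        assert calib.spl(0.1) == pytest.approx(114.0, abs=1e-9)

    def test_short_or_silent_tone_rejected(self):
        with pytest.raises(ValueError, match="0.1 s"):
            calibrate(make_tone(1000.0, 0.05))
        with pytest.raises(ValueError, match="silent"):
            calibrate(Waveform(np.zeros(int(0.5 * FS)), FS))

    def test_wrong_tone_frequency_warns_but_proceeds(self):
        tone = make_tone(2000.0, 0.5)
        with pytest.warns(UserWarning, match="1000"):
            calib = calibrate(tone)
        assert calib.tone_rms_digital > 0


class TestNoiseCorrectedSpl:
    CALIB = CalibrationReference(tone_rms_digital=0.1)

    def _segment_at(self, level_db, seed=0):
        rng = np.random.default_rng(seed)
        x = rng.standard_normal(44100)
        x *= self.CALIB.rms_for_spl(level_db) / np.sqrt(np.mean(x**2))
        return Waveform(np.clip(x, -1, 1), FS)

    def test_power_subtraction_arithmetic(self):
        meas = self._segment_at(94.0, seed=1)
        noise = self._segment_at(91.0, seed=2)
        expected = 10.0 * np.log10(10.0**9.4 - 10.0**9.1)
        assert noise_corrected_spl(meas, noise, self.CALIB) == pytest.approx(
            expected, abs=1e-6
        )
        assert expected == pytest.approx(90.98, abs=0.005)

    def test_negligible_noise_is_identity(self):
        meas = self._segment_at(80.0, seed=3)
        noise = self._segment_at(50.0, seed=4)
        assert noise_corrected_spl(meas, noise, self.CALIB) == pytest.approx(
            self.CALIB.spl(meas), abs=0.01
        )

    def test_noise_at_signal_level_flagged_missing(self):
        meas = self._segment_at(70.0, seed=5)
        with pytest.warns(UserWarning, match="missing"):
            out = noise_corrected_spl(meas, meas, self.CALIB)
        assert np.isnan(out)


class TestMeanPowerSpectrum:
    def test_bin_spacing_is_100_227_hz(self):
        spec = mean_power_spectrum(make_tone(1000.0, 0.5))
        assert spec.bin_spacing == pytest.approx(100.227, abs=0.001)

    def test_window_duration_is_9_977_ms(self):
        spec = mean_power_spectrum(make_tone(1000.0, 0.5))
        assert spec.window_length / FS == pytest.approx(9.977e-3, abs=1e-6)

    def test_on_bin_tone_concentrates_in_one_bin(self):
        f0 = 10 * FS / 440  # exactly the 10th analysis bin
        spec = mean_power_spectrum(make_tone(f0, 0.5))
        peak = np.argmax(spec.powers)
        assert spec.frequencies[peak] == pytest.approx(f0, abs=1e-6)
        # Hann main lobe spans peak +/- 1 bin; everything beyond is negligible
        outside = np.delete(spec.powers, [peak - 1, peak, peak + 1])
        assert np.all(outside < 1e-6 * spec.powers[peak])

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            mean_power_spectrum(Waveform(np.zeros(100), FS))


class TestScc:
    def _random_spectrum(self, rng):
        f = np.arange(221) * 100.227
        return MeanPowerSpectrum(f, rng.uniform(0, 1, f.size), 100.227, 440)

    def test_self_correlation_is_one(self):
        spec = self._random_spectrum(np.random.default_rng(0))
        assert scc(spec, spec) == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        a = self._random_spectrum(rng)
        b = MeanPowerSpectrum(a.frequencies, 7.3 * a.powers, 100.227, 440)
        assert scc(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = self._random_spectrum(rng), self._random_spectrum(rng)
        assert scc(a, b) == pytest.approx(scc(b, a), abs=1e-15)

    def test_matches_bruteforce_zero_lag_oracle(self):
        rng = np.random.default_rng(3)
        a, b = self._random_spectrum(rng), self._random_spectrum(rng)
        x, y = a.powers, b.powers
        # brute-force zero-lag normalized cross-correlation of centred vectors
        xc = x - x.mean()
        yc = y - y.mean()
        oracle = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert scc(a, b, fmax_hz=None) == pytest.approx(oracle, abs=1e-12)

    def test_mismatched_grids_rejected(self):
        a = self._random_spectrum(np.random.default_rng(4))
        b = MeanPowerSpectrum(a.frequencies * 2.0, a.powers, 200.454, 220)
        with pytest.raises(ValueError, match="grids"):
            scc(a, b)

    def test_constant_spectrum_flagged_missing(self):
        f = np.arange(100) * 100.227
        const = MeanPowerSpectrum(f, np.ones(100), 100.227, 440)
        other = MeanPowerSpectrum(f, np.arange(100.0), 100.227, 440)
        with pytest.warns(UserWarning, match="constant"):
            assert np.isnan(scc(const, other))


class TestTransmittedModulationDepth:
    def test_clean_pulse_recovers_design_depth(self, deep_am_params):
        pulse = synthesize_pulse(deep_am_params)
        depth = transmitted_modulation_depth(
            pulse, pulse_span_s=(0.0, deep_am_params.pulse_duration)
        )
        assert depth == pytest.approx(80.0, abs=2.0)

    def test_constant_envelope_gives_zero(self):
        tone = make_tone(2000.0, 0.5)
        depth = transmitted_modulation_depth(tone, pulse_span_s=(0.05, 0.45))
        assert depth < 2.0

    def test_scale_invariance(self, deep_am_params):
        pulse = synthesize_pulse(deep_am_params)
        half = Waveform(pulse.samples * 0.5, FS)
        span = (0.0, deep_am_params.pulse_duration)
        assert transmitted_modulation_depth(half, pulse_span_s=span) == pytest.approx(
            transmitted_modulation_depth(pulse, pulse_span_s=span), abs=1e-9
        )

    def test_autodetects_central_pulse(self, deep_am_params):
        pulse = synthesize_pulse(deep_am_params)
        padded = Waveform(
            np.concatenate([np.zeros(int(0.3 * FS)), pulse.samples,
                            np.zeros(int(0.3 * FS))]),
            FS,
        )
        assert transmitted_modulation_depth(padded) == pytest.approx(80.0, abs=3.0)


def _random_table(rng, n_transects=4, n_origins=3, distances=(0.5, 2, 4, 8, 16),
                  n_replicates=2):
    rows = []
    for t in range(n_transects):
        for o in range(n_origins):
            for d in distances:
                for r in range(n_replicates):
                    rows.append(
                        {
                            "transect": f"T{t}",
                            "origin": f"L{o}",
                            "distance_m": d,
                            "replicate": r,
                            "spl_db": rng.uniform(50, 90),
                            "modulation_depth_pct": rng.uniform(20, 95),
                            "scc": rng.uniform(0.2, 1.0),
                        }
                    )
    return pd.DataFrame(rows)


class TestStandardization:
    def test_reference_max_maps_to_one(self):
        table = pd.DataFrame(
            {
                "transect": ["T1"] * 3,
                "origin": ["A"] * 3,
                "distance_m": [0.5, 0.5, 2.0],
                "replicate": [0, 1, 0],
                "spl_db": [78.0, 80.0, 70.0],
                "modulation_depth_pct": [90.0, 85.0, 60.0],
                "scc": [1.0, 1.0, 0.9],
            }
        )
        std = standardize_by_origin(table, reference_distance=0.5)
        ref = std[std["distance_m"] == 0.5]
        assert ref.loc[ref["spl_db"] == 80.0, "sspl"].iloc[0] == 1.0
        assert np.isclose(
            ref.loc[ref["spl_db"] == 78.0, "sspl"].iloc[0], 10 ** (-2 / 20)
        )
        assert (std.groupby(["transect", "origin"])["sspl"].apply(
            lambda s: np.isclose(s.max(), 1.0)
        )).all()

    def test_single_reference_row_is_unity(self):
        table = pd.DataFrame(
            {
                "transect": ["T1"], "origin": ["A"], "distance_m": [0.5],
                "replicate": [0], "spl_db": [66.0],
                "modulation_depth_pct": [50.0], "scc": [1.0],
            }
        )
        std = standardize_by_origin(table, reference_distance=0.5)
        assert std["sspl"].iloc[0] == 1.0
        assert std["smd"].iloc[0] == 1.0

    def test_matches_bruteforce_oracle_on_random_table(self):
        rng = np.random.default_rng(21)
        table = _random_table(rng)
        std = standardize_by_origin(table, reference_distance=0.5)
        for (t, o), grp in std.groupby(["transect", "origin"]):
            ref = grp[grp["distance_m"] == 0.5]
            spl_max = ref["spl_db"].max()
            md_max = ref["modulation_depth_pct"].max()
            np.testing.assert_allclose(
                grp["sspl"], 10 ** ((grp["spl_db"] - spl_max) / 20), atol=1e-12
            )
            np.testing.assert_allclose(
                grp["smd"], grp["modulation_depth_pct"] / md_max, atol=1e-12
            )
            assert np.isclose(ref["sspl"].max(), 1.0)
            assert (ref["sspl"] <= 1.0 + 1e-12).all()
            assert (ref["smd"] <= 1.0 + 1e-12).all()

    def test_missing_reference_group_dropped_with_warning(self):
        table = pd.DataFrame(
            {
                "transect": ["T1", "T1"], "origin": ["A", "B"],
                "distance_m": [0.5, 2.0], "replicate": [0, 0],
                "spl_db": [80.0, 70.0],
                "modulation_depth_pct": [90.0, 60.0], "scc": [1.0, 0.9],
            }
        )
        with pytest.warns(UserWarning, match="lacks usable reference"):
            std = standardize_by_origin(table, reference_distance=0.5)
        assert set(std["origin"]) == {"A"}

    def test_sspl_invariant_to_global_transect_gain(self):
        rng = np.random.default_rng(22)
        table = _random_table(rng, n_transects=2)
        std = standardize_by_origin(table, reference_distance=0.5)
        gained = table.copy()
        gained.loc[gained["transect"] == "T0", "spl_db"] += 12.0  # recorder gain
        std_g = standardize_by_origin(gained, reference_distance=0.5)
        np.testing.assert_allclose(std_g["sspl"], std["sspl"], atol=1e-12)


class TestAverageReplicates:
    def test_plain_mean(self):
        rng = np.random.default_rng(30)
        table = _random_table(rng, n_transects=1, n_origins=1, distances=(0.5,),
                              n_replicates=5)
        table["spl_db"] = [1.0, 2.0, 3.0, 4.0, 5.0]
        avg = average_replicates(table)
        assert avg["spl_db"].iloc[0] == pytest.approx(3.0)

    def test_single_replicate_is_itself(self):
        rng = np.random.default_rng(31)
        table = _random_table(rng, n_transects=1, n_origins=1, distances=(0.5,),
                              n_replicates=1)
        avg = average_replicates(table)
        assert avg["spl_db"].iloc[0] == table["spl_db"].iloc[0]

    def test_flagged_missing_excluded(self):
        rng = np.random.default_rng(32)
        table = _random_table(rng, n_transects=1, n_origins=1, distances=(0.5,),
                              n_replicates=5)
        table["spl_db"] = [2.0, 4.0, 6.0, np.nan, 8.0]
        avg = average_replicates(table)
        assert avg["spl_db"].iloc[0] == pytest.approx(5.0)


class TestLocalVsForeign:
    def _null_table(self, rng, n_transects=5, n_origins=3):
        rows = []
        for t in range(n_transects):
            for o in range(n_origins):
                for d in (0.5, 2, 4, 8, 16):
                    rows.append(
                        {
                            "transect": f"T{t}", "origin": f"L{o}",
                            "distance_m": d,
                            "sspl": rng.normal(), "smd": rng.normal(),
                            "scc": rng.normal(),
                        }
                    )
        return pd.DataFrame(rows)

    def test_constructed_effect_detected(self):
        rng = np.random.default_rng(40)
        table = self._null_table(rng, n_transects=5)
        table.loc[table["origin"] == "L0", "sspl"] += 5.0  # clear local advantage
        report = local_vs_foreign_summary(table, "L0", n_permutations=2000, seed=1)
        overall = report[(report["metric"] == "sspl")
                         & (report["distance_m"] == "overall")].iloc[0]
        assert overall["contrast"] > 0
        assert overall["p_value"] <= 0.05

    def test_null_contrast_near_zero(self):
        rng = np.random.default_rng(41)
        table = self._null_table(rng, n_transects=20)
        report = local_vs_foreign_summary(table, "L1", n_permutations=500, seed=2)
        overall = report[(report["metric"] == "sspl")
                         & (report["distance_m"] == "overall")].iloc[0]
        assert abs(overall["contrast"]) < 1.0
        assert overall["p_value"] > 0.01

    def test_same_seed_identical_report(self):
        rng = np.random.default_rng(42)
        table = self._null_table(rng)
        a = local_vs_foreign_summary(table, "L0", n_permutations=200, seed=3)
        b = local_vs_foreign_summary(table, "L0", n_permutations=200, seed=3)
        pd.testing.assert_frame_equal(a, b)

    def test_no_foreign_origin_rejected(self):
        rng = np.random.default_rng(43)
        table = self._null_table(rng, n_origins=1)
        with pytest.raises(ValueError):
            local_vs_foreign_summary(table, "L0")

    def test_unknown_locality_rejected(self):
        rng = np.random.default_rng(44)
        table = self._null_table(rng)
        with pytest.raises(ValueError, match="absent"):
            local_vs_foreign_summary(table, "nowhere")
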