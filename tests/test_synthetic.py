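"""Spectral and structural properties of the synthetic soundscapes."""

import numpy as np
import pytest
from scipy.signal import find_peaks

from batpipe import synthetic as syn
from batpipe.taxonomy import PEAK_BAND_KHZ


def _count_envelope_peaks(samples, min_height=0.02):
    """Independent pulse counter: peaks of the smoothed amplitude envelope."""
    envelope = np.convolve(np.abs(samples), np.ones(600) / 600, mode="same")
    peaks, _ = find_peaks(envelope, height=min_height, distance=6000)
    return len(peaks)


class TestSynthPulse:
    @pytest.mark.parametrize("label", sorted(PEAK_BAND_KHZ))
    def test_peak_energy_inside_class_band(self, label, rng):
        """Frequency of maximum energy stays inside the class band
        (asserted over many pulses across all classes)."""
        params = syn.default_pulse_params(label)
        lo, hi = params.peak_band_khz
        for _ in range(15):
            peak = syn.peak_frequency_khz(syn.synth_pulse(params, rng))
            assert lo <= peak <= hi

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ValueError):
            syn.PulseParams("P_pip", (140.0, 160.0), 150, 130, 5, 100)
        with pytest.raises(ValueError):
            syn.PulseParams("P_pip", (0.0, 50.0), 60, 40, 5, 100)

    def test_nonfinite_amplitude_rejected(self):
        with pytest.raises(ValueError):
            syn.PulseParams("P_pip", (42.0, 50.0), 61, 31, 5, 100,
                            snr_db=-np.inf)

    def test_deterministic_under_seed(self):
        params = syn.default_pulse_params("P_pip")
        a = syn.synth_pulse(params, np.random.default_rng(9))
        b = syn.synth_pulse(params, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)


class TestSynthPulseTrain:
    def test_pulse_count_matches_ipi(self, rng):
        """2 s at 100 ms spacing places about 20 pulses (envelope oracle)."""
        params = syn.default_pulse_params("P_pip")
        params.ipi_ms = 100.0
        rec = syn.synth_pulse_train("P_pip", 2.0, rng, params=params)
        assert 17 <= _count_envelope_peaks(rec.samples) <= 22

    def test_boundary_ipi_places_single_pulse(self, rng):
        params = syn.PulseParams("P_pip", (42.0, 50.0), 61, 31, 5.0, 1000.0)
        rec = syn.synth_pulse_train("P_pip", 1.0, rng, params=params)
        assert _count_envelope_peaks(rec.samples) == 1

    def test_ipi_above_one_second_rejected(self, rng):
        params = syn.PulseParams("P_pip", (42.0, 50.0), 61, 31, 5.0, 1500.0)
        with pytest.raises(ValueError, match="one-pulse-per-second"):
            syn.synth_pulse_train("P_pip", 2.0, rng, params=params)

    def test_every_recycled_window_contains_a_pulse(self, rng):
        rec = syn.synth_pulse_train("N_noc", 5.0, rng)  # slowest default ipi
        for i in range(4):  # first 80% of 5 s
            window = rec.samples[i * 300_000:(i + 1) * 300_000]
            assert _count_envelope_peaks(window) >= 1

    def test_train_peaks_stay_in_band(self, rng):
        """Each 1 s piece of a P_nat train has its peak energy in 35-40 kHz."""
        rec = syn.synth_pulse_train("P_nat", 3.0, rng)
        for i in range(3):
            piece = rec.samples[i * 300_000:(i + 1) * 300_000]
            assert 35.0 <= syn.peak_frequency_khz(piece) <= 40.0


class TestSynthNoise:
    def test_tonal_ridge_at_30_khz(self, rng):
        rec = syn.synth_noise(syn.tonal_profile(30.0), 2.0, rng)
        assert syn.peak_frequency_khz(rec.samples) == pytest.approx(30.0,
                                                                    abs=0.5)

    def test_zero_rate_yields_floor_only(self, rng):
        rec = syn.synth_noise(syn.transient_profile(0.0), 1.0, rng)
        assert rec.samples.std() == pytest.approx(syn.FLOOR_RMS, rel=0.1)
        assert np.max(np.abs(rec.samples)) < 10 * syn.FLOOR_RMS

    def test_click_count_matches_rate(self, rng):
        """10 Hz click train over 3 s gives ~30 clicks (threshold oracle)."""
        rec = syn.synth_noise(syn.click_profile(10.0), 3.0, rng)
        n_clicks = _count_envelope_peaks(rec.samples, min_height=0.01)
        assert 27 <= n_clicks <= 31

    def test_profile_field_exclusivity(self):
        with pytest.raises(ValueError):
            syn.NoiseProfile("stationary_tonal", band_khz=(30, 1),
                             click_rate_hz=5.0)
        with pytest.raises(ValueError):
            syn.NoiseProfile("stationary_pulsed")


class TestSynthCollection:
    def test_manifest_counts_match_class_mix(self, tmp_path):
        config = syn.CollectionConfig(
            "east_2019", {"P_pip": 3, "noise": 3}, seed=3,
            bat_duration_range_s=(2.0, 3.0),
            noise_duration_range_s=(1.0, 2.0))
        catalog = syn.synth_collection(config, tmp_path)
        assert len(catalog) == 6
        assert catalog["class"].value_counts().to_dict() == {
            "P_pip": 3, "noise": 3}
        assert (tmp_path / "manifest.csv").exists()
        for file in catalog["file"]:
            assert (tmp_path / file).exists()

    def test_same_seed_is_byte_identical(self):
        config = syn.CollectionConfig(
            "west_2020", {"P_nat": 2, "noise": 2}, seed=11,
            bat_duration_range_s=(2.0, 3.0))
        recs_a, cat_a = syn.synth_corpus(config)
        recs_b, cat_b = syn.synth_corpus(config)
        assert cat_a.equals(cat_b)
        for a, b in zip(recs_a, recs_b):
            np.testing.assert_array_equal(a.samples, b.samples)

    def test_separability_knob_drives_classifier_f1(self):
        """Decreasing the peak-band overlap between two synthetic classes
        monotonically improves downstream 2-class classification."""
        from batpipe.classifier import (ClfTrainConfig, build_classifier,
                                        normalize_mfcc, predict_labels,
                                        train_classifier)
        from batpipe.evaluation import ConfusionMatrix
        from batpipe.preprocessing import compute_mfcc

        def two_class_f1(band_b, seed):
            rng = np.random.default_rng(seed)
            band_a = (38.0, 44.0)

            def samples(band, n):
                params = syn.PulseParams("P_pip", band, band[1] + 12,
                                         band[0] - 12, 5.0, 100.0)
                return [normalize_mfcc(compute_mfcc(syn.synth_pulse_train(
                    "P_pip", 1.0, rng, params=params).samples))
                    for _ in range(n)]

            x = np.stack(samples(band_a, 24) + samples(band_b, 24))
            y = np.repeat([0, 1], 24)
            train = np.r_[0:16, 24:40]
            test = np.r_[16:24, 40:48]
            model = build_classifier(2, seed=seed)
            train_classifier(model, x[train], y[train],
                             ClfTrainConfig(epochs=8, batch_size=8,
                                            seed=seed))
            cm = ConfusionMatrix.from_predictions(
                y[test], predict_labels(model, x[test]), ["a", "b"])
            return (cm.f1(0) + cm.f1(1)) / 2

        full = two_class_f1((38.0, 44.0), seed=0)    # identical bands
        half = two_class_f1((41.0, 47.0), seed=0)    # half overlap
        none = two_class_f1((46.0, 52.0), seed=0)    # disjoint bands
        assert none > full
        assert none >= half - 0.05 and half >= full - 0.05

    def test_scaled_imbalance_largest_remainder(self):
        scaled = syn.scale_class_mix({"P_pip": 17761, "P_nat": 723}, 0.01)
        assert scaled == {"P_pip": 178, "P_nat": 7}
        # count conservation at factor 1
        mix = {"a": 5, "b": 7, "c": 1}
        assert syn.scale_class_mix(mix, 1.0) == mix
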