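"""Segmentation, spectrogram/MFCC shape contracts and stratified splits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from batpipe import preprocessing as pp
from batpipe.audio_io import SAMPLE_RATE, Recording


def _recording(duration_s, label="P_pip", seed=0):
    rng = np.random.default_rng(seed)
    samples = rng.normal(0, 0.01, round(duration_s * SAMPLE_RATE))
    return Recording(samples=samples.astype(np.float32), class_label=label)


class TestRecycling:
    @pytest.mark.parametrize("duration, expected", [
        (10.0, 8), (16.0, 12), (2.0, 1), (1.25, 1), (5.5, 4),
    ])
    def test_bat_segment_counts(self, duration, expected):
        segments = pp.recycle_segments(_recording(duration))
        assert len(segments) == expected
        for i, seg in enumerate(segments):
            assert seg.samples.size == SAMPLE_RATE
            assert seg.offset_s == float(i)
            # recycling rule: every segment lies in the first 80%
            assert seg.offset_s + 1 <= 0.8 * duration + 1e-9

    def test_short_bat_recording_flagged(self):
        with pytest.warns(UserWarning, match="too short"):
            segments = pp.recycle_segments(_recording(1.2))
        assert segments == []

    def test_noise_uses_full_length(self):
        assert len(pp.recycle_segments(_recording(3.7, label="noise"))) == 3
        assert len(pp.recycle_segments(_recording(1.0, label="noise"))) == 1


class TestSpectrogram:
    def test_shape_and_range(self, rng):
        seg = rng.normal(0, 0.01, SAMPLE_RATE)
        spec = pp.compute_spectrogram(seg)
        assert spec.shape == (1025, 586)
        assert spec.min() >= 0.0 and spec.max() <= 1.0
        assert np.all(np.isfinite(spec))

    def test_window_duration_is_6_8_ms(self):
        assert pp.WINDOW_DURATION_S == pytest.approx(0.0068, abs=5e-5)

    def test_pure_tone_maps_to_expected_bin(self):
        """A tone at an exact bin center peaks at that bin in every frame."""
        bin_hz = SAMPLE_RATE / pp.N_FFT
        tone_bin = 205  # ~30 kHz: round(30000 / (300000/2048))
        t = np.arange(SAMPLE_RATE) / SAMPLE_RATE
        tone = np.sin(2 * np.pi * (tone_bin * bin_hz) * t)
        spec = pp.compute_spectrogram(tone)
        # interior frames hit the bin exactly; the reflect-padded edge
        # frames may smear by one bin
        assert np.all(spec.argmax(axis=0)[1:-1] == tone_bin)
        assert np.all(np.abs(spec.argmax(axis=0) - tone_bin) <= 1)
        # a generic 30 kHz tone still lands within one bin of 205
        spec30 = pp.compute_spectrogram(np.sin(2 * np.pi * 30_000 * t))
        assert np.all(np.abs(spec30.argmax(axis=0) - 205) <= 1)

    def test_all_zero_input_yields_all_zero_image(self):
        assert not pp.compute_spectrogram(np.zeros(SAMPLE_RATE)).any()

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            pp.compute_spectrogram(np.zeros(1000))


class TestMfcc:
    def test_shape_and_reduction(self, rng):
        mfcc = pp.compute_mfcc(rng.normal(0, 0.01, SAMPLE_RATE))
        assert mfcc.shape == (20, 586)
        reduction = 1 - (20 * 586) / (1025 * 586)
        assert reduction == pytest.approx(0.9805, abs=1e-4)

    def test_constant_zero_segment_is_finite(self):
        assert np.all(np.isfinite(pp.compute_mfcc(np.zeros(SAMPLE_RATE))))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_shape_contract_for_random_audio(self, seed):
        rng = np.random.default_rng(seed)
        seg = rng.uniform(-1, 1, SAMPLE_RATE).astype(np.float32)
        assert pp.compute_mfcc(seg).shape == (20, 586)
        assert pp.compute_spectrogram(seg).shape == (1025, 586)


def _catalog(counts: dict) -> pd.DataFrame:
    rows = []
    for label, n in counts.items():
        for i in range(n):
            rows.append({"file": f"{label}_{i}.wav", "class": label,
                         "collection": "east_2019", "height_m": 10,
                         "duration_s": 2.0})
    return pd.DataFrame(rows)


class TestStratifiedSplit:
    def test_exact_60_20_20(self):
        split = pp.stratified_split(_catalog({"P_pip": 100}), seed=0)
        assert split["split"].value_counts().to_dict() == {
            "train": 60, "val": 20, "test": 20}

    def test_ten_recordings_split_6_2_2(self):
        split = pp.stratified_split(_catalog({"P_pip": 10}), seed=0)
        assert split["split"].value_counts().to_dict() == {
            "train": 6, "val": 2, "test": 2}

    def test_deterministic_under_seed(self):
        catalog = _catalog({"P_pip": 20, "noise": 13})
        a = pp.stratified_split(catalog, seed=5)
        b = pp.stratified_split(catalog, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_each_class_split_individually(self):
        catalog = _catalog({"P_pip": 10, "N_noc": 5, "noise": 20})
        split = pp.stratified_split(catalog, seed=1)
        for label, n in (("P_pip", 10), ("N_noc", 5), ("noise", 20)):
            counts = split.loc[split["class"] == label,
                               "split"].value_counts().to_dict()
            assert counts.get("train", 0) == round(0.6 * n)
            assert sum(counts.values()) == n

    def test_rare_class_warns(self):
        with pytest.warns(UserWarning, match="only 3 recordings"):
            pp.stratified_split(_catalog({"P_pip": 10, "P_pyg": 3}), seed=0)

    def test_bad_ratios_rejected(self):
        with pytest.raises(ValueError):
            pp.stratified_split(_catalog({"P_pip": 10}), ratios=(0.5, 0.5, 0.5))
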