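"""Filter contracts and sliding-window segmentation properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stresscare.errors import ConfigurationError, ValidationError
from stresscare.preprocessing import (
    FilterConfig,
    SegmentationConfig,
    bandpass_cardiac,
    expected_segment_count,
    preprocess_recording,
    segment,
    smooth_channel,
)
from stresscare.recording_io import Channel, Recording


def _sine_channel(freq_hz, rate=64.0, dur_s=50.0, name="BVP"):
    t = np.arange(int(dur_s * rate)) / rate
    return Channel(name, "wrist", rate, np.sin(2 * np.pi * freq_hz * t))


def _rms(x):
    return float(np.sqrt(np.mean(np.square(x))))


class TestBandpass:
    def test_default_cutoffs_from_bpm(self):
        low, high = FilterConfig().band_hz
        assert low == pytest.approx(38 / 60)  # 0.6333 Hz
        assert high == pytest.approx(220 / 60)  # 3.6667 Hz

    def test_in_band_tone_passes(self):
        ch = _sine_channel(2.0)
        out = bandpass_cardiac(ch, FilterConfig())
        assert _rms(out.samples) == pytest.approx(_rms(ch.samples), rel=0.05)

    def test_out_of_band_tone_attenuated_20db(self):
        ch = _sine_channel(0.05)
        out = bandpass_cardiac(ch, FilterConfig())
        mid = slice(ch.samples.size // 4, 3 * ch.samples.size // 4)  # steady state
        atten_db = 20 * np.log10(_rms(ch.samples[mid]) / _rms(out.samples[mid]))
        assert atten_db >= 20

    def test_length_preserved(self):
        ch = _sine_channel(1.0)
        assert bandpass_cardiac(ch, FilterConfig()).samples.size == ch.samples.size

    def test_cutoff_above_nyquist_rejected(self):
        ch = _sine_channel(1.0, rate=4.0)  # Nyquist 2 Hz < 3.667 Hz
        with pytest.raises(ConfigurationError):
            bandpass_cardiac(ch, FilterConfig())

    def test_non_cardiac_channel_rejected(self):
        ch = Channel("EDA", "wrist", 4.0, np.zeros(200))
        with pytest.raises(ValidationError):
            bandpass_cardiac(ch, FilterConfig())


class TestSmoothing:
    def test_constant_series_unchanged(self):
        ch = Channel("TEMP", "wrist", 4.0, np.full(200, 3.5))
        out = smooth_channel(ch, FilterConfig())
        np.testing.assert_allclose(out.samples, ch.samples, atol=1e-12)

    def test_cubic_polynomial_reproduced(self):
        """An order-3 filter reproduces degree-3 polynomials exactly."""
        t = np.arange(200) / 4.0
        x = 0.5 * t**3 - 2 * t**2 + t - 7
        out = smooth_channel(Channel("TEMP", "wrist", 4.0, x), FilterConfig())
        interior = slice(6, -6)
        np.testing.assert_allclose(out.samples[interior], x[interior], rtol=1e-9)

    def test_even_window_rounded_up(self, caplog):
        import logging

        ch = Channel("TEMP", "wrist", 4.0, np.arange(50.0))
        with caplog.at_level(logging.INFO, logger="stresscare.preprocessing"):
            smooth_channel(ch, FilterConfig(smooth_window_samples=10))
        assert "11" in caplog.text

    def test_window_longer_than_series_rejected(self):
        ch = Channel("TEMP", "wrist", 4.0, np.zeros(5))
        with pytest.raises(ValidationError):
            smooth_channel(ch, FilterConfig())

    def test_bvp_not_smoothed(self):
        ch = _sine_channel(1.0)
        with pytest.raises(ValidationError):
            smooth_channel(ch, FilterConfig())


def _labelled_recording(total_s, label=0, rate=4.0):
    n = int(total_s * rate)
    ch = Channel("EDA", "wrist", rate, np.random.default_rng(0).standard_normal(n))
    return Recording("s", [ch], np.full(n, label, dtype=int), rate)


class TestSegmentation:
    @pytest.mark.parametrize(
        "total_s,expected_starts",
        [
            (114, [0, 8, 16, 24, 32, 40, 48, 56, 64]),  # floor((114-50)/8)+1 = 9
            (50, [0]),
            (49, []),
        ],
    )
    def test_window_placement(self, total_s, expected_starts):
        segs = segment(_labelled_recording(total_s), SegmentationConfig())
        assert [s.start_s for s in segs.segments] == expected_starts

    def test_segment_slices_cover_window(self):
        segs = segment(_labelled_recording(114), SegmentationConfig())
        for s in segs.segments:
            assert s.end_s - s.start_s == 50.0
            assert s.slices["wrist/EDA"].size == 200  # 50 s at 4 Hz

    def test_majority_label_and_drop_rule(self):
        # 100 s: 0..54 s label 0, 54..100 s label 1; window [8,58) is 46/50 label 0;
        # window [48,98) splits 6/44 -> label 1; none ties exactly.
        labels = np.array([0] * (54 * 4) + [1] * (46 * 4))
        ch = Channel("EDA", "wrist", 4.0, np.zeros(400))
        segs = segment(Recording("s", [ch], labels, 4.0), SegmentationConfig())
        by_start = {s.start_s: s.label for s in segs.segments}
        assert by_start[8.0] == 0
        assert by_start[48.0] == 1

    def test_exact_tie_dropped(self):
        # window [0,50) with 25 s of each label -> tie -> dropped
        labels = np.array([0] * 100 + [1] * 100)
        ch = Channel("EDA", "wrist", 4.0, np.zeros(200))
        segs = segment(Recording("s", [ch], labels, 4.0), SegmentationConfig())
        assert len(segs) == 0
        assert segs.n_dropped_label == 1

    def test_masked_runs_segmented_independently(self):
        # 120 s with 60..64 s masked: two runs of 60 s and 56 s -> 2 + 1 windows
        n = 120 * 4
        labels = np.zeros(n, dtype=int)
        mask = np.ones(n, dtype=bool)
        mask[60 * 4 : 64 * 4] = False
        ch = Channel("EDA", "wrist", 4.0, np.zeros(n))
        segs = segment(Recording("s", [ch], labels, 4.0, mask=mask), SegmentationConfig())
        starts = [s.start_s for s in segs.segments]
        assert starts == [0.0, 8.0, 64.0]

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        total=st.integers(min_value=1, max_value=10_000),
        window=st.integers(min_value=1, max_value=300),
        stride=st.integers(min_value=1, max_value=60),
    )
    def test_count_formula_matches_brute_force(self, total, window, stride):
        """Place every window explicitly and compare with the closed form."""
        brute = sum(1 for k in range(total) if k * stride + window <= total)
        assert expected_segment_count(total, window, stride) == brute


class TestPreprocessRecording:
    def test_segment_count_channel_independent(self, tiny_recording):
        segs = preprocess_recording(tiny_recording)
        # 120 s, W=50, S=8 -> floor(70/8)+1 = 9 candidate windows; the ones
        # straddling the 60 s boundary keep their majority label
        assert len(segs) + segs.n_dropped_label == 9
        for s in segs.segments:
            assert set(s.slices) == {f"{c.device}/{c.name}" for c in tiny_recording.channels}

    def test_deterministic(self, tiny_recording):
        a = preprocess_recording(tiny_recording)
        b = preprocess_recording(tiny_recording)
        assert [s.label for s in a.segments] == [s.label for s in b.segments]
        for sa, sb in zip(a.segments, b.segments):
            for key in sa.slices:
                np.testing.assert_array_equal(sa.slices[key], sb.slices[key])

    def test_no_cardiac_channel_ok(self):
        n = 60 * 4
        chs = [
            Channel("TEMP", "wrist", 4.0, np.random.default_rng(1).standard_normal(n)),
            Channel("EDA", "wrist", 4.0, np.random.default_rng(2).standard_normal(n)),
        ]
        rec = Recording("s", chs, np.zeros(n, dtype=int), 4.0)
        segs = preprocess_recording(rec)
        assert len(segs) == 2  # floor((60-50)/8)+1

    def test_filter_then_segment_equals_segment_of_filtered(self, tiny_recording):
        """Filters run whole-series, so slicing afterwards is equivalent."""
        from stresscare.preprocessing import CARDIAC_CHANNELS

        filt = FilterConfig()
        segs = preprocess_recording(tiny_recording, filt)
        for ch in tiny_recording.channels:
            out = ch
            if ch.name != "BVP":
                out = smooth_channel(out, filt)
            if ch.name in CARDIAC_CHANNELS:
                out = bandpass_cardiac(out, filt)
            for s in segs.segments:
                i0 = int(round(s.start_s * ch.sampling_rate_hz))
                i1 = int(round(s.end_s * ch.sampling_rate_hz))
                np.testing.assert_array_equal(
                    s.slices[f"{ch.device}/{ch.name}"], out.samples[i0:i1]
                )
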