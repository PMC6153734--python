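"""Filters, downsampling and artifact detection."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eggkit.io import HeaderMeta, Recording
from eggkit.preprocess import (
    ArtifactMask,
    FilterSpec,
    antialias_downsample,
    combine_masks,
    detect_artifacts,
    extract_egg,
    filter_channel,
)

ALL_METHODS = ["butterworth", "zero_phase_inverse_butterworth", "ib_dct"]


def _rec(data, fs):
    data = np.atleast_2d(data)
    if data.shape[0] == 1:
        data = np.tile(data, (4, 1))
    return Recording(data, ["A1", "A2", "A3", "A4"], fs, HeaderMeta(fs_hz=fs, counts_per_mv=1000))


class TestFilters:
    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_in_band_sine_amplitude_and_phase(self, method):
        # 3 cpm = 0.05 Hz is well inside the 0.008-0.15 Hz band
        fs = 4.0
        t = np.arange(int(1800 * fs)) / fs
        x = np.sin(2 * np.pi * 0.05 * t)
        y = filter_channel(x, FilterSpec(method=method), fs)
        mid = slice(2000, -2000)  # ignore edge transients
        assert np.abs(y[mid]).max() == pytest.approx(1.0, rel=0.01)
        # zero phase: cross-correlation peak at lag 0 (+-1 sample)
        seg_x, seg_y = x[mid], y[mid]
        lags = range(-5, 6)
        xc = [np.dot(seg_x[5 + l : -5 + l or None], seg_y[5:-5]) for l in lags]
        assert abs(list(lags)[int(np.argmax(xc))]) <= 1

    @pytest.mark.parametrize("method", ALL_METHODS)
    def test_dc_rejected(self, method):
        fs = 4.0
        x = np.ones(4000)
        y = filter_channel(x, FilterSpec(method=method, low_hz=0.008, high_hz=0.15), fs)
        assert np.abs(y[500:-500]).max() < 0.05

    def test_ecg_component_attenuated_40db(self):
        # designed response of the two-pass 4th-order band-pass at 1.2 Hz
        from scipy import signal as sps

        from eggkit.preprocess import _sos_bandpass

        sos = _sos_bandpass(0.008, 0.15, fs=4.0)
        _, h = sps.sosfreqz(sos, worN=[1.2], fs=4.0)
        atten_db = -20 * np.log10(np.abs(h[0])) * 2  # forward + reverse pass
        assert atten_db >= 40

    def test_invalid_band_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(low_hz=0.2, high_hz=0.1)

    def test_extract_preserves_sensor(self):
        fs = 4.0
        data = np.vstack([np.random.default_rng(0).standard_normal((4, 2000)),
                          np.ones((1, 2000))])
        rec = Recording(data, ["A1", "A2", "A3", "A4", "sensor"], fs,
                        HeaderMeta(fs_hz=fs, counts_per_mv=1000))
        out = extract_egg(rec)
        np.testing.assert_array_equal(out.data[4], data[4])
        assert not np.allclose(out.data[0], data[0])


class TestDownsample:
    def test_sample_count_90min_200hz(self):
        fs = 200.0
        n = int(90 * 60 * fs)
        rec = _rec(np.zeros(n), fs)
        out = antialias_downsample(rec)
        assert out.fs_hz == 4.0
        assert out.n_samples == 21600  # 90 * 60 * 4

    def test_spectral_peak_preserved(self):
        fs = 200.0
        t = np.arange(int(600 * fs)) / fs
        x = np.sin(2 * np.pi * 0.05 * t)  # 3 cpm
        out = antialias_downsample(_rec(x, fs))
        y = out.data[0] - out.data[0].mean()
        spec = np.abs(np.fft.rfft(y)) ** 2
        freqs = np.fft.rfftfreq(y.size, 1 / 4.0) * 60
        peak = freqs[np.argmax(spec)]
        assert abs(peak - 3.0) <= freqs[1] - freqs[0]

    def test_identity_at_4hz(self):
        rec = _rec(np.arange(1000.0), 4.0)
        out = antialias_downsample(rec)
        np.testing.assert_array_equal(out.data, rec.data)

    def test_fs_below_4_rejected(self):
        with pytest.raises(ValueError):
            HeaderMeta(fs_hz=2).validate()

    def test_non_integer_ratio(self):
        # 250 Hz -> 4 Hz needs rational resampling
        fs = 250.0
        t = np.arange(int(120 * fs)) / fs
        out = antialias_downsample(_rec(np.sin(2 * np.pi * 0.05 * t), fs))
        assert out.fs_hz == 4.0
        assert out.n_samples == pytest.approx(120 * 4, abs=2)


class TestArtifacts:
    def test_method1_flags_spiked_segment(self, rng):
        fs, seg_s = 4.0, 240.0
        x = rng.standard_normal(int(10 * seg_s * fs))
        spike_seg = 4
        x[int(spike_seg * seg_s * fs) + 100] = 100.0  # 100 x SD spike
        mask = detect_artifacts(x, fs, seg_s, method=1, threshold=4.2)
        # direct oracle: per-segment SDs, their mean, 4.2x limit
        segs = x.reshape(10, -1)
        limit = segs.std(axis=1, ddof=1).mean() * 4.2
        expected = np.abs(segs).max(axis=1) > limit
        np.testing.assert_array_equal(mask.flags, expected)
        assert mask.flags[spike_seg]
        assert mask.flags.sum() == 1

    def test_method2_homogeneous_variance_clean(self, rng):
        fs, seg_s = 4.0, 60.0
        x = np.tile(rng.standard_normal(int(seg_s * fs)), 8)  # identical segments
        mask = detect_artifacts(x, fs, seg_s, method=2, threshold=1.6)
        assert not mask.flags.any()

    def test_all_zero_signal_unflagged(self):
        mask = detect_artifacts(np.zeros(4000), 4.0, 100.0, method=1)
        assert not mask.flags.any()

    def test_bad_threshold(self):
        with pytest.raises(ValueError):
            detect_artifacts(np.ones(400), 4.0, 10.0, threshold=0)

    @pytest.mark.parametrize("method", [1, 2])
    @given(seed=st.integers(0, 200))
    @settings(deadline=None, max_examples=25)
    def test_flags_monotone_in_threshold(self, method, seed):
        """Raising the threshold never flags a previously clean segment."""
        x = np.random.default_rng(seed).standard_normal(1600)
        x[:40] *= 6.0
        prev = None
        for thr in (1.2, 2.0, 4.2, 8.0):
            flags = detect_artifacts(x, 4.0, 50.0, method=method, threshold=thr).flags
            if prev is not None:
                assert np.all(flags <= prev)
            prev = flags


class TestCombineMasks:
    def _mask(self, flags):
        return ArtifactMask(segment_len_s=240.0, flags=np.array(flags, dtype=bool))

    def test_union_across_channels(self):
        a = self._mask([0, 0, 0, 0, 0, 1, 0])
        b = self._mask([0, 0, 0, 0, 0, 0, 0])
        combined = combine_masks([a, b, b, b])
        assert combined.flags[5] and combined.flags.sum() == 1

    def test_manual_interval_overlap(self):
        clean = self._mask([0] * 8)
        combined = combine_masks([clean], manual_intervals_min=[(10.0, 12.0)])
        # 10-12 min on a 240 s grid touches segments 2 and 3
        assert list(np.nonzero(combined.flags)[0]) == [2, 3]

    def test_empty_inputs_all_clean(self):
        combined = combine_masks([], segment_len_s=240.0, n_segments=6)
        assert not combined.flags.any()

    def test_out_of_range_interval_clipped(self):
        clean = self._mask([0] * 4)
        with pytest.warns(UserWarning, match="outside"):
            combined = combine_masks([clean], manual_intervals_min=[(100.0, 101.0)])
        assert not combined.flags.any()


def test_clean_record_mostly_unflagged(noisy_3cpm_rec):
    """Default thresholds keep >= 95% of an artifact-free record."""
    from eggkit.preprocess import detect_artifacts_all_channels

    rec4 = extract_egg(antialias_downsample(noisy_3cpm_rec))
    for method in (1, 2):
        masks = detect_artifacts_all_channels(rec4, 240.0, method=method)
        combined = combine_masks(masks)
        assert combined.flags.mean() <= 0.05
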