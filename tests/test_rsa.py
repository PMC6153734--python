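"""Running spectrum analysis: estimators, order selection, dominant peak."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from eggkit.rsa import (
    RSAConfig,
    Spectrum,
    burg_all_orders,
    classify_rhythm,
    find_dominant,
    psd_ar,
    psd_periodogram,
    run_rsa,
    segment_signal,
    select_ar_order,
)


def _windows(name, n):
    from scipy.signal import windows

    return {"tukey_0.25": windows.tukey(n, 0.25), "barthann": windows.barthann(n),
            "hann": windows.hann(n)}[name]


class TestSegmentation:
    def test_1800s_240_120(self):
        fs = 4.0
        segs = segment_signal(np.zeros(int(1800 * fs)), fs, 240, 120)
        assert len(segs) == 14  # floor((1800-240)/120)+1
        assert [t for t, _ in segs] == [120.0 * k for k in range(14)]

    def test_disjoint_tiling(self):
        segs = segment_signal(np.zeros(1000), 4.0, 60, 0)
        starts = [t for t, _ in segs]
        assert starts == [0.0, 60.0, 120.0, 180.0]

    def test_exactly_one_segment(self):
        segs = segment_signal(np.zeros(960), 4.0, 240, 120)
        assert len(segs) == 1

    def test_too_short(self):
        with pytest.raises(ValueError):
            segment_signal(np.zeros(100), 4.0, 240, 120)


def _burg_sigma2_oracle(x, order):
    """Textbook Burg run from scratch for a single order."""
    f = np.asarray(x[1:], dtype=float)
    b = np.asarray(x[:-1], dtype=float)
    e = np.dot(x, x) / len(x)
    for _ in range(order):
        k = -2.0 * np.dot(f, b) / (np.dot(f, f) + np.dot(b, b))
        e *= 1.0 - k * k
        f, b = f[1:] + k * b[1:], b[:-1] + k * f[:-1]
    return e


class TestAROrder:
    def test_coefficients_match_statsmodels(self, rng):
        """Dual route: the lattice recursion against statsmodels burg."""
        from statsmodels.regression.linear_model import burg as sm_burg

        x = rng.standard_normal(400)
        for i in range(2, x.size):
            x[i] += 1.3 * x[i - 1] - 0.7 * x[i - 2]
        x -= x.mean()
        coeffs, _ = burg_all_orders(x, 10)
        for p in (2, 6, 10):
            rho, _ = sm_burg(x, order=p, demean=False)
            np.testing.assert_allclose(-coeffs[p - 1][1:], rho, rtol=1e-10)

    def test_order_is_aic_argmin_plus_6(self, rng):
        """Definitional identity against a per-order from-scratch oracle."""
        for _ in range(5):
            x = rng.standard_normal(300)
            n = x.size
            aic = [n * np.log(_burg_sigma2_oracle(x, p)) + 2 * p for p in range(1, 31)]
            expected = int(np.argmin(aic)) + 1 + 6
            assert select_ar_order(x) == expected

    def test_ar2_process_low_order(self, rng):
        x = rng.standard_normal(960)
        for i in range(2, x.size):
            x[i] += 1.2 * x[i - 1] - 0.6 * x[i - 2]
        order = select_ar_order(x - x.mean())
        assert order - 6 in range(2, 5)  # AIC argmin lands at 2..4

    def test_white_noise_low_order(self, rng):
        orders = [select_ar_order(rng.standard_normal(500)) for _ in range(5)]
        assert np.median(orders) <= 3 + 6

    def test_constant_segment_fallback(self):
        assert select_ar_order(np.zeros(100)) == 1 + 6


class TestPsdAr:
    def test_peak_at_3cpm(self, rng):
        fs = 4.0
        t = np.arange(960) / fs
        x = np.sin(2 * np.pi * 0.05 * t) + 0.1 * rng.standard_normal(t.size)
        spec = psd_ar(x, fs)
        assert spec.freq_cpm[np.argmax(spec.psd)] == pytest.approx(3.0, abs=0.2)

    def test_nonnegative(self, rng):
        spec = psd_ar(rng.standard_normal(960), 4.0)
        assert np.all(spec.psd >= 0)

    def test_white_noise_no_spurious_peak(self, rng):
        spec = psd_ar(rng.standard_normal(960), 4.0, order=8)
        band = (spec.freq_cpm >= 0.5) & (spec.freq_cpm <= 9.0)
        assert spec.psd[band].max() < 3.0 * np.median(spec.psd[band])

    def test_order_too_high_rejected(self):
        with pytest.raises(ValueError):
            psd_ar(np.ones(10), 4.0, order=20)


class TestPsdPeriodogram:
    @pytest.mark.parametrize("window", ["tukey_0.25", "barthann", "hann"])
    @pytest.mark.parametrize("n", [16, 33, 64])
    def test_equals_brute_force_dft(self, rng, window, n):
        """The implementation must match |DFT|^2 with window-energy scaling."""
        fs = 4.0
        lspv = 80
        x = rng.standard_normal(n)
        spec = psd_periodogram(x, fs, window=window, lspv=lspv)
        w = _windows(window, n)
        nfft = 2 * (lspv - 1)
        k = np.arange(lspv)
        dft = np.array(
            [np.sum(x * w * np.exp(-2j * np.pi * kk * np.arange(n) / nfft)) for kk in k]
        )
        oracle = np.abs(dft) ** 2 / (fs * np.sum(w**2))
        oracle[1:-1] *= 2  # one-sided, nfft even: DC and Nyquist not doubled
        np.testing.assert_allclose(spec.psd * 60.0, oracle, rtol=1e-9, atol=1e-12)

    def test_zero_input_zero_spectrum(self):
        spec = psd_periodogram(np.zeros(64), 4.0, lspv=128)
        assert np.all(spec.psd == 0)

    def test_pure_sine_peak_on_grid(self):
        fs = 4.0
        t = np.arange(960) / fs
        spec = psd_periodogram(np.sin(2 * np.pi * 0.05 * t), fs, lspv=4096)
        step = spec.freq_cpm[1] - spec.freq_cpm[0]
        assert abs(spec.freq_cpm[np.argmax(spec.psd)] - 3.0) <= step

    def test_window_energy_normalization(self, rng):
        """Unit-variance white noise: mean PSD independent of the window."""
        x = rng.standard_normal(4096)
        means = [
            np.mean(psd_periodogram(x, 4.0, window=w, lspv=4096).psd)
            for w in ("tukey_0.25", "barthann", "hann")
        ]
        assert max(means) / min(means) == pytest.approx(1.0, rel=0.1)

    def test_unknown_window(self):
        with pytest.raises(ValueError, match="window"):
            psd_periodogram(np.zeros(8), 4.0, window="boxcar")


def _two_peak_spectrum(gap_db, second_cpm=3.0):
    """DC-dominant spectrum with a secondary peak ``gap_db`` below it."""
    freq = np.linspace(0.0, 30.0, 1000)
    psd = np.full(freq.size, 1e-6)
    psd += 10.0 * np.exp(-(freq**2) / (2 * 0.05**2))  # DC lobe
    psd += 10.0 * 10 ** (-gap_db / 10.0) * np.exp(-((freq - second_cpm) ** 2) / (2 * 0.1**2))
    return Spectrum(freq_cpm=freq, psd=psd)


class TestFindDominant:
    def test_single_in_band_peak(self):
        freq = np.linspace(0, 30, 1000)
        psd = 1e-6 + np.exp(-((freq - 3.0) ** 2) / (2 * 0.1**2))
        dom = find_dominant(Spectrum(freq_cpm=freq, psd=psd))
        assert dom.df_cpm == pytest.approx(3.0, abs=0.05)
        assert not dom.corrected and not dom.arrhythmia

    def test_correction_applied_at_1db_gap(self):
        dom = find_dominant(_two_peak_spectrum(gap_db=1.0))
        assert dom.corrected
        assert dom.df_cpm == pytest.approx(3.0, abs=0.05)

    def test_arrhythmia_at_4db_gap(self):
        dom = find_dominant(_two_peak_spectrum(gap_db=4.0))
        assert dom.arrhythmia and dom.df_cpm is None

    def test_corrected_gap_recomputes_below_2p5(self):
        """Stored-spectrum invariant: corrected => measured gap < 2.5 dB."""
        for gap in (0.5, 1.5, 2.4):
            spec = _two_peak_spectrum(gap_db=gap)
            dom = find_dominant(spec)
            assert dom.corrected
            imax = np.argmax(spec.psd)
            gap_measured = spec.db()[imax] - dom.dp_db
            assert gap_measured < 2.5

    def test_out_of_band_high_peak_is_arrhythmia(self):
        freq = np.linspace(0, 30, 1000)
        psd = 1e-6 + np.exp(-((freq - 20.0) ** 2) / 0.02)
        dom = find_dominant(Spectrum(freq_cpm=freq, psd=psd))
        assert dom.arrhythmia

    def test_spectrum_not_covering_band(self):
        with pytest.raises(ValueError):
            find_dominant(Spectrum(freq_cpm=np.array([20.0, 25.0]), psd=np.array([1.0, 1.0])))


class TestClassifyRhythm:
    @pytest.mark.parametrize(
        "df,expected",
        [
            (3.0, "normogastria"),
            (1.0, "bradygastria"),
            (5.0, "tachygastria"),
            (2.0, "normogastria"),  # band edges inclusive
            (4.0, "normogastria"),
            (None, "arrhythmia"),
        ],
    )
    def test_bands(self, df, expected):
        assert classify_rhythm(df, (2.0, 4.0)) == expected

    @given(df=st.floats(0.5, 9.0))
    @settings(deadline=None, derandomize=True)
    def test_df_always_classified(self, df):
        assert classify_rhythm(df) in {"bradygastria", "normogastria", "tachygastria"}


class TestRunRsa:
    def test_clean_record_all_normogastria(self, clean_3cpm_rec4):
        results = run_rsa(clean_3cpm_rec4, cfg=RSAConfig())
        for segs in results.values():
            assert segs, "no segments produced"
            assert all(s.rhythm == "normogastria" for s in segs)
            assert all(0.5 <= s.df_cpm <= 9.0 for s in segs)

    def test_masked_segment_excluded_everywhere(self, clean_3cpm_rec4):
        from eggkit.preprocess import ArtifactMask

        n_tiles = int(clean_3cpm_rec4.duration_s // 240)
        flags = np.zeros(n_tiles, dtype=bool)
        flags[2] = True
        mask = ArtifactMask(segment_len_s=240.0, flags=flags)
        results = run_rsa(clean_3cpm_rec4, mask=mask, cfg=RSAConfig())
        for segs in results.values():
            excluded = [s for s in segs if s.excluded]
            assert excluded
            assert all(s.df_cpm is None and s.dp_db is None for s in excluded)
        # same exclusion pattern in all 4 channels
        patterns = {tuple(s.excluded for s in segs) for segs in results.values()}
        assert len(patterns) == 1

    def test_requires_4hz(self, noisy_3cpm_rec):
        with pytest.raises(ValueError, match="4 Hz"):
            run_rsa(noisy_3cpm_rec)

    def test_ar_method_runs(self, clean_3cpm_rec4):
        cfg = RSAConfig(method="ar_aic")
        results = run_rsa(clean_3cpm_rec4, cfg=cfg)
        dfs = [s.df_cpm for s in results["A1"] if s.df_cpm]
        assert np.median(dfs) == pytest.approx(3.0, abs=0.2)
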