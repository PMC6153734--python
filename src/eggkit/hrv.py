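"""Heart-rate-variability analysis for high-rate EGG recordings.

Recordings sampled fast enough to retain the ECG (>= ~100 Hz; 250 Hz is
the reference rate) can yield basic HRV indices alongside the EGG. The
chain is: Pan-Tompkins QRS detection (band-pass 5-15 Hz, derivative,
squaring, moving-window integration, adaptive dual thresholds with
search-back), RR interval series, cubic-spline resampling of the
irregular tachogram to a uniform 4 Hz signal, then time-domain indices
(mean/std RR and HR, RMSSD, NN50, pNN50) and Welch-style band powers in
256 s windows with 128 s overlap: VLF 0.003-0.04 Hz, LF 0.04-0.15 Hz,
HF 0.15-0.40 Hz, with relative powers against total = VLF + LF + HF.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import signal as sps
from scipy.interpolate import CubicSpline

__all__ = [
    "detect_r_peaks",
    "build_and_resample_rr",
    "hrv_time_domain",
    "hrv_freq_domain",
    "HRV_BANDS_HZ",
]

HRV_BANDS_HZ = {"vlf": (0.003, 0.04), "lf": (0.04, 0.15), "hf": (0.15, 0.40)}
RESAMPLE_FS_HZ = 4.0
WINDOW_S = 256.0
OVERLAP_S = 128.0
REFRACTORY_S = 0.2


def detect_r_peaks(ecg: np.ndarray, fs: float) -> np.ndarray:
    """R-peak times (s) by the Pan-Tompkins algorithm.

    Stages: 5-15 Hz band-pass, derivative, squaring, 150 ms
    moving-window integration, then adaptive signal/noise thresholds
    with a 200 ms refractory period and search-back at half threshold
    when an expected beat is missed. Detections are refined to the
    nearest extremum of the band-passed ECG.
    """
    x = np.asarray(ecg, dtype=float)
    if fs < 100:
        raise ValueError(f"R detection needs fs >= 100 Hz, got {fs}")
    if fs < 250:
        warnings.warn(f"fs = {fs} Hz is below the 250 Hz reference rate; R timing is coarser",
                      stacklevel=2)
    if np.ptp(x) == 0:
        raise ValueError("flat signal: no QRS complexes to detect")

    sos = sps.butter(2, [5.0 / (fs / 2), 15.0 / (fs / 2)], btype="bandpass", output="sos")
    bp = sps.sosfiltfilt(sos, x)
    deriv = np.gradient(bp)
    sq = deriv**2
    win = max(int(round(0.15 * fs)), 1)
    mwi = np.convolve(sq, np.ones(win) / win, mode="same")

    refractory = int(round(REFRACTORY_S * fs))
    cand, _ = sps.find_peaks(mwi, distance=refractory)
    if cand.size < 2:
        raise ValueError("fewer than two QRS candidates found")

    # adaptive thresholding (Pan-Tompkins running estimates)
    spki = float(np.max(mwi[: int(2 * fs)])) * 0.5 if mwi.size >= int(2 * fs) else float(mwi.max()) * 0.5
    npki = float(np.mean(mwi[: int(2 * fs)])) * 0.5 if mwi.size >= int(2 * fs) else float(mwi.mean()) * 0.5
    beats: list[int] = []
    rr_hist: list[float] = []
    last = None
    for idx in cand:
        thr = npki + 0.25 * (spki - npki)
        if mwi[idx] > thr:
            if last is not None:
                rr_hist.append((idx - last) / fs)
                rr_hist = rr_hist[-8:]
            beats.append(idx)
            last = idx
            spki = 0.125 * mwi[idx] + 0.875 * spki
        else:
            npki = 0.125 * mwi[idx] + 0.875 * npki
            # search-back: accept at half threshold if a beat is overdue
            if last is not None and rr_hist:
                if (idx - last) / fs > 1.66 * float(np.mean(rr_hist)) and mwi[idx] > thr / 2:
                    rr_hist.append((idx - last) / fs)
                    rr_hist = rr_hist[-8:]
                    beats.append(idx)
                    last = idx
                    spki = 0.25 * mwi[idx] + 0.75 * spki
    if len(beats) < 2:
        raise ValueError("fewer than two R peaks detected")

    # refine each detection to the local |band-passed| maximum
    half = int(round(0.10 * fs))
    refined = []
    for idx in beats:
        lo, hi = max(idx - half, 0), min(idx + half + 1, x.size)
        refined.append(lo + int(np.argmax(np.abs(bp[lo:hi]))))
    refined = np.unique(refined)
    return refined / fs


def build_and_resample_rr(
    r_times_s: np.ndarray, fs_out: float = RESAMPLE_FS_HZ
) -> tuple[np.ndarray, np.ndarray]:
    """Uniformly resample the RR tachogram by cubic-spline interpolation.

    Each RR interval (ms) is anchored at the time of its closing R peak;
    a cubic spline through these points is evaluated on an ``fs_out``
    grid spanning [first, last] R time. Returns (t_grid_s, rr_ms).
    """
    t = np.asarray(r_times_s, dtype=float)
    if t.size < 4:
        raise ValueError(f"need at least 4 R peaks for spline resampling, got {t.size}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("R-peak times must be strictly increasing")
    rr_ms = np.diff(t) * 1000.0
    spline = CubicSpline(t[1:], rr_ms, extrapolate=True)
    grid = np.arange(t[0], t[-1] + 0.5 / fs_out, 1.0 / fs_out)
    return grid, spline(grid)


def hrv_time_domain(rr_ms: np.ndarray) -> dict[str, float]:
    """Time-domain indices from an RR interval list (ms).

    RMSSD is the root mean square of successive RR differences; NN50
    counts successive pairs differing by more than 50 ms; pNN50 divides
    NN50 by the total number of RR intervals. Heart-rate statistics are
    taken over the instantaneous rate series 60000/RR.
    """
    rr = np.asarray(rr_ms, dtype=float)
    if rr.size < 2:
        raise ValueError("need at least two RR intervals")
    if np.any(rr <= 0):
        raise ValueError("RR intervals must be positive")
    diffs = np.diff(rr)
    hr = 60000.0 / rr
    nn50 = int(np.sum(np.abs(diffs) > 50.0))
    return {
        "mean_rr_ms": float(rr.mean()),
        "std_rr_ms": float(rr.std(ddof=1)),
        "mean_hr_bpm": float(hr.mean()),
        "std_hr_bpm": float(hr.std(ddof=1)),
        "rmssd_ms": float(np.sqrt(np.mean(diffs**2))),
        "nn50_count": nn50,
        "pnn50_pct": 100.0 * nn50 / rr.size,
    }


def _band_powers(freqs: np.ndarray, psd: np.ndarray) -> dict[str, float]:
    out = {}
    for name, (lo, hi) in HRV_BANDS_HZ.items():
        inside = (freqs > lo) & (freqs < hi)
        f = np.concatenate([[lo], freqs[inside], [hi]])
        p = np.interp(f, freqs, psd)
        out[name] = float(np.trapezoid(p, f))
    return out


def hrv_freq_domain(
    rr_resampled_ms: np.ndarray,
    fs: float = RESAMPLE_FS_HZ,
    window_s: float = WINDOW_S,
    overlap_s: float = OVERLAP_S,
) -> dict:
    """Band powers of the resampled RR signal in sliding windows.

    Each 256 s window (128 s overlap) is linearly detrended, Hann
    windowed and periodogram-estimated; VLF/LF/HF absolute powers (ms^2)
    come from trapezoidal integration, relative powers from
    total = VLF + LF + HF. Aggregate values are means over windows.
    Returns per-window lists under ``"windows"`` plus the aggregate
    means (``mean_vlf_ms2`` ... ``mean_lf_hf``).
    """
    x = np.asarray(rr_resampled_ms, dtype=float)
    nwin = int(round(window_s * fs))
    step = int(round((window_s - overlap_s) * fs))
    if x.size < nwin:
        raise ValueError(
            f"signal ({x.size / fs:.0f} s) shorter than one {window_s:.0f} s window"
        )
    windows = []
    for start in range(0, x.size - nwin + 1, step):
        seg = sps.detrend(x[start : start + nwin], type="linear")
        w = sps.windows.hann(nwin)
        freqs, psd = sps.periodogram(seg, fs=fs, window=w, detrend=False, scaling="density")
        powers = _band_powers(freqs, psd)
        total = sum(powers.values())
        entry = {
            "t_start_s": start / fs,
            "vlf_ms2": powers["vlf"],
            "lf_ms2": powers["lf"],
            "hf_ms2": powers["hf"],
        }
        if total > 0:
            entry.update(
                vlf_pct=100.0 * powers["vlf"] / total,
                lf_pct=100.0 * powers["lf"] / total,
                hf_pct=100.0 * powers["hf"] / total,
                lf_hf=powers["lf"] / powers["hf"] if powers["hf"] > 0 else np.inf,
            )
        windows.append(entry)
    agg = {}
    for key in ("vlf_ms2", "lf_ms2", "hf_ms2", "vlf_pct", "lf_pct", "hf_pct", "lf_hf"):
        vals = [w[key] for w in windows if key in w and np.isfinite(w[key])]
        agg[f"mean_{key}"] = float(np.mean(vals)) if vals else None
    return {"windows": windows, **agg}
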