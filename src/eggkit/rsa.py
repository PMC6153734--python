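"""Running Spectrum Analysis (RSA).

The 4 Hz EGG signal is cut into overlapping segments (default 240 s
with 120 s overlap); each segment gets a power spectral density
estimate — a zero-padded windowed periodogram (Tukey alpha=0.25,
Barthann or Hann window) or an autoregressive (Burg) spectrum whose
order is picked by the Akaike information criterion plus a fixed +6
enhancement — and the dominant frequency (DF, cpm) and dominant power
(DP, dB) are read off the highest spectral peak in the 0.5-9.0 cpm
gastric band. When the raw maximum sits at/near zero frequency the
next local maximum is accepted instead, but only if it lies in band and
within 2.5 dB of the raw maximum; otherwise the segment is classed as
arrhythmia. DF against the normogastria band (default 2-4 cpm) yields
the rhythm class (bradygastria / normogastria / tachygastria).

PSDs are held in linear units of mV^2/cpm on a cpm frequency grid; dB
values are 10*log10 of that (the reference, 1 mV^2/cpm, is a package
convention — only dB differences are clinically meaningful).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from scipy import signal as sps

from eggkit.io import Recording
from eggkit.preprocess import ArtifactMask

__all__ = [
    "RSAConfig",
    "Spectrum",
    "SegmentResult",
    "DominantResult",
    "segment_signal",
    "burg_all_orders",
    "select_ar_order",
    "psd_ar",
    "psd_periodogram",
    "find_dominant",
    "classify_rhythm",
    "run_rsa",
]

DF_RANGE_CPM = (0.5, 9.0)
NORMO_CPM = (2.0, 4.0)
CORRECTION_GAP_DB = 2.5
#: "next maximum" search floor: local maxima at or below this are part of the DC lobe
DC_LOBE_CPM = 0.25
AR_CANDIDATE_ORDERS = range(1, 31)
AR_ORDER_OFFSET = 6

_WINDOWS = {
    "tukey_0.25": lambda n: sps.windows.tukey(n, alpha=0.25),
    "barthann": sps.windows.barthann,
    "hann": sps.windows.hann,
}

_METHOD_WINDOW = {
    "periodogram_tukey": "tukey_0.25",
    "periodogram_barthann": "barthann",
    "periodogram_hann": "hann",
}


@dataclass
class RSAConfig:
    """Settings for running spectrum analysis.

    lseg_s: segment length in seconds (60-256, default 240).
    sseg_s: overlap between consecutive segments in seconds (default 120).
    lspv: number of spectral samples on [0, fs/2] (default 4096).
    normo_cpm: normogastria band in cpm (default 2-4).
    method: ``ar_aic`` or one of the three periodogram windows.
    df_range_cpm: search band for the dominant frequency (default 0.5-9).
    """

    lseg_s: float = 240.0
    sseg_s: float = 120.0
    lspv: int = 4096
    normo_cpm: tuple[float, float] = NORMO_CPM
    method: str = "periodogram_tukey"
    df_range_cpm: tuple[float, float] = DF_RANGE_CPM

    def __post_init__(self) -> None:
        if not 60 <= self.lseg_s <= 256:
            raise ValueError(f"segment length must be 60-256 s, got {self.lseg_s}")
        if not 0 <= self.sseg_s < self.lseg_s:
            raise ValueError(f"overlap must satisfy 0 <= sseg < lseg, got {self.sseg_s}")
        if self.method not in ("ar_aic", *_METHOD_WINDOW):
            raise ValueError(f"unknown RSA method {self.method!r}")
        if not self.normo_cpm[0] < self.normo_cpm[1]:
            raise ValueError("normogastria band is empty")


@dataclass
class Spectrum:
    """A one-sided PSD on an ascending cpm grid, linear power units."""

    freq_cpm: np.ndarray
    psd: np.ndarray
    method: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.freq_cpm = np.asarray(self.freq_cpm, dtype=float)
        self.psd = np.asarray(self.psd, dtype=float)
        if self.freq_cpm.shape != self.psd.shape:
            raise ValueError("frequency grid and PSD must have equal length")
        if np.any(self.psd < 0):
            raise ValueError("PSD must be nonnegative")

    def db(self, floor: float = 1e-300) -> np.ndarray:
        """dB view, 10*log10(psd)."""
        return 10.0 * np.log10(np.maximum(self.psd, floor))


@dataclass
class SegmentResult:
    """DF/DP, rhythm class and artifact status for one RSA segment."""

    t_start_s: float
    channel: str
    df_cpm: float | None = None
    dp_db: float | None = None
    rhythm: str | None = None
    corrected: bool = False
    excluded: bool = False


class DominantResult(NamedTuple):
    df_cpm: float | None
    dp_db: float | None
    corrected: bool
    arrhythmia: bool


def segment_signal(
    x: np.ndarray, fs: float, lseg_s: float, sseg_s: float
) -> list[tuple[float, np.ndarray]]:
    """Cut a signal into overlapping segments.

    The first segment starts at t=0 and each next one advances by
    ``lseg_s - sseg_s``; a trailing partial segment is dropped.
    Returns (t_start_s, samples) pairs.
    """
    x = np.asarray(x)
    nseg = int(round(lseg_s * fs))
    step = int(round((lseg_s - sseg_s) * fs))
    if step < 1:
        raise ValueError("overlap must be strictly smaller than the segment length")
    if x.size < nseg:
        raise ValueError(f"signal ({x.size} samples) shorter than one segment ({nseg})")
    out = []
    for start in range(0, x.size - nseg + 1, step):
        out.append((start / fs, x[start : start + nseg]))
    return out


def burg_all_orders(x: np.ndarray, max_order: int) -> tuple[list[np.ndarray], np.ndarray]:
    """Burg lattice recursion, returning AR polynomials for every order.

    Returns (coeffs, sigma2) where ``coeffs[p-1]`` is the monic AR(p)
    polynomial [1, a1..ap] of x[n] + a1 x[n-1] + ... = e[n] and
    ``sigma2[p]`` is the driving-noise variance after fitting order p
    (``sigma2[0]`` is the signal variance). Reflection coefficients are
    bounded by 1, so every returned model is stable.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if max_order >= n:
        raise ValueError(f"AR order {max_order} must be below the segment length {n}")
    ef = x[1:].astype(float)
    eb = x[:-1].astype(float)
    a = np.array([1.0])
    sigma2 = np.empty(max_order + 1)
    sigma2[0] = np.dot(x, x) / n
    coeffs: list[np.ndarray] = []
    for m in range(1, max_order + 1):
        denom = np.dot(ef, ef) + np.dot(eb, eb)
        k = 0.0 if denom == 0 else -2.0 * np.dot(ef, eb) / denom
        a_ext = np.concatenate([a, [0.0]])
        a = a_ext + k * a_ext[::-1]
        sigma2[m] = sigma2[m - 1] * (1.0 - k * k)
        ef, eb = ef[1:] + k * eb[1:], eb[:-1] + k * ef[:-1]
        coeffs.append(a.copy())
    return coeffs, sigma2


def select_ar_order(
    segment_windowed: np.ndarray,
    candidates: Sequence[int] = AR_CANDIDATE_ORDERS,
    offset: int = AR_ORDER_OFFSET,
) -> int:
    """AR model order: AIC minimum over candidate orders, plus 6.

    AIC(p) = N ln(sigma2_p) + 2p with sigma2 from the Burg recursion.
    The fixed +6 enhancement sharpens spectral detail. A degenerate
    (constant) segment falls back to the minimum candidate order.
    """
    x = np.asarray(segment_windowed, dtype=float)
    candidates = sorted(candidates)
    coeffs, sigma2 = burg_all_orders(x, candidates[-1])
    if sigma2[0] <= 0 or not np.isfinite(np.log(max(sigma2[candidates[-1]], 1e-300))):
        return candidates[0] + offset
    n = x.size
    aic = np.array([n * np.log(max(sigma2[p], 1e-300)) + 2 * p for p in candidates])
    return candidates[int(np.argmin(aic))] + offset


def _grid_cpm(fs: float, lspv: int) -> np.ndarray:
    return np.linspace(0.0, fs / 2.0, lspv) * 60.0


def psd_ar(
    segment: np.ndarray,
    fs: float,
    lspv: int = 4096,
    order: int | None = None,
    window: str | None = "tukey_0.25",
) -> Spectrum:
    """Autoregressive (Burg) power spectrum of one segment.

    The segment is demeaned and windowed, the order chosen by
    :func:`select_ar_order` unless given, and the one-sided AR spectrum
    2*sigma2 / (fs |A(f)|^2) evaluated on ``lspv`` points over
    [0, fs/2]; frequencies are reported in cpm and power in mV^2/cpm.
    """
    x = np.asarray(segment, dtype=float)
    x = x - x.mean()
    if window is not None:
        x = x * _WINDOWS[window](x.size)
    if order is None:
        order = select_ar_order(x)
    if order >= x.size:
        raise ValueError(f"AR order {order} must be below the segment length {x.size}")
    coeffs, sigma2 = burg_all_orders(x, order)
    a = coeffs[-1]
    if not np.all(np.isfinite(a)):
        raise ValueError("unstable AR fit: non-finite coefficients")
    freqs_hz = np.linspace(0.0, fs / 2.0, lspv)
    _, h = sps.freqz(1.0, a, worN=freqs_hz, fs=fs)
    psd_hz = 2.0 * sigma2[-1] / fs * np.abs(h) ** 2
    return Spectrum(
        freq_cpm=freqs_hz * 60.0,
        psd=psd_hz / 60.0,
        method="ar_aic",
        meta={"order": order, "sigma2": float(sigma2[-1])},
    )


def psd_periodogram(
    segment: np.ndarray,
    fs: float,
    window: str = "tukey_0.25",
    lspv: int = 4096,
) -> Spectrum:
    """Windowed, zero-padded periodogram of one segment.

    The window is energy-normalized (scipy ``density`` scaling by
    fs * sum(w^2)), so a unit-variance white input yields the same mean
    PSD for every window choice. ``lspv`` spectral samples cover
    [0, fs/2]; frequencies in cpm, power in mV^2/cpm.
    """
    x = np.asarray(segment, dtype=float)
    if window not in _WINDOWS:
        raise ValueError(f"unknown window {window!r}; choose from {sorted(_WINDOWS)}")
    if lspv < x.size:
        raise ValueError(f"lspv ({lspv}) must be >= segment length ({x.size})")
    w = _WINDOWS[window](x.size)
    nfft = 2 * (lspv - 1)
    freqs_hz, psd_hz = sps.periodogram(
        x, fs=fs, window=w, nfft=nfft, detrend=False, scaling="density"
    )
    return Spectrum(
        freq_cpm=freqs_hz * 60.0,
        psd=psd_hz / 60.0,
        method=f"periodogram_{window}",
        meta={"window": window, "nfft": nfft},
    )


def find_dominant(
    spec: Spectrum, df_range_cpm: tuple[float, float] = DF_RANGE_CPM
) -> DominantResult:
    """Dominant frequency/power with the 2.5 dB near-DC correction.

    DF is the frequency of the global PSD maximum when it lies in the
    gastric band. If the global maximum sits below the band (the DC
    lobe), the largest other local maximum above 0.25 cpm is examined:
    it becomes the (corrected) DF only if it lies in band and its dB gap
    to the global maximum is < 2.5 dB; otherwise the segment is
    arrhythmic. A global maximum above the band is also arrhythmic.
    Ties break toward the lower frequency.
    """
    lo, hi = df_range_cpm
    freq, psd = spec.freq_cpm, spec.psd
    if not np.any((freq >= lo) & (freq <= hi)):
        raise ValueError(f"spectrum does not cover the {lo}-{hi} cpm band")
    imax = int(np.argmax(psd))  # first occurrence -> lower frequency on ties
    f0 = freq[imax]
    if lo <= f0 <= hi:
        return DominantResult(float(f0), float(spec.db()[imax]), False, False)
    if f0 > hi:
        return DominantResult(None, None, False, True)
    # global maximum in the DC region: examine the next local maximum
    peaks, _ = sps.find_peaks(psd)
    peaks = peaks[(freq[peaks] > DC_LOBE_CPM) & (peaks != imax)]
    if peaks.size == 0:
        return DominantResult(None, None, False, True)
    second = int(peaks[np.argmax(psd[peaks])])
    gap_db = 10.0 * np.log10(psd[imax] / psd[second]) if psd[second] > 0 else np.inf
    if lo <= freq[second] <= hi and gap_db < CORRECTION_GAP_DB:
        return DominantResult(float(freq[second]), float(spec.db()[second]), True, False)
    return DominantResult(None, None, False, True)


def classify_rhythm(
    df_cpm: float | None,
    normo_cpm: tuple[float, float] = NORMO_CPM,
    df_range_cpm: tuple[float, float] = DF_RANGE_CPM,
) -> str:
    """Map a dominant frequency to its gastric rhythm class."""
    if df_cpm is None:
        return "arrhythmia"
    lo, hi = normo_cpm
    if df_cpm < lo:
        return "bradygastria"
    if df_cpm <= hi:
        return "normogastria"
    return "tachygastria"


def estimate_psd(segment: np.ndarray, fs: float, method: str, lspv: int) -> Spectrum:
    """Dispatch to the configured PSD estimator (segment is demeaned)."""
    if method == "ar_aic":
        return psd_ar(segment, fs, lspv=lspv)
    if method in _METHOD_WINDOW:
        x = np.asarray(segment, dtype=float)
        return psd_periodogram(x - x.mean(), fs, window=_METHOD_WINDOW[method], lspv=lspv)
    raise ValueError(f"unknown PSD method {method!r}")


def run_rsa(
    rec: Recording,
    mask: ArtifactMask | None = None,
    cfg: RSAConfig | None = None,
) -> dict[str, list[SegmentResult]]:
    """Per-segment DF/DP and rhythm class for every EGG channel.

    The recording must already be at the 4 Hz analysis rate. Segments
    overlapping a flagged artifact-mask segment are excluded in all
    channels and carry no DF/DP.
    """
    cfg = cfg or RSAConfig()
    if rec.fs_hz != 4.0:
        raise ValueError(f"RSA expects a 4 Hz recording (got {rec.fs_hz} Hz); downsample first")
    results: dict[str, list[SegmentResult]] = {}
    for label, x in zip(rec.egg_channels, rec.egg_data()):
        segs = segment_signal(x, rec.fs_hz, cfg.lseg_s, cfg.sseg_s)
        out = []
        for t0, seg in segs:
            if mask is not None and mask.excludes(t0, t0 + cfg.lseg_s):
                out.append(SegmentResult(t_start_s=t0, channel=label, excluded=True))
                continue
            try:
                spec = estimate_psd(seg, rec.fs_hz, cfg.method, cfg.lspv)
                dom = find_dominant(spec, cfg.df_range_cpm)
            except ValueError as exc:
                raise ValueError(f"channel {label}, segment at t={t0} s: {exc}") from exc
            rhythm = classify_rhythm(dom.df_cpm, cfg.normo_cpm, cfg.df_range_cpm)
            out.append(
                SegmentResult(
                    t_start_s=t0,
                    channel=label,
                    df_cpm=dom.df_cpm,
                    dp_db=dom.dp_db,
                    rhythm=rhythm,
                    corrected=dom.corrected,
                )
            )
        results[label] = out
    return results
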