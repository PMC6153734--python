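"""EGG band extraction, anti-alias downsampling and artifact flagging.

The gastric slow wave occupies 0.5-9.0 cpm (0.008-0.15 Hz), far below
respiration and cardiac activity, so preprocessing is (i) a zero-phase
band-pass to isolate that band, (ii) for high-rate recordings, a
zero-phase 2 Hz low-pass followed by decimation to the 4 Hz analysis
rate, and (iii) exclusion of movement-artifact segments found by
standard-deviation thresholding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft
from scipy import signal

from eggkit.io import Recording

__all__ = [
    "FilterSpec",
    "ArtifactMask",
    "extract_egg",
    "antialias_downsample",
    "detect_artifacts",
    "combine_masks",
    "DEFAULT_EGG_BAND_HZ",
]

#: Default EGG extraction band: 0.5-9.0 cpm expressed in Hz.
DEFAULT_EGG_BAND_HZ = (0.008, 0.15)

TARGET_FS_HZ = 4.0
ANTIALIAS_CUTOFF_HZ = 2.0
FILTER_ORDER = 4

METHOD_1_DEFAULT_THRESHOLD = 4.2  # amplitude test
METHOD_2_DEFAULT_THRESHOLD = 1.6  # per-segment SD test


@dataclass
class FilterSpec:
    """Band-pass filter choice for EGG extraction.

    method: ``butterworth`` (forward-reverse 4th-order band-pass),
    ``zero_phase_inverse_butterworth`` (band-stop complement: output =
    input minus the zero-phase band-stop of the same edges), or
    ``ib_dct`` (index-blocked discrete cosine transform: DCT
    coefficients outside the band are zeroed and the transform
    inverted). Pass-band edges are in Hz, each within [0, 0.5].
    """

    method: str = "butterworth"
    low_hz: float = DEFAULT_EGG_BAND_HZ[0]
    high_hz: float = DEFAULT_EGG_BAND_HZ[1]

    _METHODS = ("butterworth", "zero_phase_inverse_butterworth", "ib_dct")

    def __post_init__(self) -> None:
        if self.method not in self._METHODS:
            raise ValueError(f"unknown filter method {self.method!r}; choose from {self._METHODS}")
        if not 0 <= self.low_hz < self.high_hz <= 0.5:
            raise ValueError(
                f"pass band must satisfy 0 <= low < high <= 0.5 Hz, got ({self.low_hz}, {self.high_hz})"
            )


@dataclass
class ArtifactMask:
    """Per-segment exclusion flags on a non-overlapping segment grid.

    A flagged (True) segment is excluded from analysis in *all*
    channels. ``method`` is 1 (any-sample amplitude test), 2 (segment SD
    test) or ``"manual"``.
    """

    segment_len_s: float
    flags: np.ndarray
    method: int | str = 1
    threshold: float | None = None

    def __post_init__(self) -> None:
        self.flags = np.asarray(self.flags, dtype=bool)

    @property
    def n_segments(self) -> int:
        return self.flags.size

    def covers(self, t_start_s: float, t_end_s: float) -> np.ndarray:
        """Indices of mask segments overlapping [t_start_s, t_end_s)."""
        first = int(np.floor(t_start_s / self.segment_len_s))
        last = int(np.ceil(t_end_s / self.segment_len_s))
        return np.arange(max(first, 0), min(last, self.n_segments))

    def excludes(self, t_start_s: float, t_end_s: float) -> bool:
        idx = self.covers(t_start_s, t_end_s)
        return bool(self.flags[idx].any()) if idx.size else False


def _sos_bandpass(low_hz: float, high_hz: float, fs: float, btype: str = "bandpass"):
    nyq = fs / 2.0
    high = min(high_hz, nyq * 0.999)
    if low_hz <= 0:
        if btype == "bandstop":
            return signal.butter(FILTER_ORDER, high / nyq, btype="highpass", output="sos")
        return signal.butter(FILTER_ORDER, high / nyq, btype="lowpass", output="sos")
    if high <= low_hz:
        raise ValueError(f"pass band ({low_hz}, {high_hz}) Hz is empty after clamping to fs/2={nyq}")
    return signal.butter(FILTER_ORDER, [low_hz / nyq, high / nyq], btype=btype, output="sos")


def _ib_dct_filter(x: np.ndarray, low_hz: float, high_hz: float, fs: float) -> np.ndarray:
    # DCT-II index k maps to frequency f_k = k * fs / (2N)
    n = x.size
    coef = sfft.dct(x, type=2, norm="ortho")
    freqs = np.arange(n) * fs / (2.0 * n)
    coef[(freqs < low_hz) | (freqs > high_hz)] = 0.0
    return sfft.idct(coef, type=2, norm="ortho")


def filter_channel(x: np.ndarray, spec: FilterSpec, fs: float) -> np.ndarray:
    """Apply the chosen zero-phase band-pass to one channel."""
    x = np.asarray(x, dtype=float)
    if spec.method == "butterworth":
        sos = _sos_bandpass(spec.low_hz, spec.high_hz, fs)
        return signal.sosfiltfilt(sos, x)
    if spec.method == "zero_phase_inverse_butterworth":
        sos = _sos_bandpass(spec.low_hz, spec.high_hz, fs, btype="bandstop")
        return x - signal.sosfiltfilt(sos, x)
    return _ib_dct_filter(x, spec.low_hz, spec.high_hz, fs)


def extract_egg(rec: Recording, spec: FilterSpec | None = None) -> Recording:
    """Band-pass filter every EGG channel of a recording (zero phase).

    The sensor channel, if present, is passed through untouched.
    """
    spec = spec or FilterSpec()
    out = rec.data.copy()
    for i, label in enumerate(rec.channels):
        if label == "sensor":
            continue
        out[i] = filter_channel(rec.data[i], spec, rec.fs_hz)
    return rec.replace_data(out)


def antialias_downsample(rec: Recording) -> Recording:
    """Low-pass at 2 Hz (zero-phase, 4th order) and decimate to 4 Hz.

    A recording already at 4 Hz is returned unchanged. Sampling rates
    that are not integer multiples of 4 Hz are handled by polyphase
    rational resampling after the anti-alias filter.
    """
    fs = rec.fs_hz
    if fs < TARGET_FS_HZ:
        raise ValueError(f"sampling frequency {fs} Hz is below the 4 Hz analysis rate")
    if fs == TARGET_FS_HZ:
        return rec
    sos = signal.butter(FILTER_ORDER, ANTIALIAS_CUTOFF_HZ / (fs / 2.0), btype="lowpass", output="sos")
    filtered = signal.sosfiltfilt(sos, rec.data, axis=1)
    ratio = fs / TARGET_FS_HZ
    if abs(ratio - round(ratio)) < 1e-9:
        data = filtered[:, :: int(round(ratio))]
    else:
        from fractions import Fraction

        frac = Fraction(TARGET_FS_HZ / fs).limit_denominator(10000)
        data = signal.resample_poly(filtered, frac.numerator, frac.denominator, axis=1)
    return rec.replace_data(data, fs_hz=TARGET_FS_HZ)


def detect_artifacts(
    channel_signal: np.ndarray,
    fs: float,
    segment_len_s: float,
    method: int = 1,
    threshold: float | None = None,
) -> ArtifactMask:
    """Flag artifact segments of one channel by SD thresholding.

    The signal is tiled into non-overlapping segments of
    ``segment_len_s``; each segment's standard deviation is computed and
    the artifact limit is (mean of segment SDs) x ``threshold``.
    Method 1 flags a segment when the absolute value of *any* sample in
    it exceeds the limit (default threshold 4.2); Method 2 flags a
    segment when its own SD exceeds the limit (default threshold 1.6).
    Comparisons are strict, so an all-zero signal flags nothing.
    """
    if method not in (1, 2):
        raise ValueError(f"artifact method must be 1 or 2, got {method}")
    if threshold is None:
        threshold = METHOD_1_DEFAULT_THRESHOLD if method == 1 else METHOD_2_DEFAULT_THRESHOLD
    if threshold <= 0:
        raise ValueError(f"artifact threshold must be positive, got {threshold}")
    x = np.asarray(channel_signal, dtype=float)
    seg_len = int(round(segment_len_s * fs))
    n_seg = x.size // seg_len
    if n_seg < 1:
        raise ValueError(
            f"signal ({x.size} samples) is shorter than one {segment_len_s} s segment"
        )
    segs = x[: n_seg * seg_len].reshape(n_seg, seg_len)
    sds = segs.std(axis=1, ddof=1)
    limit = sds.mean() * threshold
    if method == 1:
        flags = np.abs(segs).max(axis=1) > limit
    else:
        flags = sds > limit
    return ArtifactMask(segment_len_s=segment_len_s, flags=flags, method=method, threshold=threshold)


def detect_artifacts_all_channels(
    rec: Recording, segment_len_s: float, method: int = 1, threshold: float | None = None
) -> list[ArtifactMask]:
    """Run :func:`detect_artifacts` independently on every EGG channel."""
    return [
        detect_artifacts(ch, rec.fs_hz, segment_len_s, method=method, threshold=threshold)
        for ch in rec.egg_data()
    ]


def combine_masks(
    masks: list[ArtifactMask],
    manual_intervals_min: list[tuple[float, float]] | None = None,
    segment_len_s: float | None = None,
    n_segments: int | None = None,
) -> ArtifactMask:
    """OR per-channel masks and add manually marked intervals.

    Exclusion is applied to all channels, so the combined mask is the
    union of the per-channel flags. ``manual_intervals_min`` gives
    (start, end) times in minutes; any segment overlapping such an
    interval is flagged. Intervals beyond the recording are clipped with
    a warning. With no masks, ``segment_len_s`` and ``n_segments``
    define the (all-clean) grid.
    """
    manual_intervals_min = manual_intervals_min or []
    if masks:
        segment_len_s = masks[0].segment_len_s
        n_segments = masks[0].n_segments
        for m in masks[1:]:
            if m.segment_len_s != segment_len_s or m.n_segments != n_segments:
                raise ValueError("all masks must share the same segment grid")
        flags = np.logical_or.reduce([m.flags for m in masks])
    else:
        if segment_len_s is None or n_segments is None:
            raise ValueError("segment_len_s and n_segments required when no masks are given")
        flags = np.zeros(n_segments, dtype=bool)

    total_s = n_segments * segment_len_s
    for start_min, end_min in manual_intervals_min:
        start_s, end_s = start_min * 60.0, end_min * 60.0
        if end_s <= start_s:
            raise ValueError(f"manual interval ({start_min}, {end_min}) min is empty")
        if start_s >= total_s or end_s <= 0:
            warnings.warn(
                f"manual interval ({start_min}, {end_min}) min lies outside the recording; ignored",
                stacklevel=2,
            )
            continue
        if start_s < 0 or end_s > total_s:
            warnings.warn(
                f"manual interval ({start_min}, {end_min}) min clipped to the recording",
                stacklevel=2,
            )
        # closed interval: an endpoint on a segment boundary flags both neighbours
        first = int(np.floor(max(start_s, 0.0) / segment_len_s))
        last = min(int(np.floor(min(end_s, total_s) / segment_len_s)), n_segments - 1)
        flags[first : last + 1] = True
    return ArtifactMask(segment_len_s=segment_len_s, flags=flags, method="manual" if not masks else masks[0].method)
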