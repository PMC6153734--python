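"""Synthetic EGG and ECG generators for validation and testing.

The validation model for the gastric slow wave is deliberately simple:
a sine at a set frequency (0.5-9.0 cpm) and amplitude (50-400 uV) plus
additive noise at a prescribed SNR, 90 minutes long, sampled at 200 Hz
and quantized with a 12-bit A/D converter — exactly the conditions a
recorder would produce. The generator writes the same 8-row-header
ASCII format the reader consumes, so every pipeline stage can be
exercised without any external data. An ECG-like channel with known
sinusoidally modulated RR intervals can be superimposed (or generated
standalone) to exercise the HRV path against ground truth.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from eggkit.io import EGG_CHANNEL_LABELS, HeaderMeta, Recording, write_egg_ascii

__all__ = ["SyntheticSpec", "gen_egg", "inject_artifacts", "gen_ecg_rr"]


@dataclass
class SyntheticSpec:
    """A stated synthetic-recording world.

    freq_cpm / amplitude_uv: slow-wave frequency and amplitude (the
    physiological ranges are 0.5-9.0 cpm and 50-400 uV).
    snr_db: signal-to-noise power ratio in dB; None disables noise.
    duration_min / fs_hz / adc_bits: 90 min at 200 Hz, 12 bits, as in
    the validation recordings.
    phases_rad: per-channel slow-wave phases (default all 0: perfectly
    coupled channels).
    noise: ``white`` (Gaussian) or ``pink`` (1/f, for robustness tests).
    meal times go into the header; (0, 0) means no meal period.
    ecg: optional (mean_hr_bpm, [(mod_freq_hz, depth_ms), ...]) adding
    an ECG-like component with modulated RR intervals to every channel.
    """

    freq_cpm: float = 3.0
    amplitude_uv: float = 200.0
    snr_db: float | None = 10.0
    duration_min: float = 90.0
    fs_hz: float = 200.0
    adc_bits: int = 12
    n_channels: int = 4
    seed: int = 0
    phases_rad: tuple[float, ...] | None = None
    noise: str = "white"
    meal_start_s: float = 0.0
    meal_end_s: float = 0.0
    ecg: tuple[float, list[tuple[float, float]]] | None = None

    def __post_init__(self) -> None:
        if not 0.5 <= self.freq_cpm <= 9.0:
            raise ValueError(f"slow-wave frequency {self.freq_cpm} cpm outside 0.5-9.0")
        if not 1 <= self.n_channels <= 4:
            raise ValueError("n_channels must be 1..4")
        if self.noise not in ("white", "pink"):
            raise ValueError("noise must be 'white' or 'pink'")
        if self.phases_rad is not None and len(self.phases_rad) != self.n_channels:
            raise ValueError("phases_rad must have one entry per channel")


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """1/f-shaped Gaussian noise, unit variance."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec /= np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def gen_egg(spec: SyntheticSpec, path: str | Path | None = None) -> Recording:
    """Generate a sine-plus-noise multichannel EGG recording.

    Noise variance is set from the sine power A^2/2 and the requested
    SNR; samples are quantized mid-tread through a counts-per-mV scale
    chosen so the full span uses <= 90% of the A/D range. The returned
    recording is the quantized one (identical to what a written file
    reads back). When ``path`` is given the ASCII file is written too.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_min * 60.0 * spec.fs_hz))
    t = np.arange(n) / spec.fs_hz
    a_mv = spec.amplitude_uv / 1000.0
    phases = spec.phases_rad or (0.0,) * spec.n_channels

    sigma = 0.0
    if spec.snr_db is not None:
        sigma = np.sqrt((a_mv**2 / 2.0) / 10.0 ** (spec.snr_db / 10.0))

    data = np.empty((4, n))
    ecg_component = None
    if spec.ecg is not None:
        hr, mods = spec.ecg
        ecg_component, _ = _ecg_train(spec.fs_hz, n, hr, mods)
    for ch in range(spec.n_channels):
        x = a_mv * np.sin(2.0 * np.pi * (spec.freq_cpm / 60.0) * t + phases[ch])
        if sigma > 0:
            noise = rng.standard_normal(n) if spec.noise == "white" else _pink_noise(rng, n)
            x = x + sigma * noise
        if ecg_component is not None:
            x = x + ecg_component
        data[ch] = x
    for ch in range(spec.n_channels, 4):  # replicate A1, as the reader would
        data[ch] = data[0]

    span_mv = np.abs(data).max()
    full_scale = 2 ** (spec.adc_bits - 1) - 1
    counts_per_mv = np.floor(0.9 * full_scale / span_mv)
    if counts_per_mv < 1:
        raise ValueError(
            f"signal span {span_mv:.3g} mV overflows a {spec.adc_bits}-bit quantizer; "
            f"needs counts_per_mv < 1"
        )
    counts = np.rint(data * counts_per_mv)
    if np.abs(counts).max() > full_scale:
        raise ValueError("quantizer overflow after scaling")

    meta = HeaderMeta(
        patient_label=f"synthetic sine {spec.freq_cpm:g} cpm",
        meal_type="",
        meal_start_s=spec.meal_start_s,
        meal_end_s=spec.meal_end_s,
        fs_hz=spec.fs_hz,
        adc_bits=spec.adc_bits,
        counts_per_mv=float(counts_per_mv),
    )
    rec = Recording(
        data=counts / counts_per_mv,
        channels=list(EGG_CHANNEL_LABELS),
        fs_hz=spec.fs_hz,
        meta=meta,
        n_egg_channels=spec.n_channels,
    )
    if path is not None:
        write_egg_ascii(rec, path)
    return rec


def inject_artifacts(
    rec: Recording,
    artifact_spec: list[tuple[float, float, float]],
    channels: list[str] | None = None,
) -> Recording:
    """Scale named intervals to simulate motion artifacts.

    ``artifact_spec`` entries are (t_start_min, duration_s, gain); the
    samples in each interval are multiplied by ``gain`` on the selected
    channels (default: all EGG channels). Overlapping intervals are
    merged with a warning, using the maximum gain.
    """
    intervals = []
    for t_min, dur_s, gain in artifact_spec:
        t0 = t_min * 60.0
        t1 = t0 + dur_s
        if t0 < 0 or t1 > rec.duration_s:
            raise ValueError(f"artifact interval ({t_min} min, {dur_s} s) outside the recording")
        intervals.append([t0, t1, gain])
    intervals.sort()
    merged: list[list[float]] = []
    for t0, t1, gain in intervals:
        if merged and t0 < merged[-1][1]:
            warnings.warn("overlapping artifact intervals merged", stacklevel=2)
            merged[-1][1] = max(merged[-1][1], t1)
            merged[-1][2] = max(merged[-1][2], gain)
        else:
            merged.append([t0, t1, gain])

    data = rec.data.copy()
    targets = channels if channels is not None else rec.egg_channels
    for t0, t1, gain in merged:
        i0, i1 = int(round(t0 * rec.fs_hz)), int(round(t1 * rec.fs_hz))
        for label in targets:
            idx = rec.channels.index(label)
            data[idx, i0:i1] *= gain
    return rec.replace_data(data)


def _ecg_train(
    fs: float, n: int, mean_hr_bpm: float, rr_modulations: list[tuple[float, float]]
) -> tuple[np.ndarray, np.ndarray]:
    """ECG-like impulse train with modulated RR; returns (signal_mv, r_times_s)."""
    # QRS-like template: narrow R gaussian flanked by small Q/S dips
    width = int(round(0.1 * fs)) | 1
    tt = (np.arange(width) - width // 2) / fs
    template = (
        1.0 * np.exp(-(tt**2) / (2 * 0.008**2))
        - 0.15 * np.exp(-((tt + 0.025) ** 2) / (2 * 0.01**2))
        - 0.2 * np.exp(-((tt - 0.03) ** 2) / (2 * 0.012**2))
    )

    def rr_ms(t: float) -> float:
        base = 60000.0 / mean_hr_bpm
        return base + sum(d * np.sin(2 * np.pi * f * t) for f, d in rr_modulations)

    min_rr = 60000.0 / mean_hr_bpm - sum(d for _, d in rr_modulations)
    if min_rr / 1000.0 <= width / fs:
        raise ValueError("RR interval shorter than the QRS template; lower the modulation depth")

    signal = np.zeros(n)
    r_times = []
    t = 0.5
    duration = n / fs
    while t < duration - width / fs:
        center = int(round(t * fs))
        lo = center - width // 2
        hi = lo + width
        if lo >= 0 and hi <= n:
            signal[lo:hi] += template
            r_times.append(center / fs)
        t += rr_ms(t) / 1000.0
    return signal, np.asarray(r_times)


def gen_ecg_rr(
    mean_hr_bpm: float = 60.0,
    rr_modulations: list[tuple[float, float]] | None = None,
    duration_min: float = 10.0,
    fs_hz: float = 250.0,
    noise_uv: float = 0.0,
    seed: int = 0,
) -> tuple[Recording, np.ndarray]:
    """High-rate ECG-like recording plus ground-truth R-peak times.

    Beats follow rr(t) = 60000/HR + sum(depth * sin(2 pi f t)) ms; the
    returned R times are the exact template centers, so detector error
    can be measured directly.
    """
    rr_modulations = rr_modulations or []
    n = int(round(duration_min * 60.0 * fs_hz))
    signal, r_times = _ecg_train(fs_hz, n, mean_hr_bpm, rr_modulations)
    if noise_uv > 0:
        rng = np.random.default_rng(seed)
        signal = signal + (noise_uv / 1000.0) * rng.standard_normal(n)
    meta = HeaderMeta(
        patient_label="synthetic ECG",
        fs_hz=fs_hz,
        adc_bits=None,
        counts_per_mv=1000.0,
    )
    rec = Recording(
        data=np.tile(signal, (4, 1)),
        channels=list(EGG_CHANNEL_LABELS),
        fs_hz=fs_hz,
        meta=meta,
        n_egg_channels=1,
    )
    return rec, r_times
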