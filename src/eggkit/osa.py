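"""Overall Spectrum Analysis (OSA).

Where RSA tracks the dominant frequency segment by segment, OSA
averages the segment PSDs of a whole 30-minute examination period (and
of the whole recording) into one overall spectrum, from which the
overall dominant frequency (ODF), overall dominant power (ODP, also
called MPSD) and the percentage distribution of EGG power over the
bradygastria / normogastria / tachygastria bands are computed.

Estimators: ``periodogram4`` (Tukey periodogram of 4-minute segments,
120 s overlap), ``ar4`` (autoregressive spectra of the same segments),
``ar1`` (autoregressive spectra of 1-minute segments, 10 s overlap) and
``music`` (MUSIC pseudospectrum of 4-minute segments; its output is a
peak-location spectrum, so ODP and band powers from it are indicative
only).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, signal as sps

from eggkit.io import HeaderMeta, Recording
from eggkit.preprocess import ArtifactMask
from eggkit.rsa import (
    DF_RANGE_CPM,
    NORMO_CPM,
    Spectrum,
    find_dominant,
    psd_ar,
    psd_periodogram,
    segment_signal,
)

__all__ = [
    "PeriodPlan",
    "PeriodResult",
    "OSAResult",
    "build_period_plan",
    "average_psd",
    "band_power_distribution",
    "psd_music",
    "run_osa",
    "OSA_METHODS",
]

#: (segment length s, overlap s) per estimator
OSA_METHODS = {
    "periodogram4": (240.0, 120.0),
    "ar4": (240.0, 120.0),
    "ar1": (60.0, 10.0),
    "music": (240.0, 120.0),
}

POST_PERIOD_S = 1800.0  # 30-minute postprandial periods
WHOLE_LABEL = "whole"


@dataclass
class PeriodPlan:
    """Ordered, non-overlapping (label, t_start_s, t_end_s) periods."""

    periods: list[tuple[str, float, float]]

    def __post_init__(self) -> None:
        last = 0.0
        for label, t0, t1 in self.periods:
            if t1 <= t0:
                raise ValueError(f"period {label!r} is empty ({t0}, {t1})")
            if t0 < last:
                raise ValueError(f"period {label!r} overlaps its predecessor")
            last = t1

    @property
    def labels(self) -> list[str]:
        return [p[0] for p in self.periods]


@dataclass
class PeriodResult:
    """Averaged spectrum and overall parameters for one period."""

    spectrum: Spectrum | None = None
    odf_cpm: float | None = None
    odp_db: float | None = None
    corrected: bool = False
    arrhythmia: bool = False
    band_power_pct: dict | None = None
    n_segments: int = 0
    computable: bool = True


@dataclass
class OSAResult:
    """Per-channel, per-period overall spectra and parameters."""

    method: str
    periods: dict[str, dict[str, PeriodResult]] = field(default_factory=dict)
    whole: dict[str, PeriodResult] = field(default_factory=dict)


def build_period_plan(
    meta: HeaderMeta,
    total_duration_s: float,
    post_period_s: float = POST_PERIOD_S,
    min_period_s: float = 240.0,
) -> PeriodPlan:
    """Split an examination into pre-prandial / meal / postprandial periods.

    Pre-prandial is [0, meal start), the meal period [meal start, meal
    end), and the remainder is cut into consecutive 30-minute
    postprandial periods; a trailing partial period is kept if it can
    still hold one OSA segment. Meal times (0, 0) mean no meal: the
    whole recording becomes a single period labelled ``all``.
    """
    start, end = meta.meal_start_s, meta.meal_end_s
    if end > total_duration_s:
        raise ValueError(f"meal end ({end} s) exceeds the recording ({total_duration_s} s)")
    if start == end == 0:
        return PeriodPlan([("all", 0.0, float(total_duration_s))])
    periods: list[tuple[str, float, float]] = []
    if start > 0:
        periods.append(("preprandial", 0.0, float(start)))
    if end > start:
        periods.append(("meal", float(start), float(end)))
    t = float(end)
    k = 1
    while t < total_duration_s:
        t1 = min(t + post_period_s, total_duration_s)
        if t1 - t >= min_period_s or t1 - t == post_period_s:
            periods.append((f"postprandial-{k}", t, t1))
            k += 1
        t = t1
    return PeriodPlan(periods)


def average_psd(spectra: list[Spectrum]) -> Spectrum:
    """Pointwise arithmetic mean of linear PSDs on a shared grid."""
    if not spectra:
        raise ValueError("no spectra to average (all segments excluded?)")
    grid = spectra[0].freq_cpm
    for s in spectra[1:]:
        if s.freq_cpm.shape != grid.shape or not np.allclose(s.freq_cpm, grid):
            raise ValueError("spectra must share a frequency grid")
    mean = np.mean([s.psd for s in spectra], axis=0)
    return Spectrum(freq_cpm=grid, psd=mean, method=spectra[0].method, meta={"n_averaged": len(spectra)})


def band_power_distribution(
    spec: Spectrum,
    normo_cpm: tuple[float, float] = NORMO_CPM,
    df_range_cpm: tuple[float, float] = DF_RANGE_CPM,
) -> dict[str, float]:
    """Percentage of 0.5-9 cpm EGG power in the brady/normo/tachy bands.

    Linear PSD is integrated by the trapezoidal rule with interpolated
    band edges, so the three percentages are exact for band edges that
    fall between grid points and always sum to 100.
    """
    lo, hi = df_range_cpm
    nlo, nhi = normo_cpm

    def integrate(a: float, b: float) -> float:
        if b <= a:
            return 0.0
        inside = (spec.freq_cpm > a) & (spec.freq_cpm < b)
        freqs = np.concatenate([[a], spec.freq_cpm[inside], [b]])
        vals = np.interp(freqs, spec.freq_cpm, spec.psd)
        return float(np.trapezoid(vals, freqs))

    brady = integrate(lo, nlo)
    normo = integrate(nlo, nhi)
    tachy = integrate(nhi, hi)
    total = brady + normo + tachy
    if total <= 0:
        raise ValueError("zero EGG-band power; band distribution undefined")
    return {
        "brady": 100.0 * brady / total,
        "normo": 100.0 * normo / total,
        "tachy": 100.0 * tachy / total,
    }


def psd_music(
    segment: np.ndarray,
    fs: float,
    lspv: int = 4096,
    n_sinusoids: int = 2,
    corr_dim: int = 64,
) -> Spectrum:
    """MUSIC pseudospectrum of one segment.

    Signal-subspace dimension is 2 * ``n_sinusoids`` (a real sinusoid
    occupies two complex exponentials). The pseudospectrum locates
    spectral peaks; its amplitude is not a power density.
    """
    x = np.asarray(segment, dtype=float)
    x = x - x.mean()
    m = min(corr_dim, x.size // 4)
    # forward covariance matrix from overlapping snapshots
    n_snap = x.size - m + 1
    snaps = np.lib.stride_tricks.sliding_window_view(x, m)
    r = snaps.T @ snaps / n_snap
    w, v = linalg.eigh(r)
    p = 2 * n_sinusoids
    noise = v[:, : m - p]  # eigenvectors of the smallest eigenvalues
    freqs_hz = np.linspace(0.0, fs / 2.0, lspv)
    steer = np.exp(-2j * np.pi * np.outer(freqs_hz / fs, np.arange(m)))
    denom = np.sum(np.abs(steer @ noise) ** 2, axis=1)
    pseudo = 1.0 / np.maximum(denom, 1e-30)
    return Spectrum(freq_cpm=freqs_hz * 60.0, psd=pseudo, method="music", meta={"corr_dim": m, "p": p})


def _segment_psd(seg: np.ndarray, fs: float, method: str, lspv: int) -> Spectrum:
    x = np.asarray(seg, dtype=float)
    x = x - x.mean()
    if method == "periodogram4":
        return psd_periodogram(x, fs, window="tukey_0.25", lspv=lspv)
    if method in ("ar4", "ar1"):
        return psd_ar(x, fs, lspv=lspv)
    if method == "music":
        return psd_music(x, fs, lspv=lspv)
    raise ValueError(f"unknown OSA method {method!r}; choose from {sorted(OSA_METHODS)}")


def run_osa(
    rec: Recording,
    mask: ArtifactMask | None = None,
    plan: PeriodPlan | None = None,
    method: str = "periodogram4",
    lspv: int = 4096,
    normo_cpm: tuple[float, float] = NORMO_CPM,
    df_range_cpm: tuple[float, float] = DF_RANGE_CPM,
    include_meal: bool = False,
) -> OSAResult:
    """Overall spectra, ODF/ODP and band power per period and whole exam.

    The recording must be at 4 Hz. Segment grids restart at each period
    start; artifact-flagged segments are dropped before averaging. The
    meal period is excluded from averaging (and from the whole-exam
    spectrum) unless ``include_meal`` is set. A period too short for a
    single segment is marked not computable.
    """
    if rec.fs_hz != 4.0:
        raise ValueError(f"OSA expects a 4 Hz recording (got {rec.fs_hz} Hz); downsample first")
    if method not in OSA_METHODS:
        raise ValueError(f"unknown OSA method {method!r}; choose from {sorted(OSA_METHODS)}")
    lseg_s, sseg_s = OSA_METHODS[method]
    plan = plan or build_period_plan(rec.meta, rec.duration_s)
    result = OSAResult(method=method)

    for label, x in zip(rec.egg_channels, rec.egg_data()):
        period_results: dict[str, PeriodResult] = {}
        whole_spectra: list[Spectrum] = []
        for plabel, t0, t1 in plan.periods:
            if plabel == "meal" and not include_meal:
                period_results[plabel] = PeriodResult(computable=False, n_segments=0)
                continue
            i0, i1 = int(round(t0 * rec.fs_hz)), int(round(t1 * rec.fs_hz))
            chunk = x[i0:i1]
            if chunk.size < int(round(lseg_s * rec.fs_hz)):
                period_results[plabel] = PeriodResult(computable=False)
                continue
            spectra = []
            for t_rel, seg in segment_signal(chunk, rec.fs_hz, lseg_s, sseg_s):
                t_abs = t0 + t_rel
                if mask is not None and mask.excludes(t_abs, t_abs + lseg_s):
                    continue
                spectra.append(_segment_psd(seg, rec.fs_hz, method, lspv))
            if not spectra:
                period_results[plabel] = PeriodResult(computable=False)
                continue
            avg = average_psd(spectra)
            dom = find_dominant(avg, df_range_cpm)
            period_results[plabel] = PeriodResult(
                spectrum=avg,
                odf_cpm=dom.df_cpm,
                odp_db=dom.dp_db,
                corrected=dom.corrected,
                arrhythmia=dom.arrhythmia,
                band_power_pct=band_power_distribution(avg, normo_cpm, df_range_cpm),
                n_segments=len(spectra),
            )
            whole_spectra.extend(spectra)
        result.periods[label] = period_results
        if whole_spectra:
            avg = average_psd(whole_spectra)
            dom = find_dominant(avg, df_range_cpm)
            result.whole[label] = PeriodResult(
                spectrum=avg,
                odf_cpm=dom.df_cpm,
                odp_db=dom.dp_db,
                corrected=dom.corrected,
                arrhythmia=dom.arrhythmia,
                band_power_pct=band_power_distribution(avg, normo_cpm, df_range_cpm),
                n_segments=len(whole_spectra),
            )
        else:
            result.whole[label] = PeriodResult(computable=False)
    return result
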