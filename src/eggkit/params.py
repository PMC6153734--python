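"""Clinical EGG parameters computed from running-spectrum results.

All statistics are taken over the *included* (non-artifact) segments of
a period; arrhythmic segments count toward the rhythm percentages but
are excluded from DF/DP statistics since they carry no dominant peak.
Percentages of bradygastria / normogastria / tachygastria / arrhythmia
sum to 100; the normogastria percentage is the normogastria index (NI).
The instability coefficients are coefficients of variation: FIC of the
dominant frequency, PIC of the dominant power (on a linear power scale
by default, which makes it invariant to the dB reference). Slow-wave
coupling (SWC) between two channels is the percentage of aligned
segments whose DFs agree within a tolerance (default 0.2 cpm).
"""

from __future__ import annotations

import math
from typing import Sequence

import numpy as np

from eggkit.osa import OSAResult, PeriodPlan
from eggkit.rsa import SegmentResult

__all__ = [
    "rhythm_percentages",
    "df_dp_statistics",
    "instability_coefficients",
    "max_df_difference",
    "slow_wave_coupling",
    "spatial_dp_difference",
    "fed_fast_power_ratio",
    "summarize_parameters",
]

SWC_TOLERANCE_CPM = 0.2


def _included(segments: Sequence[SegmentResult]) -> list[SegmentResult]:
    return [s for s in segments if not s.excluded]


def _usable(segments: Sequence[SegmentResult]) -> list[SegmentResult]:
    return [s for s in segments if not s.excluded and s.df_cpm is not None]


def _std(values: np.ndarray) -> float:
    # sample std, n=1 -> 0 by convention
    return float(values.std(ddof=1)) if values.size > 1 else 0.0


def rhythm_percentages(segments: Sequence[SegmentResult]) -> dict[str, float] | None:
    """Percentage of included segments in each gastric rhythm class."""
    inc = _included(segments)
    if not inc:
        return None
    n = len(inc)
    counts = {"bradygastria": 0, "normogastria": 0, "tachygastria": 0, "arrhythmia": 0}
    for s in inc:
        counts[s.rhythm] += 1
    return {
        "pct_brady": 100.0 * counts["bradygastria"] / n,
        "pct_normo": 100.0 * counts["normogastria"] / n,
        "pct_tachy": 100.0 * counts["tachygastria"] / n,
        "pct_arrhythmia": 100.0 * counts["arrhythmia"] / n,
    }


def df_dp_statistics(segments: Sequence[SegmentResult]) -> dict[str, float] | None:
    """Mean/median/sample-std of DF (cpm) and DP (dB) over usable segments."""
    use = _usable(segments)
    if not use:
        return None
    df = np.array([s.df_cpm for s in use])
    dp = np.array([s.dp_db for s in use])
    return {
        "df_mean_cpm": float(df.mean()),
        "df_median_cpm": float(np.median(df)),
        "df_std_cpm": _std(df),
        "dp_mean_db": float(dp.mean()),
        "dp_median_db": float(np.median(dp)),
        "dp_std_db": _std(dp),
    }


def instability_coefficients(
    segments: Sequence[SegmentResult], power_scale: str = "linear"
) -> tuple[float, float] | None:
    """(FIC, PIC): coefficients of variation of DF and dominant power.

    PIC uses linear power 10^(DP/10) by default (scale-invariant);
    ``power_scale="db"`` computes it on the dB values instead, matching
    some commercial systems.
    """
    use = _usable(segments)
    if len(use) < 2:
        return None
    df = np.array([s.df_cpm for s in use])
    if power_scale == "linear":
        p = np.array([10.0 ** (s.dp_db / 10.0) for s in use])
    elif power_scale == "db":
        p = np.array([s.dp_db for s in use])
    else:
        raise ValueError(f"power_scale must be 'linear' or 'db', got {power_scale!r}")
    if df.mean() == 0 or p.mean() == 0:
        return None
    return _std(df) / df.mean(), _std(p) / abs(p.mean())


def max_df_difference(segments: Sequence[SegmentResult]) -> float | None:
    """max(DF) - min(DF) over usable segments, in cpm."""
    use = _usable(segments)
    if not use:
        return None
    df = [s.df_cpm for s in use]
    return max(df) - min(df)


def slow_wave_coupling(
    seg_a: Sequence[SegmentResult],
    seg_b: Sequence[SegmentResult],
    tol_cpm: float = SWC_TOLERANCE_CPM,
) -> float | None:
    """Percentage of aligned segments whose DFs agree within ``tol_cpm``.

    Segments are paired by start time; only pairs where both channels
    have a dominant frequency enter the denominator. Symmetric in the
    two channels by construction.
    """
    by_time = {s.t_start_s: s for s in seg_b}
    pairs = []
    for a in seg_a:
        b = by_time.get(a.t_start_s)
        if b is None:
            continue
        if a.excluded or b.excluded or a.df_cpm is None or b.df_cpm is None:
            continue
        pairs.append((a.df_cpm, b.df_cpm))
    if not pairs:
        return None
    coupled = sum(1 for fa, fb in pairs if abs(fa - fb) <= tol_cpm)
    return 100.0 * coupled / len(pairs)


def spatial_dp_difference(
    per_channel_segments: dict[str, Sequence[SegmentResult]]
) -> float | None:
    """Spread (max - min) of per-channel mean dominant power, in dB."""
    if len(per_channel_segments) < 2:
        return None
    means = []
    for segs in per_channel_segments.values():
        use = _usable(segs)
        if use:
            means.append(float(np.mean([s.dp_db for s in use])))
    if len(means) < 2:
        return None
    return max(means) - min(means)


def fed_fast_power_ratio(
    odp_pre_db: float | None, odp_post_db: float | None
) -> tuple[float, float] | None:
    """Postprandial-to-preprandial overall dominant power ratio.

    Returns (linear ratio, dB difference): ratio = 10^((post - pre)/10).
    """
    if odp_pre_db is None or odp_post_db is None:
        return None
    diff_db = odp_post_db - odp_pre_db
    return 10.0 ** (diff_db / 10.0), diff_db


def _segments_in(segments: Sequence[SegmentResult], t0: float, t1: float) -> list[SegmentResult]:
    return [s for s in segments if t0 <= s.t_start_s < t1]


def summarize_parameters(
    rsa_results: dict[str, list[SegmentResult]],
    plan: PeriodPlan | None = None,
    osa: OSAResult | None = None,
    swc_tol_cpm: float = SWC_TOLERANCE_CPM,
    power_scale: str = "linear",
    include_meal: bool = False,
) -> dict[str, dict[str, dict]]:
    """Full per-channel, per-period (and whole-exam) parameter table.

    A segment belongs to the period containing its start time. The
    ``whole`` entry aggregates all periods (minus the meal period unless
    ``include_meal``). SWC is reported on each channel against every
    other channel; the fed/fast power ratio uses the OSA overall
    dominant powers of the pre-prandial vs first postprandial period
    when an :class:`~eggkit.osa.OSAResult` is supplied.
    """
    channels = list(rsa_results)
    if plan is None:
        spans = {"whole": (0.0, math.inf)}
    else:
        spans = {label: (t0, t1) for label, t0, t1 in plan.periods}
        whole_spans = [
            (t0, t1) for label, t0, t1 in plan.periods if include_meal or label != "meal"
        ]
        spans["whole"] = (min(t0 for t0, _ in whole_spans), max(t1 for _, t1 in whole_spans))

    out: dict[str, dict[str, dict]] = {}
    for ch in channels:
        out[ch] = {}
        for label, (t0, t1) in spans.items():
            segs = _segments_in(rsa_results[ch], t0, t1)
            if label == "whole" and plan is not None and not include_meal:
                meal = spans.get("meal")
                if meal is not None:
                    segs = [s for s in segs if not meal[0] <= s.t_start_s < meal[1]]
            entry: dict = {"n_segments": len(segs), "n_included": len(_included(segs))}
            entry.update(rhythm_percentages(segs) or {})
            entry.update(df_dp_statistics(segs) or {})
            ic = instability_coefficients(segs, power_scale=power_scale)
            entry["fic"], entry["pic"] = ic if ic else (None, None)
            entry["max_df_diff_cpm"] = max_df_difference(segs)
            for other in channels:
                if other == ch:
                    continue
                other_segs = _segments_in(rsa_results[other], t0, t1)
                entry[f"swc_{other}_pct"] = slow_wave_coupling(segs, other_segs, swc_tol_cpm)
            per_ch = {
                c: _segments_in(rsa_results[c], t0, t1) for c in channels
            }
            entry["spatial_dp_diff_db"] = spatial_dp_difference(per_ch)
            out[ch][label] = entry

    if osa is not None and plan is not None:
        post = next((l for l in plan.labels if l.startswith("postprandial")), None)
        pre = "preprandial" if "preprandial" in plan.labels else None
        if pre and post:
            for ch in channels:
                pr = osa.periods.get(ch, {})
                ratio = fed_fast_power_ratio(
                    pr[pre].odp_db if pre in pr else None,
                    pr[post].odp_db if post in pr else None,
                )
                if ratio is not None:
                    for label in out[ch]:
                        out[ch][label]["fed_fast_power_ratio"] = ratio[0]
                        out[ch][label]["fed_fast_diff_db"] = ratio[1]
    return out
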