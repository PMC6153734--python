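"""Reading and writing the ASCII EGG recording format, and result export.

The on-disk format is plain text: an 8-row header followed by
space-separated integer sample columns (up to four EGG channels A1..A4
plus one optional auxiliary sensor channel, e.g. respiration) starting
on line 9. Header rows, by position:

    1  patient label (free text, may be empty)
    2  meal type (free text/code, may be empty)
    3  meal start time in seconds, e.g. ``start: 1800``
    4  meal end time in seconds,   e.g. ``stop: 2100``
    5  sampling frequency in Hz,   e.g. ``Fs= 250 Hz``   (must be >= 4)
    6  A/D resolution in bits,     e.g. ``AD= 24 bits``  (may be empty)
    7  counts per 1 mV,            e.g. ``1mV= 20970``
    8  reserved (ignored)

Samples are stored as raw A/D counts; in memory all amplitudes are held
in millivolts (``counts / counts_per_mv``). Rows are matched by
position; the keyword prefixes are tolerated with flexible whitespace.
"""

from __future__ import annotations

import dataclasses
import json
import re
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Any, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EGGFormatError",
    "HeaderMeta",
    "Recording",
    "parse_header",
    "read_egg_ascii",
    "write_egg_ascii",
    "export_results",
    "default_export_path",
]

N_HEADER_ROWS = 8
MAX_EGG_CHANNELS = 4
EGG_CHANNEL_LABELS = ("A1", "A2", "A3", "A4")
SENSOR_LABEL = "sensor"

_NUM_RE = re.compile(r"[-+]?\d+(?:\.\d+)?(?:[eE][-+]?\d+)?")


class EGGFormatError(ValueError):
    """Raised when a file does not conform to the ASCII EGG format."""


@dataclass
class HeaderMeta:
    """Metadata from the 8-row header of an EGG data file."""

    patient_label: str = ""
    meal_type: str = ""
    meal_start_s: float = 0.0
    meal_end_s: float = 0.0
    fs_hz: float = 4.0
    adc_bits: int | None = None
    counts_per_mv: float = 1.0

    def validate(self) -> None:
        if self.fs_hz < 4:
            raise ValueError(f"sampling frequency must be >= 4 Hz, got {self.fs_hz}")
        if self.meal_end_s < self.meal_start_s:
            raise ValueError(
                f"meal end ({self.meal_end_s} s) precedes meal start ({self.meal_start_s} s)"
            )
        if self.meal_start_s < 0:
            raise ValueError("meal start time must be >= 0")
        if not self.counts_per_mv > 0:
            raise ValueError(f"counts-per-mV scale must be positive, got {self.counts_per_mv}")


@dataclass
class Recording:
    """A multichannel EGG recording in physical units (mV).

    ``data`` has shape (n_channels, n_samples); ``channels`` carries the
    matching labels (EGG channels A1..A4 first, then the optional sensor
    channel). ``n_egg_channels`` counts how many EGG columns the source
    file actually contained before replication.
    """

    data: np.ndarray
    channels: list[str]
    fs_hz: float
    meta: HeaderMeta
    n_egg_channels: int = MAX_EGG_CHANNELS

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.data.shape[0] != len(self.channels):
            raise ValueError(
                f"{self.data.shape[0]} data rows but {len(self.channels)} channel labels"
            )
        if not np.all(np.isfinite(self.data)):
            raise ValueError("recording contains non-finite amplitudes")
        if not 1 <= self.n_egg_channels <= MAX_EGG_CHANNELS:
            raise ValueError("number of EGG channels must be in 1..4")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs_hz

    @property
    def egg_channels(self) -> list[str]:
        return [c for c in self.channels if c != SENSOR_LABEL]

    def egg_data(self) -> np.ndarray:
        """The EGG channels only, shape (n_egg, n_samples)."""
        idx = [i for i, c in enumerate(self.channels) if c != SENSOR_LABEL]
        return self.data[idx]

    def replace_data(self, data: np.ndarray, fs_hz: float | None = None) -> "Recording":
        return Recording(
            data=data,
            channels=list(self.channels),
            fs_hz=self.fs_hz if fs_hz is None else fs_hz,
            meta=self.meta,
            n_egg_channels=self.n_egg_channels,
        )


def _last_number(line: str) -> float | None:
    matches = _NUM_RE.findall(line)
    return float(matches[-1]) if matches else None


def parse_header(lines: Sequence[str]) -> HeaderMeta:
    """Parse the first 8 text lines of an EGG file into :class:`HeaderMeta`.

    Rows 3, 4, 5 and 7 must contain a number (meal start/end seconds,
    sampling frequency, counts per mV); rows 1, 2 and 6 may be empty and
    are stored as-is; row 8 is ignored.
    """
    if len(lines) != N_HEADER_ROWS:
        raise EGGFormatError(f"header must be exactly {N_HEADER_ROWS} rows, got {len(lines)}")
    lines = [ln.rstrip("\r\n") for ln in lines]

    def required(row: int, what: str) -> float:
        text = lines[row - 1]
        if row == 7:  # the "1mV=" keyword itself contains a digit
            text = re.sub(r"^\s*1\s*mV\s*=?", "", text, flags=re.IGNORECASE)
        value = _last_number(text)
        if value is None:
            raise EGGFormatError(f"header row {row} ({what}) has no parsable number: {lines[row - 1]!r}")
        return value

    adc = _last_number(lines[5])
    meta = HeaderMeta(
        patient_label=lines[0].strip(),
        meal_type=lines[1].strip(),
        meal_start_s=required(3, "meal start time"),
        meal_end_s=required(4, "meal end time"),
        fs_hz=required(5, "sampling frequency"),
        adc_bits=int(adc) if adc is not None else None,
        counts_per_mv=required(7, "1 mV scale"),
    )
    meta.validate()
    return meta


def read_egg_ascii(path: str | Path) -> Recording:
    """Read an ASCII EGG file into a :class:`Recording` in mV.

    Files with fewer than 4 EGG columns have channel A1 replicated into
    the missing channels so downstream analysis always sees 4 EGG
    channels; a 5th column, when present, is the auxiliary sensor.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    if len(raw) < N_HEADER_ROWS + 1:
        raise EGGFormatError(f"{path.name}: file has no data rows after the 8-row header")
    meta = parse_header(raw[:N_HEADER_ROWS])

    rows: list[list[float]] = []
    ncols: int | None = None
    for lineno, line in enumerate(raw[N_HEADER_ROWS:], start=N_HEADER_ROWS + 1):
        tokens = line.split()
        if not tokens:
            continue
        try:
            values = [float(t) for t in tokens]
        except ValueError as exc:
            raise EGGFormatError(f"{path.name}, line {lineno}: non-numeric token ({exc})") from None
        if ncols is None:
            ncols = len(values)
        elif len(values) != ncols:
            raise EGGFormatError(
                f"{path.name}, line {lineno}: expected {ncols} columns, got {len(values)}"
            )
        rows.append(values)
    if not rows:
        raise EGGFormatError(f"{path.name}: no data rows")
    counts = np.asarray(rows, dtype=float).T  # (n_cols, n_samples)

    n_cols = counts.shape[0]
    n_egg = min(n_cols, MAX_EGG_CHANNELS)
    has_sensor = n_cols > MAX_EGG_CHANNELS
    if n_cols > MAX_EGG_CHANNELS + 1:
        raise EGGFormatError(
            f"{path.name}: at most {MAX_EGG_CHANNELS + 1} columns supported, got {n_cols}"
        )

    egg = counts[:n_egg]
    if n_egg < MAX_EGG_CHANNELS:  # replicate A1 into missing EGG channels
        pad = np.tile(egg[0], (MAX_EGG_CHANNELS - n_egg, 1))
        egg = np.vstack([egg, pad])
    data = np.vstack([egg, counts[MAX_EGG_CHANNELS:]]) if has_sensor else egg
    channels = list(EGG_CHANNEL_LABELS) + ([SENSOR_LABEL] if has_sensor else [])
    return Recording(
        data=data / meta.counts_per_mv,
        channels=channels,
        fs_hz=meta.fs_hz,
        meta=meta,
        n_egg_channels=n_egg,
    )


def write_egg_ascii(rec: Recording, path: str | Path) -> None:
    """Write a :class:`Recording` in the 8-row-header ASCII format.

    Amplitudes are converted back to integer counts with the header's
    counts-per-mV scale; a warning is emitted if any count exceeds the
    A/D range implied by ``adc_bits``.
    """
    path = Path(path)
    meta = rec.meta
    counts = np.rint(rec.data * meta.counts_per_mv).astype(np.int64)
    if meta.adc_bits is not None:
        full_scale = 2 ** (meta.adc_bits - 1) - 1
        if np.abs(counts).max(initial=0) > full_scale:
            warnings.warn(
                f"sample counts exceed the {meta.adc_bits}-bit A/D range "
                f"(|count| up to {np.abs(counts).max()} > {full_scale}); values clipped",
                stacklevel=2,
            )
            counts = np.clip(counts, -full_scale - 1, full_scale)

    def fmt(x: float) -> str:
        return f"{x:g}"

    header = [
        meta.patient_label,
        meta.meal_type,
        f"start: {fmt(meta.meal_start_s)}",
        f"stop: {fmt(meta.meal_end_s)}",
        f"Fs= {fmt(meta.fs_hz)} Hz",
        f"AD= {meta.adc_bits} bits" if meta.adc_bits is not None else "",
        f"1mV= {fmt(meta.counts_per_mv)}",
        "",
    ]
    with path.open("w") as fh:
        fh.write("\n".join(header) + "\n")
        np.savetxt(fh, counts.T, fmt="%d", delimiter=" ")


def default_export_path(
    source: str | Path, directory: str | Path, fmt: str, when: datetime | None = None
) -> Path:
    """Build an export file name embedding the source name and a timestamp."""
    when = when or datetime.now()
    stem = Path(source).stem
    ext = {"csv": "csv", "json": "json", "text": "txt"}[fmt]
    return Path(directory) / f"{stem}_{when:%Y%m%d_%H%M%S}.{ext}"


def _to_jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _to_jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and np.isnan(obj):
        return None
    return obj


def _segments_frame(results: dict) -> pd.DataFrame:
    records = []
    for channel, segs in results.get("rsa", {}).items():
        for seg in segs:
            records.append(
                {
                    "channel": channel,
                    "t_start_s": seg.t_start_s,
                    "df_cpm": seg.df_cpm,
                    "dp_db": seg.dp_db,
                    "rhythm": seg.rhythm,
                    "corrected": seg.corrected,
                    "excluded": seg.excluded,
                }
            )
    return pd.DataFrame.from_records(records)


def export_results(results: dict, path: str | Path, format: str = "json") -> None:
    """Serialize an analysis results bundle to ``csv``, ``json`` or ``text``.

    The bundle is the dictionary produced by
    :func:`eggkit.pipeline.run_analysis` (or any subset with the same
    keys). CSV emits one row per segment per channel; JSON nests the
    full per-period structure; text writes a human-readable per-period
    summary.
    """
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_to_jsonable(results), indent=2))
    elif format == "csv":
        _segments_frame(results).to_csv(path, index=False)
    elif format == "text":
        path.write_text(_text_report(results))
    else:
        raise ValueError(f"unknown export format: {format!r}")


def _text_report(results: dict) -> str:
    lines = ["EGG analysis report", "=" * 19, ""]
    meta = results.get("meta")
    if meta is not None:
        lines += [
            f"source: {results.get('source', '-')}",
            f"fs: {meta.fs_hz} Hz   meal: {meta.meal_start_s}-{meta.meal_end_s} s",
            "",
        ]
    params = results.get("parameters", {})
    for channel, periods in params.items():
        lines.append(f"channel {channel}")
        for label, p in periods.items():
            lines.append(f"  period {label}:")
            for key, value in p.items():
                if isinstance(value, float):
                    lines.append(f"    {key}: {value:.4g}")
                else:
                    lines.append(f"    {key}: {value}")
        lines.append("")
    osa = results.get("osa")
    if osa is not None:
        lines.append("overall spectra (ODF cpm / ODP dB per period):")
        for channel, periods in osa.periods.items():
            for label, pr in periods.items():
                odf = "arrhythmia" if pr.odf_cpm is None else f"{pr.odf_cpm:.2f}"
                odp = "-" if pr.odp_db is None else f"{pr.odp_db:.2f}"
                lines.append(f"  {channel} {label}: ODF {odf}  ODP {odp}")
    return "\n".join(lines) + "\n"
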