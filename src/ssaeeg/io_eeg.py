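"""Reading, writing and epoching of single-channel frontal EEG recordings.

The on-disk dialect is plain tab-separated text: one sample per row, an
optional single header line, decimal-point numbers, no quoting.  Sparse
processed-parameter columns (BIS, SEF95) may sit alongside the raw voltage
column; blank or non-numeric cells in those columns are treated as missing.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import EmptyInputError, FormatError

__all__ = [
    "EEGRecording",
    "Epoch",
    "EpochingConfig",
    "read_recording",
    "write_recording",
    "segment_epochs",
    "write_feature_table",
    "read_feature_table",
    "load_column_config",
]

DEFAULT_FS = 128.0
FEATURE_COLUMNS = [f"CF{i}" for i in range(1, 7)] + [f"TP{i}" for i in range(1, 7)]


@dataclasses.dataclass
class EEGRecording:
    """A timestamped voltage series (µV) with optional aligned processed parameters.

    Parameters
    ----------
    samples
        Voltage samples in µV, uniformly sampled at ``fs``.
    fs
        Sampling rate in Hz (BIS-monitor exports are typically 128 Hz).
    start_time
        Time offset of the first sample, in seconds.
    bis
        Optional sparse depth-of-anesthesia index (0-100), indexed by time
        in seconds.  Timestamps must fall within the recording span.
    sef95
        Optional sparse 95% spectral edge frequency (Hz), indexed by time.
    recording_id
        Free-form label used in provenance fields.
    """

    samples: np.ndarray
    fs: float = DEFAULT_FS
    start_time: float = 0.0
    bis: pd.Series | None = None
    sef95: pd.Series | None = None
    recording_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if self.samples.ndim != 1:
            raise ValueError("samples must be one-dimensional")
        if self.samples.size == 0:
            raise EmptyInputError("recording has no samples")
        if not np.all(np.isfinite(self.samples)):
            raise FormatError("EEG samples contain non-finite values")
        for name in ("bis", "sef95"):
            series = getattr(self, name)
            if series is None:
                continue
            series = pd.Series(series, dtype=float)
            t = np.asarray(series.index, dtype=float)
            lo, hi = self.start_time, self.start_time + self.duration
            if t.size and (t.min() < lo - 1e-9 or t.max() > hi + 1e-9):
                raise FormatError(f"{name} timestamps fall outside the recording span")
            setattr(self, name, series)

    @property
    def n_samples(self) -> int:
        return int(self.samples.size)

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.samples.size / self.fs

    def times(self) -> np.ndarray:
        return self.start_time + np.arange(self.samples.size) / self.fs


@dataclasses.dataclass(frozen=True)
class Epoch:
    """One fixed-length analysis window cut from a recording."""

    values: np.ndarray
    fs: float
    t_start: float
    index: int

    @property
    def t_center(self) -> float:
        return self.t_start + self.values.size / self.fs / 2.0

    def __len__(self) -> int:
        return self.values.size


@dataclasses.dataclass(frozen=True)
class EpochingConfig:
    """Sliding-window configuration.

    ``epoch_seconds=3`` at 128 Hz gives 384-sample epochs; consecutive epochs
    overlap by ``epoch_seconds - hop_seconds`` (1 s by default).
    ``embed_length`` is the number of leading samples actually embedded into
    the trajectory matrix: 383 so that a 2-s window (K=256) yields exactly
    L = 383 - 256 + 1 = 128 lagged vectors.
    """

    epoch_seconds: float = 3.0
    hop_seconds: float = 2.0
    embed_length: int = 383

    def __post_init__(self) -> None:
        if not 0 < self.hop_seconds <= self.epoch_seconds:
            raise ValueError("require 0 < hop_seconds <= epoch_seconds")
        if self.embed_length < 2:
            raise ValueError("embed_length must be at least 2")

    def epoch_samples(self, fs: float) -> int:
        n = int(round(self.epoch_seconds * fs))
        if self.embed_length > n:
            raise ValueError(
                f"embed_length={self.embed_length} exceeds epoch length {n} samples"
            )
        return n


def load_column_config(path: str | Path) -> dict:
    """Load a YAML config naming the columns {eeg, bis, sef95} and fs."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise FormatError(f"column config {path} must be a mapping")
    return cfg


def _resolve_column(df: pd.DataFrame, key, what: str):
    """Column selector: by name (requires a header) or 0-based position."""
    if key is None:
        return None
    if isinstance(key, int):
        if key >= df.shape[1]:
            raise FormatError(f"{what} column index {key} out of range ({df.shape[1]} columns)")
        return df.iloc[:, key]
    if key not in df.columns:
        raise FormatError(f"{what} column {key!r} not found; columns: {list(df.columns)}")
    return df[key]


def read_recording(
    path: str | Path,
    column_map: dict | None = None,
    fs: float | None = None,
    recording_id: str | None = None,
) -> EEGRecording:
    """Read a tab-separated recording file.

    ``column_map`` may carry keys ``eeg`` (default: column 0), ``bis``,
    ``sef95`` — each a column name or 0-based index — and ``fs``.  A single
    header line is detected automatically (first row non-numeric in the EEG
    column).  Non-numeric cells in the optional columns become missing
    values; the EEG column itself must parse throughout.
    """
    path = Path(path)
    column_map = dict(column_map or {})
    if fs is None:
        fs = float(column_map.get("fs", DEFAULT_FS))

    try:
        raw = pd.read_csv(path, sep="\t", header=None, dtype=str, skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    if raw.empty:
        raise EmptyInputError(f"{path} is empty")

    # Header sniffing: if anything in the first row fails to parse as a
    # number, treat that row as column names.
    first = raw.iloc[0]
    has_header = any(pd.isna(pd.to_numeric(v, errors="coerce")) and isinstance(v, str)
                     for v in first)
    if has_header:
        raw.columns = [str(v).strip() for v in first]
        raw = raw.iloc[1:].reset_index(drop=True)
    if raw.empty:
        raise EmptyInputError(f"{path} has a header but no data rows")

    eeg_key = column_map.get("eeg", 0)
    eeg_col = _resolve_column(raw, eeg_key, "EEG")
    try:
        # numpy's strtod round-trips "%.17g" output exactly
        eeg = eeg_col.to_numpy(dtype=str).astype(float)
    except ValueError:
        raise FormatError(f"{path}: non-numeric values in the EEG column") from None
    if np.isnan(eeg).any():
        raise FormatError(f"{path}: missing values in the EEG column")

    t = np.arange(eeg.size) / fs

    def sparse(key, what):
        col = _resolve_column(raw, column_map.get(key), what)
        if col is None:
            return None
        vals = pd.to_numeric(col, errors="coerce").to_numpy(dtype=float)
        mask = np.isfinite(vals)
        if not mask.any():
            return None
        return pd.Series(vals[mask], index=t[mask])

    return EEGRecording(
        samples=eeg,
        fs=fs,
        bis=sparse("bis", "BIS"),
        sef95=sparse("sef95", "SEF95"),
        recording_id=recording_id or path.stem,
    )


def write_recording(rec: EEGRecording, path: str | Path) -> None:
    """Write a recording in the TSV dialect (columns t, eeg[, bis[, sef95]]).

    Values are written with enough digits that a write/read round trip
    reproduces the float64 samples exactly.
    """
    path = Path(path)
    t = rec.times()
    df = pd.DataFrame({"t": t, "eeg": rec.samples})
    for name in ("bis", "sef95"):
        series = getattr(rec, name)
        if series is None:
            continue
        col = np.full(t.size, np.nan)
        idx = np.rint((np.asarray(series.index, dtype=float) - rec.start_time) * rec.fs)
        idx = np.clip(idx.astype(int), 0, t.size - 1)
        col[idx] = series.to_numpy()
        df[name] = col
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


def segment_epochs(rec: EEGRecording, cfg: EpochingConfig | None = None) -> list[Epoch]:
    """Slice a recording into overlapping epochs.

    Epoch k starts at t = k * hop_seconds (relative to the recording start);
    each epoch has exactly ``round(epoch_seconds * fs)`` samples, and a
    trailing partial window is discarded.
    """
    cfg = cfg or EpochingConfig()
    n_epoch = cfg.epoch_samples(rec.fs)
    n = rec.n_samples
    if n < n_epoch:
        raise EmptyInputError(
            f"recording of {n} samples shorter than one epoch ({n_epoch} samples)"
        )
    epochs = []
    k = 0
    while True:
        start = int(round(k * cfg.hop_seconds * rec.fs))
        if start + n_epoch > n:
            break
        epochs.append(
            Epoch(
                values=rec.samples[start:start + n_epoch],
                fs=rec.fs,
                t_start=rec.start_time + start / rec.fs,
                index=k,
            )
        )
        k += 1
    return epochs


def write_feature_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a time-indexed feature table (t, CF1..CF6, TP1..TP6[, BIS]) as TSV.

    The table must be nonempty; the round trip through
    :func:`read_feature_table` is stable to better than 1e-9 relative.
    """
    if table is None or len(table) == 0:
        raise EmptyInputError("refusing to write an empty feature table")
    out = table.copy()
    out.index.name = out.index.name or "t"
    out.to_csv(path, sep="\t", float_format="%.17g")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    """Read a feature table written by :func:`write_feature_table`."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path} is empty") from None
    return df
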