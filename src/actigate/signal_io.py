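"""Reading and writing tri-axial accelerometer streams.

Two plain-text dialects are supported:

* ``wisdm`` — the raw WISDM convention: one record per line,
  ``user,activity,timestamp,x,y,z;`` (note the trailing semicolon), units
  m/s², timestamps in milliseconds.
* ``csv`` — a generic headered CSV with columns
  ``subject,label,timestamp_ms,x,y,z``.

Samples are grouped into :class:`ContiguousRun` objects: maximal stretches of
one subject with strictly increasing timestamps, no internal gap larger than
``gap_tolerance`` and (for files, which record one activity per row) one
activity label per run. Sliding-window segmentation never crosses a run
boundary, so the run convention decides how recording discontinuities are
handled.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

#: default gap tolerance: 5 nominal sampling periods at 20 Hz
DEFAULT_GAP_TOLERANCE_MS = 250.0

CSV_COLUMNS = ["subject", "label", "timestamp_ms", "x", "y", "z"]


@dataclass
class ContiguousRun:
    """A gap-free stretch of samples from one subject.

    Parameters
    ----------
    subject_id
        Opaque subject identifier.
    timestamps
        Sample times in milliseconds, strictly increasing.
    xyz
        ``(n, 3)`` total acceleration in m/s².
    labels
        Per-sample activity labels. Runs read from files carry one label
        throughout; synthetic streams may mix labels within a run so that
        windows can straddle activity transitions.
    """

    subject_id: str
    timestamps: np.ndarray
    xyz: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.timestamps = np.asarray(self.timestamps, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        n = len(self.timestamps)
        if n == 0:
            raise ValueError("a ContiguousRun must contain at least one sample")
        if self.xyz.shape != (n, 3):
            raise ValueError(f"xyz must be ({n}, 3), got {self.xyz.shape}")
        if len(self.labels) != n:
            raise ValueError("labels must align with timestamps")
        if n > 1 and not np.all(np.diff(self.timestamps) > 0):
            raise ValueError("timestamps must be strictly increasing within a run")

    def __len__(self) -> int:
        return len(self.timestamps)

    @property
    def label(self) -> str | None:
        """The run's single activity label, or ``None`` if labels are mixed."""
        uniq = np.unique(self.labels)
        return str(uniq[0]) if len(uniq) == 1 else None


@dataclass
class AccelStream:
    """An ordered collection of contiguous recording runs."""

    runs: list[ContiguousRun]
    source: str = ""
    n_skipped: int = 0

    def __post_init__(self) -> None:
        if any(len(r) == 0 for r in self.runs):
            raise ValueError("every run must be non-empty")

    @property
    def n_samples(self) -> int:
        return sum(len(r) for r in self.runs)

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for run in self.runs:
            frames.append(
                pd.DataFrame(
                    {
                        "subject": run.subject_id,
                        "label": run.labels,
                        "timestamp_ms": run.timestamps,
                        "x": run.xyz[:, 0],
                        "y": run.xyz[:, 1],
                        "z": run.xyz[:, 2],
                    }
                )
            )
        return pd.concat(frames, ignore_index=True)


def _split_into_runs(
    df: pd.DataFrame, gap_tolerance: float
) -> list[ContiguousRun]:
    """Split parsed samples into maximal (subject, label, gap)-contiguous runs."""
    runs: list[ContiguousRun] = []
    subj = df["subject"].to_numpy()
    lab = df["label"].to_numpy()
    ts = df["timestamp_ms"].to_numpy(dtype=np.int64)
    xyz = df[["x", "y", "z"]].to_numpy(dtype=np.float64)

    n = len(df)
    if n == 0:
        return runs
    # a new run starts whenever subject or label changes, the timestamp gap is
    # too large, or time does not advance
    breaks = np.zeros(n, dtype=bool)
    breaks[0] = True
    if n > 1:
        dt = np.diff(ts)
        breaks[1:] = (
            (subj[1:] != subj[:-1])
            | (lab[1:] != lab[:-1])
            | (dt <= 0)
            | (dt > gap_tolerance)
        )
    starts = np.flatnonzero(breaks)
    ends = np.append(starts[1:], n)
    for s, e in zip(starts, ends):
        runs.append(
            ContiguousRun(
                subject_id=str(subj[s]),
                timestamps=ts[s:e],
                xyz=xyz[s:e],
                labels=lab[s:e],
            )
        )
    return runs


def _parse_wisdm_records(text: str) -> tuple[pd.DataFrame, int]:
    rows = []
    skipped = 0
    # records are ';'-terminated; some files put several on one line
    for line in text.splitlines():
        for rec in line.split(";"):
            rec = rec.strip().strip(",")
            if not rec:
                continue
            parts = rec.split(",")
            if len(parts) != 6:
                skipped += 1
                continue
            try:
                rows.append(
                    (
                        parts[0].strip(),
                        parts[1].strip(),
                        int(float(parts[2])),
                        float(parts[3]),
                        float(parts[4]),
                        float(parts[5]),
                    )
                )
            except ValueError:
                skipped += 1
    df = pd.DataFrame(rows, columns=CSV_COLUMNS)
    return df, skipped


def read_wisdm_raw(
    path: str | Path, gap_tolerance: float = DEFAULT_GAP_TOLERANCE_MS
) -> AccelStream:
    """Read a WISDM-raw-format file into an :class:`AccelStream`.

    Malformed records are skipped and counted on ``stream.n_skipped``; a file
    with zero well-formed records is an error.
    """
    path = Path(path)
    text = path.read_text()
    df, skipped = _parse_wisdm_records(text)
    if df.empty:
        raise ValueError(f"no well-formed records in {path}")
    runs = _split_into_runs(df, gap_tolerance)
    return AccelStream(runs=runs, source=str(path), n_skipped=skipped)


def read_generic_csv(
    path: str | Path, gap_tolerance: float = DEFAULT_GAP_TOLERANCE_MS
) -> AccelStream:
    """Read a generic ``subject,label,timestamp_ms,x,y,z`` CSV."""
    path = Path(path)
    try:
        df = pd.read_csv(
            path,
            dtype={"subject": str, "label": str},
            on_bad_lines="skip",
            float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"no well-formed records in {path}") from None
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path} lacks required columns: {missing}")
    n_raw = len(df)
    df = df.dropna(subset=CSV_COLUMNS)
    skipped = n_raw - len(df)
    if df.empty:
        raise ValueError(f"no well-formed records in {path}")
    runs = _split_into_runs(df.reset_index(drop=True), gap_tolerance)
    return AccelStream(runs=runs, source=str(path), n_skipped=skipped)


def write_stream(stream: AccelStream, path: str | Path, dialect: str = "csv") -> None:
    """Write a stream in the ``csv`` or ``wisdm`` dialect.

    Floats are written with full (round-trippable) precision so that
    write-then-read is the identity on samples.
    """
    if not stream.runs:
        raise ValueError("cannot write an empty stream")
    path = Path(path)
    if dialect == "csv":
        df = stream.to_frame()
        df.to_csv(path, index=False)
    elif dialect == "wisdm":
        buf = _io.StringIO()
        for run in stream.runs:
            for i in range(len(run)):
                x, y, z = (float(v) for v in run.xyz[i])
                buf.write(
                    f"{run.subject_id},{run.labels[i]},{run.timestamps[i]},"
                    f"{x!r},{y!r},{z!r};\n"
                )
        path.write_text(buf.getvalue())
    else:
        raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'wisdm'")


def merge_subject_sessions(
    stream: AccelStream, gap_tolerance: float = DEFAULT_GAP_TOLERANCE_MS
) -> list[ContiguousRun]:
    """Merge time-adjacent runs of the same subject into recording sessions.

    File readers split runs at every activity change so that training windows
    are single-activity; the streaming pipeline instead wants one continuous
    signal per recording session, with per-sample labels, so that windows may
    straddle transitions exactly as they would on a live sensor.
    """
    sessions: list[ContiguousRun] = []
    for run in stream.runs:
        prev = sessions[-1] if sessions else None
        if (
            prev is not None
            and prev.subject_id == run.subject_id
            and 0 < run.timestamps[0] - prev.timestamps[-1] <= gap_tolerance
        ):
            sessions[-1] = ContiguousRun(
                subject_id=prev.subject_id,
                timestamps=np.concatenate([prev.timestamps, run.timestamps]),
                xyz=np.vstack([prev.xyz, run.xyz]),
                labels=np.concatenate([prev.labels, run.labels]),
            )
        else:
            sessions.append(run)
    return sessions
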