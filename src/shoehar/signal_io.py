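"""Reading, writing and aligning accelerometer recordings and annotation logs.

A recording is one subject's triaxial acceleration trace in units of g,
uniformly sampled (default 100 Hz, +/-16 g dynamic range) from a sensor on
the right shoe. Annotation logs carry timed activity intervals, either from
the structured calibration protocol or from a free-living observer.

Time is expressed in seconds since session start and intervals follow the
half-open convention [start, end), so a boundary instant belongs to the
following interval.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import labels as L

#: Maximum relative sampling-period jitter accepted by :func:`read_recording`.
JITTER_TOLERANCE = 0.01


class RecordingParseError(ValueError):
    """Malformed recording file; the message names the first offending line."""


class NonUniformSamplingError(ValueError):
    """Timestamps deviate from a fixed sampling rate beyond the tolerance."""


@dataclass
class AccelRecording:
    """One subject's triaxial acceleration signal with sampling metadata.

    Parameters
    ----------
    subject_id : str
        Identifier of the subject the recording belongs to.
    samples : ndarray of shape (n, 3)
        Acceleration triples (ax, ay, az) in g.
    fs : float
        Sampling rate in Hz.
    range_g : float
        Dynamic range of the sensor in g; samples are validated against it.
    start_time : float
        Seconds since session start of the first sample.
    """

    subject_id: str
    samples: np.ndarray
    fs: float = 100.0
    range_g: float = 16.0
    start_time: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2 or self.samples.shape[1] != 3:
            raise ValueError("samples must have shape (n, 3)")
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples contain non-finite values")
        if self.samples.size and np.abs(self.samples).max() > self.range_g:
            raise ValueError("sample magnitude exceeds range_g")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    @property
    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds since session start."""
        return self.start_time + np.arange(self.n_samples) / self.fs


@dataclass(frozen=True)
class Interval:
    start: float
    end: float
    label: str
    source: str = "protocol"  # "protocol" or "observer"

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError(f"interval end must exceed start: {self}")


@dataclass
class AnnotationLog:
    """Timed activity intervals for one subject, sorted and non-overlapping."""

    subject_id: str
    intervals: list[Interval] = field(default_factory=list)
    group: str | None = None

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: iv.start)
        for a, b in zip(self.intervals, self.intervals[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"overlapping intervals: ({a.start}, {a.end}, {a.label}) and "
                    f"({b.start}, {b.end}, {b.label})"
                )
        L.validate_labels([iv.label for iv in self.intervals], L.ANNOTATION_VOCABULARY)

    def __len__(self) -> int:
        return len(self.intervals)


def read_recording(path: str | Path, format: str = "csv") -> AccelRecording:
    """Read a recording from ``csv`` (header ``time,ax,ay,az``) or columnar ``npz``.

    The sampling rate is inferred from the timestamps; files whose sampling
    period jitters by more than 1 % are rejected rather than resampled.
    Acceleration values are clipped to the +/- ``range_g`` dynamic range.
    """
    path = Path(path)
    if format == "csv":
        time, axyz = _read_recording_csv(path)
    elif format == "npz":
        with np.load(path) as data:
            time = np.asarray(data["time"], dtype=float)
            axyz = np.column_stack(
                [np.asarray(data[k], dtype=float) for k in ("ax", "ay", "az")]
            )
    else:
        raise ValueError(f"unknown recording format {format!r}")

    if time.size < 2:
        fs = 100.0
    else:
        dt = np.diff(time)
        period = float(np.median(dt))
        if period <= 0:
            raise NonUniformSamplingError(f"{path}: non-increasing timestamps")
        jitter = np.abs(dt - period) / period
        if jitter.max() > JITTER_TOLERANCE:
            i = int(np.argmax(jitter))
            raise NonUniformSamplingError(
                f"{path}: sampling gap/jitter of {dt[i]:.4f} s at t={time[i]:.4f} s "
                f"(expected period {period:.4f} s, tolerance {JITTER_TOLERANCE:.0%})"
            )
        fs = 1.0 / period

    range_g = 16.0
    axyz = np.clip(axyz, -range_g, range_g)
    start = float(time[0]) if time.size else 0.0
    return AccelRecording(
        subject_id=path.stem, samples=axyz, fs=fs, range_g=range_g, start_time=start
    )


def _read_recording_csv(path: Path) -> tuple[np.ndarray, np.ndarray]:
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:  # header/structure problems
        raise RecordingParseError(f"{path}: cannot parse CSV ({exc})") from exc
    required = ["time", "ax", "ay", "az"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise RecordingParseError(f"{path}: missing columns {missing} in header")
    numeric = df[required].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        # +2: 1-based line numbers plus the header line
        line = int(np.argmax(bad.to_numpy())) + 2
        raise RecordingParseError(f"{path}: non-numeric value at line {line}")
    return numeric["time"].to_numpy(), numeric[["ax", "ay", "az"]].to_numpy()


def write_recording(rec: AccelRecording, path: str | Path) -> None:
    """Write a recording as CSV with header ``time,ax,ay,az`` (time in s, accel in g)."""
    df = pd.DataFrame(
        {
            "time": rec.times,
            "ax": rec.samples[:, 0],
            "ay": rec.samples[:, 1],
            "az": rec.samples[:, 2],
        }
    )
    df.to_csv(path, index=False, float_format="%.7f")


def read_annotations(path: str | Path, source: str = "protocol") -> AnnotationLog:
    """Read an annotation log CSV with header ``start,end,activity[,group]``."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    required = ["start", "end", "activity"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing} in header")
    intervals = [
        Interval(float(r.start), float(r.end), str(r.activity), source=source)
        for r in df.itertuples()
    ]
    group = None
    if "group" in df.columns and len(df):
        groups = df["group"].dropna().unique()
        if len(groups) > 1:
            raise ValueError(f"{path}: multiple group tags {list(groups)}")
        if len(groups) == 1:
            group = str(groups[0])
    return AnnotationLog(subject_id=path.stem, intervals=intervals, group=group)


def write_annotations(log: AnnotationLog, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "start": [iv.start for iv in log.intervals],
            "end": [iv.end for iv in log.intervals],
            "activity": [iv.label for iv in log.intervals],
        }
    )
    if log.group is not None:
        df["group"] = log.group
    df.to_csv(path, index=False)


def label_samples(rec: AccelRecording, log: AnnotationLog) -> np.ndarray:
    """Assign each sample the label of the interval containing its timestamp.

    Intervals are half-open [start, end); samples outside every interval get
    ``"unannotated"``. Returns an object array of length ``rec.n_samples``.
    """
    out = np.full(rec.n_samples, L.UNANNOTATED, dtype=object)
    if not log.intervals:
        return out
    t = rec.times
    starts = np.array([iv.start for iv in log.intervals])
    ends = np.array([iv.end for iv in log.intervals])
    idx = np.searchsorted(starts, t, side="right") - 1
    valid = idx >= 0
    inside = np.zeros_like(valid)
    inside[valid] = t[valid] < ends[idx[valid]]
    labels_arr = np.array([iv.label for iv in log.intervals], dtype=object)
    out[inside] = labels_arr[idx[inside]]
    return out


def sample_interval_index(rec: AccelRecording, log: AnnotationLog) -> np.ndarray:
    """Index of the covering interval per sample (-1 where unannotated)."""
    idx_out = np.full(rec.n_samples, -1, dtype=int)
    if not log.intervals:
        return idx_out
    t = rec.times
    starts = np.array([iv.start for iv in log.intervals])
    ends = np.array([iv.end for iv in log.intervals])
    idx = np.searchsorted(starts, t, side="right") - 1
    valid = idx >= 0
    inside = np.zeros_like(valid)
    inside[valid] = t[valid] < ends[idx[valid]]
    idx_out[inside] = idx[inside]
    return idx_out
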