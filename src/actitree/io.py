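"""Reading, writing and geometric normalisation of raw thigh recordings.

A recording is a time-ordered sequence of triaxial acceleration samples in
units of g at a constant sampling frequency.  Devices are worn in one of two
placements; a signed axis permutation maps the device frame onto a canonical
anatomical frame in which axis 1 is longitudinal (positive toward the knee,
so quiet upright standing reads about +1 g), axis 2 anterior and axis 3
lateral.  All downstream feature definitions assume the canonical frame.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, replace
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import signal

from .errors import (
    ConfigurationError,
    FormatError,
    ParseError,
    ValidationError,
)

RAW_DEVICE = "raw_device"
CANONICAL = "canonical"

#: Working sampling rate of the classification method, Hz.
WORKING_FS = 30.0


@dataclass(frozen=True)
class TriaxialRecording:
    """Triaxial acceleration samples in g at a constant sampling rate.

    Parameters
    ----------
    fs : float
        Sampling frequency in Hz, strictly positive.
    samples : numpy.ndarray, shape (n, 3)
        Acceleration triplets in g.  In the canonical frame the columns are
        (longitudinal, anterior, lateral).
    frame : str
        Either ``"raw_device"`` or ``"canonical"``.
    start_time : float, optional
        Wall-clock anchor of the first sample, seconds since the epoch.
    """

    fs: float
    samples: np.ndarray
    frame: str = RAW_DEVICE
    start_time: Optional[float] = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.samples, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 3:
            raise ValidationError(f"samples must have shape (n, 3), got {arr.shape}")
        if arr.shape[0] < 1:
            raise ValidationError("recording must contain at least one sample")
        if not np.all(np.isfinite(arr)):
            raise ValidationError("recording contains non-finite samples")
        if not self.fs > 0:
            raise ValidationError(f"sampling frequency must be > 0, got {self.fs}")
        if self.frame not in (RAW_DEVICE, CANONICAL):
            raise ValidationError(f"unknown frame tag {self.frame!r}")
        object.__setattr__(self, "samples", arr)

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def duration(self) -> float:
        """Recording duration in seconds (n / fs)."""
        return self.n_samples / self.fs


# Signed permutation matrices: rows give the canonical axes
# (longitudinal, anterior, lateral) expressed in device (x, y, z) coordinates.
# Both presets are proper rotations (determinant +1).
_PRESET_MATRICES = {
    # y toward the knee, x lateral
    "preschool": np.array([[0, 1, 0], [0, 0, 1], [1, 0, 0]], dtype=float),
    # x toward the knee, y lateral
    "school": np.array([[1, 0, 0], [0, 0, -1], [0, 1, 0]], dtype=float),
}


@dataclass(frozen=True)
class DeviceOrientation:
    """Placement of the device on the body, as a signed axis permutation.

    ``preset`` is ``"preschool"`` (device y toward the knee, x lateral),
    ``"school"`` (device x toward the knee, y lateral) or ``"custom"`` with an
    explicit 3x3 signed permutation in ``custom_map``.
    """

    preset: str = "school"
    custom_map: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.preset == "custom":
            m = np.asarray(self.custom_map, dtype=float)
            if m.shape != (3, 3):
                raise ConfigurationError("custom_map must be a 3x3 matrix")
            if not (
                np.all(np.isin(m, (-1.0, 0.0, 1.0)))
                and np.all(np.abs(m).sum(axis=0) == 1)
                and np.all(np.abs(m).sum(axis=1) == 1)
            ):
                raise ConfigurationError("custom_map must be a signed axis permutation")
            if not math.isclose(float(np.linalg.det(m)), 1.0):
                raise ConfigurationError(
                    "custom_map must be a proper rotation (determinant +1)"
                )
            object.__setattr__(self, "custom_map", m)
        elif self.preset not in _PRESET_MATRICES:
            raise ConfigurationError(f"unknown orientation preset {self.preset!r}")

    @property
    def matrix(self) -> np.ndarray:
        if self.preset == "custom":
            return self.custom_map
        return _PRESET_MATRICES[self.preset]

    def inverse(self) -> "DeviceOrientation":
        """Orientation whose remap undoes this one (matrix transpose)."""
        return DeviceOrientation(preset="custom", custom_map=self.matrix.T.copy())

    @classmethod
    def identity(cls) -> "DeviceOrientation":
        """Orientation for data already in the canonical frame."""
        return cls(preset="custom", custom_map=np.eye(3))


@dataclass(frozen=True)
class LogEntry:
    label: str
    start: float
    end: float


@dataclass(frozen=True)
class ActivityLog:
    """Ground-truth labelled time intervals, in seconds from recording start.

    Entries are sorted, non-overlapping and have strictly positive duration.
    """

    entries: tuple[LogEntry, ...]

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        bad = []
        for i, e in enumerate(entries):
            if not e.start < e.end:
                bad.append(f"entry {i} ({e.label!r}): start {e.start} >= end {e.end}")
        for i in range(1, len(entries)):
            if entries[i].start < entries[i - 1].end:
                bad.append(
                    f"entries {i - 1}/{i} overlap or are unsorted "
                    f"({entries[i - 1].label!r} ends {entries[i - 1].end}, "
                    f"{entries[i].label!r} starts {entries[i].start})"
                )
        if bad:
            raise ValidationError("invalid activity log: " + "; ".join(bad))
        object.__setattr__(self, "entries", entries)

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(e.label for e in self.entries)

    @property
    def span(self) -> tuple[float, float]:
        return (self.entries[0].start, self.entries[-1].end)


def _sniff_dialect(text: str) -> str:
    first = text.splitlines()[0] if text else ""
    return ";" if first.count(";") > first.count(",") else ","


def _looks_like_header(fields: Sequence[str]) -> bool:
    for f in fields:
        try:
            float(f)
        except ValueError:
            return True
    return False


def read_recording(
    path,
    fs: Optional[float] = None,
    orientation: Optional[DeviceOrientation] = None,
) -> TriaxialRecording:
    """Read a recording CSV into the raw device frame.

    Rows hold three acceleration columns in g, optionally preceded by a
    timestamp column (epoch or relative seconds).  Delimiter (comma or
    semicolon) and a single header line are auto-detected.  When timestamps
    are present the sampling frequency is inferred from them and checked
    against ``fs`` if also given; a >1 % mismatch is an error.

    The ``orientation`` argument is accepted for call-site documentation but
    the returned recording stays in the raw device frame; apply
    :func:`remap_to_canonical` explicitly.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise FormatError(f"{path}: empty recording file")
    delim = _sniff_dialect(text)
    rows = list(csv.reader(text.splitlines(), delimiter=delim))
    start_line = 1
    if rows and _looks_like_header(rows[0]):
        rows = rows[1:]
        start_line = 2
    if not rows:
        raise FormatError(f"{path}: no data rows")

    ncol = len(rows[0])
    if ncol < 3:
        raise FormatError(
            f"{path}: expected at least 3 acceleration columns, found {ncol}"
        )
    has_ts = ncol >= 4
    data = np.empty((len(rows), 3), dtype=float)
    times = np.empty(len(rows), dtype=float) if has_ts else None
    for i, row in enumerate(rows):
        if len(row) < ncol:
            raise ParseError(f"{path}: line {start_line + i}: expected {ncol} fields")
        try:
            if has_ts:
                times[i] = float(row[0])
                data[i] = [float(v) for v in row[1:4]]
            else:
                data[i] = [float(v) for v in row[:3]]
        except ValueError as exc:
            raise ParseError(f"{path}: line {start_line + i}: {exc}") from None

    start_time = None
    if has_ts:
        start_time = float(times[0])
        if len(times) > 1:
            dt = np.diff(times)
            if np.any(dt <= 0):
                raise ValidationError(f"{path}: timestamps are not increasing")
            inferred = 1.0 / float(np.mean(dt))
            if fs is not None and abs(inferred - fs) > 0.01 * fs:
                raise ValidationError(
                    f"{path}: declared fs {fs} Hz disagrees with "
                    f"timestamp-inferred {inferred:.3f} Hz"
                )
            fs = fs if fs is not None else inferred
    if fs is None:
        raise ConfigurationError("fs must be given when the file has no timestamps")
    return TriaxialRecording(fs=float(fs), samples=data, start_time=start_time)


def write_recording(path, rec: TriaxialRecording, timestamps: bool = False) -> None:
    """Write a recording as CSV with full double precision (round-trip safe)."""
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        if timestamps:
            t0 = rec.start_time or 0.0
            for i, (a1, a2, a3) in enumerate(rec.samples):
                w.writerow(
                    [repr(float(t0 + i / rec.fs)), repr(float(a1)),
                     repr(float(a2)), repr(float(a3))]
                )
        else:
            for a1, a2, a3 in rec.samples:
                w.writerow([repr(float(a1)), repr(float(a2)), repr(float(a3))])


def remap_to_canonical(
    rec: TriaxialRecording, orientation: DeviceOrientation
) -> TriaxialRecording:
    """Rotate device-frame samples into the canonical anatomical frame.

    The canonical frame is (longitudinal toward the knee, anterior, lateral);
    quiet upright standing then yields a mean longitudinal reading of ~+1 g.
    Per-sample Euclidean norms are preserved exactly.
    """
    if rec.frame != RAW_DEVICE:
        raise ValidationError("recording is not in the raw device frame")
    remapped = rec.samples @ orientation.matrix.T
    return replace(rec, samples=remapped, frame=CANONICAL)


def to_device_frame(
    rec: TriaxialRecording, orientation: DeviceOrientation
) -> TriaxialRecording:
    """Express a canonical recording in a device frame (inverse of
    :func:`remap_to_canonical`); used when simulating device output."""
    if rec.frame != CANONICAL:
        raise ValidationError("recording is not in the canonical frame")
    return replace(rec, samples=rec.samples @ orientation.matrix, frame=RAW_DEVICE)


def resample(
    rec: TriaxialRecording, target_fs: float, method: str = "polyphase"
) -> TriaxialRecording:
    """Resample a recording to ``target_fs`` (downsampling only).

    ``method="polyphase"`` (default) uses anti-aliased rational polyphase
    resampling; ``method="naive"`` picks the nearest input sample for each
    output instant with no anti-alias filtering, for replication of
    pipelines that decimated without filtering.
    """
    if not 0 < target_fs <= rec.fs:
        raise ConfigurationError(
            f"unsupported upsampling: target {target_fs} Hz > input {rec.fs} Hz"
        )
    if target_fs == rec.fs:
        return rec
    if method == "polyphase":
        ratio = Fraction(target_fs / rec.fs).limit_denominator(1000)
        out = signal.resample_poly(rec.samples, ratio.numerator, ratio.denominator, axis=0)
    elif method == "naive":
        n_out = int(round(rec.n_samples * target_fs / rec.fs))
        idx = np.minimum(
            np.round(np.arange(n_out) * rec.fs / target_fs).astype(int),
            rec.n_samples - 1,
        )
        out = rec.samples[idx]
    else:
        raise ConfigurationError(f"unknown resampling method {method!r}")
    return replace(rec, fs=float(target_fs), samples=out)


def read_activity_log(path) -> ActivityLog:
    """Read an activity log CSV with columns label, start_s[, end_s].

    When the end column is missing, each entry ends where the next starts;
    the final entry must then carry an explicit end (a third field on the
    last row).
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if not text.strip():
        raise FormatError(f"{path}: empty activity log")
    delim = _sniff_dialect(text)
    rows = list(csv.reader(text.splitlines(), delimiter=delim))
    if rows and _looks_like_header(rows[0][1:]):
        rows = rows[1:]
    parsed: list[tuple[str, float, Optional[float]]] = []
    for i, row in enumerate(rows):
        if len(row) < 2:
            raise FormatError(f"{path}: row {i + 1}: expected label,start[,end]")
        try:
            start = float(row[1])
            end = float(row[2]) if len(row) > 2 and row[2].strip() else None
        except ValueError as exc:
            raise ParseError(f"{path}: row {i + 1}: {exc}") from None
        parsed.append((row[0].strip(), start, end))
    entries = []
    for i, (label, start, end) in enumerate(parsed):
        if end is None:
            if i + 1 < len(parsed):
                end = parsed[i + 1][1]
            else:
                raise ValidationError(
                    f"{path}: last entry {label!r} needs an explicit end time"
                )
        entries.append(LogEntry(label=label, start=start, end=end))
    return ActivityLog(entries=tuple(entries))


def write_activity_log(path, log: ActivityLog) -> None:
    with Path(path).open("w", encoding="utf-8", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["label", "start_s", "end_s"])
        for e in log.entries:
            w.writerow([e.label, repr(float(e.start)), repr(float(e.end))])


def trim_log(log: ActivityLog, lead_in: float) -> ActivityLog:
    """Advance every entry's start by ``lead_in`` seconds, dropping entries
    whose remaining duration is not positive.

    Used to discard the settling-in period at the start of each protocol
    activity before scoring.
    """
    if lead_in < 0:
        raise ValidationError("lead_in must be >= 0")
    kept = [
        LogEntry(e.label, e.start + lead_in, e.end)
        for e in log.entries
        if e.end - (e.start + lead_in) > 0
    ]
    return ActivityLog(entries=tuple(kept))
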