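"""Audio and annotation I/O plus the core record data model.

A :class:`PCGRecord` is a single-channel phonocardiogram: the raw waveform in
arbitrary (normalised) units and its sampling rate.  Annotations attach heart
sound labels (S1, S2, S3, S4) to onset times and cardiac cycle indices, and
round-trip through a plain CSV so that ground truth and detector output share
one format.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd
from scipy.io import wavfile

from .exceptions import InputError

logger = logging.getLogger(__name__)

VALID_LABELS = ("S1", "S2", "S3", "S4")

#: Scaling applied to integer PCM: value / 2**(bits-1), mapping to [-1, 1).
_PCM_SCALE = {
    np.dtype(np.int16): 2.0**15,
    np.dtype(np.int32): 2.0**31,
}


@dataclass
class PCGRecord:
    """Single-channel heart sound recording.

    Parameters
    ----------
    samples : ndarray
        Waveform samples (float, arbitrary units; WAV input is scaled into
        the [-1, 1] range of its container).
    fs : float
        Sampling rate in Hz.  Must be positive.
    record_id : str
        Free-text label carried through reports and annotations.
    """

    samples: np.ndarray
    fs: float
    record_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise InputError("PCGRecord samples must be one-dimensional")
        if self.fs <= 0:
            raise InputError(f"sampling rate must be positive, got {self.fs}")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise InputError("PCGRecord samples must be finite")

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.samples.size / self.fs

    @property
    def times(self) -> np.ndarray:
        """Per-sample times in seconds from record start."""
        return np.arange(self.samples.size) / self.fs


class Event(NamedTuple):
    """One annotated heart sound: label, onset in seconds, cycle index."""

    label: str
    onset_s: float
    cycle: int


@dataclass
class AnnotationSet:
    """Collection of heart-sound events for one record.

    ``source`` distinguishes ground truth from detector output; it is carried
    for bookkeeping only and does not affect scoring.
    """

    events: list[Event] = field(default_factory=list)
    record_id: str = ""
    source: str = "truth"

    def __post_init__(self) -> None:
        for ev in self.events:
            if ev.label not in VALID_LABELS:
                raise InputError(f"unknown event label {ev.label!r}")
            if ev.cycle < 0:
                raise InputError("cycle indices must be non-negative")

    def with_label(self, label: str) -> list[Event]:
        return [ev for ev in self.events if ev.label == label]

    def sorted(self) -> "AnnotationSet":
        order = sorted(self.events, key=lambda e: (e.cycle, e.onset_s, e.label))
        return AnnotationSet(order, self.record_id, self.source)

    def __len__(self) -> int:
        return len(self.events)


def read_wav(path: str | Path) -> PCGRecord:
    """Read a WAV file into a :class:`PCGRecord`.

    Integer PCM (16/24/32 bit) is scaled by ``2**(bits-1)`` into [-1, 1);
    IEEE float data is taken as-is.  Multi-channel audio keeps channel 0 with
    a logged warning, matching single-stethoscope recording practice.
    """
    path = Path(path)
    try:
        fs, data = wavfile.read(path)
    except (ValueError, OSError) as exc:
        raise InputError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise InputError(f"WAV file {path} contains no audio")
    if data.ndim > 1:
        logger.warning(
            "%s has %d channels; keeping channel 0 only", path.name, data.shape[1]
        )
        data = data[:, 0]
    if data.dtype in _PCM_SCALE:
        samples = data.astype(float) / _PCM_SCALE[data.dtype]
    elif data.dtype == np.uint8:  # 8-bit WAV is unsigned, midpoint 128
        samples = (data.astype(float) - 128.0) / 128.0
    else:
        samples = data.astype(float)
    return PCGRecord(samples=samples, fs=float(fs), record_id=path.stem)


def write_wav(rec: PCGRecord, path: str | Path) -> None:
    """Write a record as a 32-bit IEEE float WAV (lossless for our pipeline)."""
    wavfile.write(Path(path), int(round(rec.fs)), rec.samples.astype(np.float32))


def write_annotations(annots: AnnotationSet, path: str | Path) -> None:
    """Serialise annotations as CSV: ``record_id,cycle,label,onset_s``.

    Onsets are written with six decimal places (microsecond resolution), which
    exceeds any matching tolerance used downstream, so the round trip through
    :func:`read_annotations` is the identity on (label, cycle, onset).
    """
    rows = [
        {
            "record_id": annots.record_id,
            "cycle": ev.cycle,
            "label": ev.label,
            "onset_s": f"{ev.onset_s:.6f}",
        }
        for ev in annots.sorted().events
    ]
    df = pd.DataFrame(rows, columns=["record_id", "cycle", "label", "onset_s"])
    df.to_csv(Path(path), index=False)


def read_annotations(path: str | Path, source: str = "truth") -> AnnotationSet:
    """Inverse of :func:`write_annotations`."""
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"record_id": str, "label": str})
    except (OSError, pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise InputError(f"cannot read annotation CSV {path}: {exc}") from exc
    required = {"record_id", "cycle", "label", "onset_s"}
    if not required.issubset(df.columns):
        raise InputError(f"{path} is missing columns {required - set(df.columns)}")
    events = [
        Event(str(row.label), float(row.onset_s), int(row.cycle))
        for row in df.itertuples()
    ]
    record_id = str(df["record_id"].iloc[0]) if len(df) else ""
    return AnnotationSet(events=events, record_id=record_id, source=source)


def events_from_pairs(
    pairs: Iterable[tuple[str, float, int]], record_id: str = "", source: str = "truth"
) -> AnnotationSet:
    """Convenience constructor from (label, onset_s, cycle) tuples."""
    return AnnotationSet([Event(*p) for p in pairs], record_id, source)
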