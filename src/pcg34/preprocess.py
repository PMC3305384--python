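"""Filtering, envelope extraction, Shannon energy and cycle segmentation.

The segmentation chain: zero-phase Butterworth low-pass (heart sounds live
below ~600 Hz), analytic-signal envelope, peak normalisation, Shannon energy
``SE = -x^2 log(x^2)`` (which suppresses low-amplitude content relative to the
loud S1/S2 bursts), a short moving average, and threshold peak picking with a
50 ms merge rule.  Inter-peak intervals are labelled systolic (shorter than
the previous interval) or diastolic (longer); ambiguous intervals are marked
uncertain and re-searched with a secondary, lower threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .config import PipelineConfig
from .exceptions import (
    DegenerateInputError,
    ParameterError,
    SegmentationError,
)
from .io import PCGRecord

SYSTOLIC, DIASTOLIC, UNCERTAIN = "systolic", "diastolic", "uncertain"


@dataclass
class EnvelopeSignal:
    values: np.ndarray
    fs: float


@dataclass
class NormalizedSignal:
    values: np.ndarray
    fs: float


@dataclass
class ShannonEnergySignal:
    values: np.ndarray
    fs: float


@dataclass
class Interval:
    start: float
    end: float
    label: str


@dataclass
class Cycle:
    """One cardiac cycle: S1 and S2 peak times and the bounding diastole."""

    s1: float
    s2: float
    dia_start: float
    dia_end: float


@dataclass
class CycleSegmentation:
    """Peak times and systole/diastole labelling for one record."""

    peak_times: np.ndarray
    intervals: list[Interval]
    cycles: list[Cycle]
    fs: float
    unresolved: list[Interval] = field(default_factory=list)

    @property
    def s1_times(self) -> np.ndarray:
        return np.array([c.s1 for c in self.cycles])

    @property
    def s2_times(self) -> np.ndarray:
        return np.array([c.s2 for c in self.cycles])

    @property
    def diastoles(self) -> list[tuple[float, float]]:
        return [(c.dia_start, c.dia_end) for c in self.cycles]

    @property
    def n_cycles(self) -> int:
        return len(self.cycles)


def lowpass_filter(rec: PCGRecord, cutoff: float = 600.0, order: int = 6) -> PCGRecord:
    """Zero-phase (forward-backward) Butterworth low-pass.

    Zero-phase filtering preserves burst peak timing, which segmentation
    depends on; the effective magnitude response is the squared Butterworth
    response.
    """
    if not 0 < cutoff < rec.fs / 2:
        raise ParameterError(
            f"cutoff {cutoff} Hz must lie in (0, Nyquist={rec.fs / 2} Hz)"
        )
    sos = sps.butter(order, cutoff, btype="low", fs=rec.fs, output="sos")
    filtered = sps.sosfiltfilt(sos, rec.samples)
    return PCGRecord(filtered, rec.fs, rec.record_id)


def envelope(rec: PCGRecord) -> EnvelopeSignal:
    """Magnitude of the analytic signal ``x + j H{x}`` (Hilbert envelope)."""
    analytic = sps.hilbert(rec.samples)
    return EnvelopeSignal(np.abs(analytic), rec.fs)


def normalize(env: EnvelopeSignal) -> NormalizedSignal:
    """Divide by the maximal absolute value so the peak is exactly 1."""
    peak = float(np.max(np.abs(env.values))) if env.values.size else 0.0
    if peak == 0.0:
        raise DegenerateInputError("cannot normalize an all-zero envelope")
    return NormalizedSignal(env.values / peak, env.fs)


def shannon_energy(norm: NormalizedSignal) -> ShannonEnergySignal:
    """Shannon energy ``SE = -x^2 log(x^2)`` with the convention 0*log 0 = 0.

    For |x| <= 1 the result lies in [0, 1/e], peaking at |x| = e^{-1/2}; both
    silence and full-scale samples map to zero energy.
    """
    x = norm.values
    if np.max(np.abs(x), initial=0.0) > 1.0 + 1e-9:
        raise ParameterError("Shannon energy input must satisfy |x| <= 1")
    x2 = np.clip(x, -1.0, 1.0) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = -x2 * np.log(x2)
    se[x2 == 0.0] = 0.0
    return ShannonEnergySignal(se, norm.fs)


def smooth_energy(se: ShannonEnergySignal, window_ms: float = 20.0) -> ShannonEnergySignal:
    """Moving-average smoothing of the per-sample Shannon energy."""
    win = max(1, int(round(window_ms / 1000.0 * se.fs)))
    kernel = np.ones(win) / win
    smoothed = np.convolve(se.values, kernel, mode="same")
    return ShannonEnergySignal(smoothed, se.fs)


def _local_maxima(values: np.ndarray) -> np.ndarray:
    """Indices of strict local maxima; plateaus contribute their midpoint."""
    peaks, props = sps.find_peaks(values, plateau_size=1)
    # find_peaks reports the left edge for even plateaus; use the midpoint
    mids = (props["left_edges"] + props["right_edges"]) // 2
    return mids


def eliminate_close_peaks(
    times: Sequence[float], energies: Sequence[float], merge_s: float
) -> list[int]:
    """Indices of surviving peaks after the 50 ms proximity rule.

    While any two peaks lie closer than ``merge_s``, the globally
    lowest-energy peak involved in a violation is removed.  Removing the
    global minimum first makes the survivor set independent of input order.
    """
    times = np.asarray(times, dtype=float)
    energies = np.asarray(energies, dtype=float)
    order = np.argsort(times, kind="stable")
    alive = list(order)
    while True:
        violators = set()
        for a, b in zip(alive, alive[1:]):
            if abs(times[b] - times[a]) < merge_s:
                violators.update((a, b))
        if not violators:
            return sorted(alive, key=lambda i: times[i])
        worst = min(violators, key=lambda i: (energies[i], times[i]))
        alive.remove(worst)


def pick_major_peaks(
    se: ShannonEnergySignal,
    threshold_frac: float = 0.70,
    merge_ms: float = 50.0,
) -> np.ndarray:
    """Times of major Shannon-energy peaks (candidate S1/S2).

    Local maxima above ``threshold_frac`` of the global maximum are kept;
    among peaks closer than ``merge_ms`` the lower-energy one is eliminated,
    iterated until no pair violates.
    """
    if not 0 < threshold_frac < 1:
        raise ParameterError("threshold_frac must lie in (0, 1)")
    values = se.values
    if values.size == 0 or np.max(values) <= 0:
        raise SegmentationError("no energy in record")
    thresh = threshold_frac * float(np.max(values))
    idx = _local_maxima(values)
    idx = idx[values[idx] >= thresh]
    if idx.size == 0:
        raise SegmentationError("no Shannon-energy peak above threshold")
    times = idx / se.fs
    keep = eliminate_close_peaks(times, values[idx], merge_ms / 1000.0)
    return times[keep]


def label_intervals(
    peaks: Sequence[float],
    tie_tol: float = 0.10,
    max_ds_ratio: float = 2.5,
) -> list[Interval]:
    """Label inter-peak intervals systolic/diastolic/uncertain.

    An interval shorter than the previous one is systolic, longer is
    diastolic (the first interval is compared against the second).  Intervals
    within ``tie_tol`` relative difference of the reference are uncertain, as
    is any diastolic interval more than ``max_ds_ratio`` times its adjacent
    systole - at rest the diastole is longer than the systole but not by that
    much, so such a gap likely hides a missed sound.
    """
    peaks = np.asarray(peaks, dtype=float)
    if peaks.size < 3:
        raise SegmentationError("need at least 3 peaks to label intervals")
    lengths = np.diff(peaks)
    labels = []
    for i, length in enumerate(lengths):
        ref = lengths[i - 1] if i > 0 else lengths[1]
        rel = abs(length - ref) / max(length, ref)
        if rel <= tie_tol:
            labels.append(UNCERTAIN)
        elif length < ref:
            labels.append(SYSTOLIC)
        else:
            labels.append(DIASTOLIC)
    for i, label in enumerate(labels):
        if label != DIASTOLIC:
            continue
        neighbors = [
            lengths[j]
            for j in (i - 1, i + 1)
            if 0 <= j < len(labels) and labels[j] == SYSTOLIC
        ]
        if neighbors and lengths[i] > max_ds_ratio * min(neighbors):
            labels[i] = UNCERTAIN
    return [
        Interval(float(peaks[i]), float(peaks[i + 1]), labels[i])
        for i in range(len(labels))
    ]


def recover_missed_peaks(
    se: ShannonEnergySignal,
    peaks: Sequence[float],
    intervals: list[Interval],
    secondary_frac: float = 0.50,
    merge_ms: float = 50.0,
    tie_tol: float = 0.10,
    max_ds_ratio: float = 2.5,
) -> tuple[np.ndarray, list[Interval]]:
    """Re-search uncertain intervals with a secondary, lower threshold.

    New peaks above ``secondary_frac * max(SE)`` inside uncertain intervals
    are pooled with the existing peaks, the proximity rule is re-applied, and
    interval labels are recomputed.  Finding nothing is a valid outcome.
    """
    peaks = np.asarray(peaks, dtype=float)
    values = se.values
    thresh = secondary_frac * float(np.max(values))
    new_times: list[float] = []
    for iv in intervals:
        if iv.label != UNCERTAIN:
            continue
        lo = int(np.ceil(iv.start * se.fs)) + 1
        hi = int(np.floor(iv.end * se.fs))
        if hi - lo < 3:
            continue
        local = _local_maxima(values[lo:hi])
        for j in local:
            if values[lo + j] >= thresh:
                new_times.append((lo + j) / se.fs)
    if not new_times:
        return peaks, intervals
    all_times = np.concatenate([peaks, np.array(new_times)])
    all_energy = values[np.clip((all_times * se.fs).round().astype(int), 0, values.size - 1)]
    keep = eliminate_close_peaks(all_times, all_energy, merge_ms / 1000.0)
    merged = np.sort(all_times[keep])
    return merged, label_intervals(merged, tie_tol, max_ds_ratio)


def snap_to_envelope(
    peaks: Sequence[float], norm: NormalizedSignal, snap_ms: float = 25.0
) -> np.ndarray:
    """Refine each peak time to the envelope apex within ``snap_ms``.

    The Shannon energy of a normalised envelope vanishes where the envelope
    reaches 1, so the SE maximum of the loudest burst sits on the burst's
    flank rather than its acoustic peak; the envelope apex is the unbiased
    burst time.
    """
    radius = max(1, int(round(snap_ms / 1000.0 * norm.fs)))
    snapped = []
    for t in np.asarray(peaks, dtype=float):
        c = int(round(t * norm.fs))
        lo, hi = max(c - radius, 0), min(c + radius + 1, norm.values.size)
        snapped.append((lo + int(np.argmax(norm.values[lo:hi]))) / norm.fs)
    return np.array(sorted(snapped))


def _build_cycles(intervals: list[Interval]) -> list[Cycle]:
    cycles = []
    for a, b in zip(intervals, intervals[1:]):
        if a.label == SYSTOLIC and b.label == DIASTOLIC:
            cycles.append(Cycle(s1=a.start, s2=a.end, dia_start=b.start, dia_end=b.end))
    return cycles


def segment(
    rec: PCGRecord, config: PipelineConfig | None = None, assume_filtered: bool = False
) -> CycleSegmentation:
    """Full segmentation of a record into S1/S2 peaks and labelled intervals.

    Composition of the stage operations; the snapped peak times (envelope
    apices) define the final interval boundaries and cycles.
    """
    cfg = config or PipelineConfig()
    if rec.duration < 2.0:
        raise SegmentationError("record shorter than 2 s cannot contain a full cycle")
    filt = rec if assume_filtered else lowpass_filter(
        rec, cfg.lowpass.cutoff_hz, cfg.lowpass.order
    )
    norm = normalize(envelope(filt))
    se = smooth_energy(shannon_energy(norm), cfg.se.smooth_ms)
    assert 0.0 <= se.values.min() and shannon_energy(norm).values.max() <= 1 / np.e + 1e-12
    peaks = pick_major_peaks(se, cfg.seg.threshold_frac, cfg.seg.merge_ms)
    if peaks.size < 3:
        raise SegmentationError(f"only {peaks.size} major peaks found")
    intervals = label_intervals(peaks, cfg.seg.tie_tol, cfg.seg.max_ds_ratio)
    if any(iv.label == UNCERTAIN for iv in intervals):
        peaks, intervals = recover_missed_peaks(
            se, peaks, intervals, cfg.seg.secondary_frac, cfg.seg.merge_ms,
            cfg.seg.tie_tol, cfg.seg.max_ds_ratio,
        )
    peaks = snap_to_envelope(peaks, norm, cfg.seg.snap_ms)
    intervals = label_intervals(peaks, cfg.seg.tie_tol, cfg.seg.max_ds_ratio)
    cycles = _build_cycles(intervals)
    unresolved = [iv for iv in intervals if iv.label == UNCERTAIN]
    return CycleSegmentation(
        peak_times=peaks,
        intervals=intervals,
        cycles=cycles,
        fs=rec.fs,
        unresolved=unresolved,
    )
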