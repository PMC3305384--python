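"""S3/S4 recognition from the diastolic Hilbert ridge.

Within each diastole (S2 to the next S1) the maximal-amplitude instantaneous
frequency and magnitude form a point cloud; pooled over all cycles of a
record and clustered with k-means into three groups, the group with the
fewest members marks abnormal diastolic activity.  Abnormal points projected
back to time become candidate events; a candidate periodically shortly after
S2 is an S3, one periodically just before the next S1 is an S4.  An iterative
pass enforces periodicity: outlier latencies are dropped and, for labels
present in most cycles, missing cycles are re-searched around the median
latency so that sub-threshold occurrences are recovered.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans

from .config import PipelineConfig
from .exceptions import ClusteringError, SegmentationError
from .hht import (
    RidgeTrack,
    emd,
    hilbert_spectrum_tracks,
    max_amplitude_ridge,
    max_frequency_ridge,
)
from .io import AnnotationSet, Event, PCGRecord
from .preprocess import CycleSegmentation, lowpass_filter, segment

NORMAL, UNCERTAIN_GROUP, ABNORMAL = "normal", "uncertain", "abnormal"


@dataclass
class FreqMagPoints:
    """Diastolic ridge samples: time, frequency, magnitude, cycle index."""

    times: np.ndarray
    freqs: np.ndarray
    mags: np.ndarray
    cycles: np.ndarray

    def __len__(self) -> int:
        return self.times.size


@dataclass
class ClusterAssignment:
    """Three-group k-means labelling of the frequency-magnitude cloud."""

    labels: np.ndarray          # one of NORMAL/UNCERTAIN_GROUP/ABNORMAL per point
    centroids: np.ndarray       # 3 x 2, standardized (frequency, magnitude) units
    group_sizes: dict[str, int] = field(default_factory=dict)


@dataclass
class DetectionEvent:
    label: str                  # "S3" or "S4"
    onset_s: float
    cycle: int
    latency_s: float            # S3: after the cycle's S2; S4: before the next S1
    magnitude: float
    provenance: str             # "clustered" or "recovered"


@dataclass
class DetectionReport:
    """Per-record detection outcome plus enough context to reproduce it."""

    record_id: str
    n_cycles: int
    events: list[DetectionEvent]
    rejected: int               # candidates outside both physiologic windows
    unresolved_intervals: int
    seed: int
    config: dict

    def to_annotations(self) -> AnnotationSet:
        evs = [Event(e.label, e.onset_s, e.cycle) for e in self.events]
        return AnnotationSet(evs, self.record_id, source="detected").sorted()

    def cycle_rows(self) -> list[dict]:
        rows = []
        by_cycle: dict[int, dict] = {}
        for e in self.events:
            by_cycle.setdefault(e.cycle, {})[e.label] = e
        for c in range(self.n_cycles):
            row: dict = {"cycle": c}
            for label in ("S3", "S4"):
                ev = by_cycle.get(c, {}).get(label)
                row[f"{label}_onset_s"] = round(ev.onset_s, 6) if ev else None
                row[f"{label}_provenance"] = ev.provenance if ev else None
            rows.append(row)
        return rows

    def to_json(self) -> str:
        payload = {
            "record_id": self.record_id,
            "n_cycles": self.n_cycles,
            "seed": self.seed,
            "events": [
                {**dataclasses.asdict(e), "onset_s": round(e.onset_s, 6),
                 "latency_s": round(e.latency_s, 6),
                 "magnitude": round(e.magnitude, 9)}
                for e in self.events
            ],
            "cycles": self.cycle_rows(),
            "rejected_candidates": self.rejected,
            "unresolved_intervals": self.unresolved_intervals,
            "config": self.config,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


@dataclass
class _Candidate:
    time: float
    magnitude: float
    cycle: int
    peak_time: float = 0.0  # time of the run's maximal-magnitude point


def extract_diastolic_points(
    ridge: RidgeTrack,
    seg: CycleSegmentation,
    decimate: int = 8,
    guard_s: float = 0.0,
) -> FreqMagPoints:
    """Ridge samples inside diastolic intervals, decimated by ``decimate``.

    ``guard_s`` optionally excludes samples within that margin of the
    bounding S2 and S1 peaks, so the tails of the bounding sounds themselves
    do not enter the frequency-magnitude pool.  Intervals are half-open
    [start, end).
    """
    if not seg.cycles:
        raise SegmentationError("segmentation has no diastolic interval")
    idx = np.arange(0, ridge.freq_hz.size, decimate)
    t = idx / ridge.fs
    times, freqs, mags, cycles = [], [], [], []
    for ci, (d0, d1) in enumerate(seg.diastoles):
        mask = (t >= d0 + guard_s) & (t < d1 - guard_s)
        times.append(t[mask])
        freqs.append(ridge.freq_hz[idx[mask]])
        mags.append(ridge.magnitude[idx[mask]])
        cycles.append(np.full(int(mask.sum()), ci))
    return FreqMagPoints(
        np.concatenate(times), np.concatenate(freqs),
        np.concatenate(mags), np.concatenate(cycles),
    )


def cluster_points(
    pts: FreqMagPoints, seed: int = 0, restarts: int = 10, max_iter: int = 300
) -> ClusterAssignment:
    """Three-group k-means of the standardized frequency-magnitude cloud.

    Frequency (Hz) and ridge magnitude are incommensurate, so each dimension
    is standardized to zero mean / unit variance first.  The group with the
    fewest points is abnormal (ties: higher mean standardized magnitude); of
    the remaining groups the one with the smaller centroid norm - low
    amplitude and low frequency - is normal, the other uncertain.
    """
    feats = np.column_stack([pts.freqs, pts.mags]).astype(float)
    if len(pts) < 3 or np.unique(feats, axis=0).shape[0] < 3:
        raise ClusteringError("need at least 3 distinct frequency-magnitude points")
    mu = feats.mean(axis=0)
    sd = feats.std(axis=0)
    sd[sd == 0] = 1.0
    z = (feats - mu) / sd
    km = KMeans(
        n_clusters=3, n_init=restarts, max_iter=max_iter,
        random_state=seed % (2**32), init="k-means++",
    ).fit(z)
    raw = km.labels_
    sizes = np.bincount(raw, minlength=3)
    mean_mag = np.array([
        z[raw == k, 1].mean() if sizes[k] else -np.inf for k in range(3)
    ])
    order = sorted(range(3), key=lambda k: (sizes[k], -mean_mag[k]))
    abnormal = order[0]
    rest = [k for k in range(3) if k != abnormal]
    norms = np.linalg.norm(km.cluster_centers_, axis=1)
    normal = min(rest, key=lambda k: norms[k])
    name = {abnormal: ABNORMAL, normal: NORMAL}
    name[[k for k in rest if k != normal][0]] = UNCERTAIN_GROUP
    labels = np.array([name[k] for k in raw])
    group_sizes = {name[k]: int(sizes[k]) for k in range(3)}
    return ClusterAssignment(labels, km.cluster_centers_, group_sizes)


def project_to_events(
    assign: ClusterAssignment,
    pts: FreqMagPoints,
    gap_s: float = 0.060,
    max_run_s: float | None = None,
) -> list[_Candidate]:
    """Merge temporal runs of abnormal points into candidate events.

    Abnormal points sorted by time are split wherever consecutive points are
    ``gap_s`` or more apart; each run becomes one candidate at the
    magnitude-weighted mean time, carrying the run's peak magnitude.

    ``max_run_s``, when set, discards runs whose temporal extent exceeds it:
    a discrete heart sound is a transient burst, so an "abnormal" run
    smeared over most of a diastole is diffuse noise, not an event.
    """
    mask = assign.labels == ABNORMAL
    if not mask.any():
        return []
    order = np.argsort(pts.times[mask], kind="stable")
    t = pts.times[mask][order]
    m = pts.mags[mask][order]
    c = pts.cycles[mask][order]
    cuts = np.nonzero(np.diff(t) >= gap_s)[0] + 1
    cands = []
    for lo, hi in zip(np.r_[0, cuts], np.r_[cuts, t.size]):
        if max_run_s is not None and t[hi - 1] - t[lo] > max_run_s:
            continue
        w = m[lo:hi]
        center = float(np.sum(t[lo:hi] * w) / np.sum(w))
        cyc = int(np.bincount(c[lo:hi]).argmax())
        peak_t = float(t[lo:hi][np.argmax(w)])
        cands.append(_Candidate(center, float(w.max()), cyc, peak_t))
    return cands


def drop_edge_candidates(
    cands: list[_Candidate],
    seg: CycleSegmentation,
    guard_s: float,
    edge_s: float = 0.015,
) -> list[_Candidate]:
    """Discard candidates whose magnitude peaks at a guarded diastole edge.

    A genuine diastolic sound lies wholly inside the diastole, so its ridge
    magnitude peaks in the interior; a run whose maximum sits against the
    guard boundary is the truncated tail of the bounding S2 or S1 (still
    rising/falling at the cut) masquerading as a periodic diastolic event.
    """
    kept = []
    for cand in cands:
        cyc = seg.cycles[cand.cycle]
        near_start = cand.peak_time - (cyc.dia_start + guard_s) <= edge_s
        near_end = (cyc.dia_end - guard_s) - cand.peak_time <= edge_s
        if not (near_start or near_end):
            kept.append(cand)
    return kept


def _latency(label: str, t: float, cyc) -> float:
    return t - cyc.s2 if label == "S3" else cyc.dia_end - t


def classify_events(
    cands: list[_Candidate],
    seg: CycleSegmentation,
    s3_window_s: tuple[float, float] = (0.080, 0.250),
    s4_window_s: tuple[float, float] = (0.040, 0.200),
) -> tuple[list[DetectionEvent], int]:
    """Assign candidates to S3/S4 by physiologic diastolic timing.

    S3 lives in early diastole (latency after S2 inside ``s3_window_s``); S4
    in late diastole (lead before the next S1 inside ``s4_window_s``).
    Candidates in neither window are rejected; at most one event per label
    per cycle survives, the strongest by magnitude.
    """
    best: dict[tuple[int, str], DetectionEvent] = {}
    rejected = 0
    for cand in cands:
        cyc = seg.cycles[cand.cycle]
        lat_s3 = cand.time - cyc.s2
        lead_s4 = cyc.dia_end - cand.time
        in_s3 = s3_window_s[0] <= lat_s3 <= s3_window_s[1]
        in_s4 = s4_window_s[0] <= lead_s4 <= s4_window_s[1]
        if in_s3 and in_s4:
            # ambiguous mid-diastole candidate: closer window centre wins
            mid3 = sum(s3_window_s) / 2
            mid4 = sum(s4_window_s) / 2
            in_s4 = abs(lead_s4 - mid4) < abs(lat_s3 - mid3)
            in_s3 = not in_s4
        if not (in_s3 or in_s4):
            rejected += 1
            continue
        label = "S3" if in_s3 else "S4"
        ev = DetectionEvent(
            label, cand.time, cand.cycle,
            lat_s3 if in_s3 else lead_s4, cand.magnitude, "clustered",
        )
        key = (cand.cycle, label)
        if key not in best or ev.magnitude > best[key].magnitude:
            best[key] = ev
    return sorted(best.values(), key=lambda e: e.onset_s), rejected


def iterative_recognition(
    events: list[DetectionEvent],
    pts: FreqMagPoints,
    seg: CycleSegmentation,
    latency_tol_s: float = 0.050,
    presence_frac: float = 0.5,
    recover_frac: float = 0.6,
    max_rounds: int = 20,
) -> list[DetectionEvent]:
    """Enforce periodicity and recover missed events.

    Per label: events whose latency deviates from the median by more than
    ``latency_tol_s`` are discarded as non-periodic.  A label is deemed
    present in the record only when it survives in at least ``presence_frac``
    of cycles; otherwise its remaining events are sporadic and are removed
    entirely.  For present labels, each missing cycle is re-searched within
    median +/- tolerance and the strongest ridge point there is promoted when
    its magnitude exceeds ``recover_frac`` times the median magnitude of the
    detected events.  Repeats to a fixed point (idempotent).
    """
    n_cycles = seg.n_cycles
    current = {(e.cycle, e.label): e for e in events}
    for _ in range(max_rounds):
        changed = False
        for label in ("S3", "S4"):
            evs = [e for e in current.values() if e.label == label]
            if not evs:
                continue
            lats = np.array([e.latency_s for e in evs])
            med = float(np.median(lats))
            for e in evs:
                if abs(e.latency_s - med) > latency_tol_s:
                    del current[(e.cycle, e.label)]
                    changed = True
            evs = [e for e in current.values() if e.label == label]
            if not evs:
                continue
            if len(evs) / n_cycles < presence_frac:
                for e in evs:
                    del current[(e.cycle, e.label)]
                changed = True
                continue
            med = float(np.median([e.latency_s for e in evs]))
            med_mag = float(np.median([e.magnitude for e in evs]))
            have = {e.cycle for e in evs}
            for ci in range(n_cycles):
                if ci in have:
                    continue
                cyc = seg.cycles[ci]
                if label == "S3":
                    lo, hi = cyc.s2 + med - latency_tol_s, cyc.s2 + med + latency_tol_s
                else:
                    lo, hi = cyc.dia_end - med - latency_tol_s, cyc.dia_end - med + latency_tol_s
                mask = (pts.cycles == ci) & (pts.times >= lo) & (pts.times <= hi)
                if not mask.any():
                    continue
                j = np.flatnonzero(mask)[np.argmax(pts.mags[mask])]
                if pts.mags[j] > recover_frac * med_mag:
                    t = float(pts.times[j])
                    current[(ci, label)] = DetectionEvent(
                        label, t, ci, _latency(label, t, cyc),
                        float(pts.mags[j]), "recovered",
                    )
                    changed = True
        if not changed:
            break
    return sorted(current.values(), key=lambda e: (e.onset_s, e.label))


def detect_record(
    rec: PCGRecord, config: PipelineConfig | None = None, seed: int = 0
) -> DetectionReport:
    """Full S3/S4 detection pipeline on one record.

    Filter -> segment -> EMD -> Hilbert ridge -> diastolic clustering ->
    window classification -> iterative periodicity pass.  Deterministic for a
    fixed (record, config, seed).
    """
    cfg = config or PipelineConfig()
    filt = lowpass_filter(rec, cfg.lowpass.cutoff_hz, cfg.lowpass.order)
    seg = segment(filt, cfg, assume_filtered=True)
    imfset = emd(filt.samples, rec.fs, cfg.emd)
    if len(imfset) == 0:
        raise SegmentationError("record decomposed to no oscillatory component")
    ridge_fn = (
        max_frequency_ridge
        if cfg.detect.ridge == "max_frequency"
        else max_amplitude_ridge
    )
    ridge = ridge_fn(hilbert_spectrum_tracks(imfset))
    pts = extract_diastolic_points(
        ridge, seg, cfg.detect.decimate, cfg.detect.guard_ms / 1000.0
    )
    d = cfg.detect
    try:
        assign = cluster_points(pts, seed, cfg.kmeans.restarts, cfg.kmeans.max_iter)
    except ClusteringError:
        events: list[DetectionEvent] = []
        rejected = 0
        rejected_edges = 0
    else:
        cands = project_to_events(
            assign, pts, d.gap_ms / 1000.0, d.max_run_ms / 1000.0
        )
        n_before = len(cands)
        cands = drop_edge_candidates(
            cands, seg, d.guard_ms / 1000.0, d.edge_ms / 1000.0
        )
        if d.min_rel_mag > 0:
            # significance floor: a diastolic sound, though weaker than S1/S2,
            # must still stand clear of the record's own noise ripple
            peaks = np.concatenate([seg.s1_times, seg.s2_times])
            ref = float(np.median(
                ridge.magnitude[
                    np.clip((peaks * ridge.fs).round().astype(int), 0,
                            ridge.magnitude.size - 1)
                ]
            ))
            cands = [c for c in cands if c.magnitude >= d.min_rel_mag * ref]
        rejected_edges = n_before - len(cands)
        events, rejected = classify_events(
            cands, seg,
            tuple(w / 1000.0 for w in d.s3_window_ms),
            tuple(w / 1000.0 for w in d.s4_window_ms),
        )
        events = iterative_recognition(
            events, pts, seg, d.latency_tol_ms / 1000.0,
            d.presence_frac, d.recover_frac,
        )
    return DetectionReport(
        record_id=rec.record_id,
        n_cycles=seg.n_cycles,
        events=events,
        rejected=rejected + rejected_edges,
        unresolved_intervals=len(seg.unresolved),
        seed=seed,
        config=cfg.to_dict(),
    )
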