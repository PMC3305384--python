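import itertools

import numpy as np
import pytest

from pcg34.config import PipelineConfig
from pcg34.detect import (
    ABNORMAL,
    ClusterAssignment,
    FreqMagPoints,
    _Candidate,
    classify_events,
    cluster_points,
    detect_record,
    drop_edge_candidates,
    extract_diastolic_points,
    iterative_recognition,
    project_to_events,
)
from pcg34.exceptions import ClusteringError, SegmentationError
from pcg34.hht import RidgeTrack
from pcg34.preprocess import Cycle, CycleSegmentation, Interval
from pcg34.synth import SynthConfig, generate_pcg


def _segmentation(n_cycles=5, period=1.0, systole=0.3, fs=8000.0):
    cycles = []
    intervals = []
    for i in range(n_cycles):
        s1 = i * period
        s2 = s1 + systole
        nxt = (i + 1) * period
        cycles.append(Cycle(s1, s2, s2, nxt))
        intervals += [
            Interval(s1, s2, "systolic"),
            Interval(s2, nxt, "diastolic"),
        ]
    peaks = np.array(sorted({iv.start for iv in intervals} | {intervals[-1].end}))
    return CycleSegmentation(peaks, intervals, cycles, fs)


def _flat_ridge(duration=5.0, fs=8000.0):
    n = int(duration * fs)
    return RidgeTrack(np.full(n, 30.0), np.full(n, 0.01), fs)


class TestExtractDiastolicPoints:
    def test_point_count_for_half_second_diastoles(self):
        seg = _segmentation(n_cycles=5, period=1.0, systole=0.5)
        pts = extract_diastolic_points(_flat_ridge(), seg, decimate=8)
        assert len(pts) == 5 * 500

    def test_stride_one_takes_every_diastolic_sample(self):
        seg = _segmentation(n_cycles=2, period=1.0, systole=0.5)
        pts = extract_diastolic_points(_flat_ridge(2.5), seg, decimate=1)
        assert len(pts) == 2 * 4000

    def test_membership_against_brute_force_scan(self):
        seg = _segmentation(n_cycles=4, period=1.0, systole=0.3)
        pts = extract_diastolic_points(_flat_ridge(4.5), seg, decimate=8, guard_s=0.05)
        dias = [(c.dia_start + 0.05, c.dia_end - 0.05) for c in seg.cycles]
        for t in pts.times:
            assert any(lo <= t < hi for lo, hi in dias)
        # count cross-check: exhaustive loop over the decimated grid
        grid = np.arange(0, int(4.5 * 8000), 8) / 8000.0
        expected = sum(1 for t in grid if any(lo <= t < hi for lo, hi in dias))
        assert len(pts) == expected

    def test_no_diastole_rejected(self):
        seg = CycleSegmentation(np.array([0.0, 0.3]), [], [], 8000.0)
        with pytest.raises(SegmentationError):
            extract_diastolic_points(_flat_ridge(1.0), seg)


def _wcss(feats, groups):
    total = 0.0
    for g in groups:
        pts = feats[list(g)]
        total += float(np.sum((pts - pts.mean(axis=0)) ** 2))
    return total


class TestClusterPoints:
    def _pts(self, freqs, mags):
        n = len(freqs)
        return FreqMagPoints(
            np.linspace(0, 1, n), np.asarray(freqs, float),
            np.asarray(mags, float), np.zeros(n, int),
        )

    def test_three_separated_blobs_fewest_is_abnormal(self):
        rng = np.random.default_rng(0)
        freqs = np.concatenate([
            rng.normal(20, 1, 100), rng.normal(300, 1, 30), rng.normal(40, 1, 5)
        ])
        mags = np.concatenate([
            rng.normal(0.01, 0.001, 100), rng.normal(0.02, 0.001, 30),
            rng.normal(0.5, 0.01, 5),
        ])
        assign = cluster_points(self._pts(freqs, mags), seed=1)
        assert list(np.nonzero(assign.labels == ABNORMAL)[0]) == list(range(130, 135))

    def test_six_points_match_exhaustive_partition(self):
        freqs = [10.0, 12.0, 300.0, 310.0, 150.0, 155.0]
        mags = [0.01, 0.012, 0.3, 0.31, 0.1, 0.11]
        pts = self._pts(freqs, mags)
        assign = cluster_points(pts, seed=3)
        feats = np.column_stack([freqs, mags])
        z = (feats - feats.mean(0)) / feats.std(0)
        best, best_w = None, np.inf
        for labels in itertools.product(range(3), repeat=6):
            if len(set(labels)) != 3:
                continue
            groups = [
                [i for i in range(6) if labels[i] == k] for k in range(3)
            ]
            w = _wcss(z, groups)
            if w < best_w - 1e-12:
                best_w, best = w, groups
        ours = [
            sorted(np.nonzero(assign.labels == lab)[0].tolist())
            for lab in sorted(set(assign.labels))
        ]
        assert sorted(map(tuple, ours)) == sorted(
            tuple(sorted(g)) for g in best
        )

    def test_duplicated_points_same_partition(self):
        freqs = [10.0, 12.0, 300.0, 310.0, 150.0, 155.0]
        mags = [0.01, 0.012, 0.3, 0.31, 0.1, 0.11]
        a = cluster_points(self._pts(freqs, mags), seed=5)
        b = cluster_points(self._pts(freqs * 2, mags * 2), seed=5)
        np.testing.assert_array_equal(a.labels, b.labels[:6])
        np.testing.assert_array_equal(b.labels[:6], b.labels[6:])

    def test_too_few_distinct_points_rejected(self):
        with pytest.raises(ClusteringError):
            cluster_points(self._pts([10.0, 10.0, 10.0, 10.0], [0.1] * 4), seed=0)

    def test_normal_group_has_smallest_centroid(self):
        rng = np.random.default_rng(9)
        freqs = np.concatenate([
            rng.normal(15, 1, 80), rng.normal(400, 5, 40), rng.normal(35, 1, 10)
        ])
        mags = np.concatenate([
            rng.normal(0.005, 0.0005, 80), rng.normal(0.01, 0.001, 40),
            rng.normal(0.4, 0.01, 10),
        ])
        assign = cluster_points(self._pts(freqs, mags), seed=2)
        assert set(assign.labels[:80]) == {"normal"}


class TestProjectToEvents:
    def _pts(self, times, mags, cycles=None):
        times = np.asarray(times, float)
        cycles = np.zeros(times.size, int) if cycles is None else np.asarray(cycles)
        return FreqMagPoints(times, np.full(times.size, 30.0),
                             np.asarray(mags, float), cycles)

    def _all_abnormal(self, pts):
        return ClusterAssignment(np.array([ABNORMAL] * len(pts)), np.zeros((3, 2)))

    def test_points_within_30ms_merge_to_one(self):
        times = np.linspace(0.5, 0.53, 10)
        pts = self._pts(times, np.ones(10))
        cands = project_to_events(self._all_abnormal(pts), pts)
        assert len(cands) == 1

    def test_bursts_300ms_apart_stay_separate(self):
        times = np.concatenate([np.linspace(0.5, 0.52, 5), np.linspace(0.8, 0.82, 5)])
        pts = self._pts(times, np.ones(10))
        cands = project_to_events(self._all_abnormal(pts), pts)
        assert len(cands) == 2

    def test_weighted_mean_onset_hand_computed(self):
        times = [1.00, 1.01, 1.02, 1.03]
        mags = [1.0, 2.0, 3.0, 4.0]
        pts = self._pts(times, mags)
        cands = project_to_events(self._all_abnormal(pts), pts)
        want = (1.00 * 1 + 1.01 * 2 + 1.02 * 3 + 1.03 * 4) / 10.0
        assert cands[0].time == pytest.approx(want)
        assert cands[0].magnitude == 4.0

    def test_long_diffuse_run_dropped(self):
        times = np.arange(0.3, 0.75, 0.01)
        pts = self._pts(times, np.ones(times.size))
        cands = project_to_events(self._all_abnormal(pts), pts, max_run_s=0.2)
        assert cands == []

    def test_empty_abnormal_set_yields_no_candidates(self):
        pts = self._pts([0.5], [1.0])
        assign = ClusterAssignment(np.array(["normal"]), np.zeros((3, 2)))
        assert project_to_events(assign, pts) == []


class TestClassifyEvents:
    def test_candidate_150ms_after_s2_is_s3(self):
        seg = _segmentation()
        events, rejected = classify_events(
            [_Candidate(seg.cycles[1].s2 + 0.150, 0.2, 1, seg.cycles[1].s2 + 0.150)],
            seg,
        )
        assert rejected == 0
        (ev,) = events
        assert ev.label == "S3"
        assert ev.latency_s == pytest.approx(0.150)

    def test_candidate_80ms_before_next_s1_is_s4(self):
        seg = _segmentation()
        t = seg.cycles[2].dia_end - 0.080
        events, _ = classify_events([_Candidate(t, 0.2, 2, t)], seg)
        (ev,) = events
        assert ev.label == "S4"
        assert ev.latency_s == pytest.approx(0.080)

    def test_mid_diastole_candidate_outside_windows_rejected(self):
        seg = _segmentation()
        t = seg.cycles[0].s2 + 0.320  # 320 ms after S2, 380 ms before S1
        events, rejected = classify_events([_Candidate(t, 0.2, 0, t)], seg)
        assert events == []
        assert rejected == 1

    def test_strongest_per_cycle_wins(self):
        seg = _segmentation()
        s2 = seg.cycles[0].s2
        cands = [
            _Candidate(s2 + 0.140, 0.1, 0, s2 + 0.140),
            _Candidate(s2 + 0.200, 0.3, 0, s2 + 0.200),
        ]
        events, _ = classify_events(cands, seg)
        assert len(events) == 1
        assert events[0].magnitude == 0.3


class TestEdgeCandidates:
    def test_run_peaking_at_guard_edge_dropped(self):
        seg = _segmentation()
        guard = 0.060
        edge_t = seg.cycles[0].dia_end - guard - 0.005
        interior_t = seg.cycles[0].s2 + 0.150
        cands = [
            _Candidate(edge_t - 0.02, 0.5, 0, edge_t),
            _Candidate(interior_t, 0.2, 0, interior_t),
        ]
        kept = drop_edge_candidates(cands, seg, guard, 0.015)
        assert [c.time for c in kept] == [interior_t]


def _events_pts(seg, label, latencies, mags):
    """Build matching events + ridge points for iterative-recognition tests."""
    from pcg34.detect import DetectionEvent

    events, times, cycles, mlist = [], [], [], []
    for cyc_i, (lat, mag) in enumerate(zip(latencies, mags)):
        cyc = seg.cycles[cyc_i]
        if lat is None:
            continue
        t = cyc.s2 + lat if label == "S3" else cyc.dia_end - lat
        events.append(DetectionEvent(label, t, cyc_i, lat, mag, "clustered"))
    # dense ridge points across every diastole at the noise floor, with a
    # bump at the event latency in every cycle (including missed ones)
    for cyc_i, cyc in enumerate(seg.cycles):
        grid = np.arange(cyc.dia_start + 0.06, cyc.dia_end - 0.06, 0.005)
        times.extend(grid)
        cycles.extend([cyc_i] * grid.size)
        lat = latencies[cyc_i] if latencies[cyc_i] is not None else np.median(
            [l for l in latencies if l is not None]
        )
        center = cyc.s2 + lat if label == "S3" else cyc.dia_end - lat
        mag = mags[cyc_i]
        mlist.extend(
            0.005 + mag * np.exp(-0.5 * ((grid - center) / 0.01) ** 2)
        )
    pts = FreqMagPoints(
        np.array(times), np.full(len(times), 30.0),
        np.array(mlist), np.array(cycles, int),
    )
    return events, pts


class TestIterativeRecognition:
    def test_subthreshold_fifth_cycle_recovered(self):
        seg = _segmentation(n_cycles=5)
        events, pts = _events_pts(
            seg, "S3", [0.160, 0.158, 0.162, 0.161, None], [0.2, 0.21, 0.19, 0.2, 0.15]
        )
        final = iterative_recognition(events, pts, seg)
        assert len(final) == 5
        rec = [e for e in final if e.cycle == 4]
        assert rec[0].provenance == "recovered"
        assert rec[0].latency_s == pytest.approx(0.158, abs=0.02)

    def test_sporadic_single_event_removed(self):
        seg = _segmentation(n_cycles=8)
        events, pts = _events_pts(
            seg, "S3",
            [0.150] + [None] * 7,
            [0.2] + [0.0] * 7,
        )
        # only one cycle carries an event: below presence_frac, so dropped
        final = iterative_recognition(events[:1], pts, seg)
        assert final == []

    def test_idempotent_on_consistent_detections(self):
        seg = _segmentation(n_cycles=5)
        events, pts = _events_pts(
            seg, "S4", [0.090, 0.092, 0.088, 0.091, 0.090], [0.2] * 5
        )
        once = iterative_recognition(events, pts, seg)
        twice = iterative_recognition(once, pts, seg)
        assert [(e.label, e.cycle, e.onset_s) for e in once] == [
            (e.label, e.cycle, e.onset_s) for e in twice
        ]
        assert len(once) == 5


class TestDetectRecord:
    def test_events_lie_inside_diastoles(self, s3_record):
        rec, _ = s3_record
        report = detect_record(rec, seed=11)
        from pcg34.preprocess import segment

        seg = segment(rec)
        for e in report.events:
            assert any(lo <= e.onset_s <= hi for lo, hi in seg.diastoles)

    def test_determinism_byte_identical_reports(self, s3_record):
        rec, _ = s3_record
        a = detect_record(rec, seed=42).to_json()
        b = detect_record(rec, seed=42).to_json()
        assert a == b

    def test_at_most_one_event_per_label_per_cycle(self, s4_record):
        rec, _ = s4_record
        report = detect_record(rec, seed=7)
        keys = [(e.cycle, e.label) for e in report.events]
        assert len(keys) == len(set(keys))
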