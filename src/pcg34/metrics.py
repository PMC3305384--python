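"""Per-cycle scoring of detected S3/S4 events against ground truth.

Counting follows the recognised / missed / falsely-recognised convention at
the cardiac-cycle level: a truth event matched by a detection of the same
label within the tolerance is a true positive; an unmatched truth event is a
false negative; an unmatched detection is a false positive.  Sensitivity is
TP/(TP+FN) and precision TP/(TP+FP); when a denominator is zero the metric is
reported as absent (``None``), not as zero.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

from .exceptions import InputError
from .io import AnnotationSet

DIASTOLIC_LABELS = ("S3", "S4")


def sensitivity(tp: int, fn: int) -> float | None:
    """TP / (TP + FN); ``None`` when no truth events exist."""
    return tp / (tp + fn) if (tp + fn) > 0 else None


def precision(tp: int, fp: int) -> float | None:
    """TP / (TP + FP); ``None`` when there are no detections."""
    return tp / (tp + fp) if (tp + fp) > 0 else None


@dataclass
class LabelCounts:
    tp: int = 0
    fn: int = 0
    fp: int = 0

    @property
    def sensitivity(self) -> float | None:
        return sensitivity(self.tp, self.fn)

    @property
    def precision(self) -> float | None:
        return precision(self.tp, self.fp)

    def __iadd__(self, other: "LabelCounts") -> "LabelCounts":
        self.tp += other.tp
        self.fn += other.fn
        self.fp += other.fp
        return self


@dataclass
class ScoreTable:
    """Cycle-level TP/FN/FP per diastolic label, with derived metrics."""

    counts: dict[str, LabelCounts] = field(
        default_factory=lambda: {lab: LabelCounts() for lab in DIASTOLIC_LABELS}
    )
    records: list[dict] = field(default_factory=list)

    def merge(self, other: "ScoreTable") -> "ScoreTable":
        for lab in DIASTOLIC_LABELS:
            self.counts[lab] += other.counts[lab]
        self.records.extend(other.records)
        return self

    def to_dict(self) -> dict:
        out: dict = {"labels": {}, "records": self.records}
        for lab, c in self.counts.items():
            out["labels"][lab] = {
                "tp": c.tp, "fn": c.fn, "fp": c.fp,
                "sensitivity": c.sensitivity, "precision": c.precision,
            }
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def format_table(self) -> str:
        """Plain-text per-record table: recognised / missed / false per label."""
        head = f"{'record':<16}" + "".join(
            f"{lab + ' ' + col:>12}"
            for lab in DIASTOLIC_LABELS
            for col in ("recog", "missed", "false")
        )
        lines = [head]
        for row in self.records:
            line = f"{row['record_id']:<16}"
            for lab in DIASTOLIC_LABELS:
                c = row[lab]
                line += f"{c['tp']:>12}{c['fn']:>12}{c['fp']:>12}"
            lines.append(line)
        totals = f"{'total':<16}"
        for lab in DIASTOLIC_LABELS:
            c = self.counts[lab]
            totals += f"{c.tp:>12}{c.fn:>12}{c.fp:>12}"
        lines.append(totals)
        for lab in DIASTOLIC_LABELS:
            c = self.counts[lab]
            sens = "n/a" if c.sensitivity is None else f"{100 * c.sensitivity:.1f}%"
            prec = "n/a" if c.precision is None else f"{100 * c.precision:.1f}%"
            lines.append(f"{lab}: sensitivity {sens}, precision {prec}")
        return "\n".join(lines)


def _match_label(truth_evs, det_evs, tol_s: float) -> LabelCounts:
    """Greedy nearest-first one-to-one matching within ``tol_s``."""
    pairs = sorted(
        (
            (abs(d.onset_s - t.onset_s), ti, di)
            for ti, t in enumerate(truth_evs)
            for di, d in enumerate(det_evs)
            if abs(d.onset_s - t.onset_s) <= tol_s
        ),
    )
    used_t: set[int] = set()
    used_d: set[int] = set()
    tp = 0
    for _, ti, di in pairs:
        if ti in used_t or di in used_d:
            continue
        used_t.add(ti)
        used_d.add(di)
        tp += 1
    return LabelCounts(tp=tp, fn=len(truth_evs) - tp, fp=len(det_evs) - tp)


def score_cycles(
    detected: AnnotationSet,
    truth: AnnotationSet,
    tol_ms: float = 50.0,
    strict_record_id: bool = True,
) -> ScoreTable:
    """Score one record's detections against its ground truth.

    Events are matched per label, one-to-one, nearest first, within
    ``tol_ms``.  A detection in a truth-bearing cycle but beyond tolerance
    counts both as a miss (the truth went undetected) and as a false
    recognition.  Only the diastolic labels S3/S4 are scored; S1/S2 rows in
    the annotation files are ignored here.
    """
    if (
        strict_record_id
        and detected.record_id
        and truth.record_id
        and detected.record_id != truth.record_id
    ):
        raise InputError(
            f"record ids differ: {detected.record_id!r} vs {truth.record_id!r}"
        )
    table = ScoreTable()
    row: dict = {"record_id": truth.record_id or detected.record_id}
    for lab in DIASTOLIC_LABELS:
        counts = _match_label(
            truth.with_label(lab), detected.with_label(lab), tol_ms / 1000.0
        )
        table.counts[lab] += counts
        row[lab] = {"tp": counts.tp, "fn": counts.fn, "fp": counts.fp}
    table.records.append(row)
    return table
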