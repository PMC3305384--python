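"""Pipeline configuration: every tunable, with defaults, YAML/JSON round-trip.

The groups mirror the pipeline stages.  All times are milliseconds unless the
key says otherwise; fractions are of the relevant maximum (e.g. the Shannon
energy threshold is a fraction of the record's maximal Shannon energy).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .exceptions import ParameterError


@dataclass
class LowpassConfig:
    """Zero-phase Butterworth low-pass; heart sound content sits below 600 Hz."""

    cutoff_hz: float = 600.0
    order: int = 6


@dataclass
class SEConfig:
    """Shannon-energy conditioning before peak picking."""

    smooth_ms: float = 20.0  # moving-average window; well under the 50 ms merge rule


@dataclass
class SegConfig:
    """S1/S2 peak picking and systole/diastole labelling."""

    threshold_frac: float = 0.70   # primary threshold, fraction of max Shannon energy
    secondary_frac: float = 0.50   # re-pick threshold inside uncertain intervals
    merge_ms: float = 50.0         # peaks closer than this: keep the higher energy
    tie_tol: float = 0.10          # relative interval difference treated as a tie
    max_ds_ratio: float = 2.5      # diastole/systole ratio above which the gap is suspect
    snap_ms: float = 25.0          # snap peak time to the envelope apex within this radius


@dataclass
class EmdConfig:
    """Empirical mode decomposition (sifting) controls."""

    sd_tol: float = 0.2        # Cauchy-type stopping criterion on successive sifts
    max_sifts: int = 100
    max_imfs: int = 12
    boundary_extrema: int = 2  # extrema mirrored at each end for spline envelopes


@dataclass
class DetectConfig:
    """Diastolic clustering, event windows and iterative recognition."""

    s3_window_ms: tuple[float, float] = (80.0, 250.0)   # latency after S2
    s4_window_ms: tuple[float, float] = (40.0, 200.0)   # lead before next S1
    gap_ms: float = 60.0           # abnormal-point runs closer than this merge
    max_run_ms: float = 200.0      # runs longer than this are diffuse noise, not events
    edge_ms: float = 15.0          # runs peaking this close to a guarded edge are S1/S2 tails
    min_rel_mag: float = 0.05      # candidate magnitude floor, relative to the S1/S2 ridge
    latency_tol_ms: float = 50.0   # periodicity tolerance around the median latency
    presence_frac: float = 0.5     # label deemed present if found in this many cycles
    recover_frac: float = 0.6      # recovery needs mag > frac * median detected mag
    decimate: int = 8              # ridge stride for the frequency-magnitude pool
    ridge: str = "max_amplitude"   # ridge reading: "max_amplitude" or "max_frequency"
    guard_ms: float = 60.0         # diastolic samples this close to S2/S1 are excluded


@dataclass
class KMeansConfig:
    restarts: int = 10
    max_iter: int = 300
    seed: int = 0  # default k-means seed; overridden by the per-run seed


@dataclass
class PipelineConfig:
    """Full configuration for :func:`pcg34.detect.detect_record`."""

    lowpass: LowpassConfig = field(default_factory=LowpassConfig)
    se: SEConfig = field(default_factory=SEConfig)
    seg: SegConfig = field(default_factory=SegConfig)
    emd: EmdConfig = field(default_factory=EmdConfig)
    detect: DetectConfig = field(default_factory=DetectConfig)
    kmeans: KMeansConfig = field(default_factory=KMeansConfig)

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["detect"]["s3_window_ms"] = list(d["detect"]["s3_window_ms"])
        d["detect"]["s4_window_ms"] = list(d["detect"]["s4_window_ms"])
        return d

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        cfg = cls()
        groups = {f.name: f for f in dataclasses.fields(cls)}
        for group, values in (data or {}).items():
            if group not in groups:
                raise ParameterError(f"unknown config group {group!r}")
            sub = getattr(cfg, group)
            names = {f.name for f in dataclasses.fields(sub)}
            for key, val in (values or {}).items():
                if key not in names:
                    raise ParameterError(f"unknown config key {group}.{key}")
                if key in ("s3_window_ms", "s4_window_ms"):
                    val = tuple(float(v) for v in val)
                setattr(sub, key, val)
        return cfg

    @classmethod
    def load(cls, path: str | Path) -> "PipelineConfig":
        """Load from YAML or JSON (decided by suffix; YAML parses JSON too)."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        return cls.from_dict(data or {})

    def save(self, path: str | Path) -> None:
        p = Path(path)
        if p.suffix == ".json":
            p.write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))
        else:
            p.write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
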