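"""End-to-end synthetic evaluation experiments.

Runs the full simulate -> detect -> score loop over many seeded records and
aggregates cycle-level counts; used by the ``batch-eval`` CLI command and by
the reproducibility script.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Iterable, Sequence

from .config import PipelineConfig
from .detect import detect_record
from .metrics import ScoreTable, score_cycles
from .synth import SynthConfig, generate_pcg


def planted_experiment(
    seeds: Sequence[int],
    s3: bool = False,
    s4: bool = False,
    snr_db: float = 20.0,
    config: PipelineConfig | None = None,
    tol_ms: float = 50.0,
    base: SynthConfig | None = None,
) -> ScoreTable:
    """Detect planted S3/S4 across seeded records; return pooled counts.

    Each seed yields one record with the generator defaults (10 cycles,
    75 bpm, 3% timing jitter, fs 8000 Hz) and the requested components
    planted in every cycle; the same seed drives generation and clustering.
    """
    cfg = config or PipelineConfig()
    total = ScoreTable()
    for seed in seeds:
        scfg = replace(
            base or SynthConfig(),
            seed=int(seed),
            s3_present=s3,
            s4_present=s4,
            snr_db=snr_db,
        )
        rec, truth = generate_pcg(scfg)
        report = detect_record(rec, cfg, int(seed))
        total.merge(score_cycles(report.to_annotations(), truth, tol_ms))
    return total
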