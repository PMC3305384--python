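# pcg34 — detection of the third and fourth heart sounds in phonocardiograms

The third and fourth heart sounds (S3, S4) are faint, low-frequency sounds in
the diastolic part of the cardiac cycle.  In adults an S3 (early diastole,
shortly after the second heart sound S2) points to systolic dysfunction and
heart failure; an S4 (late diastole, just before the next first heart sound
S1) arises when the atria contract against a stiff ventricle, as in ischemia
or hypertrophy.  Both are hard to hear and hard to detect algorithmically:
their amplitude is a fraction of S1/S2 and their frequency content (tens of
Hz) varies from beat to beat and patient to patient.

`pcg34` implements an adaptive time–frequency pipeline that detects S3 and S4
in single-channel phonocardiogram (PCG) recordings:

1. **Preprocessing** — zero-phase Butterworth low-pass (600 Hz), analytic
   envelope |x + jH{x}|, peak normalisation, Shannon energy
   SE[n] = −x²[n]·log x²[n] smoothed with a short moving average.
2. **Segmentation** — Shannon-energy peaks above 70% of the maximum mark
   S1/S2 (peaks closer than 50 ms merge to the stronger); an interval shorter
   than its predecessor is a systole, longer a diastole; ambiguous intervals
   are re-searched with a secondary threshold.
3. **Hilbert–Huang transform** — empirical mode decomposition
   x(t) = Σᵢ cᵢ(t) + r(t) into intrinsic mode functions by cubic-spline
   sifting, then per-IMF analytic signals zᵢ = aᵢ·e^{jθᵢ} giving
   instantaneous amplitude aᵢ(t) and frequency ωᵢ(t)/2π = θᵢ′(t)/2π.
4. **Clustering and recognition** — within each diastole the per-sample
   maximal-amplitude (frequency, magnitude) ridge is pooled over the record,
   standardized and split by k-means into three groups; the fewest-member
   group is abnormal.  Abnormal points projected to time become candidate
   events; candidates 80–250 ms after S2 are S3, 40–200 ms before the next
   S1 are S4.  An iterative pass enforces periodicity (median latency ± 50
   ms), removes sporadic labels and recovers sub-threshold events in missing
   cycles.
5. **Evaluation** — per-cycle scoring against ground truth:
   sensitivity = TP/(TP+FN), precision = TP/(TP+FP).

Because clinical recordings with confirmed S3/S4 are scarce and not
redistributable, the package ships a synthetic PCG generator
(Gaussian-windowed tone bursts for S1/S2/S3/S4, cycle-timing jitter,
configurable SNR) that produces records with exact ground truth, so the whole
pipeline can be exercised and scored end to end.

## Worked example

Simulate an abnormal record with an S3 in every cycle, detect, and score:

```sh
$ pcg34 simulate --out abnormal.wav --truth truth.csv --seed 42 --s3
wrote 8.5 s record to abnormal.wav

$ pcg34 detect abnormal.wav --annotations detected.csv --out report.json --seed 42
abnormal: 10 cycles, 10 S3 and 0 S4 events

$ pcg34 evaluate --detected detected.csv --truth truth.csv
record              S3 recog   S3 missed    S3 false    S4 recog   S4 missed    S4 false
abnormal                  10           0           0           0           0           0
total                     10           0           0           0           0           0
S3: sensitivity 100.0%, precision 100.0%
S4: sensitivity n/a, precision n/a
```

The detection report lists each event with its onset, its latency from S2
(for S3) or lead before the next S1 (for S4), and whether it came from the
clustering itself or from the periodicity-based recovery:

```
S3 0.707613 0.149 clustered
S3 1.511458 0.145 clustered
S3 2.289894 0.154 clustered
...
```

The planted S3 sits 150 ms after S2, and the detected latencies land within
a few milliseconds of it.  `pcg34 batch-eval` repeats simulate → detect →
score over many seeds and prints the pooled table.  Every tunable
(thresholds, windows, EMD controls, k-means restarts) can be overridden with
`--config cfg.yaml`; see `pcg34.config.PipelineConfig` for the keys and
defaults.

The same machinery is available as a library:

```python
from pcg34 import SynthConfig, generate_pcg, detect_record, score_cycles

rec, truth = generate_pcg(SynthConfig(seed=42, s3_present=True))
report = detect_record(rec, seed=42)
table = score_cycles(report.to_annotations(), truth, tol_ms=50)
print(table.format_table())
```

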