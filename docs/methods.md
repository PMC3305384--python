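# Methods

This note documents the models, numerical choices and limitations behind
`pcg34`.  It states no result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Signal model and preprocessing

A phonocardiogram is treated as a sequence of transient, narrowband bursts
(the heart sounds) over broadband noise.  Heart sound energy lies below
~600 Hz, so records are low-pass filtered with a Butterworth filter of order
6 at 600 Hz, applied forward–backward (`sosfiltfilt`).  Zero-phase filtering
matters: segmentation and all event latencies are read off peak times, and a
causal IIR filter would shift them by a frequency-dependent group delay.
The squared magnitude response of the bidirectional filter attenuates a
2 kHz tone by >120 dB, verified against the closed-form Butterworth
magnitude in the tests.

The envelope is the modulus of the analytic signal x + jH{x}.  After peak
normalisation the Shannon energy SE = −x²·log x² (with 0·log 0 := 0)
emphasises mid-amplitude content: it is zero at x = 0 *and* at |x| = 1 and
peaks at 1/e when |x| = e^{−1/2}.  Two consequences shape the
implementation:

- **Smoothing** (`se.smooth_ms`, 20 ms moving average): the per-sample SE of
  an envelope is jagged; 20 ms is far below the 50 ms peak-merge rule, so
  smoothing cannot fuse distinct sounds.
- **Peak-time snapping** (`seg.snap_ms`, 25 ms): because SE vanishes where
  the normalised envelope reaches 1, the SE of the loudest burst is
  double-humped and its argmax sits on the burst flank, roughly one burst
  sigma off the acoustic peak.  Peaks are therefore *selected* on smoothed
  SE but *timed* at the envelope apex within ±25 ms.  Without the snap, S1
  times on synthetic records are biased by ~20 ms — the full width of the
  segmentation accuracy budget.

## Segmentation

Local SE maxima above 70% of the record maximum are candidate S1/S2; among
peaks closer than 50 ms the lower-energy one is eliminated, repeating until
no pair violates.  The elimination removes the globally weakest violating
peak first, which makes the survivor set independent of detection order
(property-tested against a brute-force reference).

Interval labelling compares each inter-peak interval with its predecessor:
shorter → systole, longer → diastole.  Two ambiguity rules produce
"uncertain" intervals: a relative difference within 10% (`seg.tie_tol`), and
a diastole-labelled interval longer than 2.5× its adjacent systole
(`seg.max_ds_ratio`) — at rest the diastole/systole ratio is ~1.5–2, so a
longer gap most likely contains a missed sound.  Uncertain intervals are
re-searched at a secondary threshold (50% of max SE, `seg.secondary_frac`;
any value below the primary 70% and above the noise floor behaves
equivalently on clean records), and the proximity rule is re-applied to the
merged peak set.

## Hilbert–Huang transform

Empirical mode decomposition extracts intrinsic mode functions by sifting:
subtract the mean of the upper and lower cubic-spline extrema envelopes
until the candidate is locally symmetric.  Numerical choices:

- **Stopping criterion**: Cauchy-type SD = Σ(h_prev − h)²/Σh_prev² < 0.2,
  at most 100 sifts per IMF.  0.2 is the standard choice for this criterion
  and is not sensitive on our signals (pure tones converge in one sift).
- **Spline boundaries**: two extrema are mirrored past each record end
  before fitting; natural boundary conditions.  Mirroring suppresses the
  end swings of the spline envelopes that would otherwise leak into the
  first and last diastoles — exactly where S4 and S3 live.
- **Termination**: extraction stops when the residual has fewer than two
  extrema or its energy falls below 1e−10 of the input, with a cap of 12
  IMFs (`emd.max_imfs`; at fs 8000 the dyadic cascade reaches sub-hertz
  modes well before the cap).
- The IMFs-plus-residual reconstruction is exact by construction
  (each residual is formed by subtraction); the test suite verifies 1e−8
  relative error over 100 signal types, and observed errors are at machine
  precision.

Each IMF's analytic signal gives instantaneous amplitude and phase; the
instantaneous frequency is the central difference of the unwrapped phase
scaled to Hz, one-sided at the record ends, with negative estimates (a
boundary/low-amplitude artefact) clamped to zero and counted.  Pure tones
between 20 and 600 Hz are recovered to well under 1% and a 20→100 Hz linear
chirp with <2 Hz RMSE.

The detector consumes the **maximal-amplitude ridge**: at each sample, the
(frequency, amplitude) of the IMF with the largest instantaneous amplitude.
An alternative maximal-*frequency* reading is selectable
(`detect.ridge = "max_frequency"`) for comparison; high-order noise modes
dominate under that rule, so it is not the default.

## Diastolic clustering and recognition

Ridge samples inside each diastole (S2 → next S1), decimated to ~1 ms
spacing (`detect.decimate` = 8 at fs 8000), are pooled over the record.
Samples within 60 ms of the bounding S2/S1 peaks are excluded
(`detect.guard_ms`): the diastolic *interval* runs peak-to-peak, but the
bounding sounds' own tails extend ~half a burst beyond their peaks and would
otherwise dominate the pool and drag merged candidates out of the
physiologic windows.

Frequency and magnitude are standardized per dimension (they are
incommensurate units) and clustered with k-means, k = 3, 10 seeded
k-means++ restarts, 300-iteration cap.  The group with the fewest points is
**abnormal** (ties: higher mean standardized magnitude); of the rest, the
smaller-centroid-norm group — low amplitude and frequency — is **normal**,
the other **uncertain**.  Only abnormal points generate candidates.

Candidate formation and filtering:

- Runs of abnormal points separated by <60 ms (`detect.gap_ms`) merge into
  one candidate at the magnitude-weighted mean time.
- Runs spanning more than 200 ms (`detect.max_run_ms`) are discarded: a
  discrete heart sound is a transient burst, and a run smeared across most
  of a diastole is diffuse noise that would otherwise alias into a
  perfectly periodic mid-diastole "event".
- Runs whose magnitude peaks within 15 ms of a guarded edge
  (`detect.edge_ms`) are discarded: a genuine diastolic sound peaks in the
  interior, whereas a truncated S1/S2 tail is still rising or falling at
  the cut and mimics a periodic S4 or S3.
- Candidates below 5% of the record's own S1/S2 ridge magnitude
  (`detect.min_rel_mag`) are discarded.  A purely relative clustering
  always produces a "fewest" group, even on a record with no diastolic
  sounds; this floor is the absence gate.  Planted S3/S4 at 15–20% of S1
  clear it by a factor of 3–4.

Surviving candidates are labelled by timing: latency 80–250 ms after S2 →
S3 (early-diastolic rapid filling), lead 40–200 ms before the next S1 → S4
(atrial contraction); one event per label per cycle, strongest magnitude
wins.  The iterative pass then (i) discards events deviating >50 ms
(`detect.latency_tol_ms`) from the label's median latency, (ii) removes a
label entirely when it survives in fewer than half the cycles
(`detect.presence_frac`) — S3/S4 are periodic findings, not one-offs — and
(iii) for retained labels re-searches each missing cycle within median ±
tolerance, promoting the strongest ridge point if it exceeds 60%
(`detect.recover_frac`) of the label's median magnitude.  The pass repeats
to a fixed point; it only ever adds events to empty cycles or removes
flagged ones, so it terminates and is idempotent (tested).

## Synthetic data generator

Each heart sound is a Gaussian-windowed cosine burst (window spans the
stated duration at ±3σ, peak at the centre).  Defaults: S1 40 Hz / 120 ms /
amplitude 1.0; S2 60 Hz / 100 ms / 0.8, 300 ms after S1; S3 35 Hz / 80 ms /
0.2, 150 ms after S2; S4 30 Hz / 80 ms / 0.15, 90 ms before the next S1;
75 bpm with 3% Gaussian timing jitter (clipped at 3σ) on the period and
every within-cycle offset; white Gaussian noise scaled for an exact 20 dB
record-level SNR (a pink-noise option exists for robustness checks).  These
place S3/S4 in the reported clinical regime — below 100 Hz, well below
S1/S2 in amplitude, at early/late-diastolic timing — while remaining strong
enough to be non-trivial (the in-band noise floor after filtering is ~3–5%
of S1, i.e. 4–6× below S4).  A record closes with one extra S1 so the last
diastole is bounded.  Nominal timings whose ±2σ burst cores overlap are
rejected as infeasible; the ±3σ tails of the default S4 and S1 interleave
by 10 ms at <1.5% of peak amplitude, which is physically meaningless and
deliberately allowed.

What the generator does **not** emulate: murmurs and valve clicks, baseline
wander and friction/movement artefacts, respiratory modulation of intensity
and rate, per-beat morphology changes, sensor coloration, and S3/S4 whose
amplitude falls to the noise floor.  Passing the synthetic gates therefore
demonstrates the pipeline's correctness and its operating point under
controlled conditions, not clinical performance on bedside recordings.

## Scoring

Detections are scored per cardiac cycle and label with one-to-one,
nearest-first matching at 50 ms tolerance (the tolerance only resolves
matching inside a cycle; counting is cycle-level).  A detection in a
truth-bearing cycle but beyond tolerance counts as both a miss and a false
recognition; a detection of one label is never counted against the other
label.  Sensitivity and precision with zero denominators are reported as
absent rather than zero.

## Experiment scale

The reproducibility script and the end-to-end test gates run 10-cycle
records (≈8.5 s at fs 8000 Hz): 50 + 50 records in the script, 25 + 25 in
the test suite.  One record takes ~0.25 s end to end, so the full surrogate
study completes in well under a minute; the scale was chosen so the pooled
cycle counts (500 per label in the script) give sub-percent resolution on
the reported rates.

## Known limitations

- **Records containing both S3 and S4**: the fewest-member rule can select
  a noise cluster once the joint S3+S4 cluster outnumbers it, degrading
  sensitivity to roughly 70–85% on synthetic both-present records.  This is
  inherent to the three-group/fewest-rule design; a k = 4 variant or
  per-window clustering would be the natural extension.
- **Murmurs and structured noise** in diastole enter the pooled cloud and,
  if louder than S3/S4, will claim the abnormal cluster — the relative
  clustering only separates sounds no larger than the targets.
- Heart rates where the diastole shortens toward the systole length (high
  tachycardia) break the shorter-is-systole labelling rule.
- The EMD is the plain (non-ensemble) variant; mode mixing between closely
  spaced components is possible, though the ridge construction is largely
  insensitive to which IMF carries a burst.
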