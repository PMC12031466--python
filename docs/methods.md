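# Methods notes

This note documents the modelling choices, defaults and known limits of the
package; it states no result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Signal model and feature extraction

The sensor delivers a 5 Hz capacitance channel proportional to
abdomen–device distance (breathing effort) and a 3-axis accelerometer in g.
Four per-sample channels feed the classifier:

* **Smoothed, normalized capacitance.** Savitzky–Golay window 11 / order 3:
  at 5 Hz and ~15 breaths/min an 11-sample window spans roughly half a
  breath, and a cubic can carry one peak and one valley. Edge handling uses
  the standard polynomial fit of the terminal window (`scipy`'s `interp`
  mode) rather than a shrinking window; the cubic-reproduction property
  holds everywhere. Windowed z-normalization uses a centered 300-sample
  (60 s) window — long enough to span several breath cycles, short enough to
  track baseline drift — with population SD and an ε = 1e-8 guard so
  constant windows map to 0. The window length is a package default, not a
  device constant; it is exposed in `FeatureConfig`.
* **Local gap** — max − min of the *smoothed, pre-normalization*
  capacitance in a 5-sample (1 s) window. Computing it before normalization
  keeps its scale interpretable as effort amplitude and decoupled from the
  normalization window. Moving windows shrink at the recording edges; no
  data is fabricated by padding.
* **Acceleration length** ‖a‖ — Euclidean norm, ≈1 g when still.
* **Position code** — roll = atan2(a_z, a_y) wrapped to [0, 360°),
  pitch = atan2(√(a_y²+a_z²), −a_x); first-match-wins cascade
  upright → supine → prone → left → right. "Axis ≈ ±1" means
  |component|/‖a‖ ≥ 0.9 (within ~26° of the axis) — the device's own
  calibration constants are unpublished, so 0.9 is a stated default.
  The roll sectors are supine 247.5–292.5°, prone 67.5–112.5°, left
  112.5–247.5°, right the wrap-around remainder, each half-open on the
  right so no direction is claimed twice. Upright claims pitch > 109°; the
  roll cascade applies at pitch ≤ 109° (boundary included) so the cascade
  covers the entire sphere — verified against a brute-force region oracle
  on a dense sphere sample. The position channel enters the model as an
  integer code scaled to [0, 1] by /4 (one-hot would also be defensible;
  the scalar keeps the input table at 4 channels).

## Classifiers

Input: 100-s windows, i.e. 500 patches × 4 channels; one sigmoid output per
patch so per-sample thresholding is direct.

**MLP-Mixer.** Per-patch linear lift to a hidden width H, then N blocks of
token mixing (two dense layers with GELU and dropout applied along the
patch axis, weights shared across hidden channels — equivalent to a
kernel-size-1 pointwise convolution) and channel mixing (same shape along
the hidden axis, shared across patches), each wrapped in a skip connection;
no layer normalization (none is part of the described architecture). GELU
is used inside the mixing blocks and sigmoid only at the head; the mixing
MLPs' hidden width equals H. Defaults H = 128, N = 3 blocks (mirroring the
three BiLSTM layers of the baseline), dropout 0.1.

**BiLSTM baseline.** Three stacked bidirectional LSTM layers (standard
gates, forget bias 1) over the patch axis, concatenated directions, linear
per-step head + sigmoid.

Both are implemented in NumPy with hand-written reverse-mode gradients and
Adam; gradient-check tests compare every parameter block against central
finite differences. Training samples windows uniformly at random from the
training recordings each iteration (the inference stride is one window,
with a final end-anchored window and last-write-wins stitching). Cross-
validation folds are assigned by recording (subject-wise) to prevent
within-night leakage. Plain BCE is used without class re-weighting.

Scale: the published protocol (hidden 128, batch 500 windows, 50,000
iterations) is preserved as configuration defaults / the `FULL_SCALE_ITERATIONS`
preset, but desk-scale runs in the tests and the acceptance script use
hidden 8–32, batch 4–8 and 40–700 iterations so the whole suite fits in CPU
minutes. On the synthetic task this is ample: out-of-fold AUC exceeds 0.99.

## Postprocessing

Samples with p ≥ θp become apnea; maximal runs become intervals; intervals
are clipped to the estimated sleep interval and those shorter than τ = 50
samples (10 s at 5 Hz) are discarded. θp comes from the Youden index
(argmax TPR − FPR, ties to the higher threshold) on *pooled* out-of-fold
validation scores — pooling yields a single deployable θp. The Youden
argmax excludes the ROC's sentinel point (no sample called positive), so
the returned θp is always an observed score.

Sleep time: 30-s epochs; an epoch is movement-free iff every ‖a‖ sample is
inside [0.9, 1.1] g (defaults chosen so gravity-plus-sensor-noise is quiet
and simulated movement is not; configurable). Sleep onset = start of first
quiet run ≥ 10 min; the morning wake period applies the identical rule to
the time-reversed epoch series. Upright time is counted only inside the
sleep interval (it is not double-counted with latency). ST = duration −
latency − morning wake − upright; AHI = 60·events/ST rounded to one
decimal, severity bands normal < 5 ≤ mild < 15 ≤ moderate < 30 ≤ severe
(cutoffs closed on the left).

## Synthetic nights

The generator states a world rather than fitting one: breathing is a
sinusoid whose instantaneous rate performs a bounded random walk around
15 breaths/min clipped to 0–30; amplitude 1 capacitance unit with slow
(15-/30-/60-min) amplitude and baseline modulation and Gaussian sensor
noise SD 0.1 (per-breath SNR ≈ 10). Events arrive as a homogeneous Poisson
process at the target AHI per sleep-hour, durations uniform in 10–60 s,
non-overlapping with a 2-s guard; apneas multiply the oscillation amplitude
by 0.05, hypopneas (30 % of events) by 0.5. The accelerometer reads the
scheduled position's gravity vector plus 0.02 g noise; wake segments at the
start/end of the night carry sustained 0.3 g movement ("restless
wakefulness"), and 2–10 s movement bursts occur during sleep at 2/h.
Bursts are kept out of the first and last 10 min of the sleep interval
(post-onset consolidation) so that ground-truth latency and morning wake
remain well defined under the 10-min quiet-run rule.

What a green end-to-end test establishes: the pipeline recovers a known
AHI, latency and wake from signals with the *stated* contrast and noise.
What it does not establish: performance on real physiology — no
paradoxical thoraco-abdominal motion, no waveform variability beyond a
sinusoid, no scorer disagreement about hypopnea desaturation criteria, no
sensor detachment or drift artifacts. The paired-device generator perturbs
truth events (onset/duration jitter, drops, insertions) to exercise the
agreement layer, not to model any particular reference device.

## Numerical and API choices

* Event intervals are half-open `[start, end)` seconds; labels use
  `start ≤ t < end`, so adjacent events never double-count a sample.
* Recordings are validated strictly: timestamps must be strictly
  increasing with jitter ≤ 0.1 of a sample period; larger gaps are
  rejected, never imputed. CSV round-trips are bit-exact (17-significant-
  digit writes, round-trip float parsing).
* `events_from_labels` places boundaries at `i / rate` (division, not
  multiplication by the period) so grid round-trips are exact.
* Bland–Altman uses the sample SD (n − 1), the standard for agreement
  analysis; AUC is kept on [0, 1] internally and ×100 only for display.
* Interfaces follow the Model/Results pattern: `ApneaScreeningModel.fit()`
  returns an `ApneaScreeningResults` with `summary()`, out-of-fold cohort
  scoring, prediction for unseen nights (fold-ensemble averaged
  probabilities) and agreement reports.

## Known limitations

* The per-sample detector is binary; obstructive/central/mixed subtypes
  are carried as metadata only and never discriminated.
* Sleep staging beyond wake/sleep/upright is out of scope; ST can be
  overestimated during motionless wakefulness.
* A low Youden θp can merge closely spaced events into one detection
  (undercounting at very high AHI); the τ filter removes only short
  detections and cannot split merged ones.
* EDF/vendor formats, clock-drift estimation and multi-night sessions are
  not supported; inputs are single-night aligned CSVs.
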