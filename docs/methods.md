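# Methods

This note documents the models, numerical choices and open design decisions
behind the package, in the spirit of a methods appendix. Quantities shown in
the README's worked example are produced by the analysis drivers and the test
suite; nothing here asserts a number the code does not compute.

## Signal derivation

**Axis frame.** X = surge (anterior–posterior), Y = heave (dorso-ventral,
carrying gravity when the fish is upright and level), Z = sway (lateral).
This is the assignment under which the standard inclination and roll formulas
are self-consistent; published prose on logger axis-to-anatomy mappings is
often garbled, and where formula and prose disagree we follow the formulas.

**Static/dynamic split.** Static acceleration is a centred box moving average
of each raw axis; dynamic is the exact residual, so raw = static + dynamic
per sample by construction. The window defaults to 3.0 s (151 samples at
50 Hz; forced odd to stay centred): it must exceed the slowest tail-beat
period (~0.9 s) so stroking stays out of the posture estimate, while
remaining short enough to track orientation changes of a few seconds. Edges
use shrinking windows rather than padding. The window is configurable
(`PipelineConfig.static_window_s`). The often-quoted "filtered means" used by
proprietary ethographic software are not documented precisely enough to
reproduce, so the package commits to this transparent filter instead.

**Pitch formula.** The inclination denominator is √(Ys² + Zs²). A published
variant prints the dimensionally inconsistent "√(Z·Z) + Y·Y"; the standard
form is used. Pitch is computed with atan2 so the ±90° poles are exact.
Orientation is computed from the *static* triplet; an all-zero static vector
(no defined orientation) propagates as NaN and is excluded from window
statistics.

**Absolute roll.** |atan2(Zs, Ys)| ∈ [0°, 180°]. Removing the sign prevents
opposite-handed rolls from cancelling in window means (a −90° and +90° roll
should both read 90°, not average to 0°).

**Tail-beat CWT.** Complex Morlet mother wavelet with angular centre
frequency ω₀ = 6 (pywt `cmor2.0-0.9549`), 50 log-spaced periods over
0.2–2.0 s, bracketing all plausible tail-beat cycles for a ~1 m fish
(reported class means span 0.42–0.9 s). Per-sample cycle is the
maximum-modulus period; amplitude is that modulus divided by a per-scale gain
calibrated numerically against unit sinusoids, so amplitude reads directly in
g (validated to ±10 % against pure tones, with period recovery better than
5 %, in the test suite; the limiting factor on period accuracy is the 4.8 %
grid spacing). Long series are transformed in 120-s chunks with 4-s
discarded margins; the chunked and monolithic transforms agree exactly away
from the series ends.

## Feature windows

Non-overlapping 1-s windows, left-aligned to the first timestamp (no
wall-clock alignment is assumed); the trailing partial window is dropped.
Six statistics per signal — mean, sample SD, population moment skewness,
excess kurtosis, min, max — over 11 signals give the full 66-column
predictor set. Constant windows (min = max) are defined to have
SD = skewness = kurtosis = 0, so training never sees undefined values.
NaN orientation samples are excluded per window.

Published analyses of this design quote predictor counts of 58 and 64
without listing the dropped columns. The package defaults to the complete
66; `predictor_columns("published64")` drops the shape statistics of absolute
roll (whose sign-folding distorts third/fourth moments) and
`"published58"` additionally drops the shape statistics of pitch, cycle and
amplitude. These subsets are reconstructions, documented as such.

A window takes a ground-truth label only when it lies entirely inside one
labelled interval; boundary-straddling windows stay unlabelled and are
excluded from training (they would mix behaviours). Burst-candidate
screening (|sway| > 1 g, or roll rate > 45°/s, intervals merged across <1-s
gaps) exists as a ground-truthing aid and feeds nothing downstream.

## Classifier

scikit-learn random forest, ntree = 1000, mtry = ⌊√p⌋, majority vote; the
70/30 split is uniform over pooled windows from all individuals (whether to
stratify by fish is an open question in the source protocol; pooling was
chosen). Vote ties break deterministically by the canonical class order
(swim, feed, escape, courtship, chafe) — prevalence order, so ties favour
the commoner behaviour. OOB error is recorded on every fit. The
tested-and-rejected stratified-sampling variant is exposed as
`stratify=True` (balanced-subsample class weighting) but off by default and
not quantitatively reproduced.

Variable importance is mean decrease in accuracy via seeded permutation
importance on a capped training subsample (1000 rows × 2 repeats). R's
randomForest permutes out-of-bag rows per tree; sklearn exposes no
OOB-permutation path, so this is the package's documented analogue. On
perfectly separable synthetic data all permutation drops can be zero (no
single predictor is load-bearing); driver 03 falls back to the Gini ranking
for narration in that case.

Evaluation computes P/R/F1 from the confusion-matrix counts directly (the
formulas above are the contract); the test suite cross-checks them against
scikit-learn's independent implementation. Report tables round half-up to
2 dp; machine outputs keep full precision.

## Prediction post-processing

- **Settling exclusion**: drop the first 60 min after release (capture-induced
  behaviour), configurable.
- **Smoothing**: one left-to-right pass; an interior second differing from
  both its (already-updated) predecessor and successor is reassigned to the
  predecessor. The update order makes alternating runs collapse
  deterministically (e.g. [A,B,C,A] → [A,A,A,A]); the pass is idempotent,
  never invents labels, and leaves no interior 1-s run. Note the cascade can
  rewrite up to n−2 interior positions on pathological alternating input.
- **Spawning events** are maximal courtship runs; event depth is the mean of
  member seconds, and the event's diel bin is the bin at its start (events
  straddling a boundary are attributed to where they began).
- **Reproductive behaviours**: single-linkage chaining with a 30-min gap —
  the lower end of the tens-of-minutes spans described for captive kingfish
  courtship; configurable (`--gap`).
- **Depth**: last observation carried forward from the sparse 5-s channel;
  seconds before the first sample stay missing.
- **Diel bins**: dawn = [sunrise−1h, sunrise+1h), dusk likewise around
  sunset, day between, night otherwise; half-open so every second falls in
  exactly one bin. Percentages round half-up to integers. Sunrise/sunset
  come from per-deployment metadata (a lookup service); the package does not
  compute them from coordinates.

## Synthetic-data generator

The generator emulates the study conditions: a 50 Hz, ±2 g logger (output is
clipped at the range bound, as the hardware would) on a fish whose behaviour
schedule embeds discrete bouts in a swim background, with a 5-s depth
channel.

Each behaviour template holds a tail-beat period and sway amplitude, a mean
1-s VeDBA target, baseline pitch, and a roll/pitch burst signature, with
bout-duration ranges (feed 3–5 min; courtship 1–2 min; escape 5-min trials;
chafe 1–3 s) and the published per-class values: swim 0.9 s / 0.02 g /
0.04 g VeDBA; feed 0.42 s / 0.21 g / 0.43 g, pitch +5°; courtship 0.43 s /
0.19 g / 0.48 g with roll/pitch bursts; escape 0.15 g VeDBA, pitch 2°, rolls
to 34.4°; chafe 0.54 s / 0.14 g / 0.31 g, pitch −6°, a 90° roll-over.
The default class mix reproduces the labelled-seconds proportions of the
captive ground-truth record (feed 11.5 %, courtship 6.6 %, escape 3.4 %,
chafe 1.0 %). A reported swim VeDBA dispersion of ±0.44 g (11× the mean) is
treated as a typo; sensor jitter defaults to 0.01 g SD per axis, a realistic
noise floor for this logger class, since no noise model is published.

A segment is built as gravity rotated by the pitch/roll profile (half-cosine
burst ramps — a fish rolls smoothly, not in steps), plus the sway sinusoid,
band-limited surge/heave "activity" noise (white Gaussian smoothed over
0.15 s, unit RMS), and per-axis jitter. Escape is realised as elevated-tempo
swimming (0.6-s period) with intermittent rolls. Burst ramps default to 4 s:
fast ramps would leak postural gravity swings into the analysed 0.2–2 s
band and corrupt the tail-beat cycle readout, which the published per-class
cycle means show does not happen in real data.

**VeDBA calibration** is closed-loop because the targets are measured
quantities, not waveform parameters: the activity-noise scale is solved by
root finding (Brent) so that the segment's mean VeDBA, *measured through the
same static/dynamic decomposition the pipeline uses*, hits the template
target. The sway amplitude is never rescaled, so the CWT amplitude stays
faithful to the template. For short large-roll segments (chafe) the
orientation swing alone can exceed the target; the calibrator then shrinks
the burst magnitude instead. Chafe is consequently burst-dominated rather
than periodic, and its cycle readout is not calibrated — matching its
real-world character as a roll manoeuvre, not a locomotion mode.

Scheduling draws bout durations uniformly from each template's range until
the per-class seconds meet the requested fractions (the final bout is
clamped toward the target, so realised fractions land within the duration
granularity of the request), shuffles bouts, and separates them with
swim gaps of ≥ 5 s drawn from a Dirichlet split of the remaining time.
Segment boundaries land on the sample grid so labels partition the track
exactly. All randomness flows from one `SeedSequence`; identical seeds give
byte-identical output.

**What the generator does not emulate** — and hence what passing tests do
not show about real deployments: school interactions and tag artefacts;
within-class kinematic variability between individuals and with body size;
temporally correlated transitions (bouts are placed independently);
behaviour intergrades and mislabelled ground truth. Because classes are
generated from well-separated templates, classifier accuracy on synthetic
data is near-perfect; this validates the pipeline's plumbing and contracts,
not the expected field performance of the ethogram.

## Problem sizes and determinism

The default study is a 2-h deployment (360 000 samples, 7 200 windows,
~7 100 labelled), which the full pipeline processes in well under a minute;
calibration checks use ≥ 500 s per class and the acceptance script uses
600-s single-class traces. These sizes give stable means (Monte-Carlo error
well inside the stated 5–10 % calibration tolerances) while keeping every
run quick. Seeds are fixed throughout (generator/split/forest defaults
11/5/7); every stochastic step is reproducible from its seed, and the test
suite asserts this.
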