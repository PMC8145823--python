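# accelethogram

Behaviour classification ("ethogram") of tri-axial accelerometer biologging
data from large pelagic fish, built around the captive-to-wild workflow used
for yellowtail kingfish (*Seriola lalandi*): derive movement signals from a
50 Hz surge/heave/sway logger, summarise them into 1-s statistical feature
windows, train a random-forest classifier on ground-truthed behaviours
(swim, feed, escape, courtship, chafe), and post-process predictions on
unseen tracks into spawning events, reproductive-behaviour clusters and
diel-period summaries.

It is written for movement ecologists who want a tested, seeded, end-to-end
reference implementation of this pipeline. Because raw deployment data of
this kind is rarely public, the package ships a first-class synthetic-data
generator calibrated to published per-class kinematics, so every stage is
reproducible and testable from a seed alone.

## The model

Raw acceleration **a**(t) ∈ ℝ³ (g) splits into posture and movement
components with a centred 3-s moving average:

    static = MA₃ₛ(a),   dynamic = a − static          (exact: a = static + dynamic)

Per-sample derived signals:

- **VeDBA** = √(dx² + dy² + dz²) over the dynamic triplet — activity proxy;
- **pitch** = atan(Xs / √(Ys² + Zs²)) · 180/π — body inclination (+ ascending);
- **roll**  = |atan2(Zs, Ys)| · 180/π ∈ [0°, 180°] — direction removed;
- **cycle, amplitude** — period and amplitude of the dominant sway
  oscillation (tail beat), from a continuous Morlet wavelet transform
  (ω₀ = 6) over 50 log-spaced periods in 0.2–2.0 s, gain-normalised so a pure
  sinusoid of amplitude A reads A.

Each 1-s window yields mean, SD, skewness, kurtosis, min and max of all 11
signals (66 predictors). A random forest (ntree = 1000, mtry = ⌊√p⌋,
70/30 pooled split) classifies windows; per-class performance is

    P = TP/(TP+FP),  R = TP/(TP+FN),  F1 = 2PR/(P+R).

On unseen tracks, the first 60 min after release is excluded, isolated 1-s
predictions are smoothed to their predecessor, maximal courtship runs become
*spawning events*, events separated by ≤ 30 min cluster into *reproductive
behaviours*, depth (5-s channel) is carried forward onto each second, and
events are binned into dawn/day/dusk/night (±1 h around sunrise/sunset).

## Worked example

The numbered drivers under `analysis/` run the whole study; `python
analysis/01_simulate_dataset.py` through `04_predict_free_ranging.py`.
Driver 02 prints the per-class kinematic signatures of the calibrated
generator, measured back through the signal pipeline:

```
behaviour  n_windows  vedba_g  cycle_s  amplitude_g  pitch_deg  roll_abs_deg
     swim       5420    0.041    0.952        0.024     -0.012         0.120
     feed        881    0.430    0.424        0.216      5.330         1.006
courtship        472    0.480    0.445        0.191      3.155        14.413
   escape        299    0.150    0.618        0.071      2.046         8.416
    chafe         35    0.350    1.791        0.166     -4.327        17.334
```

Swim is slow and quiet (0.04 g VeDBA, 0.9-s tail beat), feed and courtship
are the high-intensity classes (0.43/0.48 g) with fast strokes, escape sits
between, and chafe is a brief roll-over. Driver 03 then trains and evaluates
the forest:

```
7107 labelled windows -> 4975 train / 2132 test.
Forest: ntree=1000, mtry=8, OOB error 0.0000.
Overall held-out accuracy: 1.0000
```

(The synthetic classes are deliberately well separated, so the forest is
near-perfect; the value of the suite is the contracts it verifies, not the
difficulty of the classification.) Driver 04 applies the model to a fresh
4-h track: it reports 7 spawning events (643 courtship seconds) grouped
into 2 reproductive behaviours, concentrated at dawn.

The same chain is available as a CLI:

```sh
accelethogram simulate --duration 3600 --seed 11 --out-prefix run
accelethogram process run.accel.csv --out run.proc.csv
accelethogram featurize run.proc.csv --accel-csv run.accel.csv \
    --mask run.mask.csv --out run.features.csv
accelethogram train run.features.csv --out model.joblib --split-out test.csv
accelethogram evaluate model.joblib test.csv --out report.json
accelethogram predict model.joblib run.features.csv --accel-csv run.accel.csv \
    --start-clock 05:00 --out track.csv
accelethogram events track.csv --out-prefix run
accelethogram report report.json --diel-csv run.diel.csv
```

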