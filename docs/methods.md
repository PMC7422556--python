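# Methods

This note documents the models, parameters and design choices behind
`shoehar`, and what the synthetic study can and cannot show about real
shoe-sensor data.

## The analysis

The package implements a standard two-arm activity-classification study for
a heel-mounted triaxial accelerometer (100 Hz, ±16 g, values in g):

**Calibration.** Subjects perform eight scripted activities (sitting,
standing, slow walking, brisk walking, stair ascending, stair descending,
weight carrying, kneeling) for 1–4 min each. Only the 6th–55th second of
each activity's final minute is analysed — a 49 s steady-state segment,
implemented as the half-open interval `[end−54, end−5)`. Intervals shorter
than 60 s violate the protocol and raise. The two walking speeds are
collapsed to a single *walking* class, giving a 7-class problem.

**Windowing.** Signals are segmented into 2 s windows with 50 % overlap
(length L = 200 samples, stride S = 100); the trailing partial window is
discarded, so a signal of N samples yields `floor((N−L)/S)+1` windows — 48
per 49 s calibration segment.

**Features.** 26 per window (the exact list and definitions are in
`shoehar.features`): per-axis means and sample SDs, the three inter-axis
Pearson correlations, vector-magnitude mean/SD/range/IQR/skewness/excess
kurtosis, signal magnitude area, mean tilt of the acceleration vector from
the sensor z-axis (degrees), magnitude mean-crossing rate, per-axis and
magnitude dominant frequency with per-axis dominant power (L-point
rectangular-window periodogram `|rfft|²/L`, DC bin excluded), and the
normalized spectral entropy of the magnitude.

Degenerate-input conventions, chosen so every feature stays finite on the
stationary windows that dominate real data: a zero-variance axis pair has
correlation 0; a constant magnitude has skewness/kurtosis 0; a zero
acceleration vector has tilt 0; a spectrum whose non-DC peak is below
1e−12 of total power is treated as flat (dominant frequency, power and
entropy all 0). The same floor is applied identically in the independent
test oracle so the two routes agree bitwise-closely on random input.

**Outlier removal.** Within each activity separately, a window is removed
when *any* of its 26 features deviates from that feature's median by more
than 3 scaled MADs, where scaled MAD = 1.4826 × median(|x − median|) (the
normal-consistency scaling). A column whose scaled MAD is zero flags every
value that differs from the median — the natural limit of the rule, and the
behaviour needed for near-constant stationary features. Cleaning is one
pass over the pooled calibration set, applied once before cross-validation
(re-running it per fold is a defensible alternative; a single global pass
matches the pipeline ordering the analysis describes and keeps folds
comparable).

**Classifiers.** Three families with fixed, conventional hyperparameters
(no tuning):

| family | model | key parameters |
|---|---|---|
| `rf` | random forest | 100 bagged trees, seeded |
| `svm` | SVC | polynomial kernel degree 3, C = 1, one-vs-one, standardized features |
| `knn` | k-NN | k = 10, weights ∝ 1/d² (Euclidean), standardized features; exact-match neighbours take all weight |

Standardization (where used) is part of the fitted pipeline and is refit
inside every cross-validation fold, so no test-subject statistics leak into
training. All stochastic components derive from `ClassifierSpec.seed`; fold
f uses `seed + f`.

**Validation.** Leave-one-subject-out: for each subject, train on all other
subjects' windows and predict the held-out subject's. The per-fold training
subject sets are recorded on the result object so the no-leakage invariant
is auditable, and a label-permutation test in the suite checks that
shuffled labels drive pooled accuracy to chance.

**Scoring.** Confusion matrices are (observed row, predicted column)
counts. Lab results are row-normalized (each activity's row shows where its
windows went); free-living results are normalized to the total window count
(cells show the joint distribution, appropriate when class prevalence is
extremely uneven). Margins: *sensitivity* = row recall; the *specificity
margin* = column precision — the proportion of windows classified as a
class whose observation agrees. This is the confusion-chart convention of
the field, not the epidemiological true-negative rate; the accessor name
`specificity_margin` keeps the chart vocabulary while flagging the
difference. Margins of never-observed or never-predicted classes are
undefined (NaN internally, blank in CSV output, never 0).

**Merging.** The 7→5 map sends sitting and standing to *stationary* and the
two stair classes to *stair walking*. Merging is additive on the confusion
matrix and can only move off-diagonal mass onto the diagonal, so 5-class
accuracy is ≥ 7-class accuracy for any fixed prediction set — asserted as a
property test.

**Free-living windows vs observer logs.** Observer intervals are half-open
`[start, end)`. Each sample takes its covering interval's label
(`unannotated` outside all intervals); each window takes the majority
per-sample label, ties broken toward the earlier interval, and windows with
majority `unannotated` or purity < 0.5 are dropped from scoring. This
alignment rule is a package choice — observation studies rarely state
theirs — and is configurable via `min_purity`.

## The synthetic study

Real recordings of this kind are not publicly deposited, so the generator
stands in for them. It is phenomenological: each activity is gravity
(oriented by a static shoe pitch) + a small harmonic series at the
subject's cadence split between the vertical and fore-aft axes + Gaussian
heel-strike impact pulses (30 ms wide) + white noise. Defaults (per
activity: cadence Hz / gait amplitude g / impact g / tilt° / noise g):

* sitting, standing: 0 / – / – / 0° / 0.01 — **identical by design**; a
  flat motionless foot cannot distinguish them, which reproduces the
  sitting↔standing confusability honestly instead of tuning it in;
* kneeling: static, tilt 65°, noise 0.015;
* walking slow 1.5 / 0.35 / 0.5, brisk 2.0 / 0.55 / 0.9 (flat, noise 0.05);
* stair ascending 1.1 / 0.45 / 0.4, tilt +10°, 85 % vertical energy;
  stair descending 1.3 / 0.40 / 0.8, tilt −10°, 45 % vertical;
* weight carrying 1.2 / 0.50 / 1.1 (slowed, heavier impacts), noise 0.06.

Between-subject variation is a multiplicative lognormal effect on cadence
(σ = 0.05) and amplitude (σ = 0.15). Lab sessions run the eight activities
in protocol order with durations uniform on 60–240 s. Free-living sessions
are 48 min semi-Markov bout sequences: bout activity drawn with probability
∝ weight/mean-bout-length (so expected *time shares* equal the weights),
bout durations exponential with per-activity means (sitting 120 s, standing
90, walking 12, stairs 15, carrying 20, kneeling 30 — chosen as plausible
workplace bout scales), and walking bouts floored at 3 s (walking is
continuous locomotion; a few sidesteps remain standing). Default weights:
sitting 0.345, standing 0.345, walking 0.30, and 0.0025 for each of the
four rare classes — stationary+walking mass 0.99. Everything is
deterministic given (config, seed, subject index, arm).

**What passing tests show — and don't.** The synthetic activities are
cleanly separable by construction (except sitting/standing), so absolute
accuracies here are far higher than any real study would report and say
nothing about real-world performance. What the study *does* exercise is the
full pipeline's structural behaviour: the windowing arithmetic, feature
definitions, the robust filter, LOSO integrity, both normalization
conventions, merge monotonicity, and the qualitative pattern that merging
the stationary pair recovers most of the lost accuracy while rare-class
free-living precision is unstable. The generator models no observer error,
no sensor drift or gaps, no within-activity heterogeneity beyond the
harmonic model, and no temporal activity grammar.

## Problem sizes and runtime

The default study is 35 lab subjects (≈ 13.4k labelled windows after
cleaning) and 29 free-living subjects (≈ 83k scored windows). The
acceptance script runs the random-forest family — the headline model of
this design — end to end in about two minutes on one CPU; SVM and KNN are
equally supported in the library and CLI and covered by the unit suite on
smaller studies.

## Known limitations

* The 26-feature set is a documented, reproducible default for this sensor
  configuration; published studies of this design do not always enumerate
  theirs, so exact feature parity with any one study is not claimed.
* Single-recording analysis (right shoe); no left/right fusion, no vendor
  binary format, no resampling or gap imputation.
* One-pass outlier cleaning applied globally rather than per fold.
* No temporal smoothing of window predictions and no sequence models —
  windows are classified independently.
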