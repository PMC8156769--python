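# Methods

`runfatigue` implements an analysis pipeline for detecting
running-induced fatigue from body-worn inertial measurement units
(IMUs).  The underlying experimental design is a track session in which
a runner completes a 4000 m constant-speed run (10 laps of 400 m), a
variable-length fatiguing bout of progressively increasing speed, and a
final constant-speed 1200 m run (3 laps), with eight IMUs (sternum,
pelvis, both thighs, tibias, feet; codes L1–L8) sampled at 240 Hz, plus
model-derived sagittal joint angles for hips, knees and ankles and the
pelvis forward velocity.  Three fatigue conditions are defined per lap:
laps 2–4 of run 1 (*no fatigue*), laps 8–10 of run 1 (*mild fatigue*),
and laps 1–3 of run 3, run directly after the fatiguing bout (*heavy
fatigue*).  The question the pipeline answers is how accurately a
classifier trained on stride-level biomechanical and statistical
features can separate the three conditions for a subject it has never
seen, and how that accuracy depends on which subset of the eight sensor
locations is worn.

## Synthetic sessions

Since raw recordings are not bundled, a synthetic-data generator
produces cohorts with the same protocol structure and the statistical
structure the analysis relies on.  Every stride is an instance of
closed-form waveform templates — sums of periodic Gaussian bumps and
sinusoids over the stride phase — whose parameters are drawn per stride:

* segment accelerations carry an impact spike shortly after the ipsilateral
  initial contact (peak tibial magnitude ≈ 60 m/s², pelvis ≈ 30 m/s² at
  baseline) on top of gravity, plus a smaller active peak;
* pitch angular velocities are stride-periodic with segment-specific
  amplitudes (tibia ≈ 450 °/s baseline);
* the knee angle has a stance and a swing flexion bump and sharp
  extension notches at both initial contacts, so contacts are
  recoverable from the right knee angle alone;
* hip and ankle angles are smooth flexion/extension curves with
  realistic ranges (hip flexion at contact ≈ 30°, ankle dorsiflexion ≈
  18°);
* the pelvis forward velocity oscillates about the nominal running
  speed with a pronounced downward peak at every right initial contact
  and a minor one at the left step.

Fatigue enters as parameter shifts whose directions follow the
biomechanics literature: tibial and sacral impact peaks increase
(+8 / +3 m/s² at full intensity by default), tibial pitch
angular-velocity amplitude increases (+15 %), hip flexion at initial
contact decreases (−4°), knee swing flexion shifts (+5°), and
stride-time variability inflates (+50 % of the CV).  A per-lap intensity
(0 for laps 1–4, a linear ramp across laps 5–7, 0.5 for laps 8–10, 1.0
throughout run 3) is interpolated smoothly within the run, scaled by a
global `effect_size` and by per-subject, per-family multipliers drawn
around 1 (fatigue responses are strongly subject-dependent in real
cohorts; multipliers can flip sign).  `effect_size = 0` makes the three
conditions statistically identical by construction.  Subject profiles
(speed, cadence, amplitudes) are drawn around the characteristics of an
eight-runner reference cohort (mean speed 10.6 km/h, SD 1.4 km/h).  The
fatiguing bout itself is never analysed and is rendered as a standing
gap between the runs.

What the generator does *not* emulate: soft-tissue and skin-motion
artefacts, speed drift within a run, surface and curve effects,
realistic three-dimensional coupling between axes, or any
musculoskeletal dynamics.  Passing tests therefore show that the
*pipeline* is correct and behaves as designed under the assumed
statistical structure — not that the reported accuracies transfer to
real recordings.

## Segmentation

Run bounds come from zero-crossings of the pelvis forward velocity
around its sustained-positive stretches (1 s moving average above half
its 95th percentile).  Stride events are downward peaks of the pelvis
velocity found by peak detection with scale-free gates: prominence ≥
0.2 × the signal IQR, minimum separation = half the median stride
period (estimated from a first prominence-only pass).  Initial contacts
are knee-extension minima of the right knee angle: the minimum within
±30 % of the stride period around each stride event is the right
contact, and the analogous minimum half a stride later is the left
contact; strides missing either landmark are flagged unusable and
skipped, preserving side alternation.  Each side's cycles span
consecutive same-side contacts and all 22 signals (8 acceleration
magnitudes, 8 pitch angular velocities, 6 joint angles) are linearly
resampled to 150 points.  Linear interpolation is monotone and exactly
reproduces a 150-sample cycle; cycles shorter than 10 samples or longer
than 1.8 × the median (gaps from skipped strides) are dropped.

## Features

157 features per stride (a right cycle paired with the left cycle
starting inside it): per location, 6 statistics (peak, mean, SD, IQR,
skewness, kurtosis) of the acceleration magnitude and of the pitch
angular velocity (96 features, the 16 peaks biomechanical, the rest
statistical); 22 joint-angle event extrema (knee: initial contact,
mid-stance, toe-off, mid-swing, end-swing; ankle and hip: three each)
plus 30 joint-angle statistics; 3 left-minus-right symmetry differences
of the initial-contact extremum per joint level; 2 tibia-to-pelvis
shock attenuations, `SA = (1 − PSA/PTA) × 100` %; stride time and
stride length (nominal speed × stride time, as speed is controlled)
per side.

Numerical conventions: SD uses `ddof=1`; skewness is the biased sample
skewness and kurtosis the biased excess kurtosis, both defined as 0 for
zero-variance curves; IQR uses linear-interpolation percentiles.  Event
windows, as fractions of the cycle from initial contact, are IC 0–5 %,
mid-stance 5–35 %, toe-off 30–45 %, mid-swing 50–75 %, end-swing
85–100 %; each event takes the window maximum for flexion-type events
and the minimum for extension-type ones.  The windows are not uniquely
determined by running biomechanics and are configurable; the defaults
follow standard phase timings of running gait.

A sensor configuration (any of the 255 non-empty subsets of L1–L8)
exposes features as a column mask: the 12 per-location features for
each worn sensor, a joint's features when both adjacent segments are
worn, symmetry when both sides of a level are available, shock
attenuation when the tibia and pelvis are both worn, and the
spatiotemporal features when the segmentation sources (pelvis, right
thigh, right tibia) are worn.  Masks are monotone in the location set.
Extraction always runs on the full 8-sensor recording; configurations
only select columns.

## Smoothing, normalization, labels

All features get a trailing (causal) moving average over 400 m of
running distance — one full lap, which cancels the direction change
halfway through each run; a centered window is available by
configuration.  Rows with less than one full window of history are
dropped, and windows never cross run boundaries, so the first lap of
each run (including run-3 lap 1, a third of the heavy-fatigue segment)
is consumed as warm-up.  Labels are then attached per lap and
unlabelled rows discarded.  Finally each feature is z-scored per
subject (population SD, over the subject's labeled smoothed rows;
zero-variance features map to 0).  Whether smoothing precedes
normalization is not uniquely determined; the default is
smooth-then-z-score and the reverse order is a configuration switch.
The per-subject normalization uses rows from all three conditions,
which is a mild form of leakage-by-normalization shared by the design
it follows; it is what makes features comparable across subjects whose
speeds differ.

## Classification and evaluation

The classifier is a bagged forest of 100 decision trees
(`sqrt(n_features)` candidate features per split, unlimited depth —
scikit-learn tree defaults, pinned).  The bootstrap is drawn with an
explicit NumPy PCG64 generator, so out-of-bag membership is exact:
OOB permutation importance of a feature is the mean over trees of the
OOB accuracy drop after permuting that feature's OOB values (features a
tree never uses contribute zero drop).  Majority vote breaks ties
toward the lower class index.

Evaluation is a nested leave-one-subject-out cross-validation.  For
each held-out test subject, the inner loop excludes one further
validation subject at a time, fits a forest on the remaining subjects
and computes OOB permutation importances; importances are averaged
arithmetically over the inner folds and the top 12 features selected
(ties break toward the earlier catalogue position; masks with ≤ 12
features — the single-sensor case — keep everything).  A forest is then
retrained on all training subjects restricted to the selection and
scored on the held-out subject.  Reported metrics (accuracy,
sensitivity, specificity, precision, F1; one-vs-rest) are means ± SD
over the outer folds, alongside an aggregate confusion matrix over all
test rows.  Because lap smoothing makes within-subject rows strongly
autocorrelated, no row-level random splits exist anywhere; all
stochastic steps derive per-fold seeds from one master seed.

## Problem sizes

Default generation uses the full study conditions (8 subjects, 13 laps
of 400 m, 240 Hz).  The statistical test-suite checks and the
acceptance script run the same 13-lap protocol at 60 Hz and thin the
smoothed rows (every 2nd–6th stride): after a 400 m moving average,
adjacent stride rows are nearly identical, so thinning sacrifices
almost no information while keeping the nested evaluation (which fits
`n_subjects × (n_subjects − 1)` forests per configuration) fast.  Unit
tests additionally use shortened laps (60 m) where only structural
behaviour is at stake.

Because the lap smoothing leaves each subject only a handful of
effectively independent rows per condition, the mean accuracy of a
single null-effect cohort fluctuates noticeably around its chance
baseline; the chance-level property is therefore checked on the mean
over three independently generated null cohorts.

## Known limitations

* The generator's waveforms are templates, not physics; absolute
  feature values are only order-of-magnitude realistic.
* Initial-contact detection assumes a knee-extension minimum near
  touchdown; gait styles violating this need a different landmark rule
  (the rule is isolated behind one function).
* The causal smoothing delay means the first lap of every run yields no
  classified rows; a real-time system would share this latency.
* Speed is assumed constant per run; sessions with varying pace would
  confound the per-subject z-scoring.
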