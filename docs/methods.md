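# Methods

This note documents the models, numerical conventions and design choices in
`oculaff`, and what the synthetic-data tests do and do not establish about
real recordings.

## Recording model and validity filtering

A recording is a sample stream `(t, gaze_x, gaze_y, pupil_mm, confidence)`
at a nominal 240 Hz plus tracker blink intervals. Gaze is normalized to the
screen, origin bottom-left, x rightward, y upward; timestamps are seconds
from recording start, and irregular sampling is tolerated (the nominal rate
is used only where a sampling frequency is required).

Exclusion criteria: eyes closed longer than 10% of the clip duration,
attention decoupled from the screen longer than 20%, or aborted playback.
Eyes-closed time is the union of tracker blink intervals and contiguous
low-confidence runs. The attention criterion has no direct measurement in
a gaze stream; it is operationalized here as the fraction of samples with
gaze outside the unit square (or confidence below the blink threshold while
not inside an eyes-closed interval) — an explicit proxy, flagged as such,
since only gaze-derived signals are available. Fractions exactly at a
boundary are kept: the criteria are strictly "longer than".

## Preprocessing

Per axis, visual angle is `theta = atan(offset_from_center / distance)`
with defaults matching the emulated setup: a 24-inch 16:9 display
(531.3 x 298.9 mm, 1280 x 720) at 800 mm, so the screen subtends about
36.7 x 21.2 degrees. Angular speed between consecutive samples is the
great angle between the exact 3-D gaze directions (not the planar
approximation, which deviates a few percent at high eccentricity) divided
by the time step; the speed series has length n-1, aligned to the trailing
sample.

The 5-tap velocity filter is a symmetric FIR smoother. The literature the
pipeline follows does not print the coefficients, so the default is the
uniform moving average `(0.2, ..., 0.2)`, exposed in configuration; edges
and samples adjacent to masked gaps are handled by window truncation with
renormalization, which keeps the filter a convex combination (output never
exceeds the raw maximum). The filter is applied to the whole speed series
rather than gated on detected peaks — gating is underspecified and global
smoothing is the standard reading.

## Event detection

I-VT with velocity threshold 45 deg/s and minimum fixation duration 55 ms.
A speed exactly at the threshold is a saccade point (the fixation rule is
strictly "below"). Fixation groups shorter than the minimum are discarded
as unclassified gaps, not merged into adjacent saccades. Centroids are
arithmetic means of the group's angular positions. Samples inside blink
intervals are masked before detection so lid-closure artifacts cannot
masquerade as saccades. The numeric confidence threshold for deriving
blinks when no tracker intervals are present is not published; the default
is 0.5, configurable.

## Features

28 features per recording. Central statistics follow the published
convention: medians for fixation duration, saccade duration and saccade
amplitude; means for saccade velocity, peak velocity, blink duration and
pupil diameter. CV uses the n-1 standard-deviation denominator (the
published choice of denominator is not stated). Skewness is the
Fisher-Pearson coefficient; kurtosis is excess by default with a raw
switch, since the source tables cannot disambiguate the convention.
Frequencies divide event counts by the full recording duration (the
published units carry no valid-time caveat). Zero-dispersion samples get
skewness 0 with a warning; families with no events or fewer than two are
reported as NaN, never silently zero. Pupil statistics are computed over
samples outside blinks with confidence at or above the threshold; when two
eyes are present the exported diameter is assumed already combined
upstream (the schema carries a single pupil series).

## Annotation

"At least 1 point higher" is read as a margin of >= 1.0; ties fall to
neutral, since the rule's condition is unmet and no tiebreak is published.
Ratings are accepted as reals in [0, 10] even though collected on an
11-point scale, so group mean-rating vectors flow through the same rule.
Discreteness tests are paired t-tests per annotation group; zero-variance
differences report the exact-limit p with a warning.

## Screening and selection

Each feature is screened with `feature ~ class + (1 | participant)` fit by
REML; the omnibus p is a Wald chi-squared test on the class coefficients,
pairwise contrasts are Wald z-tests Bonferroni-adjusted by the number of
pairs, and class means with standard errors come from the fixed-effect
contrasts. A null simulation (20 participants x 6 recordings, participant
SD 0.5, 2000 replicates) checks that the omnibus type-I error stays within
[0.03, 0.07] at alpha = 0.05. If the random-intercept variance collapses
numerically, the
model falls back to ordinary least squares with a warning.

Correlation pruning treats "highly correlated" as `|r| > 0.3` (absolute
value; the published rule does not state it) and "better distinguishing" as
the smaller omnibus p (also not formalized in the source). When more than
two features inter-correlate, the worst-ranked feature among all offending
pairs is removed greedily and correlations recomputed — deterministic, with
alphabetical tie-break. The published predictor sets (6 arousal, 8 valence,
7 combined) and the published screening significance patterns ship as
versioned fixtures in `oculaff.reference` so downstream stages run without
the real data.

The luminance check block-averages the pupil series onto video frame
intervals (the coarser rate) before the Pearson correlation; categories are
|r| < 0.2 very weak, < 0.4 weak, < 0.6 moderate, else strong.

## Classifiers

The DMLP family: input width matching the predictor set (6, 7, 8 or 28),
2-3 hidden layers of 8-256 ReLU units each followed by dropout 0.25, and a
sigmoid (binary) or softmax (multiclass) head. The implementation is a
compact NumPy network wrapped as a scikit-learn estimator (Adam, binary
cross-entropy for two classes and its categorical generalization
otherwise — the stated loss is undefined for more than two classes).
Training defaults: 200 epochs, batch size 32, learning rate 1e-3, optional
early stopping with patience 20; fully deterministic given a seed.

Protocol: the 80/20 stratified split drives architecture search (smallest
held-out error, ties broken by fewest hidden neurons, architecture fixed
before cross-validation); reported metrics are means over 10 stratified
folds. Median imputation (training-fold medians) and per-feature z-scoring
are fit inside each training fold. Multiclass AUC is macro one-vs-rest;
f1 is macro-averaged.

## Synthetic recordings

The generator emulates the study conditions: 240 Hz streams, 60 s clips
(about 110-140 fixations per minute), with class profiles parameterized
from the published per-class feature means — lognormal fixation durations
(median/CV per class), lognormal saccade amplitudes, Poisson blink counts
with lognormal durations, and a pupil series `baseline + OU drift + noise`
with the class mean and CV (drift time constant 4 s). Quadrant profiles
average their parent arousal- and valence-level targets. Sessions draw DES
ratings around the published per-emotion mean vectors and inject
participant-level multiplicative offsets (lognormal, mean 1, default CV
0.05) so the random-intercept structure the screening model assumes is
present.

Saccades follow a main-sequence relation
`peak = a (1 - exp(-amplitude / b))` with `b = 10 deg` and `a` set so the
peak at the class's median amplitude equals the class's published mean peak
velocity (~300-320 deg/s). Trace kinematics are kept physically consistent
— amplitude is the integral of speed — so saccade durations come out near
60-90 ms rather than the ~22 ms the source tables print; those printed
duration/amplitude/velocity values are mutually inconsistent for a
continuous trace, and the generator follows the amplitude and peak-velocity
side. Saccade interior speeds have a 140 deg/s floor and a bounded onset,
which makes the 5-tap-smoothed speed cross the 45 deg/s threshold exactly
one sample outside the motion at each boundary; this deterministic
one-sample smear is absorbed by scheduling each fixation two samples longer
than its drawn duration. Drawn fixation durations are floored just above
the 55 ms minimum so no fixation is discarded by detection — flooring only
moves values below the median, leaving the targeted median untouched.
Blinks are scheduled between a fixation and the following saccade with gaze
held at the centroid (plus two valid hold samples after the blink), so
blink masking never splits a fixation and never hides a saccade onset.

What the generator does *not* emulate: measurement noise on gaze beyond
miniature fixational motion, smooth pursuit, post-saccadic oscillations,
tracker dropout outside blinks, luminance-coupled pupil dynamics (a
separate probe emits a V-correlated series solely to exercise the
luminance check), and realistic saccade-duration marginals (above). Passing
parameter-recovery tests therefore shows the pipeline is correct and
unbiased under the generative model, not that it is robust to every
artifact of real recordings.

## Problem sizes in the checks

Parameter recovery uses 200 recordings of 60 s per class and requires the
Monte-Carlo mean of each targeted feature (high-arousal pupil mean,
low-arousal fixation-duration median, medium-valence blink frequency,
negative-valence saccade-amplitude median) within two Monte-Carlo standard
errors of the profile target. Event-boundary recovery uses noise-free
traces and a +-1 sample tolerance. Classifier control suites use 240-sample
Gaussian class problems (permuted labels at chance, separable classes near
1.0, accuracy monotone in class separation).

## Known limitations

* The mixed-model omnibus test uses a Wald chi-squared reference; with very
  few participants an F/Kenward-Roger-style correction would be preferable.
* Pupil skewness/kurtosis of the OU-based generator do not reproduce the
  published negative-skew values; those features are generated but not
  targeted.
* `load_esee_d` expects the deposited archive re-exported to the documented
  CSV schemas; it does not parse native Pupil Capture formats.
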