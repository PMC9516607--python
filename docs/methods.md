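# Methods

## Problem and data model

Each tooth-removal experiment yields a 13-dimensional dual-rate
recording: forces and torques (3 + 3 channels, nominal 20 Hz, sensor
frame) and the pose of the instrument (3-D position plus a unit
quaternion, nominal 100 Hz, robot frame), together with a calibration
pose taken just before the extraction that fixes the *tooth frame* —
right-handed, X buccolingual (buccal +), Y mesiodistal (mesial +),
Z longitudinal (intrusion +, extrusion −). Torque and rotation signs
follow the right-hand rule about these axes (e.g. +Y torque is
buccoversion, +Z mesiobuccal rotation). Every downstream sign
convention derives from the single `ToothFrameConvention` object.

Labels are the 8 jaw × class combinations, serialized `U1/2, U3,
U4/5, U6/7, L1/2, L3, L4/5, L6/7`. "Neighboring class" means same
jaw and adjacent class rank (incisor–cuspid, cuspid–bicuspid,
bicuspid–molar); cross-jaw pairs are never neighbors, because jaw
confusion and class confusion are clinically distinct errors and the
jaw-level rate already accounts for the former. That yields exactly 3
unordered neighbor pairs per jaw.

## Preprocessing

Order of operations: optional auto-trim → restriction to the common
time window → rigid transformation → angle decomposition → filtering
→ upsampling → alignment → differentiation.

* **Trimming.** Recordings bracketed by idle time can be trimmed
  automatically: samples where ‖F‖ + ‖T‖ stays below a threshold are
  removed from both ends (never the whole recording; a fully quiet
  recording is passed through with a warning flag). The default
  threshold is 0 (off): synthetic recordings carry no idle padding,
  and for real data the threshold should be chosen against the
  sensor's noise floor.
* **Frame transformation.** Forces/torques are rotated by the inverse
  calibration orientation; positions are translated by the calibrated
  origin and rotated, giving displacement from the tooth; orientations
  become rotations relative to the calibrated orientation. Rotations
  are isometries, so force/torque magnitudes are exactly preserved.
* **Rotation angles.** Relative orientations are decomposed as
  rotation vectors (axis–angle × angle, per-axis components in
  degrees) rather than Euler angles — no ordering convention, no
  gimbal ambiguity, and for the small luxation angles involved the
  components read directly as "rotation about X/Y/Z". Quaternion
  signs are made consistent along the series so traces are continuous.
* **Filtering.** Zero-phase (forward–backward) low-pass Butterworth,
  order 4, cutoff 5 Hz for the 20 Hz force/torque stream and 10 Hz for
  the 100 Hz kinematics; all configurable. Luxation content sits below
  ~2 Hz, so these defaults suppress sensor noise without touching the
  signal; zero-phase application keeps force and motion aligned in
  time (at the cost of squaring the magnitude response: gain ½ at the
  cutoff instead of 1/√2).
* **Alignment invariant.** After filtering, angle and displacement
  traces are rebased to zero at the first sample, making "relative to
  the calibrated pose" exact even when sensor noise perturbs the first
  measurement.
* **Resampling.** The force/torque stream is FFT-resampled
  (Fourier zero-padding) from 20 to 100 Hz after transformation and
  filtering — resampling last means the filter operates at the
  stream's native rate. The kinematic traces are then linearly
  interpolated onto the resampled clock, so all five trace families
  share one uniform 100 Hz time base. DC (the signal mean) is
  preserved exactly; band-limited content is reconstructed to
  numerical precision when the record spans whole periods.

Degenerate inputs are rejected with specific errors: non-monotone
timestamps, quaternion norms off unit by more than 1e-6, cutoffs at or
above Nyquist, empty signals, disjoint stream windows.

## Feature catalogue

75 features over five trace families (force N, torque Nm, rotation
deg, rotational velocity deg/s, displacement m):

| family | definitions | count |
|---|---|---|
| force, torque | AUC (combined + 6 signed), average (combined + 6 signed), combined peak, per-axis share | 2 × 18 |
| rotation | per-axis share (3), signed maxima (6), signed averages (6), per-axis variation (3) | 18 |
| rotational velocity | signed maxima (6), per-axis variation (3) | 9 |
| displacement | signed maxima (6), per-axis variation (3), per-axis share (3) | 12 |

Definitional choices (each switchable in `FeatureConfig`):

* *Signed AUC* is the trapezoidal integral of the positive (or
  negative, reported positive) part; the two parts always sum to the
  integral of |s|.
* *Combined axes* ("X + Y + Z") is the Euclidean norm of the
  3-vector (alternative: sum of absolute components). The norm is the
  magnitude a surgeon delivers irrespective of direction, and it is
  the convention under which "summed torque" and "average torque"
  have the familiar scatter structure across tooth classes.
* *Signed averages* are conditional means over sign-matching samples
  (alternative: signed AUC / total duration). The conditional mean
  answers "how hard, when pushing that way", independent of how long
  the recording is.
* *Variation* is the range max − min (alternative: standard
  deviation).
* Per-axis shares are percentages of |AUC| and sum to 100% whenever
  any activity exists; an all-quiet denominator yields 0 rather than
  NaN.

The catalogue includes, verbatim by (family, axis, sign), the
33-feature subset that cadaver extraction experiments identified as
informative (`CLINICAL_REFERENCE_SELECTION`); the displacement family
completes the catalogue with summaries of the recorded position data.
Direction labels (buccal, extrusion, buccoversion, …) are attached to
every definition from the frame convention.

## Selection

Features are standardized per training set (population sd;
zero-variance columns keep sd 1 and are flagged). One multinomial
logistic regression with L2 penalty (C = 1.0, lbfgs, tol 1e-8) is
fit; importance is the mean |coefficient| across the 8 class rows
(alternative: max). The threshold is the arithmetic mean importance,
with ≥ comparison so an all-equal vector selects everything rather
than nothing. L2 rather than L1 keeps correlated features with evenly
split weight — exact duplicates provably receive equal coefficients at
the optimum, which the tests exercise.

By default selection is refit inside each cross-validation training
fold: selecting once on all data leaks test information into the
folds. A `scope="global"` switch performs the single all-data
selection instead, which is the right mode when the goal is one
study-level feature list rather than an unbiased accuracy estimate.

## Classifier

Gaussian naive Bayes, written out rather than wrapped: empirical class
priors, per-class sample means and population variances, variances
floored at ε = 1e-9 × (largest total feature variance) so a class
that is constant on some feature cannot contribute an infinite
density. Scores are unnormalized log posteriors; prediction is the
arg-max with ties resolved to the first label in canonical order.
Classes with fewer than two training samples are rejected by the fit.
Empirical (not uniform) priors match the stratified design, where
training-fold class proportions mirror the dataset.

## Evaluation

Stratified k-fold (default k = 4, seed 0, recorded in the report):
fold sizes differ by at most one overall and per label. At the study
scale (n = 110) this gives test folds {28, 28, 27, 27} and training
folds {82, 82, 83, 83}. Metrics are accuracy and support-weighted
precision/recall/F1 — weighted recall is algebraically identical to
accuracy, a useful internal consistency check. Confusion matrices are
accumulated over folds (test total n, train total (k−1)·n). The two
clinical rates — jaw-correct and correct-or-neighboring — are computed
on the pooled test predictions and dominate accuracy by construction.

## Synthetic data generator

The generator emulates the statistical structure the analysis relies
on, not tooth biomechanics. Per label, a `ClassProfile` drives:

* sinusoidal luxation torques about all three axes at 0.6 Hz (upper)
  or 1.0 Hz (lower jaw), with a linear amplitude envelope (±35% around
  the mid-recording value) representing progressive loosening;
* class-scaled amplitudes — combined torque scale 1.5 / 3 / 5 /
  7.5 Nm for incisor / cuspid / bicuspid / molar, ×1.3 in the lower
  jaw — and class-scaled durations (20–35 s), so summed torque AUC is
  strictly increasing front-to-back within each jaw and lower-jaw
  dorsal teeth show higher average torques than upper counterparts,
  while incisor average combined torque stays well under 6 Nm;
* a constant mesial(+, lower)/distal(−, upper) angulation torque bias,
  the second jaw signature;
* rotation amplitudes that swap roles along the arch: long-axis (Z)
  rotation dominates for single-rooted anterior teeth, buccolingual
  rocking (Y) for posterior teeth;
* an extrusion ramp on −Z force over the final 20% of the recording
  (20–50 N by class), with matching displacement travel;
* lognormal per-recording amplitude jitter (sd 0.08) and Gaussian
  sensor noise (0.3 N, 0.08 Nm, 0.3°) as tooth-to-tooth and
  measurement variability.

Amplitude choices are deliberate placeholders tuned only to those
qualitative orderings; the defaults produce a *strongly separated*
dataset on which the pipeline should be near-perfect. Passing tests on
it therefore demonstrates correctness of the machinery — frame
recovery, feature computation, leakage-free evaluation — and the
qualitative class structure, not the accuracy attainable on real
cadaver recordings, where surgeon and specimen variability dominate.
Not emulated: tooth fracture and failed extractions, operator effects,
sensor drift or gravity load of the forceps, and realistic
correlations between force and motion channels beyond their shared
envelope.

Signals are generated in the tooth frame and pushed through a random
rigid calibration pose into the sensor frame, so preprocessing
performs a genuine recovery; with a fixed seed, generation is
bit-reproducible (per-recording child seeds are spawned from the
dataset seed).

The default dataset holds 110 experiments, the scale of the cadaver
campaign this pipeline targets, split near-evenly (six labels × 14,
two × 13) because true per-label counts are not public.

## Problem sizes and determinism

All shipped analyses run at desk scale: 110 recordings of 20–35 s
(2 000–3 500 kinematic samples each), preprocessing and feature
extraction in ~4 s and the full cross-validated run in ~5 s on one
CPU. Every stochastic component (generator, fold shuffling) is driven
by explicit seeds; identical configs yield byte-identical artifacts.

## Known limitations

* The 42 features beyond the documented 33 are a reconstruction; the
  displacement family in particular is plausible rather than attested.
* FFT resampling assumes quasi-periodicity; strong trends leak
  slightly at record edges (the trim stage mitigates this on real
  data).
* Rotation-vector traces are not unwrapped past ±180°; luxation
  angles are far below that.
* The generator's class separation is optimistic by design; no
  conclusions about achievable clinical accuracy follow from it.
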