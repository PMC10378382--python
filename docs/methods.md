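# Methods

This note records the model, the numerical conventions, and the design
choices made where the procedure left genuine freedom. It is the
reference for maintainers; the README gives the short version.

## The classification model

The classifier is instance-based: no parametric decision boundary is
fitted. For each head-lag level ℓ ∈ {0, 1, 3}, the training set defines
one triangular membership function (MF) per (frame, keypoint, axis)
position of the canonicalized sequence — N × k × 2 MFs per level, where
N is the standardized frame count and k the keypoint count (13 or 5).
An MF is determined by the mean `Avg` and standard deviation `Sd` of the
training coordinates at that position: feet at `Avg ± 3·Sd`, apex 1 at
`Avg`. The three-sigma width covers 99.73% of a normal distribution, so
a coordinate drawn from the same motion distribution almost always gets
positive membership, while a coordinate from a different severity class
falls outside once the class separation exceeds the within-class spread.

A test sequence's final possibility under a level model is the mean over
frames of the mean over keypoints of `√(MF_X(x)·MF_Y(y))`. The geometric
mean makes the per-keypoint score zero whenever either axis is outside
its MF, which is the mechanism that drives separation: a lagging head
traces a different sagittal path, its coordinates exit the level-3 MFs,
and the level-3 possibility collapses. The arg-max over the three levels
gives the prediction. Possibilities are not normalized across levels —
they are possibilities, not probabilities, and the three models are
fitted independently.

Assumptions worth stating: MFs treat axes, keypoints and frames as
independent (no covariance is modeled); all keypoints carry equal
weight; and temporal alignment comes entirely from the shared
lying-to-sitting structure of the examination plus frame
standardization, not from any warping.

## Preprocessing

1. **Frame standardization.** Uniform subsampling to N frames retaining
   original indices `round(i·(M−1)/(N−1))`, half rounding up. This is
   deterministic, keeps the first and last frames (the lying start and
   sitting end shared by all recordings), reduces to dropping every
   second frame when M = 2N − 1, and never interpolates coordinates.
   Upsampling is refused: N must be the dataset minimum, so no
   coordinates are invented.
2. **Lifting.** 2D input is lifted to 3D by a caller-supplied adapter
   (one 2D frame in, one 3D frame out, same keypoint names); any
   monocular lifting network can be wrapped this way. 3D input (e.g.
   synthetic data) passes through.
3. **Canonical rotation.** The torso axis is the pelvis-midpoint →
   shoulder-midpoint vector; the mediolateral axis is the average of the
   left→right shoulder and left→right pelvis vectors (a single
   well-defined axis honoring both landmark pairs). The canonicalizing
   rotation maps the mediolateral axis onto ±Z — signed so the left
   shoulder ends with the larger Z, which removes the mirror ambiguity
   between left-side and right-side camera placements — and the torso
   (orthogonalized against it) onto +Y. The rotation is built directly
   from this orthonormal basis and then decomposed into three planar
   (Tait–Bryan) angles applied in the order XY, XZ, YZ, so the stored
   representation is three plane rotations with atan2-extracted angles
   in (−π, π]. Computing the matrix first and decomposing it — rather
   than solving each plane greedily in sequence — is what makes the
   recovery of a rotated canonical frame exact to machine precision;
   a greedy XY-then-XZ-then-YZ solve leaves a residual in-plane
   rotation whenever the camera rotation mixes all three axes.
4. **Rotation reference.** By default one rotation is computed from the
   first frame and applied to the whole recording (`first_frame`): the
   camera is fixed within a recording, and re-canonicalizing every frame
   (`per_frame`, available by configuration) would partially cancel the
   torso-elevation signal that distinguishes the levels.
5. **Projection and normalization.** Z is dropped; each axis is min–max
   scaled over all frames × keypoints of the sequence. Per-sequence
   scaling standardizes subject position and size between recordings
   (the plausible alternative — dataset-global extrema — would leak
   information across the train/test split). A zero-range axis raises an
   error naming the axis rather than silently filling a constant: it
   means a degenerate recording.

The composed pipeline is invariant under any rigid rotation, translation
and uniform scaling of the input (verified to 1e-6 per coordinate in the
tests; in practice machine precision), because lag angles, axis ratios
and the min–max frame are all camera-independent once the canonical
rotation is undone.

## Numerical conventions

* `Sd` is the population standard deviation (divide by n): the
  three-sigma bound treats the training values as the distribution
  itself. `ddof` is exposed on the fitting functions for sensitivity
  analysis.
* A degenerate MF (Sd = 0, e.g. a single training sequence) accepts only
  values within 1e-9 of its apex — the limiting behavior of the triangle
  as its width goes to zero.
* The linear MF branches are clamped to [0, 1]; everything outside
  [LB, UB] evaluates to 0.
* Tied maximal possibilities (including the all-zero case, when a test
  sequence is outside every model's support) predict the lowest level
  and emit a warning: deterministic, and clinically conservative in that
  it flags possible delay rather than health.
* Cohen's κ, the stratified fold assignment and the paired t statistic
  are implemented from first principles; scikit-learn and scipy serve
  only as independent cross-checks in the test suite. The t-tail
  probability itself uses scipy's Student-t distribution. Degenerate
  t-test inputs are explicit: all-zero deviations give t = 0, p = 1;
  constant nonzero deviations give the limiting p = 0 (both warn).
* Cross-validation randomness derives from a single integer seed; repeat
  r uses the spawned stream (seed, r), so plans are reproducible and
  repeats independent. Per label, shuffled instances are dealt
  round-robin to folds with a rotating offset, which bounds every
  per-fold label count within ±1 of exact proportionality.
* The per-run unit of the thirteen-vs-five paired t-test is one full
  5-fold repeat (one accuracy over the whole dataset per repeat);
  per-fold pairing is available by configuration. Accuracy spread is
  reported both over repeats and over folds, since the two standard
  deviations answer different questions.

## The synthetic generator

The simulator emulates the geometry the head-lag criteria are defined
on, not infant biomechanics. A torso segment anchored at the pelvis
midpoint sweeps monotonically from 0° (lying, along +Y) to 90°
(sitting) with eased endpoints; a head segment leaves the shoulder
midpoint at the torso angle minus a per-sequence lag angle; shoulders
and pelves sit at fixed mediolateral offsets; arms (raised toward the
examiner's pull) and legs (resting) articulate with per-frame Gaussian
jitter. The lag angle is sampled per sequence from the level's preset —
mean 60° (level 0), 22° (level 1, midway between the two angular
criteria), 5° (level 3), clipped to the HINE bands ≥ 30°, 15–30° and
≤ 15° respectively — and held constant through the sweep, so the
measured head-to-torso angle equals the sampled lag at every frame and
class membership is guaranteed by construction. Isotropic Gaussian noise
(default 1% of torso length, a stand-in for pose-estimator jitter) is
added before a per-sequence random camera transform (uniform random
rotation, translation, log-uniform scale in [0.5, 2]).

What the simulator does **not** model: traction forces and variable pull
speed, head wobble within a recording, gross pose-tracking outliers and
identity switches, occlusion, or any correlation structure between
keypoints beyond the rigid chain. Consequently, passing the synthetic
end-to-end tests demonstrates that the pipeline recovers the class
structure its preprocessing is designed to expose — it does not
calibrate the difficulty of real clinical footage, where within-class
variability is larger and label noise exists.

## Problem sizes

The default evaluation protocol is 30 repeats of stratified 5-fold
cross-validation. The synthetic full-scale experiment uses 270 sequences
with class counts 84 / 106 / 80 and heterogeneous frame counts in
[90, 180] (standardized to N = 90), yielding 8100 pooled test results;
the separated-preset recovery experiment uses 60 sequences of 60–90
frames. Both complete in seconds on one CPU because model fitting is a
mean/std over stacked arrays and scoring is fully vectorized.

## Known limitations

* The possibility score is diluted by uninformative keypoints: with 13
  landmarks the head contributes 1/13 of each frame's score, which is
  why the five-keypoint subset can discriminate level 0 from level 1
  better despite carrying less data.
* Sequences that fall outside every model's support are all scored 0 and
  default to level 0; callers should treat the degenerate-tie flag as
  "out of distribution", not as a confident prediction.
* The mirror convention (left shoulder toward +Z) is one consistent
  choice; recordings whose pose tracker systematically swaps left/right
  labels would need correction upstream.
* No confidence scores are consumed: low-confidence keypoints are the
  caller's responsibility to filter, and sequences with missing
  keypoints are rejected rather than imputed.
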