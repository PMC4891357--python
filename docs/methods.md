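# Methods

## The model

The arm-plus-rod system is a serial chain of five rigid segments — upper
arm, forearm, hand (wrist to finger base), finger, and an optional rod
collinear with the finger — driven by nine joint angles in a fixed
canonical order: shoulder plane of elevation, shoulder elevation, shoulder
axial rotation, elbow flexion, forearm pronation, wrist abduction, wrist
flexion, finger abduction, finger flexion.  The lab frame has its origin
at the shoulder centre, +x horizontal toward the target, +y to the
participant's left, +z up; the zero posture is the chain straightened
along +x.

Biomechanical reporting conventions for the upper limb prescribe which
angles to report but not a unique rotation-sequence implementation, so the
package defines its own explicit stack: shoulder as intrinsic
Z(plane of elevation)·Y(elevation)·X(axial rotation); elbow flexion (local
y) and forearm pronation (local x) as successive single-axis rotations;
wrist and finger each as abduction (local z) followed by flexion (local
y).  This is a package convention, not a claim about any particular
laboratory's kinematic model; every downstream quantity (GEV, NGEV, their
ratio) is defined relative to the same convention on both the analysis and
the synthetic-data side, so conclusions do not depend on it.

The 3×9 Jacobian of tip position is computed by central finite differences
with step 1e-6 rad rather than symbolically: it is robust to convention
changes, and an analytic planar two-link oracle (shoulder elevation +
elbow flexion only) pins its correctness to 1e-6 mm/rad in the tests.
Joint space is split by the SVD of J; singular values below 1e-10 of the
largest are treated as zero.  A rank-deficient Jacobian (e.g. the fully
stretched chain) sets a `singular` flag and returns bases with the actual
dimensions rather than raising — synthetic reference postures are kept
away from full extension by construction, so the flag marks data problems
when analysing real recordings.

## The UCM decomposition

At a movement instant, the across-trials joint-angle covariance `C`
(unbiased, n−1 denominator; the choice is documented rather than imposed
by any source) is projected onto the null space of the Jacobian evaluated
at the ensemble-mean configuration of that instant, and onto its
orthogonal complement:

    NGEV = trace(orth(Jᵀ)ᵀ C orth(Jᵀ)) / 3
    GEV  = trace(null(J)ᵀ C null(J)) / 6
    V_Ratio = GEV / NGEV

Both variances are per subspace dimension, in rad².  The identity
3·NGEV + 6·GEV = trace(C) holds to round-off because the two bases
together are a full orthonormal basis of joint space; the test suite
enforces it at 1e-10 relative.  An independent estimator
(`ucm_decompose_oracle`) projects each trial's deviation explicitly and
averages squared projection norms; trace formula and oracle agree to
1e-10 on random ensembles.

The log transform is the natural logarithm (the base is a free choice;
every stabilisation conclusion, `log(V_Ratio) > 0` ⇔ GEV > NGEV, is
base-invariant).  Zero variances make the ratio or a log undefined; the
result then carries NaN plus an `undefined` field listing the affected
quantities, never ±inf, so aggregation cannot silently propagate
non-finite values.  Projected variances that land within −1e-12 of zero
are clipped to 0 with a warning; more negative values mean a non-PSD input
and raise.  Covariances are computed after shifting all trials by the
first one — translation-invariant, and an ensemble of identical trials
then yields an exact zero matrix instead of cancellation round-off.

By default the decomposition is reported at the 100 % instant of the
time-normalised movement — the endpoint, the only moment the task actually
constrains — with an option to compute all 100 instants.

## Endpoint kinematics

Tangential velocity is the norm of the per-axis position derivatives
(central differences inside, one-sided at the ends); no smoothing is
applied by default, and an optional Butterworth low-pass exists for noisy
recordings.  Movement start is the first sample with speed above 25 mm/s
*and* distance from the start point above 10 mm; the end is the first
later sample with speed below 25 mm/s *and* distance to the target below
10 mm (strict inequalities, both predicates simultaneously).  Phase times
split at the earliest speed maximum within bounds.  Curvature is the
unsigned maximum deviation from the start→target chord after projecting
path and chord onto the horizontal (x–y) or sagittal (x–z) plane.  The
absolute error is the mean over trials of the endpoint-to-target distance;
the variable error is the (n−1) SD of those per-trial distances.

Time normalisation resamples the in-bounds segment linearly onto 100
points, point k at fraction k/100 of the movement time from the start
sample; "1 %" is thus the first normalised point, and the 100th point
coincides exactly with the end-of-movement sample.

A consequence of the conjunction rule worth knowing: on a perfectly
symmetric minimum-jerk reach, the detected acceleration phase is ~0.1 s
shorter than the deceleration phase, because the start fires only once the
tip leaves the 10 mm start dot (by which time it moves at ~146 mm/s for a
300 mm / 1 s reach) while the end fires at the 25 mm/s crossing, 0.5 mm
from the target.  Profile symmetry itself is verified over the true
movement span; the detector is verified against a brute-force
predicate-scan oracle.

## The synthetic generator

The generator emulates the study design the analysis was built for: eight
conditions (rod 0/100/200/300 mm × participant displaced or not), 25
trials each, 100 Hz, start and target 300 mm apart in a horizontal plane.
In the shoulder-centred frame, displacement shifts start and target by
+rod_length along x (the chair moves away from the table by the rod
length), equalising the tip amplitude and arm postures across rod lengths;
without displacement the task points stay fixed and longer rods need
smaller joint excursions (the reference trajectories' joint-space path
length decreases strictly with rod length, a tested property).

Per condition the reference movement is a straight minimum-jerk tip path
(quintic profile 10τ³ − 15τ⁴ + 6τ⁵) tracked by damped least-squares
inverse kinematics (damping 0.01, per-sample tolerance 0.01 mm, warm
started sample to sample — deterministic).  Trial variability is injected
in joint space, where the UCM analysis lives: one smooth 9-D Gaussian
process projected onto the instantaneous null space (per-dimension std
`sigma_gev`) plus an independent one projected onto the orthogonal
complement (`sigma_ngev`).  Projection matrices vary continuously along
the movement (unlike raw SVD bases, which have sign/rotation ambiguity),
so deviations stay smooth.  The ground truth is analytic: at any instant
the injected covariance is σ²_gev·P_null + σ²_ngev·P_orth, so GEV and NGEV
equal the squared sigmas up to forward-kinematics linearisation error.
Smoothness comes from Gaussian-kernel filtering of white noise, rescaled
by the exact kernel factor (not empirically), so the instantaneous
variance is exact in expectation.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| segment lengths | 300/250/80/70 mm | adult right arm |
| sigma_gev | 2° per null dimension | 4:1 std ratio with sigma_ngev — the goal-equivalent dominance typical of stabilised pointing |
| sigma_ngev | 0.5° per orthogonal dimension | gives ~5–7 mm endpoint error at the fingertip, the magnitude reported for this task |
| temporal_smoothness | 0.25 s | slow postural drift, not sample-to-sample jitter; keeps threshold detection usable on noisy trials |
| movement_time | 0.7 s | peak speed 1.875·300/0.7 ≈ 0.80 m/s and phase times of ~0.3 s, inside the envelope reported for seated 30 cm reaches |
| pre/post holds | 0.3 / 0.6 s | sub-threshold data on both sides of the reach so bounds detection is exercised |
| start point | (215, 0, −300) mm | targets at ≤ ~87 % of chain length in every condition; elbow flexion runs ~118°→64° over the finger-condition reach, matching seated pointing |

Two physical constraints of the emulated experiment shape the noise
envelope: the start posture is clamped (tip on the start dot, elbow on a
placer), so deviations ramp in smoothly from zero at movement onset to
full amplitude by mid-movement; and each trial comes to rest on its own
landing spot until the end-of-trial signal, so the deviation freezes at
its movement-end value during the post-hold.  The envelope is 1 at the
movement end, so the injected variance at the 100 % instant is exactly
σ² per dimension.

### What the generator does and does not emulate

It reproduces the design's geometry, trial counts, sampling, and a
controllable goal-equivalent/non-goal-equivalent split with analytic
truth.  It does **not** model feedback corrections, signal-dependent motor
noise, rod inertia, or the condition-dependent structure of real
joint-space covariance.  Two visible consequences:

1. Real pointing is feedback-corrected, so real endpoint scatter stays
   well inside the 10 mm target criterion.  Open-loop joint noise of 0.5°
   per orthogonal dimension instead puts 30–70 % of trials (more for
   longer rods, whose lever arms amplify joint noise at the tip) outside
   that radius at the movement end; those trials fail end detection and
   are logged and counted by the pipeline, never silently dropped.
   Passing tests therefore show the pipeline's bookkeeping and the
   decomposition's correctness — not that the noise model is a faithful
   portrait of human endpoint control.
2. Analysing only trials that pass the 10 mm criterion conditions the
   ensemble on small orthogonal deviations and biases NGEV at the 100 %
   instant low (roughly −30 % at the default noise level).  The
   detection-based path is the study-faithful analysis and remains the
   pipeline default; generator validation (parameter recovery) uses
   `estimate_ucm`, which evaluates the ensemble at the reference
   movement-end sample without detection and recovers the injected
   variances to within sampling error (~1 % bias at 500 trials).

## Numerical choices

- Jacobian step 1e-6 rad (central differences); SVD rank cut 1e-10
  relative.
- Damped least-squares IK: λ = 0.01, ≤ 200 iterations per sample, step
  norm capped at 0.3 rad; unreachable samples raise naming the sample,
  non-convergence raises with the residual.
- Ties at the velocity maximum break to the earliest sample.
- Trial CSVs store angles in degrees at 10 significant digits; re-running
  a pipeline with the same config is byte-identical.
- Seeds: every stochastic step takes an explicit seed; the pipeline
  derives per-condition seeds as `seed + condition_index`.

## Scope and limitations

- Descriptive aggregation only: the pipeline stops at means/SDs per
  condition.  Inferential statistics (repeated-measures ANOVA, post-hoc
  corrections, effect sizes) are deliberately out of scope.
- Marker-based reconstruction of joint angles from motion-capture rigid
  bodies is out of scope; the package starts from joint-angle and tip
  trajectories.
- Anatomical joint limits and dynamics (torques, rod mass/inertia) are not
  modelled.
- The printed group statistics of the motion-capture study this design
  mirrors come from 15 human participants and are not reproducible from
  synthetic data; correctness here rests on the mathematical properties
  and recovery results computed by the test suite and
  `scripts/acceptance.py`.
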