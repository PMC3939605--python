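# Methods

## Arm model

The arm is a serial Denavit–Hartenberg chain of seven links: three
prismatic links carry the spatial position of the shoulder (so that
shoulder translation can be fed into the dynamics as prescribed motion),
three revolute links realize a spherical shoulder (adduction, flexion,
external rotation) and one revolute link the elbow flexion.  Joint
angles are zero at the reference start posture — upper arm vertical
along the trunk, elbow flexed 90° (elbow-flexion joint value π/2 at that
posture).  All public kinematics are expressed in a gravity-aligned
world frame (z up); the D-H base frame differs from it by a fixed axis
permutation chosen so that the three prismatic joint values equal the
world coordinates of the shoulder.

Segment parameters come from published anthropometric regressions in the
subject's height H (cm) and weight W (kg): segment lengths as fixed
height fractions (upper arm 0.186 H, forearm+hand link 0.252 H, forearm
bone 0.146 H) and masses / CoM positions / principal moments of inertia
from the Zatsiorsky–Seluyanov regression family (e.g. upper-arm mass
0.250 + 0.03012 W − 0.0027 H kg).  Forearm, hand, and the 0.18 kg handle
the subject grips are lumped into a single rigid body: the handle mass
is added at the hand CoM, the composite CoM is the mass-weighted mean,
and the inertia tensors combine by the parallel-axis theorem about the
composite CoM.  Inertia tensors are diagonal in the segment frame with
the longitudinal axis along the segment; the mediolateral (transverse)
principal axis is the elbow-flexion axis.  The longitudinal composite
moment reproduces published per-subject tables exactly; the composite
CoM and the two transverse moments come out 10–25% lower than those
tables, whose exact composition rule is not recoverable — this affects
absolute torque amplitudes slightly but none of the dimensionality
conclusions, which are invariant to channel scaling.

Internal units are SI throughout; the table units (cm, kg·cm²) are used
only by `segment_parameter_table` for comparison against printed values.

## Kinematics

Joint angles are extracted segment by segment: shoulder adduction and
flexion from the shoulder→elbow marker vector, external rotation and
elbow flexion from the elbow→wrist vector (mean of the two wrist
markers), each via a quadrant-safe two-argument arctangent of the vector
expressed in the frame of the joint's rotation axis.  Each two-angle
pair has a two-fold branch ambiguity; it is resolved by continuity with
the previous sample, starting from a reference posture.  The composition
`compute_joint_angles ∘ forward_kinematics` is the identity to < 1e-6
rad, which is the contract the implementation is tested against.

Velocities and accelerations are central differences (one-sided at the
edges).  Movement onset and end are the outermost crossings of 10% of
the peak endpoint speed around the global peak, on the 15 Hz zero-phase
FIR-filtered endpoint trajectory; crossing times are refined by linear
interpolation.  FIR filters are odd-length windows of ≈0.1 s applied
forward-backward (`filtfilt`), so they are zero-phase; exact filter
orders are free parameters because all downstream contracts are
round-trip and event properties, not bit-exact filter output.

## Dynamics

Inverse dynamics is a recursive Newton–Euler pass vectorized over time
samples and carried out in the base frame: angular velocity/acceleration
and CoM accelerations propagate outward; forces and moments, accumulated
about the base origin, propagate inward; each joint's generalized force
is the projection of the inter-link wrench onto the joint axis.  Gravity
(9.81 m/s² along −z) enters as a fictitious base acceleration, so the
output is the full τ = M(q)q̈ + C(q,q̇)q̇ + G(q).  The implementation is
validated against an independent Lagrangian oracle (mass matrix from
geometric Jacobians, Christoffel terms by finite differences of the
mass matrix, gravity from the potential-energy gradient) to 1e-6 N·m on
random states.  G(q) is re-evaluated with zero velocities to split total
torques into gravitational and dynamic components.

Forward dynamics integrates the four revolute DoF with an adaptive
Runge–Kutta (rtol 1e-8, atol 1e-10), linearly interpolated torques, and
the shoulder translation prescribed kinematically (it carries no mass).
The mass matrix inside the right-hand side is assembled from link
Jacobians for speed; it is the same model quantity the RNE computes.
The inverse→forward round trip is evaluated per condition on
repetition-averaged trajectories (angles aligned on movement onset, as
in the torque pipeline) over a window from 0.25 s before onset to 0.25 s
after end — the holds outside that window are static and add integration
time without information.  R² is reported per joint with SSE and SST
pooled over conditions: in conditions where a joint does not move at
all (straight up/down frontal reaches leave adduction and external
rotation at zero) a per-condition R² would be a ratio of noise over
noise with no meaning.

## Preprocessing

EMG: full-wave rectification, 20 Hz zero-phase FIR, mean over
non-overlapping 10 ms bins ("integrated over 10 ms" read as bin
averaging to 100 Hz).  Repetitions are aligned on movement onset and
averaged sample-wise over the common support.  The tonic (anti-gravity)
component is modeled as a constant level before onset, a constant after
end, and a linear ramp in between; levels are means over the padding
windows excluding a 50 ms margin around the events (the estimation
window is not otherwise constrained).  The fraction of negative area
remaining after subtraction is recorded before clipping; clipping to
zero is applied for NMF, while the unclipped patterns are kept for the
gradient-descent comparison.  Every condition average is resampled by
linear interpolation to 100 samples — 50 per movement time, from 0.5 MT
before onset, so samples 25 and 75 fall on onset and end.  Channels with
artifacts are handled by an explicit drop list, not an automatic
detector.

## Decomposition

Three arrangements of the D×T×K (channels × 100 samples × conditions)
processed data: spatial D×(T·K), temporal T×(D·K), spatiotemporal
(D·T)×K with channel-major flattening.  R² = 1 − SSE/SST with SST about
the row means of the data matrix, so the 0-generator reconstruction (row
means) scores exactly 0.

* **PCA** (torques): SVD of the row-mean-centered matrix; reconstruction
  includes the row-mean offset; R² increments equal normalized
  eigenvalue shares.  Generator signs are fixed so the largest-magnitude
  element is positive.
* **NMF** (muscle patterns): Lee–Seung multiplicative updates on the
  Frobenius error, best of 20 random restarts (run r seeded with
  seed + r), each run stopping when the R² gain per iteration stays
  below 1e-4 for five consecutive iterations.  Generators are returned
  unit-norm with compensated coefficients.
* **Gradient descent** (unclipped signed patterns): alternating gradient
  steps with fixed per-arrangement step sizes (coefficients 0.05 and
  synergies 0.0005 in the spatial/spatiotemporal cases; weights 0.0018
  and temporal components 0.0019 in the temporal case) and a penalty
  λ·Σ min(0, W)² (λ = 1) on negative synergy values.  Two numerical
  choices matter: the data are scaled to unit maximum absolute value,
  and the synergy columns are re-projected to unit norm after every
  update (coefficients compensated).  Without the projection the
  penalty is vacuous — the optimizer shrinks the synergies and grows
  the coefficients, leaving the penalty near zero while rotated
  factorizations persist.  Because the step sizes were originally tuned
  to a particular data scale, a global step-scale factor is applied;
  its default (8) was selected the same way the step sizes themselves
  were described as chosen — the value giving the highest reconstruction
  R² short of divergence.  No attempt is made to replicate exact
  optimization trajectories.

## Number of generators

* **Threshold**: smallest N with R² ≥ 0.90.
* **Knee**: smallest N whose curve tail (N to the end, at least three
  points) has a linear-fit MSE < 1e-4 on the raw R² scale.  A 4-point
  spatial torque curve admits tails only at N = 1, 2, so the criterion
  is of limited use there and raises on curves shorter than 3.
* **Shuffle**: rows of the data matrix are independently permuted across
  columns, then low-pass filtered along the trial time axis to match the
  original smoothness (Butterworth cutoff at the frequency containing
  95% of the original mean non-DC spectral power; skipped if that is
  already near-Nyquist).  R² curves from 50 surrogates (5 restarts each
  for NMF, vs 20 on the original — the surrogate mean is insensitive to
  restart count) give reference increments; the selected N is the last
  point before the original increment falls below 75% of the mean
  shuffled increment at the same N (per-N comparison by default, pooled
  available as a toggle).

All three criteria are invariant to global rescaling of the data.

## Comparison

Cross-dataset reconstruction re-fits only the combination coefficients:
ordinary least squares about the target's row means for signed (PCA/GD)
generators, non-negative least squares per column for NMF generators.
Chance level is the 95th percentile of R² over 50 runs in which
generators extracted from row-shuffled data reconstruct the original.
Generator-set similarity is the mean |cosine| over the optimal pairing
(exhaustive for N ≤ 8, Hungarian otherwise), invariant to sign flips and
positive rescaling.  The synchrony (separability) index of a
spatiotemporal generator reshaped to D×T is σ₁²/Σσᵢ² of its singular
values — 1 exactly when the generator is an outer product of one
waveform and one weight vector.  The cross-talk simulation contaminates
each channel with an exponentially weighted (mean α = 0.1) copy of one
random other channel and recomputes the shuffle-criterion
dimensionality, 100 runs.

## Synthetic data

The generator emulates the study design: standing reaches between a
central start and 8 targets on a 15-cm circle in the frontal (y–z) and
sagittal (x–z) vertical planes, out and back, 5 repetitions — 160
trials.  Movement time is 0.35 s nominal (under the 400 ms task limit)
with ±10% uniform jitter across repetitions; 0.5 s holds surround the
movement; sampling is 120 Hz.  Reaches are minimum-jerk in task space
(straight path, bell-shaped speed, peak speed 15 d/8 MT); joint postures
along each path come from damped-Newton inverse kinematics with a
nullspace pull toward the start posture, precomputed on a 101-point path
grid per target and interpolated per repetition.  Marker noise is
additive Gaussian: 0.3 mm on the arm markers (optical tracker) and 2 mm
on the endpoint sphere (electromagnetic tracker) — the two tracking
systems differ by more than an order of magnitude in resolution and the
joint angles depend only on the optical markers.

Torque-like trials are built as signed condition weight vectors of
chosen spatial rank times a single zero-integral biphasic waveform
(derivative of a Gaussian) plus additive white Gaussian noise at 3% of
signal RMS — the synchronous, temporally one-dimensional structure that
fast reaches exhibit.  EMG-like trials are non-negative combinations of
smooth Gaussian-burst generators of the requested arrangement (with
optional per-muscle burst delays for asynchronous spatiotemporal
structure), plus a constant-and-ramp tonic component and multiplicative
truncated-Gaussian noise (sd 5% of the instantaneous level).

What the synthetic data do **not** emulate: soft-tissue marker
artifacts, EMG cross-talk between specific neighbor muscles, trial-to-
trial variability of the movement path, nonlinear muscle-to-torque
mappings, and systematic phasic inhibition below tonic level (negative
phasic area here arises from noise only, ≈7% of total area, versus
≈15% reported for real reaching EMG).  Passing tests therefore show the
pipeline's correctness and its behavior under the stated noise model,
not performance bounds on real recordings.

## Problem sizes used in tests

The validation suite favors small instances chosen to exercise every
code path: sessions of 4–8 conditions with 2–5 repetitions for dynamics
round trips, 20 seeds × 32 conditions for dimensionality recovery,
16 model perturbations (±5/10/15/20% in mass and height) × 3
arrangements for the robustness check, and 4 synthetic sessions for the
clipping comparison.  The acceptance script runs the frontal-plane
8-target session at the full 5 repetitions.

## Known limitations

* The composite forearm+hand+handle CoM/inertia composition cannot be
  matched exactly to published per-subject tables (see Arm model).
* The gradient-descent factorization retains a rotational gauge freedom
  (signed coefficients); on synthetic data its generators match NMF's at
  0.83–0.96 per session, mean ≈0.9 — the same spread reported for real
  data — so single-session similarity values should be interpreted
  against that variability.
* The knee criterion's 1e-4 MSE threshold is applied on the raw R²
  scale regardless of curve length; for very short curves the tail fit
  has few points and the criterion is correspondingly coarse.
* `run_emg_analysis` analyses synthetic sessions; feeding recorded EMG
  CSV files reuses the same preprocessing functions but the top-level
  orchestration assumes the study's condition structure.
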