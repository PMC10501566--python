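# Methods

## The problem

During a ski-jumping take-off the jumper extends from a deep crouch while
travelling down the table at roughly 23 m/s.  The quantities that matter for
performance — the ground reaction force (GRF), joint torques, and the
activity of the leg extensors — cannot be measured directly on the hill:
force plates cannot be built into the table and athletes cannot carry EMG
equipment.  This package reconstructs all of them from motion alone, using a
rigid-body model, an iterative inverse-dynamics GRF estimator, a
posture-indexed aerodynamic database, and per-frame static optimization of
muscle activations.

## Model

A model is a tree of rigid segments joined by one free 6-DoF base joint
(ground to pelvis) plus ball, pin and locked joints.  Locked joints carry a
fixed transform and contribute no generalized coordinates — used for joints
(e.g. subtalar, metatarsal-phalangeal) whose motion the available kinematics
cannot resolve.  The bundled 3-D model has 9 segments (pelvis, torso,
head+arms lump, both thighs, shanks and feet), 16 coordinates, and 16
lower-limb muscles representing the functional groups of the take-off
(soleus, medial gastrocnemius, tibialis anterior, vasti, rectus femoris,
gluteus maximus, biceps femoris long head, semimembranosus, per leg).
Masses follow standard anthropometric fractions of a 62 kg, 1.70 m subject.
A planar 4-segment model is bundled for hand-checkable fixtures.

The table frame is right-handed: x down the in-run, y perpendicular to the
table, z to the jumper's right.  Angles are radians internally and degrees
in every file.

**Subject scaling.**  Lengths (and all attached points) scale by
height/1.70; masses scale so the total equals the subject mass while
preserving fractions (conserved to 1e−9 kg); inertias scale by
(mass ratio)·(length ratio)².  Maximum isometric forces are optionally
doubled — professional jumpers versus the generic population — and then
multiplied by s = (m·h)/(m₀·h₀), the standard muscle-volume
proportionality; the factor can be overridden.  Whether inertial properties
should be subject-scaled beyond the default is genuinely open; we scale them
as stated and note that alternatives (e.g. regression-based per-segment
inertia) plug in by editing the model file.

## Dynamics

Inverse dynamics is a recursive Newton–Euler sweep in Featherstone spatial
algebra over an elementary-joint decomposition (free joint → 3 prismatic +
3 revolute; ball → 3 revolute).  Gravity enters through the base
acceleration.  The wrench transmitted through the base joint — the force and
torque the model would need applied at the pelvis to reconcile motion and
loads — is reported separately as the **residual** in the ground frame at
the pelvis origin; this makes the component-wise residual-to-GRF transfer of
the estimator well defined.  Forward dynamics solves M(q)q̈ = τ + ext − bias
with the mass matrix assembled from unit-acceleration inverse-dynamics
calls; it exists as the oracle for round-trip tests (consistency to ~1e−13
on random states) and for the synthetic generator, not as a simulation
engine.  Verified against the closed-form pendulum (torque m·g·l·sinθ
exactly; energy drift < 1e−6 relative over 0.1 s at integrator tolerance
1e−9).

## GRF estimation

All twelve per-leg components start at zero, applied at the "proximal
second metatarsal" station of each foot.  Each iteration runs inverse
dynamics with the current loads, then adds half of each residual component
to the matching component of both legs (the two legs are assumed to share
the load equally, so their trajectories stay bitwise identical).  The
convergence metric is the mean over active components of the RMS-over-time
of the residuals, with the published threshold 0.001 (N and N·m mixed, as
the metric is defined).  Because the residual is affine in the applied
loads and the transfer map is nilpotent (forces correct the force balance in
one step, the induced moment error is corrected the next), the iteration
typically terminates in two or three sweeps with residuals at round-off
level; the 500-iteration cap and a divergence monitor (10 consecutive
increases aborts) exist for inconsistent inputs.  Non-convergence returns a
flagged result with a warning, never a silent success.

In the constrained take-off mode, F_z and all moments are held at zero
(skis clamp the feet, the table reacts only normally and along the track),
F_y is iterated as above, and F_x is refreshed each iteration as
−μ·F_y — kinetic friction opposing the downhill +x sliding, with μ
configurable in sign and magnitude.  μ defaults to the printed 0.018; a
friction angle input (μ = tan angle) is also accepted, and tan 1° ≈ 0.01746
— the small discrepancy with the printed coefficient is left to the user.
Convergence is assessed on F_y only: F_x is slaved, not residual-driven,
and the ignored components' residuals cannot be annulled by construction;
the active set is recorded in the result metadata and configurable.
Negative F_y frames (ground pull) are flagged but not clamped, preserving
the arithmetic of the update rule.

`compare_grf` resamples the (faster) force-plate record onto the estimate's
time base by linear interpolation and reports per-axis RMSE, optionally
normalized to body weight.

## Aerodynamics

The database stores, per posture, a force and moment 3-vector for each of
10 body parts (left/right calves, thighs, forearms, upper arms, trunk,
head) at reference conditions: 1.70 m jumper, 23 m/s flow, air density
carried in the header (default 1.225 kg/m³, since the reference density is
a property of the CFD campaign that produced a real database).  The
reference grid is block-structured by knee angle δ2: take-off blocks
(δ2 = 90/120/150°) vary trunk–thigh angle δ3 and ankle angle δ1 with arms
down and skis parallel; early-flight blocks (δ2 = 150/180°) additionally
vary ski spread θ1, leg spread θ2, arm–trunk angle δ4 and angle of attack
α — 8 + 10 + 4 + 128 + 128 = 278 postures.

Queries interpolate multilinearly within a δ2 block (single-valued axes
pass through; out-of-range coordinates clamp to the boundary with a
warning) and blend linearly between the two bracketing δ2 levels.  Two
design choices resolve underdetermined corners of the scheme: (a) blending
across δ2 rather than snapping to the nearest block, for continuity; and
(b) where two blocks share a δ2 level (150° appears in both phases with
disjoint δ3 ranges), the block needing the least clamping of the query is
used, which preserves bitwise exactness at every stored node.  Multilinear
interpolation is exact for affine databases — the basis of the exactness
tests.  Interpolation and scaling are linear, so the part-sum invariant
(Σ parts = whole body) survives both.

Per-part forces map to model segments (calf+ski → shank, arm parts → the
head+arms lump on the bundled model) and are applied at the segment COM in
the ground frame — the pressure centers of a real CFD campaign are not part
of the schema, and the application point is configurable per part.  CFD
moments are carried through the schema but applied only on request
(default off), since their downstream use is not established.  The speed in
the quadratic law defaults to the whole-body COM speed per frame; a scalar
(the in-run speed) can be supplied instead.

## Kinematics

IK solves each frame as a weighted nonlinear least squares over all
coordinates (Levenberg–Marquardt, warm-started from the previous frame;
mirror-pose ties are broken by that warm start), reporting per-frame RMS
marker error.  Missing (NaN) markers drop out per frame; fewer than 6
usable markers raises an underdetermined-frame error.  Differentiation
low-passes with a zero-phase 2nd-order Butterworth (4th-order effective;
default cutoff 10 Hz at 120 fps — field pose estimates are unusable under
double differentiation without it) and uses central differences, one-sided
at the ends.  `cutoff_hz=None` skips filtering for already-smooth synthetic
data.

The seven posture angles are computed from marker geometry in degrees:
δ2 is the interior knee angle (180° = straight), δ1 the angle between the
shank axis and the heel→toe ski axis, δ3 trunk versus thigh, δ4 arm versus
trunk (0° for the bundled arm-less models), θ1 between the two ski axes, θ2
between the two leg axes; bilateral angles average left and right.  The
angle of attack α is taken between the instantaneous COM-velocity direction
and the plane of the skis — the flight-phase definition applied during
take-off; defining it against the table plane instead is a one-line change
in the extractor, and at zero speed α is reported as 0.  All angles except
α are invariant to global translation and rotation about the table normal
(property-tested).

## Static optimization

Per frame, minimize Σ aᵢ² + w Σ ρⱼ² subject to
Σ aᵢ·Fᵢmax·f_l·f_v·r_ij + ρⱼ·T_res = τⱼ and 0 ≤ aᵢ ≤ 1, with reserve
actuators (T_res = 1 N·m, w = 1000) guaranteeing feasibility and exposing
modeling gaps; reserves above 1 N·m trigger a prominent warning.  The QP
has a strictly positive diagonal Hessian, so it is solved exactly by a
small active-set method (closed-form KKT solve per working set); solutions
satisfy the torque balance and KKT optimality to ~1e−10, and an SLSQP
cross-check runs in the test suite.  Moment arms use the tendon-excursion
definition r_ij = −∂L/∂q_j with central differences (step 1e−6 rad) on
straight-line via-point paths; coordinates a muscle cannot structurally
span are exact zeros.  No wrapping surfaces are modeled — via points are
placed (ischial and patellar stations) so lines of action stay on the
anatomically correct side of each joint through the take-off range; the
closed-form check uses the chord geometry the schema actually supports
(symmetric via points at radius r give arm r·cos(q/2)).

The force model defaults to ideal (F = a·Fmax).  An optional rigid-tendon
mode multiplies by a Gaussian force-length factor exp(−(l̃−1)²/0.45) on the
normalized path length and a hyperbolic force-velocity factor (concentric
zero at the maximum shortening rate, eccentric capped at 1.4); these
inherit from common muscle-model practice and are logged in the solution
metadata.  Frames are independent — classical static optimization with no
activation dynamics, appropriate for a 0.1 s window.  Activations are raw
[0, 1]; no EMG-style normalization is applied.

## Synthetic data

The generator defines the test conditions: a 0.1 s window at 120 fps, a
crouch (knee interior 110°, trunk near horizontal, pelvis at 0.59 m) that
extends toward release, travelling at 23 m/s.  All coordinates follow
minimum-jerk profiles with closed-form derivatives, so no numerical
differentiation enters the ground-truth path.  Two deliberate geometric
choices: the ankle endpoints equal −(pelvis pitch + hip + knee), which —
because every coordinate shares the same profile shape — keeps the feet
exactly flat on the table at every instant, as skis are; and the profile
spans 0.3 s (a realistic full extension) of which the window is the
accelerating first third, so the normal force stays positive throughout, as
it must while the skis press on the table.  Peak total vertical force is
then ≈ 4 body weight — an explosive but plausible drive.

Ground truth: one inverse-dynamics call with no contact loads yields the
required external wrench at the pelvis; forces are split evenly between the
legs and the moment balance is transported to the foot application points.
Feeding the result back through inverse dynamics leaves residuals at
machine precision, and its net force equals the independent Σ mₖ(aₖ − g)
oracle.  Markers are model joint centers plus seeded Gaussian noise; every
artifact carries its generator parameters and seed in metadata.

What the generator does *not* emulate: soft-tissue artifact and
pose-estimator bias (its noise is isotropic and white), asymmetric
left/right technique, the decaying-to-zero normal force right at release,
ski flex, or wind.  Passing tests therefore demonstrate correctness of the
algorithms under dynamically consistent input, not field-grade accuracy;
with real data the kinematic error budget dominates.

Aerodynamic databases are filled from a smooth analytic whole-body force
function (defaults of the order of the take-off regime: drag tens of
newtons at 23 m/s, growing with trunk inclination and flexion), split
across the 10 parts by fixed fractions summing to 1 (trunk 0.30, calves
0.14 each — the parts that dominate in practice).

## Problem sizes and tolerances

The bundled scenario is 13 frames × 16 coordinates; the full pipeline runs
in seconds and the whole test suite in well under a minute.  Key numerical
settings: IK solver tolerances 1e−14 (exact recovery to <1e−6 rad on
noise-free markers), GRF threshold 0.001 as published, moment-arm step
1e−6 rad, QP feasibility/optimality tolerances 1e−10, forward-dynamics
oracle integrated at rtol 1e−9.  File writers serialize floats at %.17g so
every table round-trips bitwise.

## Known limitations

No closed kinematic loops, contact model or wobbling masses; straight-line
muscle paths without wrapping; the equal left/right load split is assumed,
not estimated; the friction law is kinetic and sign-fixed (configurable);
the head+arms lump makes δ4 degenerate on the bundled model; and the
residual-redistribution estimator inherits the quality of the differentiated
kinematics — garbage accelerations in, garbage forces out, which is why the
filter settings are part of every output's metadata.
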