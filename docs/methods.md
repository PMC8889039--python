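# Methods

This note documents the model behind `treadpush`: what is simulated, which
parameters matter, which choices were open and how they were made, and
what the synthetic study conditions do and do not say about real walking.

## Walking model

A sagittal-plane chain of 10 rigid segments — head-arms-trunk (HAT),
pelvis, and paired thighs, shanks, feet and toes — connected by 9 rotary
joints (lumbo-sacral, hips, knees, ankles, metatarsophalangeal). The
floating pelvis contributes 3 coordinates, for 12 generalized coordinates
in total. Conventions, used everywhere: world x anterior, y up; the belt
surface is y = 0 moving at −1.18 m/s; hip flexion, knee flexion, ankle
dorsiflexion and toe extension are positive; in the zero configuration the
model stands upright with flat feet.

Inertial parameters are de Leva-style anthropometric regressions scaled to
a configurable body mass (default 70 kg) and height (1.73 m): segment mass
fractions pelvis 11.2 %, thigh 14.2 %, shank 4.3 %, foot 1.2 %, toes
0.14 % (HAT takes the remainder, ~49 %), with literature radii of gyration.
The worn device adds 0.8 kg on the right leg, split 0.3 kg to the shank and
0.5 kg to the foot at the segment centers of mass (the split is
configurable; only the total is physically constrained by the design).

Equations of motion are evaluated numerically by a planar recursive
Newton–Euler inverse-dynamics pass; the mass matrix is assembled from
unit-acceleration calls and accelerations solve `M(q) q̈ = Q − h(q, q̇)`.
The kernels are numba-compiled. Two independent checks pin this core down:
free-flight mechanical energy is conserved to ~3×10⁻¹⁰ of the initial
energy per second, and a free-floating thigh+shank double pendulum agrees
with a symbolically derived (sympy) Lagrangian formulation to ~10⁻¹⁵
relative error.

The metatarsophalangeal joints are passive rotary springs
(12 N·m/rad, 1.5 N·m·s/rad): stiff enough to transmit the forefoot roll,
compliant enough for ~30–45° of toe extension at push-off.

## Foot–ground contact

Three spheres per foot-toes pair (heel, toe joint, toe tip; radius
2.5 cm, bottoms flush with the sole). Normal force is Hunt–Crossley,
`F_n = k δ^1.5 (1 + c δ̇)` clamped at zero, with k = 2×10⁶ N/m^1.5 and
c = 2 s/m — at body weight on one foot this gives ~4 mm of penetration and
a well-damped heel-strike transient. Friction opposes the sphere's
velocity *relative to the belt surface* through
`F_t = −μ F_n tanh(v_rel / v_s)` with μ = 0.9 and v_s = 0.01 m/s. The
belt-relative formulation matters: it is what lets the belt do work on the
planted foot, which is the energy the device harvests; the regularization
avoids stick-slip complementarity at the cost of ~5 mm/s of creep at
half-cone load (0.4 % of belt speed). Heel strikes produce 3–5 body-weight
force spikes; these are deliberate — the series are unfiltered so brake
events stay sharp — and they do not touch the 40–60 % analysis window.

## Reference kinematics

The reference is built constructively rather than taken from a recorded
subject, so that it is exactly consistent with the belt:

1. a task-space stride for each leg: near-flat initial contact
   (8.6° toes-up) whose heel point rides the belt through a short rocker,
   a flat-foot phase riding the belt, a forefoot roll about the toe-joint
   contact (pitch to −46° over 12 % of stride — the push-off proper) with
   the toe contact riding the belt until toe-off, and a clearance-shaped
   swing whose final 8 % descends along the belt-speed line so touch-down
   meets the belt with matched horizontal velocity;
2. a smooth pelvis-height curve: a single-harmonic wave (two oscillations
   per stride, amplitude 2 cm) fitted just under the leg-reach envelope,
   with maxima in mid single-stance so the pelvis descends through each
   landing — this phase choice prevents the trailing leg from launching
   the model into flight at the step-to-step transition;
3. inverse kinematics to hip/knee/ankle angles on a dense phase grid
   (task-space curves are Gaussian-smoothed, σ = 1 % of stride, *before*
   IK — smoothing joint angles directly would break foot–belt velocity
   consistency at the contact-phase kinks), then a 20-harmonic Fourier fit
   per joint. The left leg is the right leg shifted by exactly 50 %.

Nominal event phases: builder heel strike 12 % (the simulated strike lands
at ~10 %, the convention's target, once tracking sag and pitch are in
play), flat foot by 19 %, roll from 47 %, toe-off 62 %. Stride phase 0 % is
the leg's most anterior position. Toe-off at 62 % gives ~2–4 % of double
support per side; with less overlap the landing braking impulse has no
concurrent push-off to cancel it and the trunk pitch ratchets over a few
steps until the model falls. Stride length relative to the belt is
speed × cycle = 1.43 m by construction.

Users can replace the synthetic pattern with their own kinematics
(`read_reference`) as a phase/angle table; periodicity is checked.

## Control

* Per-joint PID on hips, knees and ankles against the reference
  (kp/ki/kd: hips 3200/400/220, knees 2600/300/90, ankles 2100/300/55;
  integral contribution clamped at ±60 N·m with conditional anti-windup).
  Gains were sized for near-critical damping against distal-chain inertia
  estimates, tuned once on the baseline gait and frozen. These torques are
  the reported "biological torques". There is no torque saturation: the
  model may respond to perturbations with instantaneous torque.
* Trunk-upright PD on the HAT world orientation, applied at the
  lumbo-sacral joint (1500 N·m/rad, 260 N·m·s/rad).
* Pelvis-pitch posture feedback — the floating-base orientation is
  otherwise unregulated: a PD (1500/450) applied through the hip actuators
  (whose reaction acts on the pelvis) plus a weight-scheduled term through
  the loaded ankle (900/0 × instantaneous foot load), which shifts the
  center of pressure under the stance foot. This is the actuator that
  actually stabilizes trunk pitch.
* Treadmill station keeping: a stance-hip torque bias
  (400 N·m/m, 200 N·m·s/m, clamped at ±60 N·m, load-scheduled) toward the
  treadmill origin. Fore–aft position on a treadmill is neutrally stable;
  without this loop the model drifts ~0.1 m/s backwards.

The posture and station-keeping loops are this package's additions: pure
joint tracking plus trunk feedback — the textbook description of such
models — leaves two unregulated floating-base modes that must be closed
somehow; a model driven by manually pre-stabilized recorded kinematics can
hide this, a synthetic one cannot. Their torques route through the hip and
ankle actuators and are therefore part of the reported joint torques.

## The assistance mechanism

While the brake is engaged, the elastic tendon's elongation is referenced
to the lengths captured at the engagement instant:

    e = max(0, [d(t) − d₀] + ρ · [l(t) − l₀])

where d is the anchor–spool distance, l the shank-attachment–spool
distance, and ρ = 5 the outer/inner spool radius ratio. Pretension is
exactly zero at engagement (consistent with neglecting the constant-force
spring that only keeps the tendon taut). The elastic force
`F = m_body · k · e ≥ 0` (unilateral; k in N/m per kg body mass) pulls the
spool-axis point on the foot toward the anchor; the rigid tendon carries
ρ·F, pulling the spool point and the shank attachment together. Both
attachments sit posterior to the ankle, so rigid-tendon tension is a pure
plantarflexor. Brake switching is instantaneous and scheduled open-loop on
the stride phase of the assisted leg; at disengagement the residual tendon
energy is logged as dissipated (in hardware, an eddy-current damper's
job). Tendon mass, pulley inertia, wrapping friction and brake transients
are neglected.

Geometry defaults: anchor at belt height 1.0 m anterior of the treadmill
origin; spool axis at (−0.115, −0.03) m in the foot frame and shank
attachment 0.12 m posterior, 0.10 m above the ankle. The attachment
offsets (free design parameters of the device concept, as is the anchor
position) were calibrated once so that the reference ACTIVE condition
(4.85 N/m/kg, engage 29 %, disengage 53 %) supplies ~41 % of the push-off
work; every other condition in the sweeps is then a prediction of the
model, not a calibration.

Energy bookkeeping is verified in the tests: while engaged, ½·k·m·e²
matches the net work the device forces do on the body to within the
sampling tolerance, the tendon never pushes, and energy returned never
exceeds energy harvested.

## Metrics

* **Positive ankle work**: trapezoidal integral of the positive part of
  the biological ankle power (torque × joint velocity, per kg) over
  40–60 % of stride, on a 0.1 %-phase grid of the third of the four
  chained cycles (steady state, clear of start-up and terminal
  transients).
* **Reduction %**: relative to NO-EXO. Phase intervals where the assisted
  condition would require *additional negative* ankle power compared to
  NO-EXO are not counted as adequate assistance and are excluded from the
  calculation on both sides (the reduction compares countable work only).
* **Power-burst support**: phases with positive ankle power above 5 % of
  its peak — the floor separates the push-off burst from heel-strike
  transients and small swing reorientation power.
* **Gait speed**: distance between successive same-foot heel-strike
  footprints in the belt frame, divided by the time between them.
* **Events**: threshold crossings of per-sphere normal force at 1 % of
  body weight; a fall is the pelvis dropping below 60 % of its standing
  height and terminates the run.
* **Representative solution**: of four repeated optimizations, the one
  with the largest summed torque-profile L2 distance to the others is the
  outlier and is discarded; of the remaining three the middle profile
  (smallest summed distance — the medoid) is the representative.

## Optimization

Fitness is a weighted sum (defaults all 1) of five criteria, each
dimensionless against the NO-EXO baseline: time-until-fall penalty,
belt-relative distance error, vertical GRF impulse within ±2 % of stride
around heel strikes, total absolute joint power, and torque-profile L2
distance outside the assistance window. The GA (population 32, 40
generations, tournament 3, uniform crossover, Gaussian mutation σ = 10 %
of the bound, elitism 2, seeded) searches knot offsets of the hip, knee
and ankle references — 8 evenly-phased knots per joint, bounded at ±5°,
assisted side only by default — with the zero adjustment always in the
initial population. All GA hyperparameters are configurable; full-budget
GA runs on the real model are expensive (~1300 simulations) and the tests
exercise the GA on surrogate objectives plus the fitness components on
real simulations.

## Numerical choices

LSODA with rtol 10⁻⁶, atol 10⁻⁸, max step 5 ms (penalty contact is
stiff); trajectories are integrated piecewise between the pre-known brake
switching times, with the tendon-length snapshot captured at each
engagement; samples are stored on a 1000-per-cycle grid plus the segment
boundaries. Simulations are fully deterministic: identical inputs give
bit-identical results. A 4-cycle simulation takes ~5–10 s on one CPU after
JIT compilation; the sweeps reported by the test suite and the acceptance
script use single tracking-controlled runs per parameter triplet
(26 triplets across the three one-dimensional sweeps) rather than the
4-repeat GA pipeline, which is the package's desk-scale evaluation mode.

## What the synthetic conditions do and do not show

The generator emulates treadmill walking at 1.18 m/s with a 1.21 s cycle:
belt-consistent stance, heel strike at ~10 % of stride in the
most-anterior-leg phase convention, heel-off just after 50 %, a push-off
power burst confined to ~45–60 %, cycle-averaged vertical GRF equal to
body weight, and gait speed within 2 % of the belt. It does not reproduce
any specific subject: the baseline push-off work (~0.53 J/kg) and the
heel-strike force spikes are larger than typical human values, double
support (~2–4 %) is shorter, and there is no motor variability, muscle
dynamics or co-contraction — the model meets assistance with instant
torque adjustments a human cannot make.

Two consequences are worth stating plainly, because the test suite
reports them honestly as failures of the study-level magnitudes:

* **High-assistance saturation.** Under pure tracking (no kinematic
  re-optimization), reductions rise monotonically and near-linearly
  (R² ≈ 0.99) with stiffness up to 6.97 N/m/kg but saturate at the
  stiffest tendon (~50 % instead of the study-level ~75 %) and at the
  earliest engagement (~47 % instead of ~59 %): the ankle controller
  resists the surplus device torque (the biological torque flips
  dorsiflexor, ankle power goes negative, and the exclusion rule removes
  the credit). Re-optimizing the kinematics under assistance — which the
  full pipeline implements and the original study applied to every
  parameter triplet — is what unlocks these magnitudes.
* **Contralateral crosstalk.** Left-leg joint *kinematics* change by
  < 0.3° RMS under assistance, but left-leg torque profiles change by
  7–13 % of their peak (target: < 5 %): the device's anterior tether pull
  shifts the whole-body equilibrium and the posture/station-keeping loops
  spread the correction into both legs.

Timing conclusions are robust to all of this: premature brake release
(≤ 47 %) saves essentially nothing, release at 50 % saves ~14 %, the
on-time window (51–55 %) has a steep linear dose–response (R² ≈ 0.99,
slope ~8 % of push-off work per % of stride — several times the
engagement-timing sensitivity), and beyond ~58 % further delay has no
effect because the tendon has already emptied.
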