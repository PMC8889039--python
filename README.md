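# treadpush

Planar gait simulation of a treadmill-energy-harvesting ankle exoskeleton
for push-off assistance.

## The problem

The ankle supplies the largest burst of positive work in walking — the
push-off late in stance — and it is precisely this burst that is weakened
in many neurological patients. A proposed class of rehabilitation devices
harvests energy from the treadmill the patient is already walking on:
while the foot is planted, the belt carries it posteriorly, away from a
fixed anchor in front of the treadmill. If a brake clamps the proximal end
of an elastic tendon connecting the anchor to the foot, that motion (plus
the ankle's stance-phase dorsiflexion, geared up by a 5:1 three-spool
transmission on the foot) stretches the tendon. When the heel rises, the
stored energy recoils through the transmission's rigid tendon — routed
behind the ankle like an artificial Achilles tendon — as plantarflexion
torque, precisely timed to the wearer's own push-off.

`treadpush` is a tool for exploring that concept *in silico*: which tendon
stiffnesses and brake engagement/disengagement timings give useful,
well-timed assistance?

## The model

* **Walker** — a 2-D sagittal-plane chain of 10 rigid segments (HAT,
  pelvis, paired thighs, shanks, feet, toes) with 12 generalized
  coordinates (floating pelvis + 9 rotary joints), torque-driven.
  Equations of motion are evaluated by a planar recursive Newton–Euler
  formulation compiled with numba and integrated with a stiff-capable
  variable-step scheme (LSODA).
* **Contact** — Hunt–Crossley spheres (heel, toe joint, toe tip per foot)
  against the moving belt, `F_n = k δ^1.5 (1 + c δ̇)`, with
  tanh-regularized Coulomb friction on the *belt-relative* velocity — the
  channel through which the treadmill does work on the foot.
* **Control** — per-joint PID tracking of periodic reference kinematics
  ("biological torques"), trunk-upright feedback at the lumbo-sacral
  joint, plus pelvis-pitch and treadmill station-keeping loops
  (see `docs/methods.md`).
* **Reference gait** — synthesized constructively: a belt-consistent
  task-space stride (flat-foot stance riding the belt at 1.18 m/s, heel
  rocker, forefoot roll, clearance-shaped swing) is inverse-kinematics'd
  into hip/knee/ankle trajectories and stored as truncated Fourier series
  over the 1.21 s cycle. Users can substitute their own kinematics from a
  delimited file.
* **Device** — ideal unilateral elastic tendon with snapshot-referenced
  elongation `e = max(0, Δd_anchor + 5·Δl_shank)`, rigid-tendon force
  `5 × F_elastic`, instantaneous brake switching scheduled on stride
  phase.
* **Analysis** — positive ankle work on 40–60 % of stride, reductions
  relative to the NO-EXO condition with a negative-power exclusion rule,
  the 616-triplet parameter sweep (8 stiffnesses × 7 engagement × 11
  disengagement timings), OLS/Pearson trend fits, and a seeded GA that
  adjusts the reference kinematics under assistance.

## A worked example

```python
from treadpush import ExoParams, make_reference, run_condition
from treadpush.sweep_analysis import pushoff_metrics

reference = make_reference(n_cycles=4)
baseline = run_condition("NO-EXO", reference=reference)
active = run_condition("ACTIVE", reference=reference,
                       exo_params=ExoParams(stiffness=4.85,
                                            engage_phase=29,
                                            disengage_phase=53))
w_act, w_base, reduction = pushoff_metrics(active, baseline)
```

Running `python examples/active_assistance.py` prints

```
biological positive ankle work 40-60 %: 0.527 J/kg without, 0.310 J/kg with assistance
-> the device supplies 41.1 % of the push-off work
peak elastic-tendon force: 1.63 N/kg, peak assistive ankle torque: 0.82 N m/kg
brake released at t = 0.641 s, residual tendon energy 16.0 J dissipated
```

i.e. with a 4.85 N/m/kg tendon engaged at 29 % and released at 53 % of
stride, the device takes over ~41 % of the biological push-off work; the
16 J left in the tendon at release would be dissipated by a damper in the
braking module. The other scripts in `examples/` walk through the
baseline gait's vital signs, the brake-release timing groups
(premature/on-time/overdue), and the kinematic-adjustment machinery.

A thin CLI wraps the same library calls:

```bash
treadpush simulate --exo on --triplet 4.85,29,53 --out active.csv
treadpush sweep --grid "0.91,4.85;29;44,53,62" --out sweep.csv
treadpush analyze --records sweep.csv
```

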