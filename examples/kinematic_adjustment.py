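"""Kinematic adjustment machinery: fitness and representative selection.

Under strong assistance the unassisted reference kinematics are no longer
ideal; a bounded adjustment of the hip/knee/ankle references is scored by a
five-criterion fitness (fall time, belt distance, heel-strike impulse,
total absolute power, torque similarity).  This example scores a hand-made
adjustment against the zero adjustment and demonstrates the four-repeat
representative-selection rule on synthetic torque profiles.  (The full GA
search, `ga_optimize`, runs the same evaluation inside a seeded genetic
algorithm.)
"""

import numpy as np

from treadpush import (
    ExoParams,
    FitnessWeights,
    KinematicAdjustment,
    fitness,
    make_reference,
    run_condition,
    select_representative,
)

reference = make_reference(n_cycles=4)
baseline = run_condition("NO-EXO", reference=reference)
exo = ExoParams(stiffness=4.85, engage_phase=29, disengage_phase=53)
weights = FitnessWeights()

for label, offsets in (("zero adjustment", np.zeros((3, 8))),
                       ("2 deg extra late-stance plantarflexion",
                        np.vstack([np.zeros((2, 8)),
                                   -np.deg2rad(2.0) * (np.arange(8) == 4)]))):
    adj = KinematicAdjustment(offsets)
    sim = run_condition("ACTIVE", reference=reference, exo_params=exo, adjustment=adj)
    scalar, comps = fitness(sim, baseline, weights, assistance_window=(29, 53))
    print(f"{label}: fitness {scalar:.3f} "
          f"(fall {comps['fall']:.2f}, torque-similarity {comps['torque_similarity']:.3f})")

# four repeated "solutions" with one outlier: the middle profile is chosen
profiles = [np.ones(50) * c for c in (0.0, 1.0, 2.0, 40.0)]
rep = select_representative(profiles)
print(f"representative of offsets (0, 1, 2, 40): offset {rep[0]:.0f} "
      "(outlier discarded, middle profile kept)")
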