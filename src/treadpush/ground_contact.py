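"""Penalty sphere-plane contact with belt-relative friction.

Normal force follows a Hunt-Crossley law, F_n = k * delta^e * (1 + c * ddot)
clamped at zero, so the force is continuous in both penetration and
penetration rate and vanishes at first touch.  Friction opposes the sphere's
velocity *relative to the moving belt* (surface velocity -belt_speed along
x) through a tanh-regularized Coulomb law |F_t| <= mu * F_n.  Using the
belt-relative velocity is essential: it is the channel through which the
treadmill does work on the stance foot and hence the energy the assistance
mechanism harvests.
"""

from __future__ import annotations

import numpy as np

from . import _core
from .config import ContactParams, ContactSphere  # re-exported domain types

__all__ = ["ContactParams", "ContactSphere", "contact_wrench"]


def contact_wrench(
    sphere_world_pos,
    sphere_world_vel,
    radius: float,
    belt_speed: float,
    params: ContactParams,
) -> tuple[float, float]:
    """Normal and friction force on one sphere from the plane y = 0.

    Returns ``(normal_force, friction_force)`` in N; the normal force acts
    along +y, the friction force along x.  Total function of its inputs: a
    sphere above the plane yields (0, 0).
    """
    pos = np.asarray(sphere_world_pos, dtype=float)
    vel = np.asarray(sphere_world_vel, dtype=float)
    fn, ft = _core.contact_force(
        float(pos[1]),
        float(vel[0]),
        float(vel[1]),
        float(radius),
        float(belt_speed),
        params.normal_stiffness,
        params.exponent,
        params.normal_damping,
        params.friction_coefficient,
        params.tangential_velocity_smoothing,
    )
    return float(fn), float(ft)
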