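"""The treadmill-energy-harvesting ankle assistance mechanism.

The device couples the wearer's foot to a fixed anchor in front of the
treadmill through an elastic tendon, a brake, and a three-spool transmission
on the foot.  While the brake is engaged the tendon's proximal end is fixed;
two motions then stretch it: the stance foot being carried posteriorly by
the belt (anchor-to-spool distance grows) and ankle dorsiflexion (the rigid
tendon from the shank unwinds the inner spool, winding the outer spools by
the spool ratio).  Elongation referenced to the engagement snapshot:

    e = max(0, [d(t) - d(t_engage)] + rho * [l(t) - l(t_engage)])

with d the anchor-spool distance, l the shank-attachment-spool distance and
rho the outer/inner spool radius ratio (5 by default).  The elastic tendon
is an ideal unilateral spring: F_el = m_body * k * e >= 0 pulls the spool
point toward the anchor, and the rigid tendon carries rho * F_el, pulling
the shank attachment and the spool axis together.  Both attachment points
sit posterior to the ankle, so rigid-tendon tension is a pure source of
plantarflexion torque.  Brake switching is instantaneous; a snapshot of the
two distances is captured at each engagement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ExoGeometry, ExoParams  # re-exported domain types

__all__ = [
    "ExoGeometry",
    "ExoParams",
    "BrakeState",
    "brake_update",
    "tendon_elongation",
    "exo_wrenches",
    "assist_torque",
]


@dataclass
class BrakeState:
    """Brake flag plus the tendon-length snapshot captured at engagement."""

    engaged: bool = False
    engage_snapshot: tuple[float, float] | None = None  # (d_anchor, l_shank) m

    def __post_init__(self):
        if self.engaged != (self.engage_snapshot is not None):
            raise ValueError("snapshot must be present iff engaged")


def _lengths(model, state, geometry: ExoGeometry) -> tuple[float, float]:
    spool = model.point_world("r_foot", geometry.spool_axis_local, state)
    sh = model.point_world("r_shank", geometry.shank_attachment_local, state)
    anchor = np.asarray(geometry.anchor_position, dtype=float)
    return float(np.hypot(*(anchor - spool))), float(np.hypot(*(sh - spool)))


def brake_update(
    phase: float,
    params: ExoParams,
    state: BrakeState,
    model=None,
    model_state=None,
    geometry: ExoGeometry | None = None,
) -> BrakeState:
    """Advance the brake state machine at the given stride phase (%).

    Engaged on the half-open interval [engage_phase, disengage_phase) of the
    exoskeleton-side stride; the snapshot is captured at the engagement
    transition (requires ``model`` and ``model_state``).  Idempotent within a
    cycle; a disabled exoskeleton never engages.
    """
    if not params.enabled:
        return BrakeState()
    p = phase % 100.0
    inside = params.engage_phase <= p < params.disengage_phase
    if inside and not state.engaged:
        if model is None or model_state is None:
            raise ValueError("engagement transition needs the model state for its snapshot")
        snap = _lengths(model, model_state, geometry or ExoGeometry())
        return BrakeState(engaged=True, engage_snapshot=snap)
    if not inside:
        return BrakeState()
    return state


def tendon_elongation(model, state, geometry: ExoGeometry, brake: BrakeState) -> float:
    """Elastic-tendon elongation (m); 0 whenever the brake is disengaged."""
    if not brake.engaged:
        return 0.0
    d, l = _lengths(model, state, geometry)
    d0, l0 = brake.engage_snapshot
    return max(0.0, (d - d0) + geometry.spool_ratio * (l - l0))


def exo_wrenches(
    model,
    state,
    geometry: ExoGeometry,
    params: ExoParams,
    brake: BrakeState,
    body_mass: float,
):
    """External wrenches on foot and shank: list of (segment, local_point,
    world force, torque).  Empty when slack or disengaged."""
    e = tendon_elongation(model, state, geometry, brake)
    if e <= 0.0:
        return []
    f_el = body_mass * params.stiffness * e
    spool = model.point_world("r_foot", geometry.spool_axis_local, state)
    sh = model.point_world("r_shank", geometry.shank_attachment_local, state)
    anchor = np.asarray(geometry.anchor_position, dtype=float)
    u_anchor = (anchor - spool) / np.hypot(*(anchor - spool))
    u_shank = (sh - spool) / np.hypot(*(sh - spool))
    f_rig = geometry.spool_ratio * f_el
    return [
        ("r_foot", geometry.spool_axis_local, f_el * u_anchor, 0.0),
        ("r_foot", geometry.spool_axis_local, f_rig * u_shank, 0.0),
        ("r_shank", geometry.shank_attachment_local, -f_rig * u_shank, 0.0),
    ]


def assist_torque(model, state, wrenches, body_mass: float) -> float:
    """Equivalent ankle joint torque (N m / kg) of the exoskeleton wrenches.

    Computed as the right-ankle generalized-force component of the wrenches
    (dorsiflexion positive, so assistance is negative = plantarflexing).
    """
    from . import _core

    if not wrenches:
        return 0.0
    phi, w, p, v = model.fk(state)
    Q = np.zeros(model.n_coords)
    for segment, local, force, torque in wrenches:
        b = model.body_index(segment)
        pt = _core.body_point(b, np.asarray(local, float), phi, p)
        _core.add_point_force(
            Q, b, pt, float(force[0]), float(force[1]),
            model.parent, model.sigma, model.jc, p,
        )
    return float(Q[6]) / body_mass
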