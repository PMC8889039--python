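"""Joint-space tracking: PID "biological torques" + trunk-upright feedback.

Hip, knee and ankle joints on both legs track their reference trajectories
with local PID controllers; the derivative term acts on the velocity error
using the analytic reference derivative.  The lumbo-sacral joint is not
tracked: a PD loop on the world orientation of the HAT segment keeps the
trunk upright.  Metatarsophalangeal joints are passive springs and receive
no controller torque.  The PID integral contribution is clamped at
+/- integrator_limit (conditional anti-windup).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ControllerGains  # re-exported domain type

__all__ = ["ControllerGains", "IntegratorState", "pid_torques", "hat_upright_torque"]

# joint order of the torque vector (matches config.JOINT_NAMES)
TRACKED = {"r_hip": (1, 0), "r_knee": (2, 1), "r_ankle": (3, 2),
           "l_hip": (5, 3), "l_knee": (6, 4), "l_ankle": (7, 5)}
# maps joint -> (torque index, reference row / integrator slot)


@dataclass
class IntegratorState:
    """Integral of tracking error per tracked joint (6 slots)."""

    values: np.ndarray = field(default_factory=lambda: np.zeros(6))

    def copy(self) -> "IntegratorState":
        return IntegratorState(self.values.copy())


def _gain(gains: ControllerGains, slot: int) -> tuple[float, float, float]:
    return (gains.hip, gains.knee, gains.ankle)[slot % 3]


def pid_torques(
    joint_angles,
    joint_velocities,
    ref_angles,
    ref_velocities,
    gains: ControllerGains,
    integrator: IntegratorState,
    dt: float = 0.0,
):
    """PID torques for the six tracked joints.

    ``joint_angles``/``joint_velocities`` are the 6 tracked values in
    reference order (r_hip, r_knee, r_ankle, l_hip, l_knee, l_ankle).
    Returns (torques (9,), updated IntegratorState); untracked slots
    (lumbo-sacral, toe joints) are zero.  If ``dt`` > 0 the error integral is
    advanced (conditionally frozen while the clamped I-term saturates).
    """
    q = np.asarray(joint_angles, dtype=float)
    qd = np.asarray(joint_velocities, dtype=float)
    r = np.asarray(ref_angles, dtype=float)
    rd = np.asarray(ref_velocities, dtype=float)
    tau = np.zeros(9)
    new = integrator.copy()
    lim = gains.integrator_limit
    for name, (ti, slot) in TRACKED.items():
        kp, ki, kd = _gain(gains, slot)
        e = r[slot] - q[slot]
        ed = rd[slot] - qd[slot]
        i_term = np.clip(ki * new.values[slot], -lim, lim)
        tau[ti] = kp * e + i_term + kd * ed
        if dt > 0.0:
            sat = ki * new.values[slot]
            if not ((sat >= lim and e > 0) or (sat <= -lim and e < 0)):
                new.values[slot] += e * dt
    return tau, new


def hat_upright_torque(hat_world_angle: float, hat_world_rate: float,
                       gains: ControllerGains) -> float:
    """Lumbo-sacral generalized torque from HAT-upright PD feedback.

    Drives the HAT world orientation to vertical; positive sign convention
    matches the lumbo-sacral joint coordinate (trunk flexion positive).
    """
    kp, kd = gains.hat_upright
    return kp * hat_world_angle + kd * hat_world_rate
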