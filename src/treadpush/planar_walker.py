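"""Build and integrate the planar 10-segment torque-driven walking model.

The model walks on a treadmill whose belt surface is the plane y = 0 moving
posteriorly at the belt speed.  Generalized coordinates (12 in total):

====  =======================================
q[0]  pelvis x (m, anterior positive)
q[1]  pelvis y (m, up; pelvis origin = hip joint center, both hips overlap)
q[2]  pelvis orientation (rad, CCW)
q[3]  lumbo-sacral angle (trunk flexion positive)
q[4]  right hip (flexion +)     q[8]   left hip
q[5]  right knee (flexion +)    q[9]   left knee
q[6]  right ankle (dorsifl. +)  q[10]  left ankle
q[7]  right toe joint (ext. +)  q[11]  left toe joint
====  =======================================

Joint torques are reported in the same joint conventions, normalized to body
mass.  Time integration uses a stiff-capable variable-step scheme (LSODA)
because the penalty foot-ground contact makes the dynamics stiff; brake
switching times are known a priori (phase-scheduled), so the trajectory is
integrated piecewise between switches with the tendon-length snapshot
captured at each engagement.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from . import _core
from .config import (
    JOINT_NAMES,
    MTP_X,
    MTP_Y,
    SEGMENT_NAMES,
    ControllerGains,
    ExoGeometry,
    ExoParams,
    ModelConfig,
)
from .reference_gait import GaitReference, phase_of


class TopologyError(ValueError):
    pass


class SingularMassMatrixError(RuntimeError):
    pass


@dataclass
class SimState:
    """Generalized coordinates and velocities at one instant."""

    q: np.ndarray  # (12,)
    qdot: np.ndarray  # (12,)
    t: float = 0.0

    def __post_init__(self):
        self.q = np.asarray(self.q, dtype=float)
        self.qdot = np.asarray(self.qdot, dtype=float)
        if self.q.shape != self.qdot.shape:
            raise ValueError("q and qdot must have matching shapes")
        if not (np.all(np.isfinite(self.q)) and np.all(np.isfinite(self.qdot))):
            raise ValueError("state must be finite")


@dataclass
class Event:
    label: str
    time: float
    info: dict = field(default_factory=dict)


# fixed topology arrays (see _core for the convention)
_PARENT = np.array([-1, 0, 0, 2, 3, 4, 0, 6, 7, 8], dtype=np.int64)
_SIGMA = np.array([0, -1, 1, -1, 1, 1, 1, -1, 1, 1], dtype=np.float64)
_JC = np.array([-1, 3, 4, 5, 6, 7, 8, 9, 10, 11], dtype=np.int64)


class Model:
    """Articulated planar chain assembled from a :class:`ModelConfig`."""

    def __init__(self, config: ModelConfig, with_exo_mass: bool = False):
        self.config = config
        self.with_exo_mass = with_exo_mass
        segs = {s.name: s for s in config.segments}
        if set(segs) != set(SEGMENT_NAMES):
            missing = set(SEGMENT_NAMES) - set(segs)
            raise TopologyError(f"missing/unknown segments: {sorted(missing)}")
        jnts = {j.name: j for j in config.joints}
        if set(jnts) != set(JOINT_NAMES):
            missing = set(JOINT_NAMES) - set(jnts)
            raise TopologyError(f"missing/unknown joints: {sorted(missing)}")

        self.parent = _PARENT
        self.sigma = _SIGMA
        self.jc = _JC
        self.body_names = list(SEGMENT_NAMES)
        self._body_index = {n: i for i, n in enumerate(self.body_names)}

        scale = config.body_height / 1.73
        pelvis, hat = segs["pelvis"], segs["hat"]
        mass = np.empty(10)
        inertia = np.empty(10)
        com = np.zeros((10, 2))
        attach = np.zeros((10, 2))
        foot_axis = np.array([MTP_X, MTP_Y]) / np.hypot(MTP_X, MTP_Y)

        for i, name in enumerate(self.body_names):
            s = segs[name]
            mass[i] = s.mass
            inertia[i] = s.inertia_com
            if name == "pelvis":
                com[i] = (0.0, s.com_offset)
            elif name == "hat":
                com[i] = (0.0, s.com_offset)
                attach[i] = (0.0, pelvis.length)
            elif name.endswith("thigh"):
                com[i] = (0.0, -s.com_offset)
                attach[i] = (0.0, 0.0)  # hips at pelvis origin
            elif name.endswith("shank"):
                com[i] = (0.0, -s.com_offset)
                attach[i] = (0.0, -segs[name[0] + "_thigh"].length)
            elif name.endswith("foot"):
                com[i] = foot_axis * s.com_offset
                attach[i] = (0.0, -segs[name[0] + "_shank"].length)
            elif name.endswith("toes"):
                com[i] = (s.com_offset, 0.0)
                attach[i] = (MTP_X * scale, MTP_Y * scale)

        if with_exo_mass:
            sh, ft = config.added_mass
            mass[self._body_index["r_shank"]] += sh
            mass[self._body_index["r_foot"]] += ft

        self.mass = mass
        self.inertia = inertia
        self.com = com
        self.attach = attach

        spheres = config.spheres
        self.sphere_names = []
        self.sph_body = np.empty(len(spheres), dtype=np.int64)
        self.sph_local = np.empty((len(spheres), 2))
        self.sph_radius = np.empty(len(spheres))
        counters: dict[str, int] = {}
        labels = ("heel", "mtp", "toe")
        for i, sp in enumerate(spheres):
            self.sph_body[i] = self._body_index[sp.segment]
            self.sph_local[i] = sp.local_position
            self.sph_radius[i] = sp.radius
            side = sp.segment[0]
            k = counters.get(side, 0)
            counters[side] = k + 1
            self.sphere_names.append(f"{side}_{labels[k % 3]}")

        self.standing_pelvis_height = (
            segs["r_thigh"].length + segs["r_shank"].length + 0.07 * scale
        )

    # -- queries ----------------------------------------------------------

    @property
    def n_coords(self) -> int:
        return 3 + (len(self.body_names) - 1)

    @property
    def total_mass(self) -> float:
        return float(self.mass.sum())

    def body_index(self, name: str) -> int:
        return self._body_index[name]

    def fk(self, state: SimState):
        """Frame angles, angular rates, origin positions/velocities."""
        return _core.fk_pass(state.q, state.qdot, self.parent, self.sigma, self.jc, self.attach)

    def point_world(self, segment: str, local, state: SimState) -> np.ndarray:
        phi, _, p, _ = self.fk(state)
        return _core.body_point(self._body_index[segment], np.asarray(local, float), phi, p)

    def point_velocity(self, segment: str, local, state: SimState) -> np.ndarray:
        phi, w, p, v = self.fk(state)
        return _core.body_point_vel(
            self._body_index[segment], np.asarray(local, float), phi, w, p, v
        )

    def mass_matrix(self, state: SimState) -> np.ndarray:
        return _core.mass_matrix(
            state.q, self.parent, self.sigma, self.jc, self.attach,
            self.mass, self.inertia, self.com,
        )

    def energy(self, state: SimState, gravity: float | None = None) -> float:
        g = self.config.gravity if gravity is None else gravity
        return _core.mech_energy(
            state.q, state.qdot, self.parent, self.sigma, self.jc, self.attach,
            self.mass, self.inertia, self.com, g,
        )


def build_model(config: ModelConfig, with_exo_mass: bool = False) -> Model:
    """Assemble the articulated chain; raises on invalid topology/inertia."""
    return Model(config, with_exo_mass=with_exo_mass)


def forward_dynamics(
    model: Model,
    state: SimState,
    torques,
    external_wrenches=(),
    gravity: float | None = None,
) -> np.ndarray:
    """Accelerations solving M(q) qdd = Q_applied - h(q, qd).

    ``torques`` has one entry per joint (9, in :data:`JOINT_NAMES` order).
    ``external_wrenches`` is an iterable of (segment, local_point, force,
    torque) with the force in world coordinates.
    """
    torques = np.asarray(torques, dtype=float)
    if torques.shape != (9,):
        raise ValueError("expected one torque per joint (9)")
    g = model.config.gravity if gravity is None else gravity
    nq = model.n_coords
    Q = np.zeros(nq)
    Q[3:] = torques
    phi, w, p, v = model.fk(state)
    for segment, local, force, torque in external_wrenches:
        b = model.body_index(segment)
        pt = _core.body_point(b, np.asarray(local, float), phi, p)
        _core.add_point_force(
            Q, b, pt, float(force[0]), float(force[1]),
            model.parent, model.sigma, model.jc, p,
        )
        if torque:
            _core.add_body_torque(Q, b, float(torque), model.parent, model.sigma, model.jc)
    h = _core.inv_dyn(
        state.q, state.qdot, np.zeros(nq), g,
        model.parent, model.sigma, model.jc, model.attach,
        model.mass, model.inertia, model.com,
    )
    M = model.mass_matrix(state)
    if np.linalg.cond(M) > 1e12:
        raise SingularMassMatrixError("mass matrix is singular; check inertial parameters")
    return np.linalg.solve(M, Q - h)


# ---------------------------------------------------------------------------
# simulation result


@dataclass
class SimResult:
    """Time-stepped solution with derived, body-mass-normalized channels."""

    time: np.ndarray
    q: np.ndarray
    qdot: np.ndarray
    joint_torques: np.ndarray  # (n, 9) N m / kg, JOINT_NAMES order
    joint_powers: np.ndarray  # (n, 9) W / kg
    grf: np.ndarray  # (n, 4) N/kg: (ap_R, vert_R, ap_L, vert_L)
    sphere_forces: np.ndarray  # (n, n_spheres) normal forces, N/kg
    tendon_force: np.ndarray  # (n,) elastic-tendon force, N/kg
    assist_torque: np.ndarray  # (n,) exoskeleton ankle torque, N m / kg
    stride_phase: np.ndarray  # (n,) %
    events: list[Event]
    body_mass: float
    cycle_duration: float
    n_cycles: int
    condition: str = "NO-EXO"
    belt_speed: float = 1.18
    fall_time: float | None = None
    sphere_names: list[str] = field(default_factory=list)
    brake_windows: list[tuple] = field(default_factory=list)  # (t_on, t_off, d0, l0)
    exo_stiffness_total: float = 0.0  # N/m (body-mass scaled)

    @property
    def fell(self) -> bool:
        return self.fall_time is not None

    def joint(self, name: str) -> int:
        return JOINT_NAMES.index(name)

    def cycle_mask(self, cycle: int) -> np.ndarray:
        t0 = cycle * self.cycle_duration
        t1 = (cycle + 1) * self.cycle_duration
        return (self.time >= t0 - 1e-12) & (self.time <= t1 + 1e-12)

    def to_frame(self) -> pd.DataFrame:
        cols = {"time": self.time, "phase": self.stride_phase}
        for j, name in enumerate(JOINT_NAMES):
            cols[f"angle_{name}"] = self.q[:, 3 + j]
            cols[f"torque_{name}"] = self.joint_torques[:, j]
            cols[f"power_{name}"] = self.joint_powers[:, j]
        for i, lab in enumerate(("grf_ap_r", "grf_vert_r", "grf_ap_l", "grf_vert_l")):
            cols[lab] = self.grf[:, i]
        cols["tendon_force"] = self.tendon_force
        cols["assist_torque"] = self.assist_torque
        return pd.DataFrame(cols)

    def write(self, csv_path, events_path=None) -> None:
        """Tidy delimited time series + JSON events sidecar."""
        self.to_frame().to_csv(csv_path, index=False)
        if events_path is not None:
            doc = {
                "condition": self.condition,
                "body_mass": self.body_mass,
                "cycle_duration": self.cycle_duration,
                "fall_time": self.fall_time,
                "events": [
                    {"label": e.label, "time": e.time, "info": e.info} for e in self.events
                ],
            }
            with open(events_path, "w") as fh:
                json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# integration


def _kernel_static_args(model: Model, reference: GaitReference, gains: ControllerGains):
    cfg = model.config
    kp = np.array([gains.hip[0], gains.knee[0], gains.ankle[0]] * 2)
    ki = np.array([gains.hip[1], gains.knee[1], gains.ankle[1]] * 2)
    kd = np.array([gains.hip[2], gains.knee[2], gains.ankle[2]] * 2)
    mtp = next(j for j in cfg.joints if j.name == "r_mtp")
    c = cfg.contact
    return (
        model.parent, model.sigma, model.jc, model.attach,
        model.mass, model.inertia, model.com,
        reference.cycle_duration, reference.coefficients,
        kp, ki, kd,
        float(gains.hat_upright[0]), float(gains.hat_upright[1]),
        float(gains.integrator_limit),
        float(gains.pelvis_upright[0]), float(gains.pelvis_upright[1]),
        float(gains.ankle_posture[0]), float(gains.ankle_posture[1]),
        float(gains.station_keeping[0]), float(gains.station_keeping[1]),
        float(mtp.passive_stiffness or 0.0), float(mtp.passive_damping),
        model.sph_body, model.sph_local, model.sph_radius,
        cfg.belt_speed, c.normal_stiffness, c.exponent, c.normal_damping,
        c.friction_coefficient, c.tangential_velocity_smoothing,
    )


def _exo_args(model: Model, params: ExoParams | None, geometry: ExoGeometry | None,
              engaged: bool, snap: tuple[float, float]):
    if params is None or not params.enabled:
        return (False, False, 0.0, 0.0, 0.0, 5.0,
                np.zeros(2), np.zeros(2), np.zeros(2))
    geometry = geometry or ExoGeometry()
    k_total = params.stiffness * model.config.body_mass
    return (
        True, engaged, snap[0], snap[1], k_total, geometry.spool_ratio,
        np.asarray(geometry.anchor_position, float),
        np.asarray(geometry.spool_axis_local, float),
        np.asarray(geometry.shank_attachment_local, float),
    )


def _tendon_lengths(model: Model, state: SimState, geometry: ExoGeometry):
    spool = model.point_world("r_foot", geometry.spool_axis_local, state)
    sh = model.point_world("r_shank", geometry.shank_attachment_local, state)
    anchor = np.asarray(geometry.anchor_position, float)
    d = float(np.hypot(*(anchor - spool)))
    l = float(np.hypot(*(sh - spool)))
    return d, l


def initial_state(model: Model, reference: GaitReference) -> SimState:
    """State at t = 0 taken from the reference (pelvis pose from the builder)."""
    q = np.zeros(model.n_coords)
    qd = np.zeros(model.n_coords)
    # start slightly sunk into the belt so the stance leg carries weight
    # from the first instant (static Hunt-Crossley penetration ~3 mm)
    q[0], q[1], q[2] = 0.0, reference.pelvis_height - 0.003, 0.0
    qd[1] = reference.pelvis_vy
    ang, vel = reference.evaluate(0.0)
    q[_core.TRACKED_Q] = ang
    qd[_core.TRACKED_Q] = vel
    # passive toes: lie flat (world-horizontal) wherever the foot is pitched
    # toes-down, so a mid-roll stance foot does not start with its toes
    # jammed into the belt
    phi, w, p, v = _core.fk_pass(q, qd, model.parent, model.sigma, model.jc, model.attach)
    for mtp_q, foot_b in ((7, 4), (11, 8)):
        if phi[foot_b] < 0.0:
            q[mtp_q] = -phi[foot_b]
            qd[mtp_q] = -w[foot_b]
    return SimState(q=q, qdot=qd, t=0.0)


class IntegrationError(RuntimeError):
    pass


def integrate(
    model: Model,
    reference: GaitReference,
    exo_params: ExoParams | None = None,
    exo_geometry: ExoGeometry | None = None,
    gains: ControllerGains | None = None,
    n_cycles: int | None = None,
    dt_max: float = 5e-3,
    rtol: float = 1e-6,
    atol: float = 1e-8,
    samples_per_cycle: int = 1000,
    state0: SimState | None = None,
    contact: bool = True,
    gravity: float | None = None,
    condition: str | None = None,
    detect_gait_events: bool = True,
) -> SimResult:
    """Integrate the tracked walking model over ``n_cycles`` gait cycles.

    The brake is scheduled open-loop on the stride phase of the exoskeleton
    side, so switching times are known in advance and the solution is
    integrated piecewise between them (switching is instantaneous).  A fall
    (pelvis below a fraction of standing height) terminates integration.
    """
    cfg = model.config
    gains = gains or cfg.gains
    n_cycles = n_cycles if n_cycles is not None else reference.n_cycles
    T = reference.cycle_duration
    t_end = n_cycles * T
    g = cfg.gravity if gravity is None else gravity
    geometry = exo_geometry or ExoGeometry()
    exo_active = exo_params is not None and exo_params.enabled

    static = list(_kernel_static_args(model, reference, gains))
    if not contact:
        static[21] = 0.0  # normal stiffness -> contact off

    # brake schedule
    boundaries = [0.0, t_end]
    windows = []  # (t_on, t_off)
    if exo_active:
        for k in range(n_cycles):
            t_on = (k + exo_params.engage_phase / 100.0) * T
            t_off = (k + exo_params.disengage_phase / 100.0) * T
            if t_on < t_end:
                windows.append((t_on, min(t_off, t_end)))
                boundaries += [t_on, min(t_off, t_end)]
    boundaries = sorted(set(boundaries))

    grid = np.linspace(0.0, t_end, n_cycles * samples_per_cycle + 1)
    y0 = np.zeros(2 * model.n_coords + 6)
    s0 = state0 or initial_state(model, reference)
    y0[: model.n_coords] = s0.q
    y0[model.n_coords : 2 * model.n_coords] = s0.qdot

    fall_h = cfg.fall_height_fraction * model.standing_pelvis_height

    def fall_event(t, y, *args):
        return y[1] - fall_h

    fall_event.terminal = True
    fall_event.direction = -1

    times, ys = [], []
    events: list[Event] = []
    brake_windows: list[tuple] = []
    fall_time = None
    sample_state = []  # per stored sample: (engaged, d0, l0)
    y = y0
    eps = 1e-12

    for seg_i in range(len(boundaries) - 1):
        t0, t1 = boundaries[seg_i], boundaries[seg_i + 1]
        engaged = any(t_on - eps <= t0 < t_off - eps for t_on, t_off in windows)
        snap = (0.0, 0.0)
        if exo_active and engaged:
            nq = model.n_coords
            st = SimState(y[:nq], y[nq : 2 * nq], t0)
            snap = _tendon_lengths(model, st, geometry)
            brake_windows.append((t0, t1, snap[0], snap[1]))
            events.append(Event("brake_engaged", t0, {"d0": snap[0], "l0": snap[1]}))
        args = tuple(static) + _exo_args(model, exo_params, geometry, engaged, snap) + (g,)
        t_eval = grid[(grid > t0 + 1e-9) & (grid < t1 - 1e-9)]
        t_eval = np.concatenate([t_eval, [t1]])
        if t0 == 0.0:
            t_eval = np.concatenate([[0.0], t_eval])
        sol = solve_ivp(
            _core.walker_rhs, (t0, t1), y, method="LSODA", args=args,
            t_eval=t_eval if t_eval.size else None, rtol=rtol, atol=atol,
            max_step=dt_max, events=fall_event, dense_output=True,
        )
        if not sol.success:
            raise IntegrationError(f"integrator failed at t = {sol.t[-1]:.4f} s: {sol.message}")
        times.append(sol.t)
        ys.append(sol.y)
        sample_state += [(engaged, snap[0], snap[1])] * sol.t.size
        if sol.status == 1:  # fall
            fall_time = float(sol.t_events[0][0])
            events.append(Event("fall", fall_time, {"pelvis_height": fall_h}))
            break
        y = sol.sol(t1)
        if exo_active and engaged:
            nq = model.n_coords
            st = SimState(y[:nq], y[nq : 2 * nq], t1)
            d1, l1 = _tendon_lengths(model, st, geometry)
            elong = max(0.0, (d1 - snap[0]) + geometry.spool_ratio * (l1 - snap[1]))
            k_total = exo_params.stiffness * cfg.body_mass
            events.append(
                Event("brake_disengaged", t1,
                      {"residual_energy_J": 0.5 * k_total * elong**2})
            )

    time = np.concatenate(times)
    Y = np.concatenate(ys, axis=1)

    # observation pass: recompute torques/forces at each stored sample
    n = time.size
    nq = model.n_coords
    tau = np.empty((n, 9))
    grf = np.empty((n, 4))
    sph = np.empty((n, model.sph_body.size))
    tendon = np.empty(n)
    assist = np.empty(n)
    for i in range(n):
        engaged, d0, l0 = sample_state[i]
        args = tuple(static) + _exo_args(model, exo_params, geometry, engaged, (d0, l0)) + (g,)
        _, _, tau_i, grf_i, sph_i, fel_i, as_i = _core.walker_forces(
            time[i], Y[:nq, i], Y[nq : 2 * nq, i], Y[2 * nq : 2 * nq + 6, i], *args
        )
        tau[i] = tau_i
        grf[i] = grf_i
        sph[i] = sph_i
        tendon[i] = fel_i
        assist[i] = as_i

    m = cfg.body_mass
    qd = Y[nq : 2 * nq].T
    powers = tau * qd[:, 3:] / m
    if condition is None:
        condition = "ACTIVE" if exo_active else ("NO-POWER" if model.with_exo_mass else "NO-EXO")
    res = SimResult(
        time=time,
        q=Y[:nq].T.copy(),
        qdot=qd.copy(),
        joint_torques=tau / m,
        joint_powers=powers,
        grf=grf / m,
        sphere_forces=sph / m,
        tendon_force=tendon / m,
        assist_torque=assist / m,
        stride_phase=phase_of(time, T),
        events=events,
        body_mass=m,
        cycle_duration=T,
        n_cycles=n_cycles,
        condition=condition,
        belt_speed=cfg.belt_speed,
        fall_time=fall_time,
        sphere_names=list(model.sphere_names),
        brake_windows=brake_windows,
        exo_stiffness_total=(exo_params.stiffness * m) if exo_active else 0.0,
    )
    if detect_gait_events:
        from .events import detect_events

        res.events = sorted(res.events + detect_events(res), key=lambda e: e.time)
    return res
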