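"""Dynamics core: model building, forward dynamics, integration contracts."""

import numpy as np
import pytest

from treadpush import (
    SimState,
    build_model,
    default_config,
    forward_dynamics,
    integrate,
    make_reference,
)
from treadpush import _core
from treadpush.config import ControllerGains, default_joints
from treadpush.planar_walker import TopologyError, initial_state


def _zero_gains():
    return ControllerGains(hip=(0, 0, 0), knee=(0, 0, 0), ankle=(0, 0, 0),
                           hat_upright=(0, 0), pelvis_upright=(0, 0),
                           ankle_posture=(0, 0), station_keeping=(0, 0))


def test_build_model_shape(model):
    assert len(model.body_names) == 10
    assert model.n_coords == 12
    assert model.n_coords - 3 == 9  # 9 joint coordinates after the floating base


def test_total_mass_bookkeeping(config):
    m = build_model(config)
    assert m.total_mass == pytest.approx(config.body_mass)
    m2 = build_model(config, with_exo_mass=True)
    assert m2.total_mass == pytest.approx(config.body_mass + sum(config.added_mass))
    assert sum(config.added_mass) == pytest.approx(0.8)


def test_missing_segment_is_topology_error(config):
    import dataclasses

    bad = dataclasses.replace(config)
    with pytest.raises(ValueError):
        bad.segments = config.segments[:-1]
        bad.__post_init__()


def test_duplicate_joint_names_rejected(config):
    import copy

    bad = copy.deepcopy(config)
    bad.joints[1].name = bad.joints[2].name
    with pytest.raises(ValueError):
        bad.__post_init__()


def test_equilibrium_without_forces(model, reference):
    """Zero torques, no contact, gravity off: no accelerations from rest."""
    s = initial_state(model, reference)
    s.qdot[:] = 0.0
    qdd = forward_dynamics(model, s, np.zeros(9), gravity=0.0)
    assert np.allclose(qdd, 0.0, atol=1e-10)


def test_free_fall_from_rest(model, reference):
    """Uniform gravity from rest: pelvis falls at -g, joints do not accelerate."""
    s = initial_state(model, reference)
    s.qdot[:] = 0.0
    qdd = forward_dynamics(model, s, np.zeros(9), gravity=9.81)
    expected = np.zeros(12)
    expected[1] = -9.81
    assert np.allclose(qdd, expected, atol=1e-9)


def test_internal_force_pair_cancels(model, reference):
    """Equal and opposite collinear forces on one rigid segment change nothing."""
    s = initial_state(model, reference)
    qdd0 = forward_dynamics(model, s, np.zeros(9), gravity=9.81)
    p1, p2 = np.array([0.0, -0.1]), np.array([0.0, -0.3])
    w1 = model.point_world("r_thigh", p1, s)
    w2 = model.point_world("r_thigh", p2, s)
    u = (w2 - w1) / np.linalg.norm(w2 - w1)  # world line through both points
    f = 137.0 * u
    wrenches = [("r_thigh", p1, f, 0.0), ("r_thigh", p2, -f, 0.0)]
    qdd1 = forward_dynamics(model, s, np.zeros(9), wrenches, gravity=9.81)
    assert np.allclose(qdd0, qdd1, atol=1e-9)


def test_forward_dynamics_matches_lagrangian_oracle():
    """Free-floating thigh+shank double pendulum vs an independent sympy
    Lagrangian derivation, relative error < 1e-8."""
    sp = pytest.importorskip("sympy")
    vals = dict(l1=0.42, m1=9.9, c1=0.17, I1=0.19, m2=3.0, c2=0.19, I2=0.035, g=9.81)
    t = sp.symbols("t")
    q = sp.Matrix([sp.Function(f"q{i}")(t) for i in range(4)])
    x, y, th, qk = q
    phi0, phi1 = th, th - qk  # knee-like joint, flexion positive

    def rot(a, vx, vy):
        return (sp.cos(a) * vx - sp.sin(a) * vy, sp.sin(a) * vx + sp.cos(a) * vy)

    c0 = rot(phi0, 0, -vals["c1"])
    com0 = sp.Matrix([x + c0[0], y + c0[1]])
    j1 = rot(phi0, 0, -vals["l1"])
    c1 = rot(phi1, 0, -vals["c2"])
    com1 = sp.Matrix([x + j1[0] + c1[0], y + j1[1] + c1[1]])
    dq = q.diff(t)
    v0, v1 = com0.diff(t), com1.diff(t)
    T = (vals["m1"] * (v0.T * v0)[0] + vals["m2"] * (v1.T * v1)[0]
         + vals["I1"] * phi0.diff(t) ** 2 + vals["I2"] * phi1.diff(t) ** 2) / 2
    V = vals["g"] * (vals["m1"] * com0[1] + vals["m2"] * com1[1])
    L = T - V
    qs, vs, as_, taus = (sp.symbols(f"{n}0:4") for n in "QVAT")
    sub = {}
    for i in range(4):
        sub[q[i].diff(t, 2)] = as_[i]
        sub[q[i].diff(t)] = vs[i]
        sub[q[i]] = qs[i]
    eqs = [(sp.diff(sp.diff(L, dq[i]), t) - sp.diff(L, q[i])).subs(sub) for i in range(4)]
    sol = sp.solve([sp.Eq(eqs[i], taus[i]) for i in range(4)], as_, dict=True)[0]
    oracle = sp.lambdify(qs + vs + taus, [sol[a] for a in as_], "numpy")

    parent = np.array([-1, 0], dtype=np.int64)
    sigma = np.array([0.0, -1.0])
    jc = np.array([-1, 3], dtype=np.int64)
    attach = np.array([[0.0, 0.0], [0.0, -vals["l1"]]])
    mass = np.array([vals["m1"], vals["m2"]])
    inertia = np.array([vals["I1"], vals["I2"]])
    com = np.array([[0.0, -vals["c1"]], [0.0, -vals["c2"]]])
    rng = np.random.default_rng(0)
    for _ in range(20):
        qq, vv, tt = rng.normal(0, 1, 4), rng.normal(0, 2, 4), rng.normal(0, 10, 4)
        h = _core.inv_dyn(qq, vv, np.zeros(4), vals["g"], parent, sigma, jc,
                          attach, mass, inertia, com)
        M = _core.mass_matrix(qq, parent, sigma, jc, attach, mass, inertia, com)
        qdd = np.linalg.solve(M, tt - h)
        ref = np.array(oracle(*qq, *vv, *tt), dtype=float)
        assert np.max(np.abs(qdd - ref)) < 1e-8 * max(1.0, np.max(np.abs(ref)))


def test_energy_conserved_in_free_flight():
    """Gravity-only flight (contact off, controller off, passive toe springs
    off): mechanical energy drift < 1e-6 of the initial energy per second."""
    cfg = default_config()
    cfg.joints = default_joints(mtp_stiffness=1e-12, mtp_damping=0.0)
    m = build_model(cfg)
    ref = make_reference(n_cycles=1)
    s0 = initial_state(m, ref)
    s0.q[1] += 8.0  # well above the belt for the whole flight
    sim = integrate(m, ref, gains=_zero_gains(), n_cycles=1, contact=False,
                    state0=s0, detect_gait_events=False)
    E0 = m.energy(SimState(sim.q[0], sim.qdot[0]))
    E1 = m.energy(SimState(sim.q[-1], sim.qdot[-1]))
    assert abs(E1 - E0) / abs(E0) / sim.time[-1] < 1e-6


def test_unactuated_model_falls(model, reference):
    """Zero controller gains: collapse with a fall event before one cycle."""
    sim = integrate(model, reference, gains=_zero_gains(), n_cycles=1,
                    detect_gait_events=False)
    assert sim.fell and sim.fall_time < reference.cycle_duration
    assert any(e.label == "fall" for e in sim.events)


def test_integration_is_deterministic(model, reference):
    """Identical inputs give bit-identical trajectories."""
    a = integrate(model, reference, n_cycles=1, detect_gait_events=False)
    b = integrate(model, reference, n_cycles=1, detect_gait_events=False)
    assert np.array_equal(a.q, b.q) and np.array_equal(a.qdot, b.qdot)
    assert np.array_equal(a.joint_torques, b.joint_torques)


def test_simresult_writer_roundtrip(tmp_path, baseline):
    import json

    import pandas as pd

    csv = tmp_path / "sim.csv"
    ev = tmp_path / "sim.events.json"
    baseline.write(csv, ev)
    df = pd.read_csv(csv)
    assert len(df) == baseline.time.size
    assert "torque_r_ankle" in df.columns and "grf_vert_l" in df.columns
    doc = json.loads(ev.read_text())
    assert doc["condition"] == "NO-EXO"
    assert any(e["label"] == "r_heel_strike" for e in doc["events"])
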