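"""Brake state machine, tendon elongation, transmission, and wrenches."""

import numpy as np
import pytest

from treadpush import (
    BrakeState,
    ExoGeometry,
    ExoParams,
    assist_torque,
    brake_update,
    exo_wrenches,
    tendon_elongation,
)
from treadpush.exoskeleton import _lengths
from treadpush.planar_walker import initial_state

PARAMS = ExoParams(stiffness=4.85, engage_phase=29.0, disengage_phase=53.0)
GEO = ExoGeometry()


@pytest.fixture()
def stance_state(model, reference):
    """A mid-stance pose of the exoskeleton-side leg."""
    s = initial_state(model, reference)
    ang, vel = reference.evaluate(0.40 * reference.cycle_duration)
    s.q[[4, 5, 6, 8, 9, 10]] = ang
    s.qdot[[4, 5, 6, 8, 9, 10]] = vel
    s.t = 0.40 * reference.cycle_duration
    return s


def _engaged(model, state, geometry=GEO):
    return BrakeState(engaged=True, engage_snapshot=_lengths(model, state, geometry))


def test_brake_engages_inside_window(model, stance_state):
    st = brake_update(30.0, PARAMS, BrakeState(), model, stance_state, GEO)
    assert st.engaged and st.engage_snapshot is not None


def test_brake_window_is_half_open(model, stance_state):
    st = brake_update(29.0, PARAMS, BrakeState(), model, stance_state, GEO)
    assert st.engaged
    st2 = brake_update(53.0 + 1e-9, PARAMS, st, model, stance_state, GEO)
    assert not st2.engaged and st2.engage_snapshot is None


def test_disabled_exo_never_engages(model, stance_state):
    off = ExoParams(enabled=False)
    for phase in (0.0, 29.0, 40.0, 53.0, 99.0):
        assert not brake_update(phase, off, BrakeState(), model, stance_state).engaged


def test_elongation_zero_at_engagement(model, stance_state):
    brake = _engaged(model, stance_state)
    assert tendon_elongation(model, stance_state, GEO, brake) == 0.0


def test_elongation_zero_when_disengaged(model, stance_state):
    assert tendon_elongation(model, stance_state, GEO, BrakeState()) == 0.0


def test_pure_translation_term(model, stance_state):
    """Carrying the foot away from the anchor along the tendon line by
    0.05 m lengthens the tendon by exactly 0.05 m."""
    brake = _engaged(model, stance_state)
    spool = model.point_world("r_foot", GEO.spool_axis_local, stance_state)
    anchor = np.asarray(GEO.anchor_position)
    u = (spool - anchor) / np.hypot(*(spool - anchor))
    stance_state.q[0:2] += 0.05 * u  # rigid translation: l_shank unchanged
    e = tendon_elongation(model, stance_state, GEO, brake)
    assert e == pytest.approx(0.05, abs=1e-9)


def test_spool_ratio_scales_the_rigid_tendon_term(model, stance_state):
    """A 0.01 m change of the shank-attachment distance stretches the
    elastic tendon by spool_ratio x 0.01 = 0.05 m."""
    d0, l0 = _lengths(model, stance_state, GEO)
    brake = BrakeState(engaged=True, engage_snapshot=(d0, l0 - 0.01))
    e = tendon_elongation(model, stance_state, GEO, brake)
    assert e == pytest.approx(GEO.spool_ratio * 0.01, abs=1e-12)
    assert GEO.spool_ratio == 5.0


def test_unilaterality_clamps_at_zero(model, stance_state):
    """A snapshot longer than the current lengths means a slack tendon."""
    d0, l0 = _lengths(model, stance_state, GEO)
    brake = BrakeState(engaged=True, engage_snapshot=(d0 + 0.2, l0))
    assert tendon_elongation(model, stance_state, GEO, brake) == 0.0
    assert exo_wrenches(model, stance_state, GEO, PARAMS, brake, 70.0) == []


def test_rigid_force_is_five_times_elastic(model, stance_state):
    d0, l0 = _lengths(model, stance_state, GEO)
    brake = BrakeState(engaged=True, engage_snapshot=(d0 - 0.1, l0))
    w = exo_wrenches(model, stance_state, GEO, PARAMS, brake, 70.0)
    f_el = np.linalg.norm(w[0][2])
    f_rig = np.linalg.norm(w[1][2])
    assert f_rig == pytest.approx(5.0 * f_el, rel=1e-12)
    # rigid tendon pulls shank attachment and spool together: equal, opposite
    assert np.allclose(w[1][2], -w[2][2])


def test_engaged_tendon_plantarflexes_the_ankle(model, stance_state):
    """Net ankle moment of all device forces is plantarflexing (negative in
    the dorsiflexion-positive convention)."""
    d0, l0 = _lengths(model, stance_state, GEO)
    brake = BrakeState(engaged=True, engage_snapshot=(d0 - 0.15, l0 - 0.01))
    w = exo_wrenches(model, stance_state, GEO, PARAMS, brake, 70.0)
    tau = assist_torque(model, stance_state, w, 70.0)
    assert tau < 0.0


def test_assist_torque_linear_in_stiffness(model, stance_state):
    d0, l0 = _lengths(model, stance_state, GEO)
    brake = BrakeState(engaged=True, engage_snapshot=(d0 - 0.1, l0))
    w1 = exo_wrenches(model, stance_state, GEO, PARAMS, brake, 70.0)
    double = ExoParams(stiffness=2 * PARAMS.stiffness, engage_phase=29, disengage_phase=53)
    w2 = exo_wrenches(model, stance_state, GEO, double, brake, 70.0)
    t1 = assist_torque(model, stance_state, w1, 70.0)
    t2 = assist_torque(model, stance_state, w2, 70.0)
    assert t2 == pytest.approx(2.0 * t1, rel=1e-9)
    assert assist_torque(model, stance_state, [], 70.0) == 0.0


def test_snapshot_present_iff_engaged():
    with pytest.raises(ValueError):
        BrakeState(engaged=True, engage_snapshot=None)
    with pytest.raises(ValueError):
        BrakeState(engaged=False, engage_snapshot=(1.0, 0.1))


def test_simulated_tendon_never_pushes(active):
    """Unilateral spring: the tendon force is >= 0 at every stored sample."""
    assert np.all(active.tendon_force >= 0.0)


def test_assist_peaks_between_heel_off_and_toe_off(active):
    """Peak device torque (and tendon force) occurs late in stance, in the
    heel-off..toe-off interval of the assisted leg."""
    m3 = active.cycle_mask(2)
    ph = active.stride_phase[m3]
    i_peak = np.argmin(active.assist_torque[m3])  # most plantarflexing
    t_lo = active.cycle_duration * 2
    heel_offs = [e.time for e in active.events
                 if e.label == "r_heel_off" and t_lo + 0.4 * 1.21 < e.time < t_lo + 1.21]
    toe_offs = [e.time for e in active.events
                if e.label == "r_toe_off" and t_lo + 0.5 * 1.21 < e.time < t_lo + 1.21]
    assert heel_offs and toe_offs
    t_peak = active.time[m3][i_peak]
    assert heel_offs[0] - 0.05 <= t_peak <= toe_offs[0] + 0.01


def test_disengagement_logs_residual_energy(active):
    ev = [e for e in active.events if e.label == "brake_disengaged"]
    assert len(ev) == 4  # one per cycle
    assert all(e.info["residual_energy_J"] >= 0.0 for e in ev)
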