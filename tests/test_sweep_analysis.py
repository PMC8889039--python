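"""Work metrics, sweep enumeration, regression, events, classification."""

import numpy as np
import pandas as pd
import pytest

from treadpush import (
    SweepGrid,
    classify_disengagement,
    linreg,
    positive_ankle_work,
    reduction_pct,
    run_sweep,
)
from treadpush.events import detect_events
from treadpush.planar_walker import SimResult
from treadpush.sweep_analysis import positive_power_support, pushoff_metrics


# ---------------------------------------------------------------------------
# work integrals


def test_zero_power_zero_work():
    assert positive_ankle_work(np.zeros(1000)) == 0.0


def test_negative_power_contributes_nothing():
    assert positive_ankle_work(np.full(1000, -1.0)) == 0.0


def test_rectangular_burst_work():
    """1 W/kg on exactly [45, 55] % of a 1.21 s cycle = 0.121 J/kg."""
    phase = np.linspace(0.0, 100.0, 100001)
    power = np.where((phase >= 45) & (phase <= 55), 1.0, 0.0)
    w = positive_ankle_work(power, phase, (40, 60), cycle_duration=1.21)
    assert w == pytest.approx(0.121, rel=1e-3)


def test_window_validation():
    with pytest.raises(ValueError):
        positive_ankle_work(np.zeros(10), window=(40, 120))


@pytest.mark.parametrize(
    "active, base, expected",
    [(0.3, 0.3, 0.0), (0.0, 0.3, 100.0), (0.177, 0.30, 41.0)],
)
def test_reduction_pct(active, base, expected):
    assert reduction_pct(active, base) == pytest.approx(expected)


def test_reduction_rejects_zero_baseline():
    with pytest.raises(ValueError):
        reduction_pct(0.1, 0.0)


def test_negative_power_exclusion_rule():
    """Intervals where assistance would demand extra negative power are left
    out of the reduction on both sides."""
    phase = np.linspace(0.0, 100.0, 2001)
    base = np.where((phase >= 45) & (phase <= 55), 1.0, 0.0)
    act = base.copy()
    act[(phase >= 50) & (phase <= 55)] = -0.5  # exo-induced negative power
    act[(phase >= 45) & (phase < 50)] = 0.0  # fully assisted
    w_act = positive_ankle_work(act, phase, (40, 60), baseline_power=base,
                                cycle_duration=1.21)
    assert w_act == pytest.approx(0.0, abs=1e-9)
    # a toy SimResult-free check of the interval semantics: only the
    # non-excluded half of the burst is countable baseline work


# ---------------------------------------------------------------------------
# sweep grid and driver


def test_default_grid_enumerates_616_triplets():
    grid = SweepGrid()
    triplets = list(grid.triplets())
    assert grid.n_triplets == 616
    assert len(triplets) == 616
    assert len(set(triplets)) == 616


@pytest.mark.parametrize(
    "k, e, d, n",
    [((1.0,), (25.0,), (50.0,), 1), ((1.0, 2.0), (20.0, 25.0, 30.0), (44, 50, 53, 56, 59), 30)],
)
def test_grid_cardinality(k, e, d, n):
    assert SweepGrid(k, e, d).n_triplets == n


def test_empty_grid_rejected():
    with pytest.raises(ValueError):
        SweepGrid(stiffness_values=())


def test_run_sweep_one_record_per_triplet(baseline, active):
    """With an injected evaluator the driver yields exactly one record per
    triplet and classifies the disengagement group."""
    grid = SweepGrid((4.85,), (29.0,), (44.0, 53.0, 62.0))
    records = run_sweep(grid, baseline=baseline, evaluate=lambda k, e, d: active)
    assert len(records) == 3
    assert [r.disengagement_group for r in records] == ["premature", "on-time", "overdue"]
    assert all(np.isfinite(r.reduction_pct) for r in records)


def test_run_sweep_checkpoint_resume(tmp_path, baseline, active):
    grid = SweepGrid((4.85,), (29.0,), (50.0, 53.0))
    path = tmp_path / "records.csv"
    calls = []

    def ev(k, e, d):
        calls.append(d)
        return active

    run_sweep(grid, baseline=baseline, evaluate=ev, checkpoint=path)
    assert len(calls) == 2
    records = run_sweep(grid, baseline=baseline, evaluate=ev, checkpoint=path)
    assert len(calls) == 2  # resumed entirely from the checkpoint
    assert len(records) == 2


# ---------------------------------------------------------------------------
# regression


def test_linreg_exact_line():
    x = np.arange(5.0)
    slope, icpt, r2, p = linreg(x, 2 * x + 1)
    assert slope == pytest.approx(2.0) and icpt == pytest.approx(1.0)
    assert r2 == pytest.approx(1.0)
    assert p < 1e-6


def test_linreg_constant_y():
    slope, _, r2, _ = linreg([1, 2, 3, 4], [5, 5, 5, 5])
    assert slope == 0.0 and r2 == 0.0


def test_linreg_hand_computed_pearson():
    """{(1,1),(2,3),(3,2)}: r = 0.5, so R^2 = 0.25."""
    slope, icpt, r2, p = linreg([1, 2, 3], [1, 3, 2])
    assert r2 == pytest.approx(0.25)
    assert slope == pytest.approx(0.5)


def test_linreg_rejects_constant_x():
    with pytest.raises(ValueError):
        linreg([2, 2, 2], [1, 2, 3])


# ---------------------------------------------------------------------------
# classification and events


@pytest.mark.parametrize(
    "d, group",
    [(44, "premature"), (47, "premature"), (50, "premature"),
     (51, "on-time"), (53, "on-time"), (55, "on-time"),
     (56, "overdue"), (62, "overdue")],
)
def test_classify_disengagement(d, group):
    assert classify_disengagement(d) == group


def _toy_sim(sphere_forces, sphere_names, T=1.21):
    n = sphere_forces.shape[0]
    t = np.linspace(0, T, n)
    z = np.zeros(n)
    return SimResult(
        time=t, q=np.zeros((n, 12)), qdot=np.zeros((n, 12)),
        joint_torques=np.zeros((n, 9)), joint_powers=np.zeros((n, 9)),
        grf=np.zeros((n, 4)), sphere_forces=sphere_forces,
        tendon_force=z, assist_torque=z,
        stride_phase=t / T * 100.0, events=[], body_mass=70.0,
        cycle_duration=T, n_cycles=1, sphere_names=sphere_names,
    )


def test_detect_events_threshold_crossings():
    """Heel contact on [10, 52] % by construction: strike at 10, off at 52."""
    n = 1001
    phase = np.linspace(0, 100, n)
    f = np.zeros((n, 1))
    f[(phase >= 10) & (phase <= 52), 0] = 5.0  # N/kg, far above 1 % BW
    sim = _toy_sim(f, ["r_heel"])
    ev = detect_events(sim)
    strikes = [e for e in ev if e.label == "r_heel_strike"]
    offs = [e for e in ev if e.label == "r_heel_off"]
    assert len(strikes) == 1 and len(offs) == 1
    assert strikes[0].time / 1.21 * 100 == pytest.approx(10.0, abs=0.2)
    assert offs[0].time / 1.21 * 100 == pytest.approx(52.0, abs=0.2)


def test_detect_events_no_contact():
    sim = _toy_sim(np.zeros((100, 1)), ["r_heel"])
    assert detect_events(sim) == []


def test_baseline_heel_strike_near_ten_percent(baseline):
    """Simulated NO-EXO gait: ipsilateral heel strike at 10 +/- 2 % stride."""
    from treadpush.events import event_phases

    strikes = event_phases(baseline, "r_heel_strike")
    first = [p for p in strikes if p < 20.0]
    assert len(first) >= 3  # one per steady cycle
    assert all(8.0 <= p <= 12.0 for p in first)


def test_pushoff_window_reduction_consistency(baseline, active):
    """Metrics pipeline: active work <= countable baseline work and the
    reduction matches their ratio."""
    w_act, w_base, red = pushoff_metrics(active, baseline)
    assert 0 < w_act < w_base
    assert red == pytest.approx(100.0 * (w_base - w_act) / w_base)


def test_baseline_positive_power_is_pushoff_burst(baseline):
    lo, hi = positive_power_support(baseline)
    assert 40.0 <= lo < hi <= 60.0
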