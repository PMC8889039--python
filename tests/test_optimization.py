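"""Fitness components, the seeded GA, and representative-solution selection."""

import numpy as np
import pytest

from treadpush import FitnessWeights, GASettings, fitness, ga_minimize, select_representative
from treadpush.optimization import _representative_index


def test_weights_validation():
    with pytest.raises(ValueError):
        FitnessWeights(0, 0, 0, 0, 0)
    with pytest.raises(ValueError):
        FitnessWeights(w_fall=-1)


def test_fitness_self_comparison(baseline):
    """Comparing the baseline to itself nulls the comparative criteria; the
    scalar is the weighted sum of the two absolute ones."""
    w = FitnessWeights(1.0, 1.0, 2.0, 3.0, 1.0)
    scalar, comps = fitness(baseline, baseline, w, assistance_window=(29.0, 53.0))
    assert comps["fall"] == 0.0
    assert comps["distance"] == pytest.approx(0.0, abs=1e-12)
    assert comps["torque_similarity"] == pytest.approx(0.0, abs=1e-12)
    assert scalar == pytest.approx(2.0 * comps["hs_impulse"] + 3.0 * comps["abs_power"])
    assert all(v >= 0 for v in comps.values())


def test_fitness_fall_penalty(model, reference, baseline):
    from treadpush.config import ControllerGains
    from treadpush.planar_walker import integrate

    zero = ControllerGains(hip=(0, 0, 0), knee=(0, 0, 0), ankle=(0, 0, 0),
                           hat_upright=(0, 0), pelvis_upright=(0, 0),
                           ankle_posture=(0, 0), station_keeping=(0, 0))
    fallen = integrate(model, reference, gains=zero, n_cycles=4, detect_gait_events=False)
    assert fallen.fell
    _, comps = fitness(fallen, baseline, FitnessWeights(), assistance_window=(29, 53))
    assert comps["fall"] > 0.0


def test_fitness_linear_in_weights(baseline, active):
    s1, _ = fitness(active, baseline, FitnessWeights())
    s2, _ = fitness(active, baseline, FitnessWeights(2, 2, 2, 2, 2))
    assert s2 == pytest.approx(2.0 * s1)


def test_fitness_rejects_mismatched_time_bases(baseline):
    import copy

    other = copy.copy(baseline)
    other.cycle_duration = 1.0
    with pytest.raises(ValueError):
        fitness(other, baseline, FitnessWeights())


# ---------------------------------------------------------------------------
# GA


def _quadratic(target):
    def f(x):
        return float(np.sum((x - target) ** 2))

    return f


def test_ga_recovers_quadratic_minimum():
    """Surrogate with a known interior minimizer: recovered to within 5 % of
    the bound range."""
    bound = 0.1
    rng = np.random.default_rng(7)
    target = rng.uniform(-0.5 * bound, 0.5 * bound, size=8)
    settings = GASettings(population=32, generations=40)
    x, f, hist = ga_minimize(_quadratic(target), 8, bound, settings, seed=11)
    assert np.all(np.abs(x - target) < 0.05 * (2 * bound))


def test_ga_seeded_determinism():
    settings = GASettings(population=16, generations=10)
    r1 = ga_minimize(_quadratic(np.full(5, 0.02)), 5, 0.1, settings, seed=3)
    r2 = ga_minimize(_quadratic(np.full(5, 0.02)), 5, 0.1, settings, seed=3)
    assert np.array_equal(r1[0], r2[0]) and r1[1] == r2[1] and r1[2] == r2[2]


def test_ga_elitism_monotone_history():
    settings = GASettings(population=16, generations=15)
    _, _, hist = ga_minimize(_quadratic(np.zeros(6) + 0.03), 6, 0.1, settings, seed=5)
    assert all(b <= a + 1e-15 for a, b in zip(hist, hist[1:]))


def test_ga_zero_adjustment_in_initial_population():
    """With the optimum exactly at zero adjustment the GA never does worse
    than the unadjusted reference (it is an initial individual)."""
    settings = GASettings(population=8, generations=3)
    x, f, hist = ga_minimize(_quadratic(np.zeros(4)), 4, 0.1, settings, seed=1)
    assert f <= 1e-12


def test_ga_reports_total_failure():
    settings = GASettings(population=6, generations=2)
    with pytest.raises(RuntimeError):
        ga_minimize(lambda x: np.nan, 4, 0.1, settings, seed=1)


# ---------------------------------------------------------------------------
# representative selection (4 repeats -> outlier -> median)


def test_representative_of_identical_solutions():
    prof = np.sin(np.linspace(0, 6, 50))
    out = select_representative([prof] * 4)
    assert np.array_equal(out, prof)


def test_outlier_is_discarded():
    base = np.zeros(30)
    cluster = [base + 0.01, base - 0.01, base + 0.02]
    distant = base + 5.0
    sols = [cluster[0], distant, cluster[1], cluster[2]]
    outlier, rep = _representative_index([np.asarray(s) for s in sols])
    assert outlier == 1
    assert rep in (0, 2, 3)


def test_median_profile_is_chosen():
    """Scalar offsets {0, 1, 2} after outlier removal: the middle one wins."""
    base = np.ones(20)
    sols = [base * 0.0, base * 1.0, base * 2.0, base * 50.0]
    out = select_representative(sols)
    assert np.allclose(out, base * 1.0)


def test_brute_force_oracle_for_selection():
    """Exhaustive re-derivation of the rule on random profile sets."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        profs = [rng.normal(size=12) for _ in range(4)]
        D = np.array([[np.linalg.norm(a - b) for b in profs] for a in profs])
        outlier = int(np.argmax(D.sum(axis=1)))
        rest = [i for i in range(4) if i != outlier]
        expected = min(rest, key=lambda i: D[i, rest].sum())  # middle profile
        got_out, got_rep = _representative_index(profs)
        assert got_out == outlier and got_rep == expected


def test_selection_requires_exactly_four():
    with pytest.raises(ValueError):
        select_representative([np.zeros(3)] * 3)
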