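"""Genetic-algorithm adjustment of reference kinematics under assistance.

When the device pushes on the leg, tracking the unassisted reference is no
longer optimal; a GA searches small periodic offsets of the hip/knee/ankle
reference trajectories (spline knots, bounded so the gait stays close to
NO-EXO).  Fitness is a weighted sum of five criteria, each normalized by
its NO-EXO value: fall penalty, belt-relative distance error, heel-strike
GRF impulse, total absolute joint power, and torque-profile similarity to
NO-EXO outside the assistance window.  Lower is better.

Each parameter triplet is optimized four times with different seeds; the
solution farthest (summed torque-profile L2 distance) from the other three
is discarded as an outlier and of the remaining three the middle profile
(the medoid: smallest summed distance to the other two) is kept as the
representative with the median torque characteristic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ExoGeometry, ExoParams
from .planar_walker import SimResult
from .reference_gait import GaitReference, KinematicAdjustment
from .simulate import run_condition
from .sweep_analysis import METRIC_CYCLE

__all__ = [
    "FitnessWeights", "GASettings", "fitness", "ga_minimize", "ga_optimize",
    "select_representative", "KinematicAdjustment",
]


@dataclass
class FitnessWeights:
    w_fall: float = 1.0
    w_distance: float = 1.0
    w_hs_impulse: float = 1.0
    w_abs_power: float = 1.0
    w_torque_similarity: float = 1.0

    def __post_init__(self):
        vals = (self.w_fall, self.w_distance, self.w_hs_impulse,
                self.w_abs_power, self.w_torque_similarity)
        if any(v < 0 for v in vals):
            raise ValueError("weights must be >= 0")
        if not any(v > 0 for v in vals):
            raise ValueError("at least one weight must be > 0")

    def as_array(self) -> np.ndarray:
        return np.array([self.w_fall, self.w_distance, self.w_hs_impulse,
                         self.w_abs_power, self.w_torque_similarity])


def _belt_distance(sim: SimResult) -> float:
    """Pelvis distance traveled relative to the belt over the simulation."""
    x = sim.q[:, 0] + sim.time * sim.belt_speed
    return float(x[-1] - x[0])


def _torque_profile(sim: SimResult, cycle: int = METRIC_CYCLE, resolution: float = 0.5):
    grid = np.arange(0.0, 100.0, resolution)
    t0 = cycle * sim.cycle_duration
    tq = t0 + grid / 100.0 * sim.cycle_duration
    cols = [sim.joint(n) for n in ("r_hip", "r_knee", "r_ankle",
                                   "l_hip", "l_knee", "l_ankle")]
    prof = np.stack([np.interp(tq, sim.time, sim.joint_torques[:, c]) for c in cols])
    return grid, prof


def _hs_impulse(sim: SimResult, half_width_pct: float = 2.0) -> float:
    """Vertical GRF impulse within +/- 2 % of stride around heel strikes."""
    from .events import event_phases

    total = 0.0
    T = sim.cycle_duration
    for side, col in (("r", 1), ("l", 3)):
        for t_ev in (e.time for e in sim.events if e.label == f"{side}_heel_strike"):
            mask = np.abs(sim.time - t_ev) <= half_width_pct / 100.0 * T
            if mask.any():
                total += float(np.trapezoid(np.abs(sim.grf[mask, col]), sim.time[mask]))
    return total


def _abs_power(sim: SimResult) -> float:
    return float(np.trapezoid(np.abs(sim.joint_powers).sum(axis=1), sim.time))


def fitness(
    sim: SimResult,
    baseline: SimResult,
    weights: FitnessWeights,
    assistance_window: tuple[float, float] | None = None,
) -> tuple[float, dict]:
    """Scalar fitness (lower better) and the per-criterion breakdown.

    Comparative criteria (distance, torque similarity) vanish for
    sim == baseline; absolute criteria (heel-strike impulse, total absolute
    power) are normalized by their baseline values.
    """
    if abs(sim.cycle_duration - baseline.cycle_duration) > 1e-12:
        raise ValueError("mismatched time bases")
    T_total = baseline.n_cycles * baseline.cycle_duration

    c_fall = 0.0 if not sim.fell else (T_total - sim.fall_time) / T_total

    d_base = _belt_distance(baseline)
    c_dist = abs(_belt_distance(sim) - d_base) / max(abs(d_base), 1e-9)

    i_base = _hs_impulse(baseline)
    c_imp = _hs_impulse(sim) / max(i_base, 1e-9)

    p_base = _abs_power(baseline)
    c_pow = _abs_power(sim) / max(p_base, 1e-9)

    if assistance_window is None:
        if sim.brake_windows:
            t_on, t_off = sim.brake_windows[0][:2]
            assistance_window = ((t_on % sim.cycle_duration) / sim.cycle_duration * 100.0,
                                 (t_off % sim.cycle_duration) / sim.cycle_duration * 100.0)
        else:
            assistance_window = (0.0, 0.0)
    g, prof = _torque_profile(sim)
    _, prof_b = _torque_profile(baseline)
    lo, hi = assistance_window
    outside = ~((g >= lo) & (g <= hi))
    diff = prof[:, outside] - prof_b[:, outside]
    norm = np.linalg.norm(prof_b[:, outside]) + 1e-9
    c_sim = float(np.linalg.norm(diff) / norm)

    comps = {"fall": c_fall, "distance": c_dist, "hs_impulse": c_imp,
             "abs_power": c_pow, "torque_similarity": c_sim}
    w = weights.as_array()
    scalar = float(np.dot(w, np.array([c_fall, c_dist, c_imp, c_pow, c_sim])))
    return scalar, comps


# ---------------------------------------------------------------------------
# generic seeded GA


@dataclass
class GASettings:
    population: int = 32
    generations: int = 40
    tournament: int = 3
    mutation_sigma_frac: float = 0.10  # of the bound range
    mutation_rate: float = 0.25
    elitism: int = 2
    crossover_rate: float = 0.7
    init_sigma_frac: float = 0.05
    n_knots: int = 8
    bound: float = float(np.deg2rad(5.0))
    exo_side_only: bool = True


def ga_minimize(fun, n_genes: int, bound: float, settings: GASettings, seed: int):
    """Minimize fun(x) over the box [-bound, bound]^n with a seeded GA.

    Tournament selection, uniform crossover, Gaussian mutation, elitism.
    Returns (best x, best f, history of best-per-generation).  Deterministic
    for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    pop = rng.normal(0.0, settings.init_sigma_frac * bound,
                     size=(settings.population, n_genes))
    pop[0] = 0.0  # the unadjusted reference is always in the initial population
    pop = np.clip(pop, -bound, bound)
    fit = np.array([fun(x) for x in pop])
    if not np.any(np.isfinite(fit)):
        raise RuntimeError("all individuals failed in generation 0")
    history = [float(np.nanmin(fit))]
    sigma = settings.mutation_sigma_frac * bound
    for _ in range(settings.generations):
        order = np.argsort(fit)
        new = [pop[i].copy() for i in order[: settings.elitism]]
        while len(new) < settings.population:
            idx = rng.integers(0, settings.population, size=settings.tournament)
            p1 = pop[idx[np.argmin(fit[idx])]]
            idx = rng.integers(0, settings.population, size=settings.tournament)
            p2 = pop[idx[np.argmin(fit[idx])]]
            child = p1.copy()
            if rng.random() < settings.crossover_rate:
                mask = rng.random(n_genes) < 0.5
                child[mask] = p2[mask]
            mut = rng.random(n_genes) < settings.mutation_rate
            child[mut] += rng.normal(0.0, sigma, size=int(mut.sum()))
            new.append(np.clip(child, -bound, bound))
        keep = fit[order[: settings.elitism]]
        pop = np.stack(new)
        fit = np.concatenate([keep, [fun(x) for x in pop[settings.elitism:]]])
        history.append(float(np.nanmin(fit)))
    best = int(np.nanargmin(fit))
    return pop[best].copy(), float(fit[best]), history


def ga_optimize(
    model_config,
    exo_params: ExoParams,
    base_reference: GaitReference,
    weights: FitnessWeights,
    settings: GASettings,
    seed: int,
    baseline: SimResult | None = None,
    exo_geometry: ExoGeometry | None = None,
    **sim_kwargs,
):
    """GA search for the kinematic adjustment under assistance.

    Returns (best KinematicAdjustment, best fitness, history).  The initial
    population is seeded around the zero adjustment (the NO-EXO reference).
    """
    if baseline is None:
        baseline = run_condition("NO-EXO", config=model_config,
                                 reference=base_reference, **sim_kwargs)
    rows = 3 if settings.exo_side_only else 6
    n_genes = rows * settings.n_knots
    window = (exo_params.engage_phase, exo_params.disengage_phase)

    def evaluate(x):
        adj = KinematicAdjustment(x.reshape(rows, settings.n_knots), bound=settings.bound)
        try:
            sim = run_condition(
                "ACTIVE", exo_params=exo_params, exo_geometry=exo_geometry,
                config=model_config, reference=base_reference, adjustment=adj,
                **sim_kwargs,
            )
        except Exception:
            return np.inf
        scalar, _ = fitness(sim, baseline, weights, assistance_window=window)
        return scalar

    x, f, hist = ga_minimize(evaluate, n_genes, settings.bound, settings, seed)
    adj = KinematicAdjustment(x.reshape(rows, settings.n_knots), bound=settings.bound)
    return adj, f, hist


# ---------------------------------------------------------------------------
# representative-solution selection (4 repeats -> outlier -> median)


def _as_profile(sol) -> np.ndarray:
    if isinstance(sol, SimResult):
        return _torque_profile(sol)[1].ravel()
    return np.asarray(sol, dtype=float).ravel()


def _representative_index(profiles: list[np.ndarray]) -> tuple[int, int]:
    """(outlier index, representative index) by L2 torque-profile distance."""
    n = len(profiles)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(profiles[i] - profiles[j]))
            D[i, j] = D[j, i] = d
    outlier = int(np.argmax(D.sum(axis=1)))
    rest = [i for i in range(n) if i != outlier]
    # the "median torque characteristic": the middle profile of the three,
    # i.e. the one closest in total to the other two (their medoid)
    sums = [D[i, rest].sum() for i in rest]
    rep = rest[int(np.argmin(sums))]
    return outlier, rep


def select_representative(solutions):
    """Pick the representative of exactly 4 repeated solutions.

    The solution with the largest summed L2 torque-profile distance to the
    other three is discarded as the outlier; of the remaining three, the
    middle profile -- the one with the smallest summed distance to the
    other two -- is returned as the median torque characteristic.
    """
    solutions = list(solutions)
    if len(solutions) != 4:
        raise ValueError("exactly 4 solutions are required")
    profiles = [_as_profile(s) for s in solutions]
    _, rep = _representative_index(profiles)
    return solutions[rep]
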