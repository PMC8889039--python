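"""Parameter sweep over stiffness and brake timings; push-off work metrics.

The efficacy metric is the reduction of positive biological ankle work in
the push-off window (40-60 % of stride) relative to the NO-EXO condition.
Phases where the assisted condition would require *additional negative*
ankle power compared to NO-EXO are not counted as assistance.  Metrics are
evaluated on the third of the four chained cycles (steady state, away from
the start-up and terminal transients) on a 0.1 %-phase grid.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import ExoGeometry, ExoParams
from .events import detect_events, event_phases  # noqa: F401  (re-export)
from .planar_walker import SimResult
from .simulate import run_condition

METRIC_CYCLE = 2  # 0-based: the 3rd of 4 chained cycles
PUSHOFF_WINDOW = (40.0, 60.0)


@dataclass
class SweepGrid:
    """Cartesian sweep values; defaults are the study's full grid."""

    stiffness_values: tuple = (0.91, 1.52, 2.12, 2.73, 3.79, 4.85, 6.97, 9.09)
    engage_values: tuple = (20.0, 23.0, 26.0, 29.0, 32.0, 35.0, 38.0)
    disengage_values: tuple = (44.0, 47.0, 50.0, 51.0, 52.0, 53.0, 54.0, 55.0, 56.0, 59.0, 62.0)

    def __post_init__(self):
        if not (self.stiffness_values and self.engage_values and self.disengage_values):
            raise ValueError("all three value lists must be non-empty")

    @property
    def n_triplets(self) -> int:
        return (
            len(self.stiffness_values) * len(self.engage_values) * len(self.disengage_values)
        )

    def triplets(self):
        """Yield (stiffness, engage, disengage) for every combination."""
        return itertools.product(
            self.stiffness_values, self.engage_values, self.disengage_values
        )


@dataclass
class SweepRecord:
    stiffness: float  # N/m/kg
    engage_phase: float  # % stride
    disengage_phase: float  # % stride
    positive_ankle_work: float  # J/kg, assisted condition (adjusted)
    baseline_work: float  # J/kg, NO-EXO
    reduction_pct: float
    disengagement_group: str
    fell: bool = False


# ---------------------------------------------------------------------------
# work metrics


def _phase_grid_power(sim: SimResult, joint: str = "r_ankle", cycle: int = METRIC_CYCLE,
                      resolution: float = 0.1):
    """Resample a joint's biological power onto a uniform phase grid (one cycle)."""
    j = sim.joint(joint)
    t0 = cycle * sim.cycle_duration
    grid = np.arange(0.0, 100.0, resolution)
    tq = t0 + grid / 100.0 * sim.cycle_duration
    p = np.interp(tq, sim.time, sim.joint_powers[:, j])
    return grid, p


def positive_ankle_work(
    power: np.ndarray,
    phase: np.ndarray | None = None,
    window: tuple[float, float] = PUSHOFF_WINDOW,
    baseline_power: np.ndarray | None = None,
    cycle_duration: float = 1.21,
) -> float:
    """Integral of positive power (W/kg) over a stride-phase window, in J/kg.

    With ``baseline_power`` given, phases where the power is more negative
    than both zero and the baseline (assistance demanding *additional*
    negative power) are marked inadequate and contribute nothing; the
    companion exclusion on the baseline side lives in
    :func:`pushoff_metrics`.
    """
    power = np.asarray(power, dtype=float)
    if phase is None:
        phase = np.linspace(0.0, 100.0, power.size, endpoint=False)
    phase = np.asarray(phase, dtype=float)
    lo, hi = window
    if not (0.0 <= lo < hi <= 100.0):
        raise ValueError("window must lie inside [0, 100] % stride")
    mask = (phase >= lo) & (phase <= hi)
    integrand = np.maximum(power, 0.0)
    if baseline_power is not None:
        base = np.asarray(baseline_power, dtype=float)
        integrand = np.where(power < np.minimum(base, 0.0), 0.0, integrand)
    dt = cycle_duration / 100.0  # seconds per % stride
    return float(np.trapezoid(integrand[mask], phase[mask] * dt))


def reduction_pct(active_work: float, baseline_work: float) -> float:
    """Percentage reduction relative to the NO-EXO work; negative if worse."""
    if baseline_work <= 0:
        raise ValueError("baseline work must be > 0")
    return 100.0 * (baseline_work - active_work) / baseline_work


def pushoff_metrics(sim: SimResult, baseline: SimResult,
                    window: tuple[float, float] = PUSHOFF_WINDOW) -> tuple[float, float, float]:
    """(active work, baseline work, reduction %) for the right ankle.

    Phase intervals where the assisted condition would require *additional
    negative* power compared to NO-EXO are not considered adequate
    assistance and are left out of the reduction calculation on both sides:
    the reduction compares the two conditions' positive ankle work over the
    remaining part of the push-off window.
    """
    g, p_act = _phase_grid_power(sim)
    _, p_base = _phase_grid_power(baseline)
    excluded = p_act < np.minimum(p_base, 0.0)
    base_ok = np.where(excluded, 0.0, p_base)
    w_base = positive_ankle_work(base_ok, g, window, cycle_duration=baseline.cycle_duration)
    w_act = positive_ankle_work(p_act, g, window, baseline_power=p_base,
                                cycle_duration=sim.cycle_duration)
    return w_act, w_base, reduction_pct(w_act, w_base)


def positive_power_support(sim: SimResult, joint: str = "r_ankle",
                           threshold_frac: float = 0.05) -> tuple[float, float]:
    """Phase interval (%) containing all positive power above a noise floor.

    The floor is a fraction of the peak positive power (default 5 %), which
    separates the push-off burst from heel-strike transients and small
    swing-phase reorientation power.
    """
    g, p = _phase_grid_power(sim, joint)
    peak = p.max()
    if peak <= 0:
        return (np.nan, np.nan)
    on = np.nonzero(p > threshold_frac * peak)[0]
    return (float(g[on[0]]), float(g[on[-1]]))


def gait_speed(sim: SimResult, model, side: str = "r", cycle: int = METRIC_CYCLE) -> float:
    """Average gait speed: stance-foot stride relative to the belt / cycle time.

    Measured between successive heel strikes of the same foot: the distance
    between the two footprints in the belt's (moving) frame divided by the
    time between them.  For periodic no-slip gait this equals the belt speed.
    """
    from .planar_walker import SimState

    label = f"{side}_heel_strike"
    T = sim.cycle_duration

    def first_strike(c):
        for e in sim.events:
            if e.label == label and c * T <= e.time < (c + 1) * T:
                if (e.time % T) / T * 100.0 < 20.0:
                    return e.time
        return None

    t0, t1 = first_strike(cycle), first_strike(cycle + 1)
    if t0 is None or t1 is None:
        raise ValueError("heel strikes missing in the requested cycles")
    heel_idx = sim.sphere_names.index(f"{side}_heel")
    local = model.sph_local[heel_idx]
    seg = f"{side}_foot"

    def heel_x(tq):
        i = np.clip(np.searchsorted(sim.time, tq), 1, sim.time.size - 1)
        w = (tq - sim.time[i - 1]) / (sim.time[i] - sim.time[i - 1])
        q = (1 - w) * sim.q[i - 1] + w * sim.q[i]
        qd = (1 - w) * sim.qdot[i - 1] + w * sim.qdot[i]
        return float(model.point_world(seg, local, SimState(q, qd, tq))[0])

    stride = heel_x(t1) - heel_x(t0) + sim.belt_speed * (t1 - t0)
    return stride / (t1 - t0)


# ---------------------------------------------------------------------------
# sweep driver


def classify_disengagement(disengage_phase: float,
                           thresholds: tuple[float, float] = (50.0, 55.0)) -> str:
    """premature (<= first threshold), on-time, or overdue (> second)."""
    lo, hi = thresholds
    if disengage_phase <= lo:
        return "premature"
    if disengage_phase <= hi:
        return "on-time"
    return "overdue"


def run_sweep(
    grid: SweepGrid,
    baseline: SimResult | None = None,
    evaluate=None,
    checkpoint: str | Path | None = None,
    exo_geometry: ExoGeometry | None = None,
    **sim_kwargs,
) -> list[SweepRecord]:
    """One record per parameter triplet in the grid's Cartesian product.

    ``evaluate(stiffness, engage, disengage) -> SimResult`` may be injected
    (e.g. a representative-solution pipeline with optimization repeats); the
    default runs the tracking-controlled ACTIVE condition directly.  With
    ``checkpoint`` set, finished records are appended to a CSV and already
    present triplets are skipped, making long sweeps resumable.  Per-triplet
    failures are recorded (fell/NaN), not fatal.
    """
    if baseline is None:
        baseline = run_condition("NO-EXO", **sim_kwargs)

    if evaluate is None:
        def evaluate(k, e, d):
            return run_condition(
                "ACTIVE",
                exo_params=ExoParams(stiffness=k, engage_phase=e, disengage_phase=d),
                exo_geometry=exo_geometry,
                **sim_kwargs,
            )

    done: dict[tuple, SweepRecord] = {}
    path = Path(checkpoint) if checkpoint else None
    if path is not None and path.exists():
        for row in pd.read_csv(path).itertuples(index=False):
            rec = SweepRecord(**row._asdict())
            done[(rec.stiffness, rec.engage_phase, rec.disengage_phase)] = rec

    records = []
    for k, e, d in grid.triplets():
        key = (k, e, d)
        if key in done:
            records.append(done[key])
            continue
        try:
            sim = evaluate(k, e, d)
            if sim.fell:
                rec = SweepRecord(k, e, d, np.nan, np.nan, np.nan,
                                  classify_disengagement(d), fell=True)
            else:
                w_act, w_base, red = pushoff_metrics(sim, baseline)
                rec = SweepRecord(k, e, d, w_act, w_base, red, classify_disengagement(d))
        except Exception:
            rec = SweepRecord(k, e, d, np.nan, np.nan, np.nan,
                              classify_disengagement(d), fell=True)
        records.append(rec)
        if path is not None:
            df = pd.DataFrame([rec.__dict__])
            df.to_csv(path, mode="a", header=not path.exists(), index=False)
    return records


def records_frame(records: list[SweepRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def save_records(records, csv_path, meta: dict | None = None) -> None:
    records_frame(records).to_csv(csv_path, index=False)
    if meta is not None:
        with open(str(csv_path) + ".meta.json", "w") as fh:
            json.dump(meta, fh, indent=1)


# ---------------------------------------------------------------------------
# regression


def linreg(x, y):
    """OLS fit: (slope, intercept, R^2, two-sided p for slope != 0).

    R^2 is the squared Pearson correlation; p comes from the t distribution
    of the slope with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0:
        raise ValueError("x is constant")
    if np.ptp(y) == 0:
        return 0.0, float(y[0]), 0.0, 1.0
    res = stats.linregress(x, y)
    return res.slope, res.intercept, res.rvalue**2, res.pvalue
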