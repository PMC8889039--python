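"""Synthetic periodic reference kinematics and the stride-phase convention.

Stride phase convention (used by every timing parameter in the package):
0 % = the leg's most anterior position; heel strike occurs around 10 % of the
cycle, the contralateral leg is shifted by exactly 50 %, contralateral heel
strike lands around 60 %, and toe-off shortly before 60 %.

The default reference is built constructively rather than from a recorded
subject: a task-space stride (flat-foot stance riding the belt, heel rise
pivoting about the toe joint, a clearance-shaped swing) is laid out for the
ankle point and foot pitch, inverse kinematics gives hip/knee/ankle angle
samples, and a truncated Fourier series is fitted per joint.  The result is
exactly periodic, C-1 smooth, and consistent with the belt speed: during
stance the foot translates posteriorly at the belt speed, which is what lets
the assistance mechanism harvest treadmill energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

REF_JOINTS = ("r_hip", "r_knee", "r_ankle", "l_hip", "l_knee", "l_ankle")

# default event phases (% stride) targeted by the constructive builder
PHASE_HEEL_STRIKE = 12.0  # near-flat-foot initial contact (builder nominal;
# the simulated strike lands 2-3 % earlier, at the study's ~10 %)
PHASE_FLATFOOT = 19.0  # heel rocker ends, full sole contact
PHASE_ROLL = 47.0  # forefoot roll begins (heel starts to rise)
PHASE_TOE_OFF = 62.0  # last contact; overlaps the contralateral strike


def phase_of(t, cycle_duration: float):
    """Stride phase in % for time(s) t: (t mod T) / T * 100."""
    t = np.asarray(t, dtype=float)
    out = (t % cycle_duration) / cycle_duration * 100.0
    return out if out.ndim else float(out)


def _fit_fourier(samples: np.ndarray, n_harmonics: int,
                 smoothing_pct: float = 0.0) -> np.ndarray:
    """Least-squares periodic fit; returns [a0, a1..aH, b1..bH].

    ``smoothing_pct`` applies a periodic Gaussian filter of that standard
    deviation (in % stride) in the spectral domain before truncation, which
    suppresses Gibbs ringing at curvature kinks of constructed trajectories.
    """
    n = samples.size
    F = np.fft.rfft(samples) / n
    H = n_harmonics
    k = np.arange(1, H + 1)
    gain = np.ones(H)
    if smoothing_pct > 0.0:
        gain = np.exp(-0.5 * (2.0 * np.pi * k * smoothing_pct / 100.0) ** 2)
    out = np.empty(2 * H + 1)
    out[0] = F[0].real
    out[1 : H + 1] = 2.0 * F[1 : H + 1].real * gain
    out[H + 1 :] = -2.0 * F[1 : H + 1].imag * gain
    return out


def _eval_fourier(coeffs: np.ndarray, p, deriv: bool = False):
    """Evaluate rows of coeffs at stride fraction p in [0, 1)."""
    p = np.atleast_1d(np.asarray(p, dtype=float))
    H = (coeffs.shape[-1] - 1) // 2
    k = np.arange(1, H + 1)
    arg = 2.0 * np.pi * np.outer(p, k)  # (np, H)
    c, s = np.cos(arg), np.sin(arg)
    a = coeffs[..., 1 : H + 1]
    b = coeffs[..., H + 1 :]
    ang = coeffs[..., [0]] @ np.ones((1, p.size)) + a @ c.T + b @ s.T
    if not deriv:
        return ang
    vel = 2.0 * np.pi * ((-a * k) @ s.T + (b * k) @ c.T)  # per stride fraction
    return ang, vel


@dataclass
class GaitReference:
    """Periodic per-joint reference trajectories as truncated Fourier series.

    ``coefficients`` has one row per joint in :data:`REF_JOINTS` order; the
    left-leg rows equal the right-leg rows phase-shifted by 50 %.
    """

    cycle_duration: float  # s
    coefficients: np.ndarray  # (6, 2H+1), rad
    n_cycles: int = 4
    phase_offset_contralateral: float = 50.0  # % stride
    speed: float = 1.18  # m/s (belt)
    pelvis_height: float = 0.87  # m, builder's hip height at 0 % stride
    pelvis_vy: float = 0.0  # m/s, hip vertical velocity at 0 % stride
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.coefficients = np.ascontiguousarray(self.coefficients, dtype=float)
        if self.coefficients.shape[0] != 6 or self.coefficients.shape[1] % 2 != 1:
            raise ValueError("coefficients must be (6, 2H+1)")
        if self.cycle_duration <= 0 or self.n_cycles < 1:
            raise ValueError("cycle_duration must be > 0 and n_cycles >= 1")

    @property
    def stride_length(self) -> float:
        """Implied stride length relative to the belt: speed x cycle duration."""
        return self.speed * self.cycle_duration

    @property
    def duration(self) -> float:
        return self.n_cycles * self.cycle_duration

    def evaluate(self, t):
        """Angles (rad) and angular velocities (rad/s) at time(s) t."""
        p = np.atleast_1d(np.asarray(t, dtype=float) / self.cycle_duration) % 1.0
        ang, vel = _eval_fourier(self.coefficients, p, deriv=True)
        vel = vel / self.cycle_duration
        if np.ndim(t) == 0:
            return ang[:, 0], vel[:, 0]
        return ang, vel

    def evaluate_phase(self, phase_pct):
        """Angles (rad) at stride phase(s) in %."""
        p = np.atleast_1d(np.asarray(phase_pct, dtype=float)) / 100.0 % 1.0
        ang = _eval_fourier(self.coefficients, p)
        return ang[:, 0] if np.ndim(phase_pct) == 0 else ang


# ---------------------------------------------------------------------------
# constructive builder


def _ik_leg(xa, ya, h_hip, l1, l2):
    """Hip/knee angles for an ankle point relative to the hip at (0, h_hip)."""
    dx = xa
    dy = ya - h_hip
    D = np.hypot(dx, dy)
    Dmax = 0.998 * (l1 + l2)
    if np.any(D > Dmax):
        raise ValueError("reference stride exceeds leg reach; adjust builder parameters")
    gamma = np.arctan2(dx, -dy)
    cos_int = np.clip((l1**2 + l2**2 - D**2) / (2 * l1 * l2), -1.0, 1.0)
    interior = np.arccos(cos_int)
    q_knee = np.pi - interior
    cos_beta = np.clip((l1**2 + D**2 - l2**2) / (2 * l1 * D), -1.0, 1.0)
    beta = np.arccos(cos_beta)
    phi_thigh = gamma + beta  # knee anterior of the hip-ankle line
    phi_shank = phi_thigh - q_knee
    return phi_thigh, phi_shank, q_knee


def _periodic_smooth(samples: np.ndarray, sigma_pct: float) -> np.ndarray:
    """Periodic Gaussian smoothing (std in % stride) via the FFT."""
    n = samples.size
    F = np.fft.rfft(samples)
    k = np.arange(F.size)
    F *= np.exp(-0.5 * (2.0 * np.pi * k * sigma_pct / 100.0) ** 2)
    return np.fft.irfft(F, n)


def _smoothstep(s):
    s = np.clip(s, 0.0, 1.0)
    return s * s * (3.0 - 2.0 * s)


def _rot(psi, vx, vy):
    c, s = np.cos(psi), np.sin(psi)
    return c * vx - s * vy, s * vx + c * vy


def _default_task_space(
    cycle_duration,
    speed,
    sole_y,
    heel_local,
    mtp_local,
    p_hs=PHASE_HEEL_STRIKE,
    p_ff=PHASE_FLATFOOT,
    p_roll=PHASE_ROLL,
    p_to=PHASE_TOE_OFF,
    psi_hs=0.08,
    psi_to=-0.65,
    heel_contact_x=0.19,
    landing_overspeed=0.0,
    roll_rotation=12.0,
):
    """Ankle position and foot pitch of one leg over one stride.

    Stance is built from contact kinematics riding the belt: a short heel
    rocker after the near-flat initial contact, a flat-foot phase, then a
    forefoot roll about the toe-joint contact while the heel rises.  Swing
    is a clearance-shaped spline returning the foot to its most anterior
    position at 0 %/100 % of stride.
    """
    vT = speed * cycle_duration
    dxdp = -vT / 100.0  # belt riding, m per % stride
    heel_x = heel_local[0]  # ankle is at -heel_local from the heel contact
    mtp_x = mtp_local[0]
    # landing overspeed: the foot is commanded slightly faster than the belt
    # through the rocker and tapering off in early flat stance; the friction
    # reaction is propulsive and trims the net fore-aft impulse of the cycle
    beta = landing_overspeed
    taper_end = p_ff + 10.0

    def _extra(p):
        """extra posterior displacement from the overspeed bias up to phase p."""
        p = np.minimum(p, taper_end)
        rock = np.clip(p - p_hs, 0.0, p_ff - p_hs)
        tap = np.clip(p - p_ff, 0.0, 10.0)
        return beta * dxdp * (rock + tap - tap * tap / 20.0)

    def rocker(p):
        """heel-rocker entry [p_hs, p_ff]: heel contact point rides the belt."""
        psi = psi_hs * (1.0 - _smoothstep((p - p_hs) / (p_ff - p_hs)))
        hx = heel_contact_x + dxdp * (p - p_hs) + _extra(p)
        rx, ry = _rot(psi, -heel_x, sole_y)
        return hx + rx, ry, psi

    def flat(p):
        x_ff = heel_contact_x + dxdp * (p_ff - p_hs) - heel_x + _extra(p_ff)
        return (x_ff + dxdp * (p - p_ff) + _extra(p) - _extra(p_ff),
                np.full_like(p, sole_y), np.zeros_like(p))

    x_roll0 = (heel_contact_x + dxdp * (p_roll - p_hs) - heel_x + mtp_x
               + _extra(p_roll))

    def roll(p):
        """forefoot roll [p_roll, p_to]: toe-joint contact rides the belt.

        The pitch rotation (the push-off proper) completes in
        ``roll_rotation`` % of stride; afterwards the foot translates with
        the belt at constant pitch until toe-off, keeping light contact for
        the step-to-step handover without adding late ankle power.
        """
        psi = psi_to * _smoothstep((p - p_roll) / roll_rotation)
        mx = x_roll0 + dxdp * (p - p_roll)
        rx, ry = _rot(psi, -mtp_x, sole_y)
        return mx + rx, ry, psi

    # swing spline [p_to, 100 + p_hs], boundary-matched to the contact phases
    one = np.array([1.0])
    x1, y1, psi1 = (float(v[0]) for v in roll(np.full(1, p_to)))
    eps = 1e-4
    x1e, y1e, psi1e = (float(v[0]) for v in roll(np.full(1, p_to - eps)))
    dx1, dy1, dpsi1 = (x1 - x1e) / eps, (y1 - y1e) / eps, (psi1 - psi1e) / eps
    x_hs, y_hs, _ = (float(v[0]) for v in rocker(np.full(1, p_hs)))

    # the last ~8 % of swing rides the belt-speed line so that an early
    # touch-down meets the belt with matched horizontal velocity (no slip
    # braking at the strike)
    p_end = 100.0 + p_hs
    knots = np.array([p_to, 68.0, 74.0, 84.0, 93.0, 100.0, p_end - 8.0,
                      p_end - 4.0, p_end])
    adx = -dxdp  # belt travel per % (positive)
    sx = CubicSpline(
        knots,
        [x1, -0.31, -0.21, 0.02, 0.20, x_hs + 8.0 * adx + 0.006,
         x_hs + 8.0 * adx, x_hs + 4.0 * adx, x_hs],
        bc_type=((1, dx1), (1, dxdp * (1.0 + beta))),
    )
    sy = CubicSpline(knots, [y1, 0.165, 0.172, 0.150, 0.140, 0.132, 0.127, 0.112, y_hs],
                     bc_type=((1, dy1), (1, -0.009)))
    spsi = CubicSpline(knots, [psi1, -0.50, -0.38, -0.08, 0.05, 0.10, psi_hs, psi_hs, psi_hs],
                       bc_type=((1, dpsi1), (1, 0.0)))

    def task(p):
        """(ankle x, ankle y, foot pitch) at stride phase p in [0, 100)."""
        p = np.atleast_1d(np.asarray(p, dtype=float)) % 100.0
        xa = np.empty_like(p)
        ya = np.empty_like(p)
        psi = np.empty_like(p)
        for mask, fn in (
            (p < p_hs, lambda pp: (sx(pp + 100), sy(pp + 100), spsi(pp + 100))),
            ((p >= p_hs) & (p < p_ff), rocker),
            ((p >= p_ff) & (p < p_roll), flat),
            ((p >= p_roll) & (p <= p_to), roll),
            (p > p_to, lambda pp: (sx(pp), sy(pp), spsi(pp))),
        ):
            if mask.any():
                xa[mask], ya[mask], psi[mask] = fn(p[mask])
        return xa, ya, psi

    stance = dict(p_hs=p_hs, p_ff=p_ff, p_roll=p_roll, p_to=p_to)
    return task, stance


def _pelvis_height_fn(task, l1, l2, p_hs, p_to, margin=0.006,
                      amplitude=0.02, peak_phase=40.0):
    """Smooth periodic pelvis (hip) height consistent with the leg geometry.

    The hip rides a single-harmonic curve (two oscillations per stride, like
    the human pelvis) whose level is fitted just below the leg-reach
    envelope: at every phase each leg bounds the hip height from above by
    hip-knee-ankle triangle closure over its ankle point.  ``peak_phase``
    places the maxima in mid single-stance so the pelvis *descends* through
    terminal stance and each landing, and rises only once the new stance leg
    has the load -- this keeps the step-to-step transition from launching
    the model into flight.  Knee flexion emerges from inverse kinematics.
    """
    dmax = 0.995 * (l1 + l2)
    pp = np.arange(0.0, 100.0, 0.25)
    U = np.full(pp.size, np.inf)
    for shift in (0.0, 50.0):
        xa, ya, _ = task((pp + shift) % 100.0)
        reach = dmax * dmax - xa * xa
        ok = reach > 0
        U[ok] = np.minimum(U[ok], ya[ok] + np.sqrt(reach[ok]))
    wave = amplitude * np.cos(4.0 * np.pi * (pp - peak_phase) / 100.0)
    h0 = float(np.min(U - margin - wave))
    coeffs = np.zeros(2 * 2 + 1)
    coeffs[0] = h0
    # a0 + a2 cos(2*2pi p) + b2 sin(...) reproduces the designed wave
    coeffs[2] = amplitude * np.cos(4.0 * np.pi * peak_phase / 100.0)
    coeffs[4] = amplitude * np.sin(4.0 * np.pi * peak_phase / 100.0)

    def h(p, deriv: bool = False):
        frac = np.atleast_1d(np.asarray(p, dtype=float)) / 100.0 % 1.0
        if deriv:
            ang, vel = _eval_fourier(coeffs[None, :], frac, deriv=True)
            return ang[0], vel[0] / 100.0  # per % stride
        return _eval_fourier(coeffs[None, :], frac)[0]

    return h


def make_reference(
    cycle_duration: float = 1.21,
    speed: float = 1.18,
    harmonics: np.ndarray | None = None,
    n_cycles: int = 4,
    n_harmonics: int = 20,
    smoothing_pct: float = 1.0,
    thigh_length: float = 0.42,
    shank_length: float = 0.43,
    sole_height: float = 0.07,
    heel_local: tuple[float, float] = (-0.055, -0.07),
    mtp_local: tuple[float, float] = (0.13, -0.07),
    heel_strike_phase: float = PHASE_HEEL_STRIKE,
    flatfoot_phase: float = PHASE_FLATFOOT,
    roll_phase: float = PHASE_ROLL,
    toe_off_phase: float = PHASE_TOE_OFF,
    heel_contact_x: float = 0.19,
    landing_overspeed: float = 0.0,
    toe_off_pitch: float = -0.8,
) -> GaitReference:
    """Build the periodic reference; defaults emulate treadmill gait at
    1.18 m/s with a 1.21 s cycle.

    If ``harmonics`` (a (6, 2H+1) coefficient array) is given it is used
    directly and the constructive builder is skipped.  ``heel_local`` /
    ``mtp_local`` are the ground contact points of heel and toe joint in the
    foot frame (sphere bottoms in the standing pose).
    """
    if harmonics is not None:
        return GaitReference(
            cycle_duration=cycle_duration,
            coefficients=np.asarray(harmonics, dtype=float),
            n_cycles=n_cycles,
            speed=speed,
        )
    task, stance = _default_task_space(
        cycle_duration, speed, sole_height, heel_local, mtp_local,
        heel_strike_phase, flatfoot_phase, roll_phase, toe_off_phase,
        heel_contact_x=heel_contact_x, landing_overspeed=landing_overspeed,
        psi_to=toe_off_pitch,
    )
    h_fn = _pelvis_height_fn(task, thigh_length, shank_length,
                             heel_strike_phase, toe_off_phase)
    n = 2048
    pp = np.arange(n) / n * 100.0
    xa, ya, psi = task(pp)
    # smooth the *task-space* stride before inverse kinematics: smoothing
    # joint angles directly would break the foot-belt velocity consistency
    # at the contact-phase kinks
    if smoothing_pct > 0.0:
        xa = _periodic_smooth(xa, smoothing_pct)
        ya = _periodic_smooth(ya, smoothing_pct)
        psi = _periodic_smooth(psi, smoothing_pct)
    h = h_fn(pp)
    phi_t, phi_s, q_knee = _ik_leg(xa, ya - h, 0.0, thigh_length, shank_length)
    q_hip = phi_t  # pelvis reference orientation is 0
    q_ankle = psi - phi_s
    pelvis_height = float(h[0])
    dh0 = float(h_fn(0.0, deriv=True)[1][0])  # m per % stride
    coeffs = np.empty((6, 2 * n_harmonics + 1))
    coeffs[0] = _fit_fourier(q_hip, n_harmonics)
    coeffs[1] = _fit_fourier(q_knee, n_harmonics)
    coeffs[2] = _fit_fourier(q_ankle, n_harmonics)
    # contralateral leg: identical pattern shifted by 50 % of stride
    H = n_harmonics
    k = np.arange(1, H + 1)
    flip = (-1.0) ** k
    for j in range(3):
        coeffs[3 + j, 0] = coeffs[j, 0]
        coeffs[3 + j, 1 : H + 1] = coeffs[j, 1 : H + 1] * flip
        coeffs[3 + j, H + 1 :] = coeffs[j, H + 1 :] * flip
    return GaitReference(
        cycle_duration=cycle_duration,
        coefficients=coeffs,
        n_cycles=n_cycles,
        speed=speed,
        pelvis_height=pelvis_height,
        pelvis_vy=dh0 * 100.0 / cycle_duration,
        meta={
            "heel_strike_phase": heel_strike_phase,
            "flatfoot_phase": flatfoot_phase,
            "roll_phase": roll_phase,
            "toe_off_phase": toe_off_phase,
            "n_harmonics": n_harmonics,
        },
    )


# ---------------------------------------------------------------------------
# kinematic adjustment (solution space of the optimization)


@dataclass
class KinematicAdjustment:
    """Knot offsets (rad) added to hip/knee/ankle reference trajectories.

    ``offsets`` is (3, n_knots) for the exoskeleton-side leg only, or
    (6, n_knots) for both legs, rows in :data:`REF_JOINTS` order.  Knots are
    evenly spaced in stride phase and interpolated by a periodic cubic
    spline.  The lumbo-sacral joint is never part of the adjustment.
    """

    offsets: np.ndarray
    bound: float = np.deg2rad(5.0)

    def __post_init__(self):
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.ndim != 2 or self.offsets.shape[0] not in (3, 6):
            raise ValueError("offsets must be (3, n_knots) or (6, n_knots)")
        if np.any(np.abs(self.offsets) > self.bound + 1e-12):
            raise ValueError("adjustment exceeds the solution-space bound")

    @property
    def n_knots(self) -> int:
        return self.offsets.shape[1]


def adjust_reference(base: GaitReference, adjustment: KinematicAdjustment) -> GaitReference:
    """Apply knot offsets to the reference and re-fit the Fourier series."""
    nk = adjustment.n_knots
    H = (base.coefficients.shape[1] - 1) // 2
    n = max(512, 8 * nk)
    pp = np.arange(n) / n  # stride fraction
    ang = _eval_fourier(base.coefficients, pp)  # (6, n)
    knots = np.arange(nk + 1) / nk
    rows = adjustment.offsets.shape[0]
    new = ang.copy()
    for r in range(rows):
        vals = np.append(adjustment.offsets[r], adjustment.offsets[r, 0])
        spl = CubicSpline(knots, vals, bc_type="periodic")
        new[r] += spl(pp)
    coeffs = np.vstack([_fit_fourier(new[j], H) for j in range(6)])
    return GaitReference(
        cycle_duration=base.cycle_duration,
        coefficients=coeffs,
        n_cycles=base.n_cycles,
        phase_offset_contralateral=base.phase_offset_contralateral,
        speed=base.speed,
        pelvis_height=base.pelvis_height,
        pelvis_vy=base.pelvis_vy,
        meta=dict(base.meta),
    )


# ---------------------------------------------------------------------------
# delimited-file I/O for user-supplied kinematics


def write_reference(ref: GaitReference, path, n_samples: int = 200) -> None:
    """Write phase (%) + joint angle (rad) columns, one stride."""
    pp = np.arange(n_samples) / n_samples
    ang = _eval_fourier(ref.coefficients, pp)
    df = pd.DataFrame({"phase": pp * 100.0})
    for j, name in enumerate(REF_JOINTS):
        df[name] = ang[j]
    df.to_csv(path, index=False)


def read_reference(
    path,
    cycle_duration: float = 1.21,
    speed: float = 1.18,
    n_cycles: int = 4,
    n_harmonics: int = 12,
    pelvis_height: float = 0.87,
) -> GaitReference:
    """Read per-joint angles vs stride phase from a delimited file.

    The file needs a ``phase`` column (% stride) plus one column per joint in
    :data:`REF_JOINTS`.  Trajectories must be periodic: if both 0 % and 100 %
    rows are present they must agree.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("phase", *REF_JOINTS) if c not in df.columns]
    if missing:
        raise ValueError(f"reference file lacks columns: {missing}")
    phase = df["phase"].to_numpy(dtype=float)
    if phase.max() > 100.0 + 1e-9 or phase.min() < 0.0:
        raise ValueError("phase column must lie in [0, 100]")
    has_end = np.isclose(phase[-1], 100.0)
    coeffs = np.empty((6, 2 * n_harmonics + 1))
    n = 1024
    pp = np.arange(n) / n * 100.0
    for j, name in enumerate(REF_JOINTS):
        y = df[name].to_numpy(dtype=float)
        if has_end and abs(y[-1] - y[0]) > 1e-6:
            raise ValueError(f"column {name} is not periodic (0% and 100% differ)")
        grid = np.interp(pp, phase, y, period=100.0)
        coeffs[j] = _fit_fourier(grid, n_harmonics)
    return GaitReference(
        cycle_duration=cycle_duration, coefficients=coeffs, n_cycles=n_cycles,
        speed=speed, pelvis_height=pelvis_height,
    )
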