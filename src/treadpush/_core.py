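"""Numba kernels for planar articulated-chain dynamics.

The walking model is a kinematic tree of planar rigid bodies.  Body 0 is the
floating base (pelvis) whose frame pose is (q[0], q[1], q[2]).  Every other
body b attaches to ``parent[b]`` at a point ``attach[b]`` expressed in the
parent frame, and rotates relative to the parent by ``sigma[b] * q[jc[b]]``
where ``jc[b]`` is the body's generalized-coordinate index.  In the zero
configuration all body frames are aligned with the world frame (x anterior,
y up), which lets all geometry be written down in the standing pose.

Inverse dynamics uses a planar recursive Newton-Euler pass; the mass matrix
is assembled column-wise from unit-acceleration inverse-dynamics calls and
the bias vector from a zero-acceleration call.  External point forces map to
generalized forces by walking the tree towards the root (Jacobian-transpose
without forming Jacobians).
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# kinematics


@njit(cache=True)
def fk_pass(q, qd, parent, sigma, jc, attach):
    """Forward kinematics: frame angles, angular rates, origin pos/vel."""
    n = parent.shape[0]
    phi = np.empty(n)
    w = np.empty(n)
    p = np.empty((n, 2))
    v = np.empty((n, 2))
    phi[0] = q[2]
    w[0] = qd[2]
    p[0, 0] = q[0]
    p[0, 1] = q[1]
    v[0, 0] = qd[0]
    v[0, 1] = qd[1]
    for b in range(1, n):
        par = parent[b]
        phi[b] = phi[par] + sigma[b] * q[jc[b]]
        w[b] = w[par] + sigma[b] * qd[jc[b]]
        c = np.cos(phi[par])
        s = np.sin(phi[par])
        wx = c * attach[b, 0] - s * attach[b, 1]
        wy = s * attach[b, 0] + c * attach[b, 1]
        p[b, 0] = p[par, 0] + wx
        p[b, 1] = p[par, 1] + wy
        v[b, 0] = v[par, 0] - w[par] * wy
        v[b, 1] = v[par, 1] + w[par] * wx
    return phi, w, p, v


@njit(cache=True)
def body_point(b, local, phi, p):
    """World position of a point given in body b's frame."""
    c = np.cos(phi[b])
    s = np.sin(phi[b])
    return np.array(
        [
            p[b, 0] + c * local[0] - s * local[1],
            p[b, 1] + s * local[0] + c * local[1],
        ]
    )


@njit(cache=True)
def body_point_vel(b, local, phi, w, p, v):
    c = np.cos(phi[b])
    s = np.sin(phi[b])
    rx = c * local[0] - s * local[1]
    ry = s * local[0] + c * local[1]
    return np.array([v[b, 0] - w[b] * ry, v[b, 1] + w[b] * rx])


@njit(cache=True)
def inv_dyn(q, qd, qdd, g, parent, sigma, jc, attach, mass, inertia, com):
    """Generalized forces required for (q, qd, qdd) under gravity g (>= 0, down).

    Returns Q with M(q) qdd + h(q, qd) = Q_applied convention:
    Q = inv_dyn(q, qd, qdd) is the applied generalized force producing qdd.
    """
    n = parent.shape[0]
    nq = 3 + (n - 1)
    phi = np.empty(n)
    w = np.empty(n)
    al = np.empty(n)
    p = np.empty((n, 2))
    v = np.empty((n, 2))
    a = np.empty((n, 2))
    phi[0] = q[2]
    w[0] = qd[2]
    al[0] = qdd[2]
    p[0, 0] = q[0]
    p[0, 1] = q[1]
    v[0, 0] = qd[0]
    v[0, 1] = qd[1]
    a[0, 0] = qdd[0]
    a[0, 1] = qdd[1]
    for b in range(1, n):
        par = parent[b]
        phi[b] = phi[par] + sigma[b] * q[jc[b]]
        w[b] = w[par] + sigma[b] * qd[jc[b]]
        al[b] = al[par] + sigma[b] * qdd[jc[b]]
        c = np.cos(phi[par])
        s = np.sin(phi[par])
        wx = c * attach[b, 0] - s * attach[b, 1]
        wy = s * attach[b, 0] + c * attach[b, 1]
        p[b, 0] = p[par, 0] + wx
        p[b, 1] = p[par, 1] + wy
        v[b, 0] = v[par, 0] - w[par] * wy
        v[b, 1] = v[par, 1] + w[par] * wx
        ww = w[par] * w[par]
        a[b, 0] = a[par, 0] - al[par] * wy - ww * wx
        a[b, 1] = a[par, 1] + al[par] * wx - ww * wy
    # net inertial force/torque per body, accumulated up the tree
    F = np.zeros((n, 2))
    N = np.zeros(n)  # moment about body origin p[b]
    for b in range(n):
        c = np.cos(phi[b])
        s = np.sin(phi[b])
        rcx = c * com[b, 0] - s * com[b, 1]
        rcy = s * com[b, 0] + c * com[b, 1]
        ww = w[b] * w[b]
        acx = a[b, 0] - al[b] * rcy - ww * rcx
        acy = a[b, 1] + al[b] * rcx - ww * rcy
        fx = mass[b] * acx
        fy = mass[b] * (acy + g)
        F[b, 0] += fx
        F[b, 1] += fy
        N[b] += inertia[b] * al[b] + rcx * fy - rcy * fx
    Q = np.zeros(nq)
    for b in range(n - 1, 0, -1):
        par = parent[b]
        Q[jc[b]] = sigma[b] * N[b]
        F[par, 0] += F[b, 0]
        F[par, 1] += F[b, 1]
        N[par] += N[b] + (p[b, 0] - p[par, 0]) * F[b, 1] - (p[b, 1] - p[par, 1]) * F[b, 0]
    Q[0] = F[0, 0]
    Q[1] = F[0, 1]
    Q[2] = N[0]
    return Q


@njit(cache=True)
def mass_matrix(q, parent, sigma, jc, attach, mass, inertia, com):
    n = parent.shape[0]
    nq = 3 + (n - 1)
    M = np.empty((nq, nq))
    zero = np.zeros(nq)
    e = np.zeros(nq)
    for i in range(nq):
        e[i] = 1.0
        M[:, i] = inv_dyn(q, zero, e, 0.0, parent, sigma, jc, attach, mass, inertia, com)
        e[i] = 0.0
    # symmetrize against round-off
    for i in range(nq):
        for j in range(i + 1, nq):
            m = 0.5 * (M[i, j] + M[j, i])
            M[i, j] = m
            M[j, i] = m
    return M


@njit(cache=True)
def add_point_force(Q, b, pt, fx, fy, parent, sigma, jc, p):
    """Accumulate generalized force of a world force (fx, fy) at world point pt on body b."""
    Q[0] += fx
    Q[1] += fy
    Q[2] += (pt[0] - p[0, 0]) * fy - (pt[1] - p[0, 1]) * fx
    bb = b
    while bb > 0:
        Q[jc[bb]] += sigma[bb] * ((pt[0] - p[bb, 0]) * fy - (pt[1] - p[bb, 1]) * fx)
        bb = parent[bb]


@njit(cache=True)
def add_body_torque(Q, b, tz, parent, sigma, jc):
    Q[2] += tz
    bb = b
    while bb > 0:
        Q[jc[bb]] += sigma[bb] * tz
        bb = parent[bb]


# ---------------------------------------------------------------------------
# foot-ground contact (Hunt-Crossley normal force, tanh-regularized Coulomb
# friction relative to the belt surface)


@njit(cache=True)
def contact_force(cy, cvx, cvy, radius, belt_speed, k_n, e_n, c_n, mu, v_smooth):
    """Normal and tangential force on a sphere from the treadmill plane y=0.

    The belt surface moves with velocity -belt_speed along x.  Returns
    (fn, ft) acting on the sphere (fn >= 0 up, ft along x).
    """
    delta = radius - cy
    if delta <= 0.0:
        return 0.0, 0.0
    ddot = -cvy
    fn = k_n * delta ** e_n * (1.0 + c_n * ddot)
    if fn < 0.0:
        fn = 0.0
    v_rel = cvx + belt_speed
    ft = -mu * fn * np.tanh(v_rel / v_smooth)
    return fn, ft


# ---------------------------------------------------------------------------
# periodic reference evaluation (truncated Fourier series over stride phase)


@njit(cache=True)
def ref_eval(t, cycle_t, coeffs, out_ang, out_vel):
    """Evaluate reference angles/velocities for each row of coeffs.

    coeffs[j] = [a0, a1..aH, b1..bH]; angle(p) = a0 + sum a_k cos(2 pi k p)
    + b_k sin(2 pi k p) with p = t/T mod 1.
    """
    nj, nc = coeffs.shape
    H = (nc - 1) // 2
    p = (t / cycle_t) % 1.0
    two_pi = 2.0 * np.pi
    for j in range(nj):
        ang = coeffs[j, 0]
        vel = 0.0
        for k in range(1, H + 1):
            ck = np.cos(two_pi * k * p)
            sk = np.sin(two_pi * k * p)
            a = coeffs[j, k]
            b = coeffs[j, H + k]
            ang += a * ck + b * sk
            vel += two_pi * k / cycle_t * (-a * sk + b * ck)
        out_ang[j] = ang
        out_vel[j] = vel


# ---------------------------------------------------------------------------
# full model right-hand side

# body indices of the walking model (fixed topology)
B_PELVIS, B_HAT = 0, 1
B_RTHIGH, B_RSHANK, B_RFOOT, B_RTOES = 2, 3, 4, 5
B_LTHIGH, B_LSHANK, B_LFOOT, B_LTOES = 6, 7, 8, 9

# generalized-coordinate indices of tracked joints and their reference rows
TRACKED_Q = np.array([4, 5, 6, 8, 9, 10], dtype=np.int64)
MTP_Q = np.array([7, 11], dtype=np.int64)
Q_LS = 3


@njit(cache=True)
def walker_forces(
    t,
    q,
    qd,
    eint,
    # topology / inertia
    parent,
    sigma,
    jc,
    attach,
    mass,
    inertia,
    com,
    # reference
    cycle_t,
    ref_coeffs,
    # controller: per tracked joint kp, ki, kd; hat (kp, kd); int limit; mtp spring
    kp,
    ki,
    kd,
    hat_kp,
    hat_kd,
    int_limit,
    pp_kp,
    pp_kd,
    ank_kp,
    ank_kd,
    sk_kx,
    sk_kv,
    mtp_k,
    mtp_c,
    # contact
    sph_body,
    sph_local,
    sph_radius,
    belt_speed,
    k_n,
    e_n,
    c_n,
    mu,
    v_smooth,
    # exoskeleton
    exo_on,
    engaged,
    snap_d0,
    snap_l0,
    exo_k,
    exo_ratio,
    anchor,
    spool_local,
    shank_local,
    gravity,
):
    """Compute applied generalized forces plus per-channel observables.

    Returns (Q, eint_dot, tau_joint[9], grf[4], sphere_fn[6], f_elastic,
    assist_tau) where grf is (ap_R, vert_R, ap_L, vert_L) and assist_tau the
    generalized ankle torque of all exoskeleton forces.
    """
    nq = q.shape[0]
    phi, w, p, v = fk_pass(q, qd, parent, sigma, jc, attach)
    Q = np.zeros(nq)
    eint_dot = np.zeros(6)
    tau_joint = np.zeros(9)

    ref_ang = np.empty(6)
    ref_vel = np.empty(6)
    ref_eval(t, cycle_t, ref_coeffs, ref_ang, ref_vel)

    # foot-ground contact (first: posture feedback is weight-scheduled)
    grf = np.zeros(4)
    sphere_fn = np.zeros(sph_body.shape[0])
    for i in range(sph_body.shape[0]):
        b = sph_body[i]
        cw = body_point(b, sph_local[i], phi, p)
        cv = body_point_vel(b, sph_local[i], phi, w, p, v)
        fn, ft = contact_force(
            cw[1], cv[0], cv[1], sph_radius[i], belt_speed, k_n, e_n, c_n, mu, v_smooth
        )
        sphere_fn[i] = fn
        if fn > 0.0 or ft != 0.0:
            cp = np.array([cw[0], cw[1] - sph_radius[i]])
            add_point_force(Q, b, cp, ft, fn, parent, sigma, jc, p)
            if b == B_RFOOT or b == B_RTOES:
                grf[0] += ft
                grf[1] += fn
            else:
                grf[2] += ft
                grf[3] += fn
    weight = mass.sum() * gravity
    load_r = min((sphere_fn[0] + sphere_fn[1] + sphere_fn[2]) / weight, 1.0)
    load_l = min((sphere_fn[3] + sphere_fn[4] + sphere_fn[5]) / weight, 1.0)

    # station keeping: a stance-hip torque bias (load-scheduled) pushes the
    # trunk towards the treadmill origin, regulating the otherwise neutral
    # antero-posterior drift of treadmill walking
    sk_tau = sk_kx * q[0] + sk_kv * qd[0]
    if sk_tau > 60.0:
        sk_tau = 60.0
    elif sk_tau < -60.0:
        sk_tau = -60.0
    for c, load in ((4, load_r), (8, load_l)):
        tau = load * sk_tau
        Q[c] += tau
        tau_joint[c - 3] += tau

    # PID tracking of hip/knee/ankle on both legs
    for k in range(6):
        c = TRACKED_Q[k]
        e = ref_ang[k] - q[c]
        ed = ref_vel[k] - qd[c]
        i_term = ki[k] * eint[k]
        if i_term > int_limit:
            i_term = int_limit
        elif i_term < -int_limit:
            i_term = -int_limit
        tau = kp[k] * e + i_term + kd[k] * ed
        Q[c] += tau
        tau_joint[c - 3] += tau
        # conditional anti-windup: stop integrating when saturated and error
        # drives further into saturation
        sat = ki[k] * eint[k]
        if (sat >= int_limit and e > 0.0) or (sat <= -int_limit and e < 0.0):
            eint_dot[k] = 0.0
        else:
            eint_dot[k] = e

    # trunk-upright feedback at the lumbo-sacral joint (phi_hat -> 0)
    tau_ls = hat_kp * phi[B_HAT] + hat_kd * w[B_HAT]
    Q[Q_LS] += tau_ls
    tau_joint[Q_LS - 3] += tau_ls

    # pelvis-pitch posture feedback (the floating-base orientation is
    # otherwise unregulated): through the hip actuators (reaction torque on
    # the pelvis) and, weight-scheduled, through the loaded ankle, which
    # shifts the center of pressure under the stance foot
    e_th = q[2]
    tau_pp = pp_kp * e_th + pp_kd * qd[2]
    for c in (4, 8):
        Q[c] += 0.5 * tau_pp
        tau_joint[c - 3] += 0.5 * tau_pp
    for c, load in ((6, load_r), (10, load_l)):
        tau = load * (ank_kp * e_th + ank_kd * qd[2])
        Q[c] += tau
        tau_joint[c - 3] += tau

    # passive metatarsophalangeal springs
    for i in range(2):
        c = MTP_Q[i]
        tau = -mtp_k * q[c] - mtp_c * qd[c]
        Q[c] += tau
        tau_joint[c - 3] += tau

    # exoskeleton (worn on the right leg)
    f_elastic = 0.0
    assist_tau = 0.0
    if exo_on and engaged:
        spool = body_point(B_RFOOT, spool_local, phi, p)
        sh = body_point(B_RSHANK, shank_local, phi, p)
        dax = anchor[0] - spool[0]
        day = anchor[1] - spool[1]
        d = np.sqrt(dax * dax + day * day)
        lsx = sh[0] - spool[0]
        lsy = sh[1] - spool[1]
        l = np.sqrt(lsx * lsx + lsy * lsy)
        elong = (d - snap_d0) + exo_ratio * (l - snap_l0)
        if elong > 0.0 and d > 1e-9 and l > 1e-9:
            f_elastic = exo_k * elong
            f_rigid = exo_ratio * f_elastic
            Qx = np.zeros(nq)
            # elastic tendon pulls the spool-axis point towards the anchor
            add_point_force(
                Qx, B_RFOOT, spool, f_elastic * dax / d, f_elastic * day / d,
                parent, sigma, jc, p,
            )
            # rigid tendon pulls spool point and shank attachment together
            add_point_force(
                Qx, B_RFOOT, spool, f_rigid * lsx / l, f_rigid * lsy / l,
                parent, sigma, jc, p,
            )
            add_point_force(
                Qx, B_RSHANK, sh, -f_rigid * lsx / l, -f_rigid * lsy / l,
                parent, sigma, jc, p,
            )
            assist_tau = Qx[6]  # right-ankle generalized component
            Q += Qx

    return Q, eint_dot, tau_joint, grf, sphere_fn, f_elastic, assist_tau


@njit(cache=True)
def walker_rhs(
    t,
    y,
    parent,
    sigma,
    jc,
    attach,
    mass,
    inertia,
    com,
    cycle_t,
    ref_coeffs,
    kp,
    ki,
    kd,
    hat_kp,
    hat_kd,
    int_limit,
    pp_kp,
    pp_kd,
    ank_kp,
    ank_kd,
    sk_kx,
    sk_kv,
    mtp_k,
    mtp_c,
    sph_body,
    sph_local,
    sph_radius,
    belt_speed,
    k_n,
    e_n,
    c_n,
    mu,
    v_smooth,
    exo_on,
    engaged,
    snap_d0,
    snap_l0,
    exo_k,
    exo_ratio,
    anchor,
    spool_local,
    shank_local,
    gravity,
):
    nq = 3 + (parent.shape[0] - 1)
    q = y[:nq]
    qd = y[nq : 2 * nq]
    eint = y[2 * nq : 2 * nq + 6]
    Q, eint_dot, _, _, _, _, _ = walker_forces(
        t, q, qd, eint,
        parent, sigma, jc, attach, mass, inertia, com,
        cycle_t, ref_coeffs,
        kp, ki, kd, hat_kp, hat_kd, int_limit, pp_kp, pp_kd, ank_kp, ank_kd,
        sk_kx, sk_kv, mtp_k, mtp_c,
        sph_body, sph_local, sph_radius,
        belt_speed, k_n, e_n, c_n, mu, v_smooth,
        exo_on, engaged, snap_d0, snap_l0, exo_k, exo_ratio,
        anchor, spool_local, shank_local, gravity,
    )
    h = inv_dyn(q, qd, np.zeros(nq), gravity, parent, sigma, jc, attach, mass, inertia, com)
    M = mass_matrix(q, parent, sigma, jc, attach, mass, inertia, com)
    qdd = np.linalg.solve(M, Q - h)
    out = np.empty(2 * nq + 6)
    out[:nq] = qd
    out[nq : 2 * nq] = qdd
    out[2 * nq : 2 * nq + 6] = eint_dot
    return out


@njit(cache=True)
def mech_energy(q, qd, parent, sigma, jc, attach, mass, inertia, com, gravity):
    """Total mechanical energy (kinetic + gravitational potential)."""
    n = parent.shape[0]
    phi, w, p, v = fk_pass(q, qd, parent, sigma, jc, attach)
    E = 0.0
    for b in range(n):
        c = np.cos(phi[b])
        s = np.sin(phi[b])
        rcx = c * com[b, 0] - s * com[b, 1]
        rcy = s * com[b, 0] + c * com[b, 1]
        vcx = v[b, 0] - w[b] * rcy
        vcy = v[b, 1] + w[b] * rcx
        E += 0.5 * mass[b] * (vcx * vcx + vcy * vcy)
        E += 0.5 * inertia[b] * w[b] * w[b]
        E += mass[b] * gravity * (p[b, 1] + rcy)
    return E
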