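"""Numba-compiled physics core: planar skeleton dynamics, Hill muscles,
Hunt-Crossley contact and the closed-loop delayed-feedback simulation loop.

All quantities here are SI with angles in radians.  Generalized coordinates
q = (pelvis_x, pelvis_z, pelvis_tilt, hip_flexion, knee_angle, ankle_angle);
segment orientations are the cumulative sums described in ``params``.

Packed parameter layout (built by ``model.PackedModel``):

* ``seg``      (4,4): rows trunk/thigh/shank/foot, cols mass, com offset,
                length, inertia.  Leg rows enter with multiplicity 2.
* ``foot_com`` (2,):  foot COM in the foot frame (origin ankle).
* ``sph_off``  (2,2), ``sph_r`` (2,), ``sph_par`` (2,4): per sphere
                stiffness k, exponent n, damping c, friction mu.
* muscle arrays (9,) / (9,3): see ``model``.
* ``gains``    (9,10): u0, K_l, K_ldot, K_F, K_cop, K_xddot, K_phi,
                K_phiddot, K_x, K_xdot per muscle; ``lm0`` (9,);
                ``refs`` (3,): x_cop0, phi0, x0; ``delays`` (9,3) int64
                control steps (somatosensory, vestibular, visual).

Sensor channel order in the delay buffer (33 channels):
0-8 l_m, 9-17 l_m_dot, 18-26 F_m, 27 COP (foot-relative), 28 head x_ddot,
29 head phi, 30 head phi_ddot, 31 head x, 32 head x_dot.
"""

import math

import numpy as np
from numba import njit

N_MUSCLES = 9
N_Q = 6
N_CHANNELS = 33

# leg segments (thigh, shank, foot) and feet are mirrored: multiplicity 2
_MULT = (1.0, 2.0, 2.0, 2.0)


# ---------------------------------------------------------------------------
# kinematics
# ---------------------------------------------------------------------------

@njit(cache=True)
def _angles(q):
    e_t = q[2]
    e_th = q[2] + q[3]
    e_sh = e_th + q[4]
    e_f = e_sh + q[5]
    return e_t, e_th, e_sh, e_f


@njit(cache=True)
def fk_points(q, seg, foot_com):
    """Joint points, segment COM positions and orientations.

    Returns (hip, knee, ankle) as (2,) arrays, compos (4,2), eps (4,).
    """
    e_t, e_th, e_sh, e_f = _angles(q)
    ct = seg[0, 1]
    cth = seg[1, 1]
    csh = seg[2, 1]
    lth = seg[1, 2]
    lsh = seg[2, 2]

    hip = np.empty(2)
    hip[0] = q[0]
    hip[1] = q[1]
    knee = np.empty(2)
    knee[0] = hip[0] + lth * math.sin(e_th)
    knee[1] = hip[1] - lth * math.cos(e_th)
    ankle = np.empty(2)
    ankle[0] = knee[0] + lsh * math.sin(e_sh)
    ankle[1] = knee[1] - lsh * math.cos(e_sh)

    compos = np.empty((4, 2))
    compos[0, 0] = hip[0] - ct * math.sin(e_t)
    compos[0, 1] = hip[1] + ct * math.cos(e_t)
    compos[1, 0] = hip[0] + cth * math.sin(e_th)
    compos[1, 1] = hip[1] - cth * math.cos(e_th)
    compos[2, 0] = knee[0] + csh * math.sin(e_sh)
    compos[2, 1] = knee[1] - csh * math.cos(e_sh)
    cf, sf = math.cos(e_f), math.sin(e_f)
    compos[3, 0] = ankle[0] + cf * foot_com[0] - sf * foot_com[1]
    compos[3, 1] = ankle[1] + sf * foot_com[0] + cf * foot_com[1]

    eps = np.empty(4)
    eps[0] = e_t
    eps[1] = e_th
    eps[2] = e_sh
    eps[3] = e_f
    return hip, knee, ankle, compos, eps


@njit(cache=True)
def com_position(q, seg, foot_com):
    """Mass-weighted whole-body COM (x, z) and total mass."""
    hip, knee, ankle, compos, eps = fk_points(q, seg, foot_com)
    mx = 0.0
    mz = 0.0
    mtot = 0.0
    for s in range(4):
        m = _MULT[s] * seg[s, 0]
        mx += m * compos[s, 0]
        mz += m * compos[s, 1]
        mtot += m
    return mx / mtot, mz / mtot, mtot


@njit(cache=True)
def _jacobians(q, qd, seg, foot_com):
    """COM Jacobians J (4,2,6), their time derivatives Jd, angular rows W."""
    e_t, e_th, e_sh, e_f = _angles(q)
    de_t = qd[2]
    de_th = qd[2] + qd[3]
    de_sh = de_th + qd[4]
    de_f = de_sh + qd[5]

    ct = seg[0, 1]
    cth = seg[1, 1]
    csh = seg[2, 1]
    lth = seg[1, 2]
    lsh = seg[2, 2]

    J = np.zeros((4, 2, 6))
    Jd = np.zeros((4, 2, 6))
    W = np.zeros((4, 6))
    for s in range(4):
        J[s, 0, 0] = 1.0
        J[s, 1, 1] = 1.0

    # trunk: hip + ct * u(e_t), u = (-sin, cos), u' = (-cos, -sin)
    upx, upz = -ct * math.cos(e_t), -ct * math.sin(e_t)
    J[0, 0, 2] = upx
    J[0, 1, 2] = upz
    Jd[0, 0, 2] = ct * math.sin(e_t) * de_t
    Jd[0, 1, 2] = -ct * math.cos(e_t) * de_t
    W[0, 2] = 1.0

    # d(e) = (sin, -cos), d'(e) = (cos, sin), d'' = -d
    dthx, dthz = math.cos(e_th), math.sin(e_th)      # d'(e_th)
    dshx, dshz = math.cos(e_sh), math.sin(e_sh)      # d'(e_sh)
    dthx2, dthz2 = -math.sin(e_th), math.cos(e_th)   # -d(e_th)
    dshx2, dshz2 = -math.sin(e_sh), math.cos(e_sh)   # -d(e_sh)

    # thigh: hip + cth * d(e_th); e_th depends on q2, q3
    for c in (2, 3):
        J[1, 0, c] = cth * dthx
        J[1, 1, c] = cth * dthz
        Jd[1, 0, c] = cth * dthx2 * de_th
        Jd[1, 1, c] = cth * dthz2 * de_th
    W[1, 2] = 1.0
    W[1, 3] = 1.0

    # shank: hip + lth d(e_th) + csh d(e_sh)
    for c in (2, 3):
        J[2, 0, c] = lth * dthx + csh * dshx
        J[2, 1, c] = lth * dthz + csh * dshz
        Jd[2, 0, c] = lth * dthx2 * de_th + csh * dshx2 * de_sh
        Jd[2, 1, c] = lth * dthz2 * de_th + csh * dshz2 * de_sh
    J[2, 0, 4] = csh * dshx
    J[2, 1, 4] = csh * dshz
    Jd[2, 0, 4] = csh * dshx2 * de_sh
    Jd[2, 1, 4] = csh * dshz2 * de_sh
    W[2, 2] = 1.0
    W[2, 3] = 1.0
    W[2, 4] = 1.0

    # foot: hip + lth d(e_th) + lsh d(e_sh) + R(e_f) fc
    cf, sf = math.cos(e_f), math.sin(e_f)
    rx = cf * foot_com[0] - sf * foot_com[1]
    rz = sf * foot_com[0] + cf * foot_com[1]
    rpx = -sf * foot_com[0] - cf * foot_com[1]   # R'(e_f) fc
    rpz = cf * foot_com[0] - sf * foot_com[1]
    for c in (2, 3):
        J[3, 0, c] = lth * dthx + lsh * dshx + rpx
        J[3, 1, c] = lth * dthz + lsh * dshz + rpz
        Jd[3, 0, c] = (lth * dthx2 * de_th + lsh * dshx2 * de_sh - rx * de_f)
        Jd[3, 1, c] = (lth * dthz2 * de_th + lsh * dshz2 * de_sh - rz * de_f)
    J[3, 0, 4] = lsh * dshx + rpx
    J[3, 1, 4] = lsh * dshz + rpz
    Jd[3, 0, 4] = lsh * dshx2 * de_sh - rx * de_f
    Jd[3, 1, 4] = lsh * dshz2 * de_sh - rz * de_f
    J[3, 0, 5] = rpx
    J[3, 1, 5] = rpz
    Jd[3, 0, 5] = -rx * de_f
    Jd[3, 1, 5] = -rz * de_f
    W[3, 2] = 1.0
    W[3, 3] = 1.0
    W[3, 4] = 1.0
    W[3, 5] = 1.0
    return J, Jd, W


@njit(cache=True)
def mass_bias_grav(q, qd, seg, foot_com, g):
    """Mass matrix M, velocity bias h and gravity generalized force Qg.

    Equations of motion: M qdd + h = Qg + Q_muscle + Q_contact.
    """
    J, Jd, W = _jacobians(q, qd, seg, foot_com)
    M = np.zeros((6, 6))
    h = np.zeros(6)
    Qg = np.zeros(6)
    for s in range(4):
        m = _MULT[s] * seg[s, 0]
        inert = _MULT[s] * seg[s, 3]
        # velocity-product acceleration of this COM
        vx = 0.0
        vz = 0.0
        for k in range(6):
            vx += Jd[s, 0, k] * qd[k]
            vz += Jd[s, 1, k] * qd[k]
        for a_ in range(6):
            h[a_] += m * (J[s, 0, a_] * vx + J[s, 1, a_] * vz)
            Qg[a_] += -m * g * J[s, 1, a_]
            for b_ in range(a_, 6):
                M[a_, b_] += (m * (J[s, 0, a_] * J[s, 0, b_]
                                   + J[s, 1, a_] * J[s, 1, b_])
                              + inert * W[s, a_] * W[s, b_])
    for a_ in range(6):
        for b_ in range(a_):
            M[a_, b_] = M[b_, a_]
    return M, h, Qg


@njit(cache=True)
def head_state(q, qd, qdd, head_h):
    """Head point kinematics: x, xdot, xddot, phi, phiddot (SI, rad)."""
    e = q[2]
    de = qd[2]
    dde = qdd[2]
    s, c = math.sin(e), math.cos(e)
    x = q[0] - head_h * s
    xd = qd[0] - head_h * c * de
    xdd = qdd[0] - head_h * (c * dde - s * de * de)
    return x, xd, xdd, e, dde


@njit(cache=True)
def mech_energy(q, qd, seg, foot_com, g):
    """Kinetic and gravitational potential energy of the whole model."""
    M, h, Qg = mass_bias_grav(q, qd, seg, foot_com, g)
    ke = 0.0
    for a_ in range(6):
        for b_ in range(6):
            ke += 0.5 * qd[a_] * M[a_, b_] * qd[b_]
    hip, knee, ankle, compos, eps = fk_points(q, seg, foot_com)
    pe = 0.0
    for s in range(4):
        pe += _MULT[s] * seg[s, 0] * g * compos[s, 1]
    return ke, pe


# ---------------------------------------------------------------------------
# contact
# ---------------------------------------------------------------------------

@njit(cache=True)
def contact_terms(q, qd, seg, foot_com, sph_off, sph_r, sph_par,
                  vreg, min_force, plat_v):
    """Hunt-Crossley sphere-ground contact for both feet.

    Ground is the plane z = 0 translating horizontally with velocity
    ``plat_v``.  Returns generalized force Qc (both feet), total GRF
    (fx, fz), world COP, foot-relative COP, COP validity flag and the
    per-sphere normal forces of one foot.
    """
    e_t, e_th, e_sh, e_f = _angles(q)
    de_th = qd[2] + qd[3]
    de_sh = de_th + qd[4]
    de_f = de_sh + qd[5]
    lth = seg[1, 2]
    lsh = seg[2, 2]
    cf, sf = math.cos(e_f), math.sin(e_f)
    dthx, dthz = math.cos(e_th), math.sin(e_th)
    dshx, dshz = math.cos(e_sh), math.sin(e_sh)

    ankle_x = q[0] + lth * math.sin(e_th) + lsh * math.sin(e_sh)
    ankle_z = q[1] - lth * math.cos(e_th) - lsh * math.cos(e_sh)
    ankle_vx = qd[0] + lth * dthx * de_th + lsh * dshx * de_sh
    ankle_vz = qd[1] + lth * dthz * de_th + lsh * dshz * de_sh

    Qc = np.zeros(6)
    grf_x = 0.0
    grf_z = 0.0
    fns = np.zeros(2)
    num = 0.0
    den = 0.0
    mid = 0.0
    for i in range(2):
        ox, oz = sph_off[i, 0], sph_off[i, 1]
        rx = cf * ox - sf * oz
        rz = sf * ox + cf * oz
        rpx = -sf * ox - cf * oz      # d/d(e_f) of the rotated offset
        rpz = cf * ox - sf * oz
        px = ankle_x + rx
        pz = ankle_z + rz
        vx = ankle_vx + rpx * de_f
        vz = ankle_vz + rpz * de_f
        mid += 0.5 * px

        delta = sph_r[i] - pz
        if delta > 0.0:
            k = sph_par[i, 0]
            n = sph_par[i, 1]
            cdamp = sph_par[i, 2]
            mu = sph_par[i, 3]
            ddot = -vz
            fn = k * delta ** n * (1.0 + cdamp * ddot)
            if fn < 0.0:
                fn = 0.0
            ft = -mu * fn * math.tanh((vx - plat_v) / vreg)
            fns[i] = fn
            grf_x += 2.0 * ft
            grf_z += 2.0 * fn
            num += fn * px
            den += fn
            # point Jacobian columns (translation + chain angles)
            Qc[0] += 2.0 * ft
            Qc[1] += 2.0 * fn
            jx23 = lth * dthx + lsh * dshx + rpx
            jz23 = lth * dthz + lsh * dshz + rpz
            Qc[2] += 2.0 * (jx23 * ft + jz23 * fn)
            Qc[3] += 2.0 * (jx23 * ft + jz23 * fn)
            jx4 = lsh * dshx + rpx
            jz4 = lsh * dshz + rpz
            Qc[4] += 2.0 * (jx4 * ft + jz4 * fn)
            Qc[5] += 2.0 * (rpx * ft + rpz * fn)

    valid = grf_z > min_force
    if den > 0.0:
        cop = num / den
    else:
        cop = mid
    cop_rel = cop - mid
    return Qc, grf_x, grf_z, cop, cop_rel, valid, fns


# ---------------------------------------------------------------------------
# muscles
# ---------------------------------------------------------------------------

@njit(cache=True)
def muscle_lengths(q, qd, r0, r1, qref, lopt, lmref):
    """Normalized fiber lengths and velocities from the joint angles.

    L(theta) integrates dL/dtheta = -r(theta) exactly for the
    constant-plus-linear moment arms.
    """
    lm = np.empty(N_MUSCLES)
    lmd = np.empty(N_MUSCLES)
    for i in range(N_MUSCLES):
        s = 0.0
        sd = 0.0
        for j in range(3):
            th = q[3 + j]
            thr = qref[j]
            s += r0[i, j] * (th - thr) + 0.5 * r1[i, j] * (th * th - thr * thr)
            sd += (r0[i, j] + r1[i, j] * th) * qd[3 + j]
        lm[i] = lmref[i] - s / lopt[i]
        lmd[i] = -sd / lopt[i]
    return lm, lmd


@njit(cache=True)
def muscle_forces(a, lm, lmd, fmax, vmax, curve):
    """Hill-muscle tendon forces: F = f_max (a fL fV + fP), rigid tendon.

    curve = (fl_width, ecc_plateau, fv_shape, fp_width).
    """
    flw = curve[0]
    necc = curve[1]
    fva = curve[2]
    fpw = curve[3]
    F = np.empty(N_MUSCLES)
    Fn = np.empty(N_MUSCLES)
    for i in range(N_MUSCLES):
        x = (lm[i] - 1.0) / flw
        fl = math.exp(-x * x)
        v = lmd[i]
        vm = vmax[i]
        if v < 0.0:
            if v <= -vm:
                fv = 0.0
            else:
                fv = (vm + v) / (vm - v / fva)
        else:
            cshape = fva * vm
            fv = necc - (necc - 1.0) * cshape / (cshape + v)
        if lm[i] > 1.0:
            y = (lm[i] - 1.0) / fpw
            fp = y * y
        else:
            fp = 0.0
        fn = a[i] * fl * fv + fp
        if fn < 0.0:
            fn = 0.0
        Fn[i] = fn
        F[i] = fmax[i] * fn
    return F, Fn


@njit(cache=True)
def muscle_joint_torques(F, q, r0, r1):
    """Single-leg joint torques tau = sum_i r_i(theta) F_i (hip, knee, ankle)."""
    tau = np.zeros(3)
    for i in range(N_MUSCLES):
        for j in range(3):
            r = r0[i, j] + r1[i, j] * q[3 + j]
            if r != 0.0:
                tau[j] += r * F[i]
    return tau


@njit(cache=True)
def activation_rate(u, a, tact, tdeact):
    """First-order activation dynamics da/dt per muscle."""
    adot = np.empty(N_MUSCLES)
    for i in range(N_MUSCLES):
        if u[i] >= a[i]:
            adot[i] = (u[i] - a[i]) / tact[i]
        else:
            adot[i] = (u[i] - a[i]) / tdeact[i]
    return adot


# ---------------------------------------------------------------------------
# coupled dynamics
# ---------------------------------------------------------------------------

@njit(cache=True)
def solve_accels(M, Q, locked):
    """Solve M qdd = Q with locked coordinates held at zero acceleration."""
    nf = 0
    for k in range(6):
        if not locked[k]:
            nf += 1
    qdd = np.zeros(6)
    if nf == 6:
        sol = np.linalg.solve(M, Q)
        for k in range(6):
            qdd[k] = sol[k]
        return qdd
    idx = np.empty(nf, dtype=np.int64)
    j = 0
    for k in range(6):
        if not locked[k]:
            idx[j] = k
            j += 1
    Mf = np.empty((nf, nf))
    bf = np.empty(nf)
    for a_ in range(nf):
        bf[a_] = Q[idx[a_]]
        for b_ in range(nf):
            Mf[a_, b_] = M[idx[a_], idx[b_]]
    sol = np.linalg.solve(Mf, bf)
    for a_ in range(nf):
        qdd[idx[a_]] = sol[a_]
    return qdd


@njit(cache=True)
def dynamics(q, qd, a, u, plat_v, contact_on,
             seg, foot_com, g, sph_off, sph_r, sph_par, vreg, min_force,
             fmax, lopt, vmax, lmref, tact, tdeact, r0, r1, qref, curve,
             jlim, jstop, locked):
    """One evaluation of the coupled skeleton+muscle+contact dynamics."""
    M, h, Qg = mass_bias_grav(q, qd, seg, foot_com, g)
    Q = Qg - h
    lm, lmd = muscle_lengths(q, qd, r0, r1, qref, lopt, lmref)
    F, Fn = muscle_forces(a, lm, lmd, fmax, vmax, curve)
    tau = muscle_joint_torques(F, q, r0, r1)
    for j in range(3):
        Q[3 + j] += 2.0 * tau[j]     # both legs
    # passive joint stops (soft end-range elasticity + damping, per leg)
    ks = jstop[0]
    cs_ = jstop[1]
    for j in range(3):
        th = q[3 + j]
        if th > jlim[j, 1]:
            Q[3 + j] += 2.0 * (-ks * (th - jlim[j, 1]) - cs_ * qd[3 + j])
        elif th < jlim[j, 0]:
            Q[3 + j] += 2.0 * (-ks * (th - jlim[j, 0]) - cs_ * qd[3 + j])
    if contact_on:
        Qc, gx, gz, cop, coprel, valid, fns = contact_terms(
            q, qd, seg, foot_com, sph_off, sph_r, sph_par,
            vreg, min_force, plat_v)
        for k in range(6):
            Q[k] += Qc[k]
    else:
        gx = 0.0
        gz = 0.0
        cop = 0.0
        coprel = 0.0
        valid = False
        fns = np.zeros(2)
    qdd = solve_accels(M, Q, locked)
    adot = activation_rate(u, a, tact, tdeact)
    return qdd, adot, lm, lmd, Fn, gx, gz, cop, coprel, valid, fns


@njit(cache=True)
def _rk4(q, qd, a, u, hstep, plat_v, contact_on,
         seg, foot_com, g, sph_off, sph_r, sph_par, vreg, min_force,
         fmax, lopt, vmax, lmref, tact, tdeact, r0, r1, qref, curve,
         jlim, jstop, locked):
    """One RK4 sub-step of (q, qd, a); returns the new state and end qdd."""
    k1q = qd
    k1v, k1a = dynamics(q, qd, a, u, plat_v, contact_on, seg, foot_com, g,
                        sph_off, sph_r, sph_par, vreg, min_force,
                        fmax, lopt, vmax, lmref, tact, tdeact,
                        r0, r1, qref, curve, jlim, jstop, locked)[:2]
    q2 = q + 0.5 * hstep * k1q
    v2 = qd + 0.5 * hstep * k1v
    a2 = a + 0.5 * hstep * k1a
    k2q = v2
    k2v, k2a = dynamics(q2, v2, a2, u, plat_v, contact_on, seg, foot_com, g,
                        sph_off, sph_r, sph_par, vreg, min_force,
                        fmax, lopt, vmax, lmref, tact, tdeact,
                        r0, r1, qref, curve, jlim, jstop, locked)[:2]
    q3 = q + 0.5 * hstep * k2q
    v3 = qd + 0.5 * hstep * k2v
    a3 = a + 0.5 * hstep * k2a
    k3q = v3
    k3v, k3a = dynamics(q3, v3, a3, u, plat_v, contact_on, seg, foot_com, g,
                        sph_off, sph_r, sph_par, vreg, min_force,
                        fmax, lopt, vmax, lmref, tact, tdeact,
                        r0, r1, qref, curve, jlim, jstop, locked)[:2]
    q4 = q + hstep * k3q
    v4 = qd + hstep * k3v
    a4 = a + hstep * k3a
    k4q = v4
    k4v, k4a = dynamics(q4, v4, a4, u, plat_v, contact_on, seg, foot_com, g,
                        sph_off, sph_r, sph_par, vreg, min_force,
                        fmax, lopt, vmax, lmref, tact, tdeact,
                        r0, r1, qref, curve, jlim, jstop, locked)[:2]
    qn = q + (hstep / 6.0) * (k1q + 2.0 * k2q + 2.0 * k3q + k4q)
    vn = qd + (hstep / 6.0) * (k1v + 2.0 * k2v + 2.0 * k3v + k4v)
    an = a + (hstep / 6.0) * (k1a + 2.0 * k2a + 2.0 * k3a + k4a)
    return qn, vn, an, k4v


@njit(cache=True)
def run_loop(q0, qd0, a0,
             seg, foot_com, g, head_h,
             sph_off, sph_r, sph_par, vreg, min_force,
             fmax, lopt, vmax, lmref, tact, tdeact, r0, r1, qref, curve,
             jlim, jstop,
             gains, lm0, refs, delays, noise_par,
             noise_sens, noise_act, plat_pos, plat_vel,
             dt, nsub, nsteps, fall_frac, locked,
             out_q, out_qd, out_u, out_a, out_lm, out_lmd, out_fm,
             out_grf, out_cop, out_copv, out_fns, out_com, out_head):
    """Closed-loop single-shooting simulation at the 200 Hz control rate.

    Per control step: read sensors from the current state, add
    signal-dependent sensor noise, push into the delay ring buffers,
    evaluate the feedback law on the delayed samples, add actuator noise,
    clamp to [0,1] and integrate skeleton + activation dynamics over
    ``nsub`` RK4 sub-steps.

    Returns (fall_step, fall_flag): fall_flag 0 = completed, 1 = COM fell
    below ``fall_frac`` of its initial height, 2 = non-finite state.
    """
    q = q0.copy()
    qd = qd0.copy()
    a = a0.copy()

    # delay ring buffers, pre-filled with the initial sensor values
    maxd = 0
    for i in range(N_MUSCLES):
        for j in range(3):
            if delays[i, j] > maxd:
                maxd = delays[i, j]
    nbuf = maxd + 1
    buf = np.empty((N_CHANNELS, nbuf))

    cx0, cz0, mtot = com_position(q, seg, foot_com)
    com0z = cz0

    # initial dynamics evaluation seeds the acceleration-based sensors
    qdd_prev, adot0, lm_i, lmd_i, fn_i, gx_i, gz_i, cop_i, coprel_i, \
        valid_i, fns_i = dynamics(
            q, qd, a, a, plat_vel[0] if nsteps > 0 else 0.0, True,
            seg, foot_com, g, sph_off, sph_r, sph_par, vreg, min_force,
            fmax, lopt, vmax, lmref, tact, tdeact, r0, r1, qref, curve,
            jlim, jstop, locked)
    hx, hxd, hxdd, hphi, hphidd = head_state(q, qd, qdd_prev, head_h)
    for i in range(N_MUSCLES):
        for t_ in range(nbuf):
            buf[i, t_] = lm_i[i]
            buf[9 + i, t_] = lmd_i[i]
            buf[18 + i, t_] = fn_i[i]
    for t_ in range(nbuf):
        buf[27, t_] = coprel_i
        buf[28, t_] = hxdd
        buf[29, t_] = hphi
        buf[30, t_] = hphidd
        buf[31, t_] = hx
        buf[32, t_] = hxd

    nbase = noise_par[0]
    nslope = noise_par[1]

    fall_step = -1
    fall_flag = 0
    u = np.zeros(N_MUSCLES)
    sens = np.empty(N_CHANNELS)

    for k in range(nsteps):
        # --- sensors at the current state ---------------------------------
        finite = True
        for j in range(6):
            if not (math.isfinite(q[j]) and math.isfinite(qd[j])):
                finite = False
        if not finite:
            fall_step = k
            fall_flag = 2
            break

        lm, lmd = muscle_lengths(q, qd, r0, r1, qref, lopt, lmref)
        F, Fn = muscle_forces(a, lm, lmd, fmax, vmax, curve)
        Qc, gx, gz, cop, coprel, valid, fns = contact_terms(
            q, qd, seg, foot_com, sph_off, sph_r, sph_par,
            vreg, min_force, plat_vel[k])
        cx, cz, mtot = com_position(q, seg, foot_com)
        hx, hxd, hxdd, hphi, hphidd = head_state(q, qd, qdd_prev, head_h)

        # --- record -------------------------------------------------------
        for j in range(6):
            out_q[k, j] = q[j]
            out_qd[k, j] = qd[j]
        for i in range(N_MUSCLES):
            out_a[k, i] = a[i]
            out_lm[k, i] = lm[i]
            out_lmd[k, i] = lmd[i]
            out_fm[k, i] = Fn[i]
        out_grf[k, 0] = gx
        out_grf[k, 1] = gz
        out_cop[k] = cop
        out_copv[k] = 1.0 if valid else 0.0
        out_fns[k, 0] = fns[0]
        out_fns[k, 1] = fns[1]
        out_com[k, 0] = cx
        out_com[k, 1] = cz
        out_head[k, 0] = hx
        out_head[k, 1] = hxd
        out_head[k, 2] = hxdd
        out_head[k, 3] = hphi
        out_head[k, 4] = hphidd

        if cz < fall_frac * com0z:
            fall_step = k
            fall_flag = 1
            break

        # --- noisy sensors into the delay buffers -------------------------
        for i in range(N_MUSCLES):
            sens[i] = lm[i]
            sens[9 + i] = lmd[i]
            sens[18 + i] = Fn[i]
        sens[27] = coprel
        sens[28] = hxdd
        sens[29] = hphi
        sens[30] = hphidd
        sens[31] = hx
        sens[32] = hxd
        w = k % nbuf
        for ch in range(N_CHANNELS):
            v = sens[ch]
            v = v + (nbase + nslope * abs(v)) * noise_sens[k, ch]
            buf[ch, w] = v

        # --- delayed feedback excitations ---------------------------------
        for i in range(N_MUSCLES):
            ds = (k - delays[i, 0]) % nbuf
            dv = (k - delays[i, 1]) % nbuf
            dw = (k - delays[i, 2]) % nbuf
            lm_d = buf[i, ds]
            lmd_d = buf[9 + i, ds]
            fm_d = buf[18 + i, ds]
            cop_d = buf[27, ds]
            xdd_d = buf[28, dv]
            phi_d = buf[29, dv]
            phidd_d = buf[30, dv]
            x_d = buf[31, dw]
            xd_d = buf[32, dw]

            usom = (gains[i, 1] * max(0.0, lm_d - lm0[i])
                    + gains[i, 2] * max(0.0, lmd_d)
                    + gains[i, 3] * fm_d
                    + gains[i, 4] * (cop_d - refs[0]))
            uves = (gains[i, 5] * xdd_d
                    + gains[i, 6] * (phi_d - refs[1])
                    + gains[i, 7] * phidd_d)
            uvis = (gains[i, 8] * (x_d - refs[2])
                    + gains[i, 9] * xd_d)
            ui = gains[i, 0] + usom + uves + uvis
            if ui < 0.0:
                ui = 0.0
            elif ui > 1.0:
                ui = 1.0
            ui = ui + (nbase + nslope * abs(ui)) * noise_act[k, i]
            if ui < 0.0:
                ui = 0.0
            elif ui > 1.0:
                ui = 1.0
            u[i] = ui
            out_u[k, i] = ui

        # --- integrate over sub-steps --------------------------------------
        hstep = dt / nsub
        pv = plat_vel[k]
        for _ in range(nsub):
            q, qd, a, qdd_prev = _rk4(
                q, qd, a, u, hstep, pv, True,
                seg, foot_com, g, sph_off, sph_r, sph_par, vreg, min_force,
                fmax, lopt, vmax, lmref, tact, tdeact, r0, r1, qref, curve,
                jlim, jstop, locked)
        for i in range(N_MUSCLES):
            if a[i] < 0.0:
                a[i] = 0.0
            elif a[i] > 1.0:
                a[i] = 1.0

    # final row (state after the last completed step)
    kend = fall_step if fall_flag != 0 else nsteps
    if fall_flag == 0:
        lm, lmd = muscle_lengths(q, qd, r0, r1, qref, lopt, lmref)
        F, Fn = muscle_forces(a, lm, lmd, fmax, vmax, curve)
        Qc, gx, gz, cop, coprel, valid, fns = contact_terms(
            q, qd, seg, foot_com, sph_off, sph_r, sph_par,
            vreg, min_force, plat_vel[nsteps - 1] if nsteps > 0 else 0.0)
        cx, cz, mtot = com_position(q, seg, foot_com)
        hx, hxd, hxdd, hphi, hphidd = head_state(q, qd, qdd_prev, head_h)
        for j in range(6):
            out_q[nsteps, j] = q[j]
            out_qd[nsteps, j] = qd[j]
        for i in range(N_MUSCLES):
            out_a[nsteps, i] = a[i]
            out_lm[nsteps, i] = lm[i]
            out_lmd[nsteps, i] = lmd[i]
            out_fm[nsteps, i] = Fn[i]
            out_u[nsteps, i] = u[i]
        out_grf[nsteps, 0] = gx
        out_grf[nsteps, 1] = gz
        out_cop[nsteps] = cop
        out_copv[nsteps] = 1.0 if valid else 0.0
        out_fns[nsteps, 0] = fns[0]
        out_fns[nsteps, 1] = fns[1]
        out_com[nsteps, 0] = cx
        out_com[nsteps, 1] = cz
        out_head[nsteps, 0] = hx
        out_head[nsteps, 1] = hxd
        out_head[nsteps, 2] = hxdd
        out_head[nsteps, 3] = hphi
        out_head[nsteps, 4] = hphidd
    return fall_step, fall_flag
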