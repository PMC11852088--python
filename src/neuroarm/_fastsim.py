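"""Compiled fast path for predictive-control rollouts.

The human-aware controller evaluates thousands of forward simulations of
the full hierarchy per movement; this module holds a numba-compiled
replica of the coupled, noise-free closed-loop step used only inside
those rollouts.  It must remain numerically identical to
``HolisticSimulator.step`` (the reference implementation); the test suite
asserts agreement to float precision over whole horizons.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["rollout_effort", "pack_kernel_args"]

_FV_PLATEAU = 1.5
_FV_SHORT_K = 0.25
_FV_LEN_GAMMA = 0.2
_BAUMGARTE = 20.0


@njit(cache=True)
def _muscle_geometry(q1, q2, pts, m_torso, m_upper, m_fore, l1):
    """Lengths (6,) and moment arms (6,2) of the straight-line paths."""
    n = 6
    c1, s1 = np.cos(q1), np.sin(q1)
    c12, s12 = np.cos(q1 + q2), np.sin(q1 + q2)
    ex, ey = l1 * c1, l1 * s1
    rel = np.empty((12, 2))
    d1 = np.empty((12, 2))
    d2 = np.empty((12, 2))
    for i in range(12):
        px, py = pts[i, 0], pts[i, 1]
        if m_torso[i]:
            wx, wy = px, py
        elif m_upper[i]:
            wx = px * c1 - py * s1
            wy = px * s1 + py * c1
        else:
            wx = ex + px * c12 - py * s12
            wy = ey + px * s12 + py * c12
        rel[i, 0], rel[i, 1] = wx, wy
        if m_torso[i]:
            d1[i, 0] = 0.0
            d1[i, 1] = 0.0
        else:
            d1[i, 0] = -wy
            d1[i, 1] = wx
        if m_fore[i]:
            d2[i, 0] = -(wy - ey)
            d2[i, 1] = wx - ex
        else:
            d2[i, 0] = 0.0
            d2[i, 1] = 0.0
    lengths = np.empty(n)
    arms = np.empty((n, 2))
    for i in range(n):
        vx = rel[6 + i, 0] - rel[i, 0]
        vy = rel[6 + i, 1] - rel[i, 1]
        l = np.sqrt(vx * vx + vy * vy)
        lengths[i] = l
        ux, uy = vx / l, vy / l
        arms[i, 0] = -(ux * (d1[6 + i, 0] - d1[i, 0]) + uy * (d1[6 + i, 1] - d1[i, 1]))
        arms[i, 1] = -(ux * (d2[6 + i, 0] - d2[i, 0]) + uy * (d2[6 + i, 1] - d2[i, 1]))
    return lengths, arms


@njit(cache=True)
def _mass_coriolis(q2, dq1, dq2, l1, m1, m2, d1, d2, I1, I2):
    c2 = np.cos(q2)
    a = I1 + I2 + m1 * d1 * d1 + m2 * (l1 * l1 + d2 * d2 + 2.0 * l1 * d2 * c2)
    b = I2 + m2 * (d2 * d2 + l1 * d2 * c2)
    c = I2 + m2 * d2 * d2
    h = m2 * l1 * d2 * np.sin(q2)
    c1v = -h * dq2 * dq2 - 2.0 * h * dq1 * dq2
    c2v = h * dq1 * dq1
    return a, b, c, c1v, c2v


@njit(cache=True)
def _jacobian(q1, q2, l1, l2):
    s1, c1 = np.sin(q1), np.cos(q1)
    s12, c12 = np.sin(q1 + q2), np.cos(q1 + q2)
    J = np.empty((2, 2))
    J[0, 0] = -l1 * s1 - l2 * s12
    J[0, 1] = -l2 * s12
    J[1, 0] = l1 * c1 + l2 * c12
    J[1, 1] = l2 * c12
    return J


@njit(cache=True)
def _jacobian_dot(q1, q2, dq1, dq2, l1, l2):
    d12 = dq1 + dq2
    c1, s1 = np.cos(q1), np.sin(q1)
    c12, s12 = np.cos(q1 + q2), np.sin(q1 + q2)
    Jd = np.empty((2, 2))
    Jd[0, 0] = -l1 * c1 * dq1 - l2 * c12 * d12
    Jd[0, 1] = -l2 * c12 * d12
    Jd[1, 0] = -l1 * s1 * dq1 - l2 * s12 * d12
    Jd[1, 1] = -l2 * s12 * d12
    return Jd


@njit(cache=True)
def _nnls_2x4(Bmat, f):
    """Non-negative least squares for a 2x4 system by KKT enumeration.

    The optimum (unique for bases in general position) has an active support
    of at most 2 columns; each candidate support is solved by its normal
    equations and accepted when primal and dual feasible.
    """
    best = np.zeros(4)
    # empty support: optimal iff B^T f <= 0
    dual_ok = True
    for j in range(4):
        if Bmat[0, j] * f[0] + Bmat[1, j] * f[1] > 1e-12:
            dual_ok = False
            break
    if dual_ok:
        return best
    # single-column supports
    for i in range(4):
        bb = Bmat[0, i] * Bmat[0, i] + Bmat[1, i] * Bmat[1, i]
        if bb < 1e-300:
            continue
        ci = (Bmat[0, i] * f[0] + Bmat[1, i] * f[1]) / bb
        if ci < -1e-12:
            continue
        rx = f[0] - Bmat[0, i] * ci
        ry = f[1] - Bmat[1, i] * ci
        ok = True
        for j in range(4):
            if j == i:
                continue
            if Bmat[0, j] * rx + Bmat[1, j] * ry > 1e-10:
                ok = False
                break
        if ok:
            best[i] = max(ci, 0.0)
            return best
    # two-column supports
    best_res = np.inf
    found = False
    for i in range(4):
        for j in range(i + 1, 4):
            a11 = Bmat[0, i] * Bmat[0, i] + Bmat[1, i] * Bmat[1, i]
            a12 = Bmat[0, i] * Bmat[0, j] + Bmat[1, i] * Bmat[1, j]
            a22 = Bmat[0, j] * Bmat[0, j] + Bmat[1, j] * Bmat[1, j]
            det = a11 * a22 - a12 * a12
            if abs(det) < 1e-300:
                continue
            b1 = Bmat[0, i] * f[0] + Bmat[1, i] * f[1]
            b2 = Bmat[0, j] * f[0] + Bmat[1, j] * f[1]
            ci = (a22 * b1 - a12 * b2) / det
            cj = (a11 * b2 - a12 * b1) / det
            if ci < -1e-12 or cj < -1e-12:
                continue
            rx = f[0] - Bmat[0, i] * ci - Bmat[0, j] * cj
            ry = f[1] - Bmat[1, i] * ci - Bmat[1, j] * cj
            ok = True
            for m in range(4):
                if m == i or m == j:
                    continue
                if Bmat[0, m] * rx + Bmat[1, m] * ry > 1e-10:
                    ok = False
                    break
            if ok:
                res = rx * rx + ry * ry
                if res < best_res:
                    best_res = res
                    best[:] = 0.0
                    best[i] = max(ci, 0.0)
                    best[j] = max(cj, 0.0)
                    found = True
    if found:
        return best
    # numerically degenerate corner: fall back to the best single column
    best[:] = 0.0
    best_obj = f[0] * f[0] + f[1] * f[1]
    for i in range(4):
        bb = Bmat[0, i] * Bmat[0, i] + Bmat[1, i] * Bmat[1, i]
        if bb < 1e-300:
            continue
        ci = (Bmat[0, i] * f[0] + Bmat[1, i] * f[1]) / bb
        if ci <= 0.0:
            continue
        rx = f[0] - Bmat[0, i] * ci
        ry = f[1] - Bmat[1, i] * ci
        obj = rx * rx + ry * ry
        if obj < best_obj:
            best_obj = obj
            best[:] = 0.0
            best[i] = ci
    return best


@njit(cache=True)
def _coupled_rates(y, e, T1, T2, field_b,
                   pts, m_torso, m_upper, m_fore,
                   hl1, hl2, hm1, hm2, hd1, hd2, hI1, hI2, shx, shy,
                   l0, fmax, width, vmax, tau_act, tau_deact,
                   rl1, rl2, rm1, rm2, rd1, rd2, rI1, rI2, bx, by):
    """Time derivatives of [q, dq, th, dth, act] for the coupled system."""
    q1, q2, dq1, dq2 = y[0], y[1], y[2], y[3]
    t1, t2, dt1, dt2 = y[4], y[5], y[6], y[7]
    act = y[8:14]
    lengths, arms = _muscle_geometry(q1, q2, pts, m_torso, m_upper, m_fore, hl1)
    tau_hx = 0.0
    tau_hy = 0.0
    dact = np.empty(6)
    for i in range(6):
        ln = lengths[i] / l0[i]
        fl = np.exp(-(((ln - 1.0) / width[i]) ** 2))
        v = -(arms[i, 0] * dq1 + arms[i, 1] * dq2) / (vmax[i] * l0[i])
        if v < 0.0:
            if v <= -1.0:
                fv = 0.0
            else:
                fv = (1.0 + v) / (1.0 - v / _FV_SHORT_K)
        else:
            fv = 1.0 + (_FV_PLATEAU - 1.0) * v / (v + _FV_LEN_GAMMA)
        force = act[i] * fl * fv * fmax[i]
        tau_hx += arms[i, 0] * force
        tau_hy += arms[i, 1] * force
        a = act[i]
        ei = e[i]
        gain = 0.5 + 1.5 * a
        if ei > a:
            dact[i] = (ei - a) / (tau_act[i] * gain)
        else:
            dact[i] = (ei - a) * gain / tau_deact[i]

    Jh = _jacobian(q1, q2, hl1, hl2)
    if field_b != 0.0:
        vx = Jh[0, 0] * dq1 + Jh[0, 1] * dq2
        vy = Jh[1, 0] * dq1 + Jh[1, 1] * dq2
        fx = field_b * vy
        fy = -field_b * vx
        tau_hx += Jh[0, 0] * fx + Jh[1, 0] * fy
        tau_hy += Jh[0, 1] * fx + Jh[1, 1] * fy

    ha, hb, hc, hc1, hc2 = _mass_coriolis(q2, dq1, dq2, hl1, hm1, hm2, hd1, hd2, hI1, hI2)
    ra, rb, rc, rc1, rc2 = _mass_coriolis(t2, dt1, dt2, rl1, rm1, rm2, rd1, rd2, rI1, rI2)
    rhs_h1 = tau_hx - hc1
    rhs_h2 = tau_hy - hc2
    rhs_r1 = T1 - rc1
    rhs_r2 = T2 - rc2

    Jr = _jacobian(t1, t2, rl1, rl2)
    # hand / end-effector positions and velocities
    hx = shx + hl1 * np.cos(q1) + hl2 * np.cos(q1 + q2)
    hy = shy + hl1 * np.sin(q1) + hl2 * np.sin(q1 + q2)
    ex = bx + rl1 * np.cos(t1) + rl2 * np.cos(t1 + t2)
    ey = by + rl1 * np.sin(t1) + rl2 * np.sin(t1 + t2)
    hvx = Jh[0, 0] * dq1 + Jh[0, 1] * dq2
    hvy = Jh[1, 0] * dq1 + Jh[1, 1] * dq2
    evx = Jr[0, 0] * dt1 + Jr[0, 1] * dt2
    evy = Jr[1, 0] * dt1 + Jr[1, 1] * dt2
    Jhd = _jacobian_dot(q1, q2, dq1, dq2, hl1, hl2)
    Jrd = _jacobian_dot(t1, t2, dt1, dt2, rl1, rl2)
    bias1 = (Jrd[0, 0] * dt1 + Jrd[0, 1] * dt2) - (Jhd[0, 0] * dq1 + Jhd[0, 1] * dq2) \
        - 2.0 * _BAUMGARTE * (hvx - evx) - _BAUMGARTE * _BAUMGARTE * (hx - ex)
    bias2 = (Jrd[1, 0] * dt1 + Jrd[1, 1] * dt2) - (Jhd[1, 0] * dq1 + Jhd[1, 1] * dq2) \
        - 2.0 * _BAUMGARTE * (hvy - evy) - _BAUMGARTE * _BAUMGARTE * (hy - ey)

    kkt = np.zeros((6, 6))
    kkt[0, 0] = ha
    kkt[0, 1] = hb
    kkt[1, 0] = hb
    kkt[1, 1] = hc
    kkt[2, 2] = ra
    kkt[2, 3] = rb
    kkt[3, 2] = rb
    kkt[3, 3] = rc
    for r in range(2):
        for c in range(2):
            kkt[r, 4 + c] = -Jh[c, r]       # -Jh^T
            kkt[2 + r, 4 + c] = Jr[c, r]    # +Jr^T
            kkt[4 + r, c] = Jh[r, c]
            kkt[4 + r, 2 + c] = -Jr[r, c]
    rhs = np.empty(6)
    rhs[0], rhs[1] = rhs_h1, rhs_h2
    rhs[2], rhs[3] = rhs_r1, rhs_r2
    rhs[4], rhs[5] = bias1, bias2
    sol = np.linalg.solve(kkt, rhs)

    dy = np.empty(14)
    dy[0], dy[1] = dq1, dq2
    dy[2], dy[3] = sol[0], sol[1]
    dy[4], dy[5] = dt1, dt2
    dy[6], dy[7] = sol[2], sol[3]
    dy[8:14] = dact
    return dy


@njit(cache=True)
def rollout_effort(q, dq, th, dth, act, a_abs, xhat, xhat_d,
                   meas_buf, ctrl_buf, head, k0, n_horizon, beta,
                   L, K, K_eff, A, Bm, n_delay, targetx, targety,
                   fmax_abstract, tau_abs, dt, n_total, field_b,
                   pts, m_torso, m_upper, m_fore,
                   hl1, hl2, hm1, hm2, hd1, hd2, hI1, hI2, shx, shy,
                   l0, fmax, width, vmax, tau_act, tau_deact,
                   rl1, rl2, rm1, rm2, rd1, rd2, rI1, rI2, bx, by,
                   S):
    """Mean squared excitation over a noise-free coupled rollout.

    State arrays are copied internally; the caller's snapshot is untouched.
    """
    q = q.copy()
    dq = dq.copy()
    th = th.copy()
    dth = dth.copy()
    act = act.copy()
    a_abs = a_abs.copy()
    xhat = xhat.copy()
    xhat_d = xhat_d.copy()
    meas_buf = meas_buf.copy()
    ctrl_buf = ctrl_buf.copy()

    total = 0.0
    y_state = np.empty(14)
    for j in range(n_horizon):
        kg = min(k0 + j, n_total - 1)
        # measurement
        Jh = _jacobian(q[0], q[1], hl1, hl2)
        hx = shx + hl1 * np.cos(q[0]) + hl2 * np.cos(q[0] + q[1])
        hy = shy + hl1 * np.sin(q[0]) + hl2 * np.sin(q[0] + q[1])
        meas = np.empty(6)
        meas[0] = hx - targetx
        meas[1] = hy - targety
        meas[2] = Jh[0, 0] * dq[0] + Jh[0, 1] * dq[1]
        meas[3] = Jh[1, 0] * dq[0] + Jh[1, 1] * dq[1]
        meas[4] = a_abs[0]
        meas[5] = a_abs[1]
        # abstract command
        u = L[kg] @ xhat
        # task-force command with velocity-product compensation
        _, _, _, cc1, cc2 = _mass_coriolis(q[1], dq[0], dq[1], hl1, hm1, hm2,
                                           hd1, hd2, hI1, hI2)
        detJ = Jh[0, 0] * Jh[1, 1] - Jh[0, 1] * Jh[1, 0]
        f_task = np.empty(2)
        f_task[0] = u[0] * fmax_abstract
        f_task[1] = u[1] * fmax_abstract
        if abs(detJ) >= 1e-8:
            # J^-T @ c  (inverse-transpose of the 2x2 Jacobian)
            f_task[0] += (Jh[1, 1] * cc1 - Jh[1, 0] * cc2) / detJ
            f_task[1] += (-Jh[0, 1] * cc1 + Jh[0, 0] * cc2) / detJ
        # synergy basis at the current posture
        lengths, arms = _muscle_geometry(q[0], q[1], pts, m_torso, m_upper,
                                         m_fore, hl1)
        G = np.empty((2, 6))
        for i in range(6):
            ln = lengths[i] / l0[i]
            fl = np.exp(-(((ln - 1.0) / width[i]) ** 2))
            t1 = arms[i, 0] * fl * fmax[i]
            t2 = arms[i, 1] * fl * fmax[i]
            G[0, i] = (Jh[1, 1] * t1 - Jh[1, 0] * t2) / detJ
            G[1, i] = (-Jh[0, 1] * t1 + Jh[0, 0] * t2) / detJ
        basis = G @ S
        C = _nnls_2x4(basis, f_task)
        e = S @ C
        for i in range(6):
            if e[i] < 0.0:
                e[i] = 0.0
            elif e[i] > 1.0:
                e[i] = 1.0
        total += e @ e
        # robot torques from the polynomial profile
        T1 = beta[0, 0] + beta[0, 1] * j + beta[0, 2] * j * j
        T2 = beta[1, 0] + beta[1, 1] * j + beta[1, 2] * j * j
        # belief update (delayed innovation against the ring buffer)
        if n_delay == 0:
            innov = meas - xhat
            xhat = A @ xhat + Bm @ u + K[kg] @ innov
            xhat_d = xhat
        else:
            y_old = meas_buf[head].copy()
            u_old = ctrl_buf[head].copy()
            innov = y_old - xhat_d
            jd = kg - n_delay
            if jd < 0:
                jd = 0
            xhat_d = A @ xhat_d + Bm @ u_old + K[jd] @ innov
            xhat = A @ xhat + Bm @ u + K_eff[kg] @ innov
            meas_buf[head] = meas
            ctrl_buf[head] = u
            head = (head + 1) % n_delay
        # RK4 plant integration
        y_state[0], y_state[1] = q[0], q[1]
        y_state[2], y_state[3] = dq[0], dq[1]
        y_state[4], y_state[5] = th[0], th[1]
        y_state[6], y_state[7] = dth[0], dth[1]
        y_state[8:14] = act
        k1 = _coupled_rates(y_state, e, T1, T2, field_b, pts, m_torso, m_upper,
                            m_fore, hl1, hl2, hm1, hm2, hd1, hd2, hI1, hI2,
                            shx, shy, l0, fmax, width, vmax, tau_act, tau_deact,
                            rl1, rl2, rm1, rm2, rd1, rd2, rI1, rI2, bx, by)
        k2 = _coupled_rates(y_state + 0.5 * dt * k1, e, T1, T2, field_b, pts,
                            m_torso, m_upper, m_fore, hl1, hl2, hm1, hm2, hd1,
                            hd2, hI1, hI2, shx, shy, l0, fmax, width, vmax,
                            tau_act, tau_deact, rl1, rl2, rm1, rm2, rd1, rd2,
                            rI1, rI2, bx, by)
        k3 = _coupled_rates(y_state + 0.5 * dt * k2, e, T1, T2, field_b, pts,
                            m_torso, m_upper, m_fore, hl1, hl2, hm1, hm2, hd1,
                            hd2, hI1, hI2, shx, shy, l0, fmax, width, vmax,
                            tau_act, tau_deact, rl1, rl2, rm1, rm2, rd1, rd2,
                            rI1, rI2, bx, by)
        k4 = _coupled_rates(y_state + dt * k3, e, T1, T2, field_b, pts,
                            m_torso, m_upper, m_fore, hl1, hl2, hm1, hm2, hd1,
                            hd2, hI1, hI2, shx, shy, l0, fmax, width, vmax,
                            tau_act, tau_deact, rl1, rl2, rm1, rm2, rd1, rd2,
                            rI1, rI2, bx, by)
        y_new = y_state + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        q[0], q[1] = y_new[0], y_new[1]
        dq[0], dq[1] = y_new[2], y_new[3]
        th[0], th[1] = y_new[4], y_new[5]
        dth[0], dth[1] = y_new[6], y_new[7]
        for i in range(6):
            a = y_new[8 + i]
            if a < 0.0:
                a = 0.0
            elif a > 1.0:
                a = 1.0
            act[i] = a
        # internal model's own activation propagation
        a_abs[0] = a_abs[0] + dt * (u[0] - a_abs[0]) / tau_abs
        a_abs[1] = a_abs[1] + dt * (u[1] - a_abs[1]) / tau_abs
    return total / n_horizon


def pack_kernel_args(sim) -> tuple:
    """Constant trailing arguments of :func:`rollout_effort`, in positional
    order, for a :class:`HolisticSimulator`."""
    arm = sim.arm
    p = arm.params
    rp = sim.robot.params
    return (
        sim.solution.L, sim.solution.K, sim.solution.K_eff,
        sim.model.A, sim.model.B, sim.model.delay_steps,
        float(sim.target[0]), float(sim.target[1]),
        sim.params.fmax, sim.params.tau, sim.params.dt, sim.params.n_steps,
        sim.field.b,
        arm._att_pts,
        arm._m_torso[:, 0].astype(np.bool_),
        arm._m_upper[:, 0].astype(np.bool_),
        arm._m_fore[:, 0].astype(np.bool_),
        p.l1, p.l2, p.m1, p.m2, p.d1, p.d2, p.I1, p.I2,
        float(p.shoulder[0]), float(p.shoulder[1]),
        arm.l0, arm.fmax, arm.width, arm.vmax, arm.tau_act, arm.tau_deact,
        rp.l1, rp.l2, rp.m1, rp.m2, rp.d1, rp.d2, rp.I1, rp.I2,
        float(rp.base[0]), float(rp.base[1]),
        sim.synergies.S,
    )
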