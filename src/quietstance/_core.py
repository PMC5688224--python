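"""Compiled inner loop of the closed-loop stance simulation.

One stochastic Euler step composes, in order: delayed/noisy sensing, the
control law producing the descending threshold-rate command, threshold
integration, the stretch-reflex activation law with saturation, the
calcium-kinetics torque filter, passive elastic and viscous torques, and the
three-link pendulum dynamics.  Everything here operates on plain float64
arrays; noise sample paths are pregenerated outside and indexed per step, and
transport delays are exact integer-step reads into the stored history (signals
are held at their initial values for t < 0).

The public API lives in :mod:`quietstance.simulator`; this module is an
implementation detail kept free of Python objects so numba can compile it.
"""

import math

import numpy as np
from numba import njit

# scheme / ablation codes
SCHEME_CODE = {"A": 0, "B": 1, "C": 2, "D": 3}
ABLATION_CODE = {"none": 0, "outer_cut": 1, "all_cut": 2}

_RAD2DEG = 180.0 / math.pi


@njit(cache=True)
def _passive_torque(theta, pe1, pe2, pe_off, pe_hs, anat_sign, out):
    for j in range(3):
        a1 = pe1[j, 0]
        a2 = pe2[j, 0]
        for i in range(3):
            ang = anat_sign[i] * theta[i] * _RAD2DEG
            a1 += pe1[j, i + 1] * ang
            a2 += pe2[j, i + 1] * ang
        t = math.exp(a1) - math.exp(a2) + pe_off[j]
        if j == 1:
            t += math.exp(pe_hs[0] + pe_hs[1] * anat_sign[1] * theta[1] * _RAD2DEG)
        # torque conjugate to the angle map
        out[j] = anat_sign[j] * t


@njit(cache=True)
def _saturate_scalar(e, e_star, c1, c2, c3):
    if e > e_star:
        return c1 / (e + c2) + c3
    return e


@njit(cache=True)
def trial_kernel(
    n_steps, dt, dr_steps, db_steps,
    # chain constants
    h, gcoef, p_coef, c_coef,
    # muscle
    A, Ainv, B,
    pe1, pe2, pe_off, pe_hs, anat_sign,
    alpha_E, mu, rho, tau_m, E_max, e_star, c1, c2, c3,
    # control
    alpha_pdot, alpha_pddot, alpha_o, o_ref, alpha_theta, alpha_theta_dot,
    theta_ref,
    scheme, ablation, R_floor,
    # initial state
    theta0, lam0, E_ag0, E_an0, T_act0,
    # pregenerated noise paths
    eta_th, eta_thd, eta_pd, eta_pdd, eta_or, eta_ld, eta_mag, eta_man,
    fall_limit,
    # outputs (n_steps x ...)
    out_theta, out_theta_dot, out_lam, out_E,
    out_T_act, out_T_ela, out_T_vis,
    out_p, out_o, out_c, out_p_dot, out_p_ddot,
):
    """Simulate up to ``n_steps`` Euler steps; returns the number of steps
    actually stored (less than ``n_steps`` if the body fell over or the state
    left the finite range)."""
    theta = theta0.copy()
    theta_dot = np.zeros(3)
    lam = lam0.copy()
    T_act = T_act0.copy()
    T_act_dot = np.zeros(3)

    T_ela = np.zeros(3)
    phi = np.zeros(3)
    v = np.zeros(3)
    th_hat = np.zeros(3)
    thd_hat = np.zeros(3)
    u = np.zeros(3)
    M_abs = np.zeros((3, 3))
    M = np.zeros((3, 3))
    F = np.zeros(3)
    lam_dot = np.zeros(3)
    E = np.zeros(3)

    for k in range(n_steps):
        # --- store current state -------------------------------------------
        for j in range(3):
            out_theta[k, j] = theta[j]
            out_theta_dot[k, j] = theta_dot[j]
            out_lam[k, j] = lam[j]

        # absolute segment angles and task kinematics at the current state
        phi[0] = theta[0]
        phi[1] = theta[0] + theta[1]
        phi[2] = theta[0] + theta[1] + theta[2]
        phi_dot0 = theta_dot[0]
        phi_dot1 = theta_dot[0] + theta_dot[1]
        phi_dot2 = theta_dot[0] + theta_dot[1] + theta_dot[2]

        s0, s1, s2 = math.sin(phi[0]), math.sin(phi[1]), math.sin(phi[2])
        co0, co1, co2 = math.cos(phi[0]), math.cos(phi[1]), math.cos(phi[2])

        p = -(p_coef[0] * s0 + p_coef[1] * s1 + p_coef[2] * s2)
        cpos = -(c_coef[0] * s0 + c_coef[1] * s1 + c_coef[2] * s2)
        o = -phi[2]
        # head Jacobian J_p[a] = -sum_{j>=a} p_coef_j cos(phi_j)
        Jp0 = -(p_coef[0] * co0 + p_coef[1] * co1 + p_coef[2] * co2)
        Jp1 = -(p_coef[1] * co1 + p_coef[2] * co2)
        Jp2 = -(p_coef[2] * co2)
        Jc0 = -(c_coef[0] * co0 + c_coef[1] * co1 + c_coef[2] * co2)
        Jc1 = -(c_coef[1] * co1 + c_coef[2] * co2)
        Jc2 = -(c_coef[2] * co2)
        p_dot = Jp0 * theta_dot[0] + Jp1 * theta_dot[1] + Jp2 * theta_dot[2]

        out_p[k] = p
        out_o[k] = o
        out_c[k] = cpos
        out_p_dot[k] = p_dot

        # --- sensing -------------------------------------------------------
        # proprioception: joint state delayed by the reflex delay, plus noise
        idx = k - dr_steps
        if idx < 0:
            idx = 0
        for j in range(3):
            th_hat[j] = out_theta[idx, j] + eta_th[k, j]
            thd_hat[j] = out_theta_dot[idx, j] + eta_thd[k, j]

        # body-in-space estimates: delayed by the brain delay. The head
        # acceleration depends on theta_dd of the source step, which is only
        # known after the dynamics, so with zero delay the most recent
        # completed step is used.
        idxb = k - db_steps
        if db_steps == 0:
            idxb = k - 1
        if idxb < 0:
            p_dot_del = out_p_dot[0]
            p_ddot_del = 0.0
            o_del = out_o[0]
        else:
            p_dot_del = out_p_dot[idxb]
            p_ddot_del = out_p_ddot[idxb]
            o_del = out_o[idxb]
        p_dot_hat = p_dot_del + eta_pd[k]
        p_ddot_hat = p_ddot_del + eta_pdd[k]
        o_hat = o_del + eta_or[k]

        # --- control law ---------------------------------------------------
        f_p = -alpha_pdot * p_dot_hat - alpha_pddot * p_ddot_hat
        f_o = -alpha_o * (o_hat - o_ref)

        if ablation == 1:  # outer loop cut: no descending commands
            lam_dot[0] = 0.0
            lam_dot[1] = 0.0
            lam_dot[2] = 0.0
        else:
            # F_p: task feedback mapped to the joints. The ankle-strategy
            # schemes (A, B, C) use the reduced (ankle-only) head Jacobian;
            # the distributed scheme (D) spreads f_p over all joints with the
            # minimum-norm pseudo-inverse of the full Jacobian.
            if scheme == 3:  # D
                nrm2 = Jp0 * Jp0 + Jp1 * Jp1 + Jp2 * Jp2
                F[0] = Jp0 * f_p / nrm2
                F[1] = Jp1 * f_p / nrm2
                F[2] = Jp2 * f_p / nrm2
            else:            # A, B, C: ankle only
                F[0] = f_p / Jp0
                F[1] = 0.0
                F[2] = 0.0
            if scheme >= 2:
                # F_o (C/D only): trunk orientation feedback leaving the CoM
                # unchanged: minimum-norm solution of [J_o; J_c] F_o = (f_o, 0)
                # via F_o = J^T (J J^T)^-1 rhs with J_o = (-1,-1,-1)
                g11 = 3.0
                g12 = -(Jc0 + Jc1 + Jc2)
                g22 = Jc0 * Jc0 + Jc1 * Jc1 + Jc2 * Jc2
                det = g11 * g22 - g12 * g12
                y0 = (g22 * f_o) / det
                y1 = (-g12 * f_o) / det
                F[0] += -y0 + Jc0 * y1
                F[1] += -y0 + Jc1 * y1
                F[2] += -y0 + Jc2 * y1

            # inertia matrix at the current posture (internal model)
            for a in range(3):
                for b in range(3):
                    M_abs[a, b] = h[a, b] * math.cos(phi[a] - phi[b])
            # M = L^T M_abs L with L lower-triangular ones:
            # M[a,b] = sum_{j>=a, k>=b} M_abs[j,k]
            for a in range(2, -1, -1):
                for b in range(2, -1, -1):
                    m = M_abs[a, b]
                    if a < 2:
                        m += M[a + 1, b]
                    if b < 2:
                        m += M[a, b + 1]
                    if a < 2 and b < 2:
                        m -= M[a + 1, b + 1]
                    M[a, b] = m

            # lambda_dot = R^-1 A^-1 M F + noise, R from the current reflex
            # operating point (previous step's command as lambda_dot input)
            MF0 = M[0, 0] * F[0] + M[0, 1] * F[1] + M[0, 2] * F[2]
            MF1 = M[1, 0] * F[0] + M[1, 1] * F[1] + M[1, 2] * F[2]
            MF2 = M[2, 0] * F[0] + M[2, 1] * F[1] + M[2, 2] * F[2]
            u[0] = Ainv[0, 0] * MF0 + Ainv[0, 1] * MF1 + Ainv[0, 2] * MF2
            u[1] = Ainv[1, 0] * MF0 + Ainv[1, 1] * MF1 + Ainv[1, 2] * MF2
            u[2] = Ainv[2, 0] * MF0 + Ainv[2, 1] * MF1 + Ainv[2, 2] * MF2
            for j in range(3):
                x = (th_hat[j] - lam[j]
                     + mu * (thd_hat[j] - lam_dot[j]))
                arg_ag = alpha_E * (x + rho[j])
                arg_an = -alpha_E * (x - rho[j])
                # clamp exponents: far beyond the saturation crossover the
                # hyperbolic branch is flat, so the clamp only guards
                # floating-point overflow
                if arg_ag > 30.0:
                    arg_ag = 30.0
                if arg_an > 30.0:
                    arg_an = 30.0
                e_ag = math.expm1(arg_ag) if arg_ag > 0.0 else 0.0
                e_an = math.expm1(arg_an) if arg_an > 0.0 else 0.0
                dag = -alpha_E * (e_ag + 1.0) if arg_ag > 0.0 else 0.0
                dan = alpha_E * (e_an + 1.0) if arg_an > 0.0 else 0.0
                sag = -c1 / ((e_ag + c2) * (e_ag + c2)) if e_ag > e_star else 1.0
                san = -c1 / ((e_an + c2) * (e_an + c2)) if e_an > e_star else 1.0
                R = -sag * dag + san * dan
                if abs(R) < R_floor[j]:
                    R = R_floor[j] if R >= 0.0 else -R_floor[j]
                lam_dot[j] = u[j] / R + eta_ld[k, j]
            # schemes A and B command the proximal thresholds differently:
            # A holds them constant (stability from raised co-contraction),
            # B replaces them with local proprioceptive PD feedback, and the
            # ankle keeps the calibrated f_p command on top of its local term
            if scheme == 0:      # A
                lam_dot[1] = 0.0
                lam_dot[2] = 0.0
            elif scheme == 1:    # B
                for j in range(3):
                    local = (-alpha_theta * (th_hat[j] - theta_ref[j])
                             - alpha_theta_dot * theta_dot[j])
                    if j == 0:
                        lam_dot[0] += local
                    else:
                        lam_dot[j] = local + eta_ld[k, j]

        # --- threshold integration and reflex activation -------------------
        # signal-dependent motor noise multiplies each pool's output
        if ablation == 2:  # all feedback cut: pool activations frozen
            for j in range(3):
                E[j] = (-E_ag0[j] * eta_mag[k, j] + E_an0[j] * eta_man[k, j])
        else:
            for j in range(3):
                x = th_hat[j] - lam[j] + mu * (thd_hat[j] - lam_dot[j])
                arg_ag = alpha_E * (x + rho[j])
                arg_an = -alpha_E * (x - rho[j])
                if arg_ag > 30.0:
                    arg_ag = 30.0
                if arg_an > 30.0:
                    arg_an = 30.0
                e_ag = math.expm1(arg_ag) if arg_ag > 0.0 else 0.0
                e_an = math.expm1(arg_an) if arg_an > 0.0 else 0.0
                e_ag = _saturate_scalar(e_ag, e_star, c1, c2, c3)
                e_an = _saturate_scalar(e_an, e_star, c1, c2, c3)
                E[j] = (-e_ag * eta_mag[k, j] + e_an * eta_man[k, j])
        for j in range(3):
            lam[j] += dt * lam_dot[j]
            out_E[k, j] = E[j]

        # --- torques -------------------------------------------------------
        _passive_torque(theta, pe1, pe2, pe_off, pe_hs, anat_sign, T_ela)
        for j in range(3):
            out_T_act[k, j] = T_act[j]
            out_T_ela[k, j] = T_ela[j]
        Tv0 = -(B[0, 0] * theta_dot[0] + B[0, 1] * theta_dot[1] + B[0, 2] * theta_dot[2])
        Tv1 = -(B[1, 0] * theta_dot[0] + B[1, 1] * theta_dot[1] + B[1, 2] * theta_dot[2])
        Tv2 = -(B[2, 0] * theta_dot[0] + B[2, 1] * theta_dot[1] + B[2, 2] * theta_dot[2])
        out_T_vis[k, 0] = Tv0
        out_T_vis[k, 1] = Tv1
        out_T_vis[k, 2] = Tv2

        T0 = T_act[0] + T_ela[0] + Tv0
        T1 = T_act[1] + T_ela[1] + Tv1
        T2 = T_act[2] + T_ela[2] + Tv2

        # calcium-kinetics filter update (Euler)
        Tt0 = A[0, 0] * E[0] + A[0, 1] * E[1] + A[0, 2] * E[2]
        Tt1 = A[1, 0] * E[0] + A[1, 1] * E[1] + A[1, 2] * E[2]
        Tt2 = A[2, 0] * E[0] + A[2, 1] * E[1] + A[2, 2] * E[2]
        inv_tm2 = 1.0 / (tau_m * tau_m)
        new_T0 = T_act[0] + dt * T_act_dot[0]
        new_T1 = T_act[1] + dt * T_act_dot[1]
        new_T2 = T_act[2] + dt * T_act_dot[2]
        T_act_dot[0] += dt * (Tt0 - T_act[0] - 2.0 * tau_m * T_act_dot[0]) * inv_tm2
        T_act_dot[1] += dt * (Tt1 - T_act[1] - 2.0 * tau_m * T_act_dot[1]) * inv_tm2
        T_act_dot[2] += dt * (Tt2 - T_act[2] - 2.0 * tau_m * T_act_dot[2]) * inv_tm2
        T_act[0] = new_T0
        T_act[1] = new_T1
        T_act[2] = new_T2

        # --- dynamics ------------------------------------------------------
        # velocity-product + gravity force vector in absolute angles:
        # v_j = sum_k h_jk sin(phi_j - phi_k) phi_dot_k^2 - gcoef_j sin(phi_j)
        pd2_0 = phi_dot0 * phi_dot0
        pd2_1 = phi_dot1 * phi_dot1
        pd2_2 = phi_dot2 * phi_dot2
        v[0] = (h[0, 1] * math.sin(phi[0] - phi[1]) * pd2_1
                + h[0, 2] * math.sin(phi[0] - phi[2]) * pd2_2
                - gcoef[0] * s0)
        v[1] = (h[1, 0] * math.sin(phi[1] - phi[0]) * pd2_0
                + h[1, 2] * math.sin(phi[1] - phi[2]) * pd2_2
                - gcoef[1] * s1)
        v[2] = (h[2, 0] * math.sin(phi[2] - phi[0]) * pd2_0
                + h[2, 1] * math.sin(phi[2] - phi[1]) * pd2_1
                - gcoef[2] * s2)
        # relative-coordinate RHS: T - L^T v  (L^T v)[a] = sum_{j>=a} v_j
        rhs0 = T0 - (v[0] + v[1] + v[2])
        rhs1 = T1 - (v[1] + v[2])
        rhs2 = T2 - v[2]

        # inertia matrix (recompute; schemes A/B skip the control-branch build)
        for a in range(3):
            for b in range(3):
                M_abs[a, b] = h[a, b] * math.cos(phi[a] - phi[b])
        for a in range(2, -1, -1):
            for b in range(2, -1, -1):
                m = M_abs[a, b]
                if a < 2:
                    m += M[a + 1, b]
                if b < 2:
                    m += M[a, b + 1]
                if a < 2 and b < 2:
                    m -= M[a + 1, b + 1]
                M[a, b] = m

        # solve M theta_dd = rhs (3x3, symmetric PD) by Cramer's rule
        m00, m01, m02 = M[0, 0], M[0, 1], M[0, 2]
        m11, m12, m22 = M[1, 1], M[1, 2], M[2, 2]
        c00 = m11 * m22 - m12 * m12
        c01 = m02 * m12 - m01 * m22
        c02 = m01 * m12 - m02 * m11
        c11 = m00 * m22 - m02 * m02
        c12 = m01 * m02 - m00 * m12
        c22 = m00 * m11 - m01 * m01
        det = m00 * c00 + m01 * c01 + m02 * c02
        tdd0 = (c00 * rhs0 + c01 * rhs1 + c02 * rhs2) / det
        tdd1 = (c01 * rhs0 + c11 * rhs1 + c12 * rhs2) / det
        tdd2 = (c02 * rhs0 + c12 * rhs1 + c22 * rhs2) / det

        # head acceleration of this step: p_dd = J_p theta_dd + Jdot_p theta_dot
        Jd0 = (p_coef[0] * s0 * phi_dot0 + p_coef[1] * s1 * phi_dot1
               + p_coef[2] * s2 * phi_dot2)
        Jd1 = (p_coef[1] * s1 * phi_dot1 + p_coef[2] * s2 * phi_dot2)
        Jd2 = (p_coef[2] * s2 * phi_dot2)
        out_p_ddot[k] = (Jp0 * tdd0 + Jp1 * tdd1 + Jp2 * tdd2
                         + Jd0 * theta_dot[0] + Jd1 * theta_dot[1]
                         + Jd2 * theta_dot[2])

        # --- Euler integration of the mechanical state ---------------------
        theta[0] += dt * theta_dot[0]
        theta[1] += dt * theta_dot[1]
        theta[2] += dt * theta_dot[2]
        theta_dot[0] += dt * tdd0
        theta_dot[1] += dt * tdd1
        theta_dot[2] += dt * tdd2

        ok = True
        for j in range(3):
            if not math.isfinite(theta[j]) or abs(theta[j]) > fall_limit:
                ok = False
        if not ok:
            return k + 1
    return n_steps
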