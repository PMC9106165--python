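"""Compiled numerical core: right-hand side and two adaptive integrators.

The RHS is evaluated tens of thousands of times per model fit, so both the
derivative and the integration loops are JIT-compiled.  Two integrators are
provided: an explicit Dormand-Prince 4(5) pair (the default) and a
linearly-implicit Rosenbrock 2(3) method for stiff regimes — osteoclast
clearance scaled by large inhibition terms can reach 1e3-1e7 per day, which
stability-limits any explicit method.  Correctness is cross-checked in the
test suite against a literal transcription of the printed equations, a
fixed-step classical RK4 integrator, and ``scipy.integrate.solve_ivp``.

Parameter array layout follows ``parameters.PARAM_NAMES``; state array
layout follows ``state.VARIABLES``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# status codes returned by the integrator
OK = 0
STEP_UNDERFLOW = 1
MAX_STEPS = 2
NONFINITE = 3


@njit(cache=True)
def rhs(y, th, a, b, c, out):
    """Time derivative of the 9-variable system (time-autonomous)."""
    Mo = y[0]
    M = y[1]
    M1 = y[2]
    M2 = y[3]
    Mo1 = y[4]
    OB = y[5]
    OC = y[6]
    B = y[7]
    D = y[8]
    pro = M1 + Mo1

    # polarization forms (aspect c)
    if c == 1:
        p1 = th[22] * D + th[23] * D * pro
        depol1 = th[25] * M2
        p21 = 0.0
        p22 = th[24] * D
        depol21 = th[26]
        depol22 = 0.0
        p3 = th[19] * D + th[20] * D * pro
        depol3 = th[21] * M2
    elif c == 2:
        p1 = th[22] * D + th[23] * D * pro
        depol1 = th[25] * M2
        p21 = th[24] * pro
        p22 = 0.0
        depol21 = th[26]
        depol22 = 0.0
        p3 = th[19] * D + th[20] * D * pro
        depol3 = th[21] * M2
    else:  # c == 3
        p1 = th[22] * D
        depol1 = 0.0
        p21 = 0.0
        p22 = th[24] * D
        depol21 = 0.0
        depol22 = th[26]
        p3 = th[20] * M1
        depol3 = th[21]

    # osteoclast regulation (aspect a)
    if a == 1:
        doc = (th[12] + th[13] * pro) / (1.0 + th[14] * M2)
        dltoc = th[3] * (1.0 + th[15] * M2)
    elif a == 2:
        doc = (th[12] + th[13] * pro) / (1.0 + th[14] * OB)
        dltoc = th[3] * (1.0 + th[15] * OB)
    else:  # a == 3
        doc = th[12] * OB / (1.0 + th[14] * M2)
        dltoc = th[3] * (1.0 + th[15] * M2)

    # osteoblast expansion (aspect b)
    if b == 1:
        gob = th[4] * M2
    else:
        gob = th[4] * D

    out[0] = th[9] - th[0] * Mo + th[17] * pro + th[18] * D - p3 * Mo + depol3 * Mo1
    out[1] = (th[10] - th[1] * M - doc * M - p1 * M - p21 * M
              + depol1 * M1 + depol21 * M2)
    out[2] = p1 * M - depol1 * M1 - p22 * M1 + depol22 * M2 - th[1] * M1
    out[3] = p21 * M + p22 * M1 - depol21 * M2 - depol22 * M2 - th[1] * M2
    out[4] = p3 * Mo - depol3 * Mo1 - th[0] * Mo1
    out[5] = th[11] * OC + gob - th[2] * OB * B
    out[6] = doc * M - dltoc * OC
    out[7] = th[6] * (1.0 + th[8] * M2) * OB - th[5] * (1.0 + th[7] * pro) * OC * B
    out[8] = -th[16] * pro * D


# Dormand-Prince 5(4) coefficients (FSAL).
_C2, _C3, _C4, _C5 = 1.0 / 5.0, 3.0 / 10.0, 4.0 / 5.0, 8.0 / 9.0
_A21 = 1.0 / 5.0
_A31, _A32 = 3.0 / 40.0, 9.0 / 40.0
_A41, _A42, _A43 = 44.0 / 45.0, -56.0 / 15.0, 32.0 / 9.0
_A51, _A52, _A53, _A54 = 19372.0 / 6561.0, -25360.0 / 2187.0, 64448.0 / 6561.0, -212.0 / 729.0
_A61, _A62, _A63, _A64, _A65 = (9017.0 / 3168.0, -355.0 / 33.0, 46732.0 / 5247.0,
                                49.0 / 176.0, -5103.0 / 18656.0)
_B1, _B3, _B4, _B5, _B6 = 35.0 / 384.0, 500.0 / 1113.0, 125.0 / 192.0, -2187.0 / 6784.0, 11.0 / 84.0
# error weights: b5 - b4hat
_E1, _E3, _E4, _E5, _E6, _E7 = (35.0 / 384.0 - 5179.0 / 57600.0,
                                500.0 / 1113.0 - 7571.0 / 16695.0,
                                125.0 / 192.0 - 393.0 / 640.0,
                                -2187.0 / 6784.0 + 92097.0 / 339200.0,
                                11.0 / 84.0 - 187.0 / 2100.0,
                                -1.0 / 40.0)


@njit(cache=True)
def integrate(y0, t_eval, th, a, b, c, rtol, atol, max_steps):
    """Adaptive Dormand-Prince 4(5) integration, dense at ``t_eval``.

    ``atol`` is a per-variable absolute-tolerance array.  Returns
    ``(traj, status, t_fail)`` where ``traj`` has shape
    ``(len(t_eval), 9)`` and status is one of the module status codes.
    """
    n = y0.shape[0]
    n_out = t_eval.shape[0]
    traj = np.empty((n_out, n))
    for j in range(n):
        traj[0, j] = y0[j]

    y = y0.copy()
    ytmp = np.empty(n)
    ynew = np.empty(n)
    k1 = np.empty(n)
    k2 = np.empty(n)
    k3 = np.empty(n)
    k4 = np.empty(n)
    k5 = np.empty(n)
    k6 = np.empty(n)
    k7 = np.empty(n)

    t = t_eval[0]
    rhs(y, th, a, b, c, k1)
    h = 1e-4
    steps = 0

    for i_out in range(1, n_out):
        t_end = t_eval[i_out]
        while t < t_end:
            if steps >= max_steps:
                return traj, MAX_STEPS, t
            hit_end = False
            if h >= t_end - t:
                h = t_end - t
                hit_end = True
            # stages
            for j in range(n):
                ytmp[j] = y[j] + h * _A21 * k1[j]
            rhs(ytmp, th, a, b, c, k2)
            for j in range(n):
                ytmp[j] = y[j] + h * (_A31 * k1[j] + _A32 * k2[j])
            rhs(ytmp, th, a, b, c, k3)
            for j in range(n):
                ytmp[j] = y[j] + h * (_A41 * k1[j] + _A42 * k2[j] + _A43 * k3[j])
            rhs(ytmp, th, a, b, c, k4)
            for j in range(n):
                ytmp[j] = y[j] + h * (_A51 * k1[j] + _A52 * k2[j] + _A53 * k3[j] + _A54 * k4[j])
            rhs(ytmp, th, a, b, c, k5)
            for j in range(n):
                ytmp[j] = y[j] + h * (_A61 * k1[j] + _A62 * k2[j] + _A63 * k3[j]
                                      + _A64 * k4[j] + _A65 * k5[j])
            rhs(ytmp, th, a, b, c, k6)
            for j in range(n):
                ynew[j] = y[j] + h * (_B1 * k1[j] + _B3 * k3[j] + _B4 * k4[j]
                                      + _B5 * k5[j] + _B6 * k6[j])
            rhs(ynew, th, a, b, c, k7)
            # scaled error norm
            errnorm = 0.0
            finite = True
            for j in range(n):
                e = h * (_E1 * k1[j] + _E3 * k3[j] + _E4 * k4[j]
                         + _E5 * k5[j] + _E6 * k6[j] + _E7 * k7[j])
                ay = abs(y[j])
                ayn = abs(ynew[j])
                sc = atol[j] + rtol * (ay if ay > ayn else ayn)
                q = e / sc
                errnorm += q * q
                if not np.isfinite(ynew[j]):
                    finite = False
            if not finite:
                h *= 0.25
                if h < 1e-14:
                    return traj, NONFINITE, t
                steps += 1
                continue
            errnorm = np.sqrt(errnorm / n)
            steps += 1
            if errnorm <= 1.0:
                t = t_end if hit_end else t + h
                for j in range(n):
                    y[j] = ynew[j]
                    k1[j] = k7[j]  # FSAL
                fac = 0.9 * errnorm ** -0.2 if errnorm > 0.0 else 5.0
                if fac > 5.0:
                    fac = 5.0
                h *= fac
            else:
                fac = 0.9 * errnorm ** -0.2
                if fac < 0.2:
                    fac = 0.2
                h *= fac
                if h < 1e-14:
                    return traj, STEP_UNDERFLOW, t
        for j in range(n):
            traj[i_out, j] = y[j]
    return traj, OK, t


# Rosenbrock 2(3) constants (ode23s-class, autonomous form).
_ROS_D = 1.0 / (2.0 + np.sqrt(2.0))
_ROS_E32 = 6.0 + np.sqrt(2.0)


@njit(cache=True)
def integrate_ros23(y0, t_eval, th, a, b, c, rtol, atol, max_steps):
    """Linearly-implicit Rosenbrock 2(3) integration, dense at ``t_eval``.

    L-stable second-order method with an embedded third-order error
    estimate; the Jacobian is formed by forward differences at every step
    (the system is only 9-dimensional).  Same return convention as
    :func:`integrate`.
    """
    n = y0.shape[0]
    n_out = t_eval.shape[0]
    traj = np.empty((n_out, n))
    for j in range(n):
        traj[0, j] = y0[j]

    y = y0.copy()
    ytmp = np.empty(n)
    f0 = np.empty(n)
    f1 = np.empty(n)
    f2 = np.empty(n)
    fj = np.empty(n)
    jac = np.empty((n, n))
    w = np.empty((n, n))
    rhs_k = np.empty(n)

    t = t_eval[0]
    h = 1e-4
    steps = 0

    for i_out in range(1, n_out):
        t_end = t_eval[i_out]
        while t < t_end:
            if steps >= max_steps:
                return traj, MAX_STEPS, t
            hit_end = False
            if h >= t_end - t:
                h = t_end - t
                hit_end = True

            rhs(y, th, a, b, c, f0)
            # forward-difference Jacobian
            for jcol in range(n):
                dy = 1e-8 * (abs(y[jcol]) + atol[jcol] + 1e-12)
                save = y[jcol]
                y[jcol] = save + dy
                rhs(y, th, a, b, c, fj)
                y[jcol] = save
                for irow in range(n):
                    jac[irow, jcol] = (fj[irow] - f0[irow]) / dy

            hd = h * _ROS_D
            for irow in range(n):
                for jcol in range(n):
                    w[irow, jcol] = -hd * jac[irow, jcol]
                w[irow, irow] += 1.0

            for j in range(n):
                rhs_k[j] = f0[j]
            k1 = np.linalg.solve(w, rhs_k)
            for j in range(n):
                ytmp[j] = y[j] + 0.5 * h * k1[j]
            rhs(ytmp, th, a, b, c, f1)
            for j in range(n):
                rhs_k[j] = f1[j] - k1[j]
            k2 = np.linalg.solve(w, rhs_k)
            for j in range(n):
                k2[j] += k1[j]
                ytmp[j] = y[j] + h * k2[j]
            rhs(ytmp, th, a, b, c, f2)
            for j in range(n):
                rhs_k[j] = (f2[j] - _ROS_E32 * (k2[j] - f1[j])
                            - 2.0 * (k1[j] - f0[j]))
            k3 = np.linalg.solve(w, rhs_k)

            errnorm = 0.0
            finite = True
            for j in range(n):
                e = (h / 6.0) * (k1[j] - 2.0 * k2[j] + k3[j])
                ay = abs(y[j])
                ayn = abs(ytmp[j])
                sc = atol[j] + rtol * (ay if ay > ayn else ayn)
                q = e / sc
                errnorm += q * q
                if not np.isfinite(ytmp[j]) or not np.isfinite(e):
                    finite = False
            if not finite:
                h *= 0.25
                if h < 1e-14:
                    return traj, NONFINITE, t
                steps += 1
                continue
            errnorm = np.sqrt(errnorm / n)
            steps += 1
            if errnorm <= 1.0:
                t = t_end if hit_end else t + h
                for j in range(n):
                    y[j] = ytmp[j]
                fac = 0.9 * errnorm ** (-1.0 / 3.0) if errnorm > 0.0 else 5.0
                if fac > 5.0:
                    fac = 5.0
                h *= fac
            else:
                fac = 0.9 * errnorm ** (-1.0 / 3.0)
                if fac < 0.2:
                    fac = 0.2
                h *= fac
                if h < 1e-14:
                    return traj, STEP_UNDERFLOW, t
        for j in range(n):
            traj[i_out, j] = y[j]
    return traj, OK, t
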