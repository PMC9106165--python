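"""Independent oracles for the test suite.

``rhs_literal`` is a second, deliberately naive transcription of the nine
printed rate equations, written directly from the equations with no shared
code with the package kernel.  ``rk4_fixed`` is a classical fixed-step
Runge-Kutta integrator used to validate the adaptive solver.
"""

from __future__ import annotations

import numpy as np

# state order: Mo, M, M1, M2, Mo1, OB, OC, B, D


def rhs_literal(y, p, a, b, c):
    """Literal re-transcription of the nine equations (dict-based params)."""
    Mo, M, M1, M2, Mo1, OB, OC, B, D = y

    # hypothesis c: polarization forms
    if c == 1:
        p1 = p["p_11"] * D + p["p_12"] * D * (M1 + Mo1)
        depol1 = p["depol_1"] * M2
        p21 = 0.0
        p22 = p["p_2"] * D
        depol21 = p["depol_2"]
        depol22 = 0.0
        p3 = p["p_31"] * D + p["p_32"] * D * (M1 + Mo1)
        depol3 = p["depol_3"] * M2
    elif c == 2:
        p1 = p["p_11"] * D + p["p_12"] * D * (M1 + Mo1)
        depol1 = p["depol_1"] * M2
        p21 = p["p_2"] * (M1 + Mo1)
        p22 = 0.0
        depol21 = p["depol_2"]
        depol22 = 0.0
        p3 = p["p_31"] * D + p["p_32"] * D * (M1 + Mo1)
        depol3 = p["depol_3"] * M2
    elif c == 3:
        p1 = p["p_11"] * D
        depol1 = 0.0
        p21 = 0.0
        p22 = p["p_2"] * D
        depol21 = 0.0
        depol22 = p["depol_2"]
        p3 = p["p_32"] * M1
        depol3 = p["depol_3"]
    else:
        raise ValueError(c)

    # hypothesis a: osteoclast formation and clearance
    if a == 1:
        d_oc = (p["d_OC"] + p["d_OC2"] * (M1 + Mo1)) / (1.0 + p["Inhib_OC"] * M2)
        del_oc = p["delta_OC"] * (1.0 + p["Inhib_OC2"] * M2)
    elif a == 2:
        d_oc = (p["d_OC"] + p["d_OC2"] * (M1 + Mo1)) / (1.0 + p["Inhib_OC"] * OB)
        del_oc = p["delta_OC"] * (1.0 + p["Inhib_OC2"] * OB)
    elif a == 3:
        d_oc = p["d_OC"] * OB / (1.0 + p["Inhib_OC"] * M2)
        del_oc = p["delta_OC"] * (1.0 + p["Inhib_OC2"] * M2)
    else:
        raise ValueError(a)

    # hypothesis b: osteoblast expansion
    gamma = p["gamma_OB"] * M2 if b == 1 else p["gamma_OB"] * D

    dMo = (p["H_Mo"] - p["delta_Mo"] * Mo + p["I_1"] * (M1 + Mo1) + p["I_2"] * D
           - p3 * Mo + depol3 * Mo1)
    dM = (p["H_M"] - p["delta_M"] * M - d_oc * M - p1 * M - p21 * M
          + depol1 * M1 + depol21 * M2)
    dM1 = p1 * M - depol1 * M1 - p22 * M1 + depol22 * M2 - p["delta_M"] * M1
    dM2 = p21 * M + p22 * M1 - depol21 * M2 - depol22 * M2 - p["delta_M"] * M2
    dMo1 = p3 * Mo - depol3 * Mo1 - p["delta_Mo"] * Mo1
    dOB = p["H_OB"] * OC + gamma - p["delta_OB"] * OB * B
    dOC = d_oc * M - del_oc * OC
    dB = (p["Pi_B"] * (1.0 + p["beta"] * M2) * OB
          - p["delta_B"] * (1.0 + p["alpha"] * (M1 + Mo1)) * OC * B)
    dD = -p["delta_D"] * (M1 + Mo1) * D

    return np.array([dMo, dM, dM1, dM2, dMo1, dOB, dOC, dB, dD])


def rk4_fixed(y0, t_grid, p, a, b, c, dt=1e-3):
    """Classical RK4 at fixed step ``dt``, sampled at ``t_grid``.

    Uses plain Python floats in the inner loop for speed; ``t_grid`` entries
    must be (near-)multiples of ``dt``.
    """
    f = _rhs_floats(p, a, b, c)
    y = [float(v) for v in y0]
    out = [list(y)]
    t = float(t_grid[0])
    for t_end in t_grid[1:]:
        n_steps = int(round((t_end - t) / dt))
        h = (t_end - t) / n_steps
        for _ in range(n_steps):
            k1 = f(y)
            y2 = [yi + 0.5 * h * ki for yi, ki in zip(y, k1)]
            k2 = f(y2)
            y3 = [yi + 0.5 * h * ki for yi, ki in zip(y, k2)]
            k3 = f(y3)
            y4 = [yi + h * ki for yi, ki in zip(y, k3)]
            k4 = f(y4)
            y = [yi + h / 6.0 * (a1 + 2 * a2 + 2 * a3 + a4)
                 for yi, a1, a2, a3, a4 in zip(y, k1, k2, k3, k4)]
        t = t_end
        out.append(list(y))
    return np.array(out)


def _rhs_floats(p, a, b, c):
    def f(y):
        return list(rhs_literal(y, p, a, b, c))
    return f


# --- compiled variant of the same oracle -----------------------------------
# The stiff a2 models need stability-respecting step sizes (down to ~1e-6 d),
# which is too slow for the pure-Python loop.  This is the same independent
# transcription, compiled; it shares no code or parameter layout with the
# package kernel.

_ORACLE_PARAMS = (
    "H_Mo", "delta_Mo", "I_1", "I_2", "H_M", "delta_M", "H_OB", "delta_OB",
    "gamma_OB", "d_OC", "d_OC2", "Inhib_OC", "delta_OC", "Inhib_OC2", "Pi_B",
    "beta", "delta_B", "alpha", "delta_D", "p_11", "p_12", "depol_1", "p_2",
    "depol_2", "p_31", "p_32", "depol_3",
)

try:
    from numba import njit
except ImportError:  # pragma: no cover
    njit = None


def _oracle_rhs_py(y, q, a, b, c):
    Mo, M, M1, M2, Mo1, OB, OC, B, D = (y[0], y[1], y[2], y[3], y[4],
                                        y[5], y[6], y[7], y[8])
    (H_Mo, delta_Mo, I_1, I_2, H_M, delta_M, H_OB, delta_OB, gamma_OB, d_OC,
     d_OC2, Inhib_OC, delta_OC, Inhib_OC2, Pi_B, beta, delta_B, alpha,
     delta_D, p_11, p_12, depol_1, p_2, depol_2, p_31, p_32, depol_3) = (
        q[0], q[1], q[2], q[3], q[4], q[5], q[6], q[7], q[8], q[9], q[10],
        q[11], q[12], q[13], q[14], q[15], q[16], q[17], q[18], q[19], q[20],
        q[21], q[22], q[23], q[24], q[25], q[26])
    pro = M1 + Mo1
    if c == 1:
        p1 = p_11 * D + p_12 * D * pro
        depol1 = depol_1 * M2
        p21 = 0.0
        p22 = p_2 * D
        depol21 = depol_2
        depol22 = 0.0
        p3 = p_31 * D + p_32 * D * pro
        depol3 = depol_3 * M2
    elif c == 2:
        p1 = p_11 * D + p_12 * D * pro
        depol1 = depol_1 * M2
        p21 = p_2 * pro
        p22 = 0.0
        depol21 = depol_2
        depol22 = 0.0
        p3 = p_31 * D + p_32 * D * pro
        depol3 = depol_3 * M2
    else:
        p1 = p_11 * D
        depol1 = 0.0
        p21 = 0.0
        p22 = p_2 * D
        depol21 = 0.0
        depol22 = depol_2
        p3 = p_32 * M1
        depol3 = depol_3
    if a == 1:
        d_oc = (d_OC + d_OC2 * pro) / (1.0 + Inhib_OC * M2)
        del_oc = delta_OC * (1.0 + Inhib_OC2 * M2)
    elif a == 2:
        d_oc = (d_OC + d_OC2 * pro) / (1.0 + Inhib_OC * OB)
        del_oc = delta_OC * (1.0 + Inhib_OC2 * OB)
    else:
        d_oc = d_OC * OB / (1.0 + Inhib_OC * M2)
        del_oc = delta_OC * (1.0 + Inhib_OC2 * M2)
    gamma = gamma_OB * M2 if b == 1 else gamma_OB * D
    return np.array([
        H_Mo - delta_Mo * Mo + I_1 * pro + I_2 * D - p3 * Mo + depol3 * Mo1,
        H_M - delta_M * M - d_oc * M - p1 * M - p21 * M
        + depol1 * M1 + depol21 * M2,
        p1 * M - depol1 * M1 - p22 * M1 + depol22 * M2 - delta_M * M1,
        p21 * M + p22 * M1 - depol21 * M2 - depol22 * M2 - delta_M * M2,
        p3 * Mo - depol3 * Mo1 - delta_Mo * Mo1,
        H_OB * OC + gamma - delta_OB * OB * B,
        d_oc * M - del_oc * OC,
        Pi_B * (1.0 + beta * M2) * OB
        - delta_B * (1.0 + alpha * pro) * OC * B,
        -delta_D * pro * D,
    ])


def _rk4_loop_py(y0, t_grid, q, a, b, c, dt):
    y = y0.copy()
    out = np.empty((t_grid.shape[0], y0.shape[0]))
    out[0] = y
    t = t_grid[0]
    for i in range(1, t_grid.shape[0]):
        t_end = t_grid[i]
        n_steps = int(round((t_end - t) / dt))
        h = (t_end - t) / n_steps
        for _ in range(n_steps):
            k1 = _oracle_rhs(y, q, a, b, c)
            k2 = _oracle_rhs(y + 0.5 * h * k1, q, a, b, c)
            k3 = _oracle_rhs(y + 0.5 * h * k2, q, a, b, c)
            k4 = _oracle_rhs(y + h * k3, q, a, b, c)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        t = t_end
        out[i] = y
    return out


if njit is not None:
    _oracle_rhs = njit(cache=True)(_oracle_rhs_py)
    _rk4_loop = njit(cache=True)(_rk4_loop_py)
else:  # pragma: no cover
    _oracle_rhs = _oracle_rhs_py
    _rk4_loop = _rk4_loop_py


def rk4_fixed_compiled(y0, t_grid, p, a, b, c, dt=1e-3):
    """Compiled classical RK4 at fixed step ``dt`` (dict-based params)."""
    q = np.array([float(p[name]) for name in _ORACLE_PARAMS])
    return _rk4_loop(np.asarray(y0, dtype=float),
                     np.asarray(t_grid, dtype=float), q, a, b, c, float(dt))
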