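"""Model dynamics: derivative evaluation, homeostasis constraints, simulation.

The homeostasis constraint sets every replenishment rate equal to the
corresponding clearance flux at the measured day-0 baseline, so that the
uninjured system is an exact fixed point.  The derived quantities are the
monocyte, macrophage and osteoblast replenishment rates, the osteoclast
formation rate and the bone apposition rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernel
from .errors import DomainError, HomeostasisError, IntegrationError
from .hypotheses import HypothesisCombination
from .parameters import ParameterSet
from .state import VARIABLES, ModelState

__all__ = [
    "evaluate_rhs",
    "derive_homeostatic_parameters",
    "simulate_trajectory",
    "Trajectory",
]


def evaluate_rhs(state: ModelState, params: ParameterSet,
                 combo: HypothesisCombination) -> np.ndarray:
    """Time derivatives (per day) of all nine variables at ``state``.

    Raises :class:`DomainError` on negative state components (enforced by
    ``ModelState`` itself when constructed normally).
    """
    y = state.to_array()
    if np.any(y < 0):
        raise DomainError("state contains negative components")
    out = np.empty(len(VARIABLES))
    _kernel.rhs(y, params.to_array(), combo.a, combo.b, combo.c, out)
    return out


def derive_homeostatic_parameters(baseline: ModelState, params: ParameterSet,
                                  combo: HypothesisCombination) -> dict[str, float]:
    """Replenishment parameters that make ``baseline`` an exact fixed point.

    ``baseline`` must be an uninjured state (no polarized cells, D = 0) with
    positive cell counts.  Returns the five derived parameters
    ``H_Mo, H_M, H_OB, d_OC, Pi_B``; lifespans and inhibition constants are
    read from ``params``.

    The osteoclast balance depends on the regulation variant: under a3 the
    formation term is osteoblast-proportional, so
    ``d_OC = delta_OC * OC0 / (OB0 * M0)``; under a1 the inhibition terms
    vanish at baseline (no anti-inflammatory macrophages), giving
    ``d_OC = delta_OC * OC0 / M0``; under a2 both inhibition terms involve
    the osteoblast count, which is nonzero at baseline, so the full balance
    ``d_OC = delta_OC * (1 + Inhib_OC2*OB0) * (1 + Inhib_OC*OB0) * OC0 / M0``
    is used.
    """
    if baseline.M1 != 0 or baseline.M2 != 0 or baseline.Mo1 != 0 or baseline.D != 0:
        raise HomeostasisError(
            "homeostatic baseline requires M1 = M2 = Mo1 = 0 and D = 0"
        )
    Mo0, M0, OB0, OC0, B0 = baseline.Mo, baseline.M, baseline.OB, baseline.OC, baseline.B
    for name, v in (("Mo", Mo0), ("M", M0), ("OB", OB0), ("OC", OC0), ("B", B0)):
        if v <= 0:
            raise HomeostasisError(
                f"homeostasis underdetermined: baseline {name} must be > 0, got {v}"
            )

    H_Mo = params.delta_Mo * Mo0
    Pi_B = params.delta_B * OC0 * B0 / OB0
    H_OB = params.delta_OB * OB0 * B0 / OC0

    if combo.a == 3:
        d_OC = params.delta_OC * OC0 / (OB0 * M0)
        delta_OC_eff = params.delta_OC
    elif combo.a == 1:
        d_OC = params.delta_OC * OC0 / M0
        delta_OC_eff = params.delta_OC
    else:  # a == 2: inhibition by osteoblasts is active at baseline
        delta_OC_eff = params.delta_OC * (1.0 + params.Inhib_OC2 * OB0)
        d_OC = delta_OC_eff * (1.0 + params.Inhib_OC * OB0) * OC0 / M0

    # macrophage balance: replenishment covers death plus the
    # macrophage-to-osteoclast differentiation flux (= OC clearance flux).
    H_M = params.delta_M * M0 + delta_OC_eff * OC0

    return {"H_Mo": H_Mo, "H_M": H_M, "H_OB": H_OB, "d_OC": d_OC, "Pi_B": Pi_B}


@dataclass(frozen=True)
class Trajectory:
    """A simulated time course: times (days) and a (n_times, 9) state matrix."""

    times: np.ndarray
    states: np.ndarray
    combo: HypothesisCombination

    def __post_init__(self):
        if self.states.shape != (len(self.times), len(VARIABLES)):
            raise DomainError(
                f"trajectory shape {self.states.shape} does not match "
                f"({len(self.times)}, {len(VARIABLES)})"
            )

    def get(self, variable: str) -> np.ndarray:
        return self.states[:, VARIABLES.index(variable)]

    def at_times(self, times) -> np.ndarray:
        """State matrix rows at the requested times (must be grid members)."""
        times = np.asarray(times, dtype=float)
        idx = []
        for t in times:
            hits = np.nonzero(np.isclose(self.times, t, rtol=0, atol=1e-9))[0]
            if hits.size == 0:
                raise DomainError(f"time {t} not on the trajectory grid")
            idx.append(hits[0])
        return self.states[idx]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(VARIABLES))
        df.insert(0, "time_days", self.times)
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame,
                   combo: HypothesisCombination) -> "Trajectory":
        missing = {"time_days", *VARIABLES} - set(df.columns)
        if missing:
            raise DomainError(f"trajectory frame missing columns: {sorted(missing)}")
        return cls(times=df["time_days"].to_numpy(dtype=float),
                   states=df[list(VARIABLES)].to_numpy(dtype=float),
                   combo=combo)


def _atol_vector(initial: np.ndarray, atol: float) -> np.ndarray:
    # absolute tolerance scaled by the magnitude of each variable's baseline
    scale = np.maximum(np.abs(initial), 1.0)
    return atol * scale


INTEGRATORS = ("dopri45", "rosenbrock23")


def simulate_trajectory(initial: ModelState, params: ParameterSet,
                        combo: HypothesisCombination, t_grid,
                        rtol: float = 1e-6, atol: float = 1e-8,
                        max_steps: int = 10_000_000,
                        method: str = "dopri45") -> Trajectory:
    """Integrate the system over ``t_grid``.

    ``method`` selects the integrator: ``"dopri45"`` (explicit adaptive
    Dormand-Prince 4(5), the default) or ``"rosenbrock23"`` (linearly
    implicit, for stiff parameter regimes).  ``t_grid`` must start at 0 and
    be strictly increasing.  States are integrated unclipped;
    round-off-level negative excursions are clamped to zero on output, and
    excursions beyond the tolerance raise :class:`IntegrationError`.
    """
    if method not in INTEGRATORS:
        raise DomainError(
            f"method must be one of {sorted(INTEGRATORS)}, got {method!r}")
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or len(t_grid) < 1:
        raise DomainError("t_grid must be a 1-D array of times")
    if t_grid[0] != 0:
        raise DomainError(f"t_grid must start at 0, got {t_grid[0]}")
    if len(t_grid) > 1 and not np.all(np.diff(t_grid) > 0):
        raise DomainError("t_grid must be strictly increasing")

    y0 = initial.to_array()
    atol_vec = _atol_vector(y0, atol)
    kernel_fn = (_kernel.integrate if method == "dopri45"
                 else _kernel.integrate_ros23)
    try:
        traj, status, t_fail = kernel_fn(
            y0, t_grid, params.to_array(), combo.a, combo.b, combo.c,
            rtol, atol_vec, max_steps,
        )
    except np.linalg.LinAlgError as exc:  # singular Rosenbrock stage matrix
        raise IntegrationError(f"integration failed: {exc}", t=float("nan"))
    if status != _kernel.OK:
        reason = {
            _kernel.STEP_UNDERFLOW: "step size collapsed",
            _kernel.MAX_STEPS: "maximum step count exceeded",
            _kernel.NONFINITE: "non-finite state encountered",
        }[status]
        raise IntegrationError(f"integration failed at t = {t_fail:.6g}: {reason}", t=t_fail)

    # the equations are structurally non-negative; anything beyond a modest
    # multiple of the local tolerance signals a real solver failure.
    floor = -1e3 * atol_vec
    if np.any(traj < floor[None, :]):
        worst = float(traj.min())
        raise IntegrationError(
            f"state went negative beyond tolerance (min = {worst:.3g})"
        )
    np.clip(traj, 0.0, None, out=traj)
    traj[0] = y0  # exact initial condition
    return Trajectory(times=t_grid, states=traj, combo=combo)
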