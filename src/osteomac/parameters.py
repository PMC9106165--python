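"""Rate constants of the bone-injury repair model.

Defaults are the published best-fit values of the osteoblast-driven
osteoclastogenesis / injury-driven osteoblast expansion / pro-inflammatory-
cell-driven anti-inflammatory polarization variant (a3 b2 c2).  Each
parameter carries a role flag: fixed from the literature, derived from the
homeostasis (steady-state) constraint, or free and estimated by fitting.

Units: lifespans in day^-1; counts in cells; volumes in mm^3; see field
docstrings below for composite units.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, fields

import numpy as np

from .errors import ConfigurationError


class Role(str, enum.Enum):
    FIXED_LITERATURE = "fixed_literature"
    DERIVED_HOMEOSTASIS = "derived_homeostasis"
    FREE_FITTED = "free_fitted"


#: Canonical parameter order used when packing to arrays for the ODE kernel.
PARAM_NAMES: tuple[str, ...] = (
    "delta_Mo", "delta_M", "delta_OB", "delta_OC",
    "gamma_OB", "delta_B", "Pi_B", "alpha", "beta",
    "H_Mo", "H_M", "H_OB", "d_OC", "d_OC2",
    "Inhib_OC", "Inhib_OC2", "delta_D", "I_1", "I_2",
    "p_31", "p_32", "depol_3", "p_11", "p_12", "p_2",
    "depol_1", "depol_2",
)


@dataclass(frozen=True)
class ParameterSet:
    """All rate constants of the coupled model.

    delta_Mo, delta_M, delta_OB, delta_OC : clearance / lifespan rates (day^-1;
        delta_OB effectively mm^-3 day^-1 since it multiplies OB*B, and
        delta_B is cell^-1 day^-1 since it multiplies OC*B).
    gamma_OB : injury- or M2-driven osteoblast formation (cell mm^-3 day^-1
        under b2; cell cell^-1 day^-1 under b1).
    Pi_B : homeostatic bone apposition rate (mm^3 cell^-1 day^-1).
    alpha, beta : pro-/anti-inflammatory modulation of resorption /
        apposition (cell^-1).
    H_Mo, H_M : homeostatic replenishment (cell day^-1).
    H_OB : osteoclast-coupled osteoblast replenishment (cell cell^-1 day^-1).
    d_OC : osteoclast formation rate (cell^-1 day^-1 under a3 where it
        multiplies OB*M; day^-1-like constant under a1/a2).
    d_OC2 : pro-inflammatory contribution to osteoclast formation, used by
        the a1/a2 variants only (no published value; defaults to 0).
    Inhib_OC, Inhib_OC2 : inhibition of osteoclast formation / survival
        (cell^-1).
    delta_D : efferocytosis-driven injury clearance (cell^-1 day^-1).
    I_1, I_2 : monocyte recruitment by pro-inflammatory cells / injury
        factors.
    p_31, p_32, p_11, p_12, p_2, depol_1, depol_2, depol_3 :
        polarization / depolarization rate constants.
    """

    delta_Mo: float = 0.45
    delta_M: float = 0.1
    delta_OB: float = 0.32
    delta_OC: float = 0.53
    gamma_OB: float = 4.33e4
    delta_B: float = 5.99e-7
    Pi_B: float = 6.018e-7
    alpha: float = 0.0022
    beta: float = 0.012
    H_Mo: float = 1.5e4
    H_M: float = 1.8e4
    H_OB: float = 0.014
    d_OC: float = 5.35e-5
    d_OC2: float = 0.0
    Inhib_OC: float = 0.016
    Inhib_OC2: float = 0.052
    delta_D: float = 1.71e-5
    I_1: float = 1.21e-22
    I_2: float = 6.15e3
    p_31: float = 6.094e-73
    p_32: float = 3.42e-5
    depol_3: float = 0.029
    p_11: float = 5.86e-9
    p_12: float = 4.69e-4
    p_2: float = 2.34e-6
    depol_1: float = 0.37
    depol_2: float = 1.47e-39

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(
                    f"parameter {f.name} must be finite and >= 0, got {v}"
                )

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ParameterSet":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(PARAM_NAMES),):
            raise ConfigurationError(
                f"parameter array must have shape ({len(PARAM_NAMES)},), got {arr.shape}"
            )
        return cls(**dict(zip(PARAM_NAMES, arr)))

    def to_dict(self) -> dict[str, float]:
        return {n: float(getattr(self, n)) for n in PARAM_NAMES}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        unknown = set(d) - set(PARAM_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown parameter name(s): {sorted(unknown)}")
        return cls(**d)

    def replace(self, **kwargs) -> "ParameterSet":
        d = self.to_dict()
        unknown = set(kwargs) - set(PARAM_NAMES)
        if unknown:
            raise ConfigurationError(f"unknown parameter name(s): {sorted(unknown)}")
        d.update(kwargs)
        return ParameterSet(**d)


#: Role flags of the published best-fit parameter table (a3 b2 c2 column).
DEFAULT_ROLES: dict[str, Role] = {
    "delta_Mo": Role.FIXED_LITERATURE,
    "delta_M": Role.FIXED_LITERATURE,
    "delta_OC": Role.FIXED_LITERATURE,
    "H_Mo": Role.DERIVED_HOMEOSTASIS,
    "H_M": Role.DERIVED_HOMEOSTASIS,
    "H_OB": Role.DERIVED_HOMEOSTASIS,
    "d_OC": Role.DERIVED_HOMEOSTASIS,
    "Pi_B": Role.DERIVED_HOMEOSTASIS,
    **{
        n: Role.FREE_FITTED
        for n in PARAM_NAMES
        if n not in ("delta_Mo", "delta_M", "delta_OC",
                     "H_Mo", "H_M", "H_OB", "d_OC", "Pi_B")
    },
}
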