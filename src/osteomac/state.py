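"""Dynamical state of the bone-injury repair model.

Nine variables: seven myeloid / bone cell populations (absolute counts),
bone volume B (mm^3) and a lumped injury-factor / cellular-debris variable
D (mm^3).  The default initial condition is the experimentally measured
murine tibial baseline at day 0.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

from .errors import DomainError

#: Canonical variable order used throughout (arrays, CSV columns).
VARIABLES: tuple[str, ...] = ("Mo", "M", "M1", "M2", "Mo1", "OB", "OC", "B", "D")

#: The eight variables observed in the study design (D is latent).
OBSERVED_VARIABLES: tuple[str, ...] = ("OB", "OC", "B", "Mo", "M", "Mo1", "M1", "M2")


@dataclass(frozen=True)
class ModelState:
    """One point of the 9-dimensional state space.

    Attributes
    ----------
    Mo : naive monocytes (cells)
    M : naive macrophages (cells)
    M1 : pro-inflammatory macrophages (cells)
    M2 : anti-inflammatory macrophages (cells)
    Mo1 : pro-inflammatory monocytes (cells)
    OB : osteoblasts (cells)
    OC : osteoclasts (cells)
    B : bone volume (mm^3)
    D : injury factors / cellular debris (mm^3)
    """

    Mo: float = 1.4e4
    M: float = 2.8e4
    M1: float = 0.0
    M2: float = 0.0
    Mo1: float = 0.0
    OB: float = 3.1e4
    OC: float = 8.8e4
    B: float = 0.3530
    D: float = 2.8

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not np.isfinite(v) or v < 0:
                raise DomainError(f"state variable {f.name} must be finite and >= 0, got {v}")

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, v) for v in VARIABLES], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ModelState":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (len(VARIABLES),):
            raise DomainError(f"state array must have shape ({len(VARIABLES)},), got {arr.shape}")
        return cls(**dict(zip(VARIABLES, arr)))

    def replace(self, **kwargs) -> "ModelState":
        d = {v: getattr(self, v) for v in VARIABLES}
        d.update(kwargs)
        return ModelState(**d)


#: Day-0 injured baseline (injury factors present).
BASELINE = ModelState()

#: Homeostatic baseline: same cell counts and bone volume, no injury.
HOMEOSTATIC_BASELINE = ModelState(D=0.0)
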