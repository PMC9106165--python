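"""Hypothesis combinations and the 18-model space.

Three mechanistic aspects of bone-injury repair are each modelled by
alternative functional forms:

* ``a`` — osteoclast regulation (3 variants): a1 inhibits formation and
  survival by anti-inflammatory macrophages, a2 by osteoblasts (OPG-like),
  a3 makes formation osteoblast-proportional (RANKL-like) with M2
  inhibition.  a1/a2 add a pro-inflammatory contribution ``d_OC2``.
* ``b`` — osteoblast expansion (2 variants): driven by anti-inflammatory
  macrophages (b1) or by injury factors (b2).
* ``c`` — monocyte/macrophage polarization (3 variants): injury- and
  pro-inflammatory-cell-driven pro-inflammatory polarization with
  injury-driven (c1) or pro-inflammatory-cell-driven (c2) anti-inflammatory
  polarization, or a cascade where injury polarizes macrophages which in
  turn polarize monocytes and repolarize into the anti-inflammatory state
  by debris uptake (c3).

The Cartesian product gives 18 distinct models.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigurationError
from .parameters import DEFAULT_ROLES, PARAM_NAMES, ParameterSet, Role


@dataclass(frozen=True)
class HypothesisCombination:
    """A triple (a, b, c) selecting one functional form per aspect."""

    a: int = 3
    b: int = 2
    c: int = 2

    def __post_init__(self) -> None:
        if self.a not in (1, 2, 3):
            raise ConfigurationError(f"osteoclast-regulation variant a must be 1, 2 or 3, got {self.a}")
        if self.b not in (1, 2):
            raise ConfigurationError(f"osteoblast-expansion variant b must be 1 or 2, got {self.b}")
        if self.c not in (1, 2, 3):
            raise ConfigurationError(f"polarization variant c must be 1, 2 or 3, got {self.c}")

    @property
    def name(self) -> str:
        return f"a{self.a}b{self.b}c{self.c}"

    @classmethod
    def from_name(cls, name: str) -> "HypothesisCombination":
        import re

        m = re.fullmatch(r"a(\d)b(\d)c(\d)", name.strip())
        if not m:
            raise ConfigurationError(
                f"combination name must look like 'a3b2c2', got {name!r}"
            )
        return cls(a=int(m.group(1)), b=int(m.group(2)), c=int(m.group(3)))

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def enumerate_combinations() -> list[HypothesisCombination]:
    """All 18 hypothesis combinations in deterministic a-major order."""
    return [
        HypothesisCombination(a, b, c)
        for a, b, c in itertools.product((1, 2, 3), (1, 2), (1, 2, 3))
    ]


# ---------------------------------------------------------------------------
# Rate-function bundle: the concrete functional forms per combination.
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateFunctionBundle:
    """Evaluable rate laws selected by a hypothesis combination.

    Each attribute is a callable from state components to a rate:

    * ``p1(D, M1, Mo1)``, ``p21(D, M1, Mo1)``, ``p22(D, M1)``,
      ``p3(D, M1, Mo1)`` — polarization rates (the c3 transfer term
      ``p22`` uses D only; M1 is accepted for a uniform signature).
    * ``depol1(M2)``, ``depol3(M2)`` — depolarization rates; ``depol21``
      and ``depol22`` are constants.
    * ``d_OC(OB, M1, Mo1, M2)`` — osteoclast formation rate per naive
      macrophage; ``delta_OC(M2, OB)`` — osteoclast clearance rate.
    * ``gamma_OB(D, M2)`` — osteoblast expansion rate.
    """

    combo: HypothesisCombination
    p1: callable
    depol1: callable
    p21: callable
    p22: callable
    depol21: float
    depol22: float
    p3: callable
    depol3: callable
    d_OC: callable
    delta_OC: callable
    gamma_OB: callable


def build_rate_functions(combo: HypothesisCombination, params: ParameterSet) -> RateFunctionBundle:
    """Instantiate the functional forms of ``combo`` at ``params``."""
    th = params
    c = combo.c
    if c == 1:
        p1 = lambda D, M1, Mo1: th.p_11 * D + th.p_12 * D * (M1 + Mo1)
        depol1 = lambda M2: th.depol_1 * M2
        p21 = lambda D, M1, Mo1: 0.0
        p22 = lambda D, M1=0.0: th.p_2 * D
        depol21, depol22 = th.depol_2, 0.0
        p3 = lambda D, M1, Mo1: th.p_31 * D + th.p_32 * D * (M1 + Mo1)
        depol3 = lambda M2: th.depol_3 * M2
    elif c == 2:
        p1 = lambda D, M1, Mo1: th.p_11 * D + th.p_12 * D * (M1 + Mo1)
        depol1 = lambda M2: th.depol_1 * M2
        p21 = lambda D, M1, Mo1: th.p_2 * (M1 + Mo1)
        p22 = lambda D, M1=0.0: 0.0
        depol21, depol22 = th.depol_2, 0.0
        p3 = lambda D, M1, Mo1: th.p_31 * D + th.p_32 * D * (M1 + Mo1)
        depol3 = lambda M2: th.depol_3 * M2
    else:  # c == 3
        p1 = lambda D, M1, Mo1: th.p_11 * D
        depol1 = lambda M2: 0.0
        p21 = lambda D, M1, Mo1: 0.0
        p22 = lambda D, M1=0.0: th.p_2 * D
        depol21, depol22 = 0.0, th.depol_2
        p3 = lambda D, M1, Mo1: th.p_32 * M1
        depol3 = lambda M2: th.depol_3

    a = combo.a
    if a == 1:
        d_OC = lambda OB, M1, Mo1, M2: (th.d_OC + th.d_OC2 * (M1 + Mo1)) / (1.0 + th.Inhib_OC * M2)
        delta_OC = lambda M2, OB: th.delta_OC * (1.0 + th.Inhib_OC2 * M2)
    elif a == 2:
        d_OC = lambda OB, M1, Mo1, M2: (th.d_OC + th.d_OC2 * (M1 + Mo1)) / (1.0 + th.Inhib_OC * OB)
        delta_OC = lambda M2, OB: th.delta_OC * (1.0 + th.Inhib_OC2 * OB)
    else:  # a == 3
        d_OC = lambda OB, M1, Mo1, M2: th.d_OC * OB / (1.0 + th.Inhib_OC * M2)
        delta_OC = lambda M2, OB: th.delta_OC * (1.0 + th.Inhib_OC2 * M2)

    if combo.b == 1:
        gamma_OB = lambda D, M2: th.gamma_OB * M2
    else:
        gamma_OB = lambda D, M2: th.gamma_OB * D

    return RateFunctionBundle(
        combo=combo, p1=p1, depol1=depol1, p21=p21, p22=p22,
        depol21=depol21, depol22=depol22, p3=p3, depol3=depol3,
        d_OC=d_OC, delta_OC=delta_OC, gamma_OB=gamma_OB,
    )


# ---------------------------------------------------------------------------
# Parameter manifest: which parameters each combination actually uses, and
# in which role they enter the fit.
# ---------------------------------------------------------------------------

_COMMON = (
    "delta_Mo", "delta_M", "delta_OB", "delta_OC",
    "gamma_OB", "delta_B", "Pi_B", "alpha", "beta",
    "H_Mo", "H_M", "H_OB", "d_OC",
    "Inhib_OC", "Inhib_OC2", "delta_D", "I_1", "I_2",
)
_C_BRANCH = {
    1: ("p_11", "p_12", "depol_1", "p_2", "depol_2", "p_31", "p_32", "depol_3"),
    2: ("p_11", "p_12", "depol_1", "p_2", "depol_2", "p_31", "p_32", "depol_3"),
    3: ("p_11", "p_2", "depol_2", "p_32", "depol_3"),
}

_FIXED = ("delta_Mo", "delta_M", "delta_OC")


@dataclass(frozen=True)
class ParameterManifest:
    """Role assignment of every parameter a combination uses.

    ``p`` — the free-parameter count entering the AIC penalty; parameters of
    unused hypothesis branches are excluded entirely.
    """

    combo: HypothesisCombination
    free: tuple[str, ...]
    fixed: tuple[str, ...]
    derived: tuple[str, ...]

    @property
    def p(self) -> int:
        return len(self.free)

    @property
    def used(self) -> tuple[str, ...]:
        return tuple(self.free) + tuple(self.fixed) + tuple(self.derived)

    def to_frame(self, params: ParameterSet | None = None,
                 bounds: dict[str, tuple[float, float]] | None = None) -> pd.DataFrame:
        """Tabular export: combo, parameter, role, default, bounds."""
        params = params or ParameterSet()
        rows = []
        for name in PARAM_NAMES:
            if name in self.free:
                role = Role.FREE_FITTED
            elif name in self.fixed:
                role = Role.FIXED_LITERATURE
            elif name in self.derived:
                role = Role.DERIVED_HOMEOSTASIS
            else:
                continue
            lb, ub = (bounds or {}).get(name, (float("nan"), float("nan")))
            rows.append({
                "combo": self.combo.name, "parameter": name, "role": role.value,
                "default": getattr(params, name), "lower_bound": lb, "upper_bound": ub,
            })
        return pd.DataFrame(rows)


def parameter_manifest(combo: HypothesisCombination,
                       homeostatic_replenishment: str = "derived") -> ParameterManifest:
    """Free/fixed/derived parameter roles for ``combo``.

    ``homeostatic_replenishment`` — "derived" constrains H_Mo and H_M by the
    steady-state relations (the stated estimation procedure); "free" lets the
    optimizer fit them (the published parameter table lists them as
    estimated; the two readings disagree, so both are supported).
    """
    if homeostatic_replenishment not in ("derived", "free"):
        raise ConfigurationError(
            "homeostatic_replenishment must be 'derived' or 'free', "
            f"got {homeostatic_replenishment!r}"
        )
    used = set(_COMMON) | set(_C_BRANCH[combo.c])
    if combo.a in (1, 2):
        used.add("d_OC2")

    derived = {"H_OB", "Pi_B"}
    if homeostatic_replenishment == "derived":
        derived |= {"H_Mo", "H_M"}
    # Osteoclast formation magnitude is pinned by the steady state only under
    # the osteoblast-proportional variant; a1/a2 fit it directly.
    if combo.a == 3:
        derived.add("d_OC")

    fixed = set(_FIXED)
    free = used - fixed - derived
    # canonical ordering for determinism
    order = {n: i for i, n in enumerate(PARAM_NAMES)}
    key = order.__getitem__
    return ParameterManifest(
        combo=combo,
        free=tuple(sorted(free, key=key)),
        fixed=tuple(sorted(fixed & used, key=key)),
        derived=tuple(sorted(derived & used, key=key)),
    )
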