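"""In-silico oncostatin-M depletion.

OSM is an osteogenic cytokine produced by anti-inflammatory macrophages.
Its depletion is emulated by scaling down three anti-inflammatory effects:
the M2 contribution to osteoblast expansion, the M2 modulation of bone
mineralization (beta), and the M2-mediated inhibition of osteoclast
formation and survival (Inhib_OC, Inhib_OC2).  The published experiment
reduces osteoblast expansion and mineralization by 50% and osteoclast
inhibition by 80%, i.e. factors (0.5, 0.5, 0.2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dynamics import Trajectory
from .errors import ConfigurationError, DataError
from .hypotheses import HypothesisCombination
from .parameters import ParameterSet
from .state import VARIABLES


@dataclass(frozen=True)
class PerturbationSpec:
    """Multiplicative scaling of the anti-inflammatory effect channels.

    Factors of 1.0 are the identity.  ``b2_expansion_mode`` decides how the
    osteoblast-expansion factor maps onto the injury-driven expansion
    variant (b2), whose expansion term carries no M2 dependence: ``"noop"``
    (default) leaves it untouched; ``"scale_gamma"`` scales gamma_OB anyway.
    Under b1 the factor always scales gamma_OB (the M2-driven channel).
    """

    factor_ob_expansion: float = 0.5
    factor_mineralization: float = 0.5
    factor_oc_inhibition: float = 0.2
    b2_expansion_mode: str = "noop"

    def __post_init__(self):
        for name in ("factor_ob_expansion", "factor_mineralization", "factor_oc_inhibition"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ConfigurationError(f"{name} must be finite and >= 0, got {v}")
        if self.b2_expansion_mode not in ("noop", "scale_gamma"):
            raise ConfigurationError(
                f"b2_expansion_mode must be 'noop' or 'scale_gamma', got {self.b2_expansion_mode!r}"
            )


def apply_osm_depletion(params: ParameterSet, spec: PerturbationSpec,
                        combo: HypothesisCombination) -> ParameterSet:
    """Return a scaled copy of ``params``; the input is untouched.

    Repeated application composes multiplicatively.
    """
    updates = {
        "beta": spec.factor_mineralization * params.beta,
        "Inhib_OC": spec.factor_oc_inhibition * params.Inhib_OC,
        "Inhib_OC2": spec.factor_oc_inhibition * params.Inhib_OC2,
    }
    if combo.b == 1 or spec.b2_expansion_mode == "scale_gamma":
        updates["gamma_OB"] = spec.factor_ob_expansion * params.gamma_OB
    return params.replace(**updates)


def compare_trajectories(baseline: Trajectory, perturbed: Trajectory) -> pd.DataFrame:
    """Per-variable peak value, peak time and terminal value for both runs."""
    if not np.array_equal(baseline.times, perturbed.times):
        raise DataError("trajectories must share the same time grid")
    rows = []
    for run, traj in (("baseline", baseline), ("perturbed", perturbed)):
        for j, var in enumerate(VARIABLES):
            y = traj.states[:, j]
            k = int(np.argmax(y))
            rows.append({
                "run": run, "variable": var,
                "peak_value": float(y[k]),
                "peak_time_days": float(traj.times[k]),
                "terminal_value": float(y[-1]),
            })
    return pd.DataFrame(rows)
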