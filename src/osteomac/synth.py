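"""Synthetic replicate time courses emulating the in vivo study design.

The generator simulates a chosen model and samples replicate observations
with multiplicative Gaussian noise (a fixed coefficient of variation,
truncated at zero) or additive Gaussian noise with a fixed SD.  The default
design mirrors the experiment: 8 observed variables at days 0, 1, 2, 3, 7
and 14 with 5 animals per time point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataset import TimeCourseDataset, dataset_from_long, summarize_replicates
from .dynamics import simulate_trajectory
from .errors import ConfigurationError
from .hypotheses import HypothesisCombination
from .parameters import ParameterSet
from .state import OBSERVED_VARIABLES, VARIABLES, ModelState

DEFAULT_TIMES = (0.0, 1.0, 2.0, 3.0, 7.0, 14.0)


@dataclass(frozen=True)
class StudyDesign:
    """Sampling design of a synthetic experiment.

    ``noise`` is per-variable when a dict is given, otherwise shared.
    ``cv`` (gaussian_cv mode) is the coefficient of variation; the default
    0.2 mimics the relative spread of the in vivo error bars.  ``sd``
    (gaussian_sd mode) is an absolute SD in each variable's own units.
    """

    times: tuple[float, ...] = DEFAULT_TIMES
    replicates: int = 5
    variables: tuple[str, ...] = OBSERVED_VARIABLES
    noise_model: str = "gaussian_cv"
    cv: float | dict[str, float] = 0.2
    sd: float | dict[str, float] = 0.0
    seed: int = 0
    sd_floor: float = 1e-6

    def __post_init__(self):
        if self.noise_model not in ("gaussian_cv", "gaussian_sd"):
            raise ConfigurationError(
                f"noise_model must be 'gaussian_cv' or 'gaussian_sd', got {self.noise_model!r}"
            )
        if self.times[0] != 0:
            raise ConfigurationError("design times must start at 0")
        if self.replicates < 2:
            raise ConfigurationError("at least 2 replicates are required to estimate SDs")
        for v in self._noise_values():
            if v < 0:
                raise ConfigurationError("noise levels must be >= 0")
        unknown = set(self.variables) - set(OBSERVED_VARIABLES)
        if unknown:
            raise ConfigurationError(f"unknown observed variable(s): {sorted(unknown)}")

    def _noise_values(self):
        spec = self.cv if self.noise_model == "gaussian_cv" else self.sd
        if isinstance(spec, dict):
            return list(spec.values())
        return [spec]

    def noise_for(self, variable: str) -> float:
        spec = self.cv if self.noise_model == "gaussian_cv" else self.sd
        if isinstance(spec, dict):
            if variable not in spec:
                raise ConfigurationError(f"no noise level configured for {variable!r}")
            return float(spec[variable])
        return float(spec)


def generate_replicates(combo: HypothesisCombination, params: ParameterSet,
                        initial: ModelState, design: StudyDesign,
                        seed: int | None = None) -> TimeCourseDataset:
    """Simulate ``combo`` and sample noisy replicates under ``design``.

    Observations are ``max(0, truth * (1 + cv * eps))`` with standard-normal
    ``eps`` in gaussian_cv mode, or ``max(0, truth + sd * eps)`` in
    gaussian_sd mode.  Deterministic given the seed (``seed`` overrides
    ``design.seed``).
    """
    rng = np.random.default_rng(design.seed if seed is None else seed)
    t_grid = np.asarray(design.times, dtype=float)
    traj = simulate_trajectory(initial, params, combo, t_grid)

    rows = []
    eps = rng.standard_normal((len(t_grid), len(design.variables), design.replicates))
    for i, t in enumerate(t_grid):
        for j, var in enumerate(design.variables):
            truth = traj.states[i, VARIABLES.index(var)]
            level = design.noise_for(var)
            for r in range(design.replicates):
                if design.noise_model == "gaussian_cv":
                    val = truth * (1.0 + level * eps[i, j, r])
                else:
                    val = truth + level * eps[i, j, r]
                rows.append({"time_days": t, "variable": var,
                             "replicate": r + 1, "value": max(0.0, val)})
    long_df = pd.DataFrame(rows)
    return dataset_from_long(long_df, sd_floor=design.sd_floor)


def summarize_dataset(dataset: TimeCourseDataset,
                      sd_floor: float = 1e-6) -> TimeCourseDataset:
    """Summary-form dataset (means, SDs) from a replicate-level dataset."""
    if dataset.replicates is None:
        raise ConfigurationError("dataset carries no replicates to summarize")
    means, sds = summarize_replicates(dataset.replicates, sd_floor=sd_floor)
    return TimeCourseDataset(means=means, sds=sds)
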