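"""Run configuration: validation, defaults, YAML round trip.

Every pipeline run is controlled by a :class:`RunConfig`; unknown keys are
rejected and each run writes its fully resolved config next to its outputs
for auditability.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field, ValidationError, field_validator

from .errors import ConfigurationError
from .hypotheses import HypothesisCombination
from .parameters import PARAM_NAMES, ParameterSet
from .state import OBSERVED_VARIABLES, ModelState
from .synth import DEFAULT_TIMES, StudyDesign


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SolverConfig(_Strict):
    rtol: float = Field(1e-6, gt=0)
    atol: float = Field(1e-8, gt=0)
    max_steps: int = Field(10_000_000, gt=0)


class OptimizerConfig(_Strict):
    objective: str = "J2"
    restarts: int = Field(20, ge=1)
    maxiter: int = Field(2000, ge=1)
    maxfev: int | None = Field(None, ge=1)
    seed: int = 0
    sigma_mode: str = "per_cell"
    penalty_w: float = Field(1e6, gt=0)
    method: str = "auto"
    max_steps: int = Field(50_000, gt=0)

    @field_validator("objective")
    @classmethod
    def _obj(cls, v):
        if v not in ("J2", "Jinf"):
            raise ValueError(f"objective must be 'J2' or 'Jinf', got {v!r}")
        return v

    @field_validator("sigma_mode")
    @classmethod
    def _sig(cls, v):
        if v not in ("per_cell", "per_time"):
            raise ValueError(f"sigma_mode must be 'per_cell' or 'per_time', got {v!r}")
        return v

    @field_validator("method")
    @classmethod
    def _method(cls, v):
        if v not in ("auto", "dopri45", "rosenbrock23"):
            raise ValueError(
                f"method must be 'auto', 'dopri45' or 'rosenbrock23', got {v!r}")
        return v


class DesignConfig(_Strict):
    times: list[float] = Field(default_factory=lambda: list(DEFAULT_TIMES))
    replicates: int = Field(5, ge=2)
    noise_model: str = "gaussian_cv"
    cv: float = Field(0.2, ge=0)
    seed: int = 42

    def to_design(self) -> StudyDesign:
        return StudyDesign(times=tuple(self.times), replicates=self.replicates,
                           noise_model=self.noise_model, cv=self.cv, seed=self.seed)


class PerturbationConfig(_Strict):
    factor_ob_expansion: float = Field(0.5, ge=0)
    factor_mineralization: float = Field(0.5, ge=0)
    factor_oc_inhibition: float = Field(0.2, ge=0)
    b2_expansion_mode: str = "noop"


class RunConfig(_Strict):
    """Top-level run configuration with model, solver and optimizer blocks."""

    combo: str = "a3b2c2"
    parameters: dict[str, float] = Field(default_factory=dict)
    initial_conditions: dict[str, float] = Field(default_factory=dict)
    homeostatic_replenishment: str = "derived"
    derive_homeostasis: bool = True
    t_end: float = Field(14.0, gt=0)
    n_output_points: int = Field(141, ge=2)
    solver: SolverConfig = Field(default_factory=SolverConfig)
    optimizer: OptimizerConfig = Field(default_factory=OptimizerConfig)
    design: DesignConfig = Field(default_factory=DesignConfig)
    perturbation: PerturbationConfig = Field(default_factory=PerturbationConfig)
    bounds: dict[str, tuple[float, float]] = Field(default_factory=dict)
    output_dir: str = "results"

    @field_validator("combo")
    @classmethod
    def _combo(cls, v):
        HypothesisCombination.from_name(v)  # raises ConfigurationError
        return v

    @field_validator("parameters", "bounds")
    @classmethod
    def _params(cls, v):
        unknown = set(v) - set(PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown parameter name(s): {sorted(unknown)}")
        return v

    @field_validator("initial_conditions")
    @classmethod
    def _ics(cls, v):
        from .state import VARIABLES

        unknown = set(v) - set(VARIABLES)
        if unknown:
            raise ValueError(f"unknown state variable(s): {sorted(unknown)}")
        return v

    @field_validator("homeostatic_replenishment")
    @classmethod
    def _hr(cls, v):
        if v not in ("derived", "free"):
            raise ValueError(
                f"homeostatic_replenishment must be 'derived' or 'free', got {v!r}"
            )
        return v

    # -- resolved objects ---------------------------------------------------

    def hypothesis(self) -> HypothesisCombination:
        return HypothesisCombination.from_name(self.combo)

    def parameter_set(self) -> ParameterSet:
        return ParameterSet().replace(**self.parameters)

    def initial_state(self) -> ModelState:
        return ModelState().replace(**self.initial_conditions)


def load_config(path) -> RunConfig:
    """Load and validate a YAML (JSON-compatible) run config."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig(**raw)
    except ValidationError as e:
        first = e.errors()[0]
        loc = ".".join(str(p) for p in first["loc"]) or "<root>"
        raise ConfigurationError(f"invalid config key {loc!r}: {first['msg']}") from e


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(
        yaml.safe_dump(config.model_dump(mode="json"), sort_keys=False)
    )
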