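import numpy as np
import pytest

from osteomac import (
    BASELINE,
    HOMEOSTATIC_BASELINE,
    HypothesisCombination,
    ParameterSet,
    derive_homeostatic_parameters,
    generate_replicates,
    StudyDesign,
)


@pytest.fixture(scope="session")
def best_combo():
    return HypothesisCombination(3, 2, 2)


@pytest.fixture(scope="session")
def table_params():
    """Published best-fit parameter defaults."""
    return ParameterSet()


@pytest.fixture(scope="session")
def balanced_params(best_combo, table_params):
    """Defaults with homeostasis-derived replenishment (exact fixed point)."""
    derived = derive_homeostatic_parameters(HOMEOSTATIC_BASELINE, table_params, best_combo)
    return table_params.replace(**derived)


def balanced(params: ParameterSet, combo: HypothesisCombination) -> ParameterSet:
    return params.replace(
        **derive_homeostatic_parameters(HOMEOSTATIC_BASELINE, params, combo)
    )


@pytest.fixture(scope="session")
def synthetic_dataset(best_combo, balanced_params):
    """Canonical seed-42 study-design dataset generated from the best model."""
    design = StudyDesign(seed=42, cv=0.1)
    return generate_replicates(best_combo, balanced_params, BASELINE, design)
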