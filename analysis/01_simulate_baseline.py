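"""Simulate the reference model (a3b2c2) response to injury over 14 days.

Writes ``results/trajectory_a3b2c2.csv``.
"""

from pathlib import Path

import numpy as np

from osteomac import (
    BASELINE,
    HOMEOSTATIC_BASELINE,
    HypothesisCombination,
    ParameterSet,
    derive_homeostatic_parameters,
    simulate_trajectory,
)

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    combo = HypothesisCombination(3, 2, 2)
    params = ParameterSet()
    params = params.replace(
        **derive_homeostatic_parameters(HOMEOSTATIC_BASELINE, params, combo))
    t_grid = np.linspace(0.0, 14.0, 141)
    traj = simulate_trajectory(BASELINE, params, combo, t_grid)
    path = OUT / f"trajectory_{combo.name}.csv"
    traj.to_frame().to_csv(path, index=False, float_format="%.17g")
    print(f"wrote {path}")


if __name__ == "__main__":
    main()
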