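"""Fit all 18 hypothesis combinations to the synthetic dataset and rank them.

Reads ``results/dataset_long.csv`` (run ``02_generate_data.py`` first),
fits every combination with the J2 objective and writes the AIC ranking to
``results/model_ranking.tsv``.  With the default budget (8 restarts, 600
iterations per start) this takes tens of minutes; pass ``--quick`` for a
coarse, fast screen.
"""

import argparse
from pathlib import Path

from osteomac import (
    OptimizerSettings,
    enumerate_combinations,
    fit_model,
    rank_models,
    read_dataset,
)
from osteomac.hypotheses import parameter_manifest

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--quick", action="store_true",
                    help="coarse screen: 2 restarts, 150 iterations")
    args = ap.parse_args()

    dataset = read_dataset(OUT / "dataset_long.csv")
    restarts, maxiter = (2, 150) if args.quick else (8, 600)
    fits = []
    for combo in enumerate_combinations():
        settings = OptimizerSettings(seed=args.seed, restarts=restarts,
                                     maxiter=maxiter)
        fit = fit_model(combo, dataset, parameter_manifest(combo), "J2", settings)
        print(f"{combo.name}: J2={fit.J2:.4g}  AIC={fit.AIC_J2:.4g}  "
              f"n_lt1={fit.n_below_one}/{dataset.n_residual_cells}")
        fits.append(fit)
    table = rank_models(fits)
    path = OUT / "model_ranking.tsv"
    table.to_csv(path, sep="\t", index=False, float_format="%.6g")
    print(f"wrote {path}")
    print(table.head(5).to_string(index=False))


if __name__ == "__main__":
    main()
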