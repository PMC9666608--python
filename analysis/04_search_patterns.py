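#!/usr/bin/env python
"""Seed and refine a feature pattern for every (model, band) pair.

Seeds each pattern with the features screening strictly above 50%
accuracy, then runs one pass of greedy remove/add/swap refinement under
shared CV folds, and writes the 28 searched patterns to
results/patterns.json.
"""

import argparse
import dataclasses
import json

import pandas as pd

from erpscreen import make_models
from erpscreen.evaluation import make_folds
from erpscreen.selection import ScreeningGrid, greedy_pattern_search, seed_pattern
from erpscreen.synthetic import BAND_NAMES

from common import DEMO_CV, DL_MAX_ITER, RESULTS


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--max-iter", type=int, default=1,
                        help="greedy refinement passes (demo default 1)")
    args = parser.parse_args()

    tables = {
        band: pd.read_csv(RESULTS / f"features_{band}.csv")
        for band in BAND_NAMES
    }
    grid = ScreeningGrid(table=pd.read_csv(RESULTS / "screening_grid.csv"))
    models = make_models(seed=args.seed, dl_max_iter=DL_MAX_ITER)
    cv = dataclasses.replace(DEMO_CV, seed=args.seed)

    patterns = {}
    for band in BAND_NAMES:
        table = tables[band]
        folds = make_folds(
            table["group"].to_numpy(), table["subject_id"].to_numpy(), cv
        )
        for name, model in models.items():
            seeded = seed_pattern(grid, name, band)
            pattern, result, trace = greedy_pattern_search(
                model, table, seeded, cv, folds=folds, max_iter=args.max_iter
            )
            patterns[f"{name}/{band}"] = {
                "model": name,
                "band": band,
                "seed_features": list(seeded.features),
                "features": list(pattern.features),
                "cv_accuracy_percent": result.metrics.accuracy,
                "n_candidates_evaluated": trace.n_evaluated,
            }
            print(f"  {name:<4} {band:<6} seed {len(seeded.features):2d} -> "
                  f"{len(pattern.features):2d} features, "
                  f"{result.metrics.accuracy:5.1f}%")

    with open(RESULTS / "patterns.json", "w") as fh:
        json.dump(patterns, fh, indent=2)
    print(f"\nwrote {len(patterns)} searched patterns to patterns.json")


if __name__ == "__main__":
    main()
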