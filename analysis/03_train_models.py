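#!/usr/bin/env python
"""Fit the 3 models × 3 feature sets × 3 targets regression grid.

Reads results/features.csv (run 02_extract_features.py first), fits SVR,
random forest and Lasso on spectral-only, structural-only, and combined
features for TRN, NO3 and DW on a stratified 70/30 split, and reports the
ME/MAE/RMSE/rRMSE/R² grid. Writes results/metrics.csv.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from nitroscan import regression

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--grid-search", action="store_true",
                    help="tune hyperparameters by 5-fold CV instead of the defaults")
args = parser.parse_args()

features = pd.read_csv("results/features.csv")
seeds = np.random.SeedSequence(args.seed).generate_state(32) % (2**31)

rows = []
for t_i, target in enumerate(("TRN", "NO3", "DW")):
    train, test = regression.split_table(features, 0.7, seed=int(seeds[t_i]))
    for fset in ("spectral", "structural", "combined"):
        for m_i, model in enumerate(("SVR", "RF", "Lasso")):
            cfg = regression.ModelConfig(model=model, grid_search=args.grid_search,
                                         seed=int(seeds[8 + t_i * 3 + m_i]))
            r = regression.fit_predict(train, test, target, cfg,
                                       features=regression.feature_columns(fset))
            rows.append({"target": target, "feature_set": fset, "model": model,
                         **r.metrics.as_dict()})

metrics = pd.DataFrame(rows)
Path("results").mkdir(exist_ok=True)
metrics.to_csv("results/metrics.csv", index=False)

print(metrics.round(3).to_string(index=False))
best = metrics.loc[metrics.groupby("target")["RMSE"].idxmin()]
print("\nLowest test RMSE per trait:")
print(best[["target", "feature_set", "model", "RMSE", "R2"]].round(3).to_string(index=False))
print("\nExpected pattern: spectral features carry the leaf-nitrogen signal, "
      "structural features the biomass signal; the combined set is competitive "
      "with the better single modality for every trait.")
print("\nMetrics -> results/metrics.csv")
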