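#!/usr/bin/env python
"""Clone-size distributions under neutral and non-neutral competition.

Runs desk-scale ensembles (100 × 100 torus, divisions per cell matching the
full-scale design) of the three scenarios — neutral, 1% and 25% non-neutral
mutations with fitness effects ~ N(0.1, 0.1) — then compares:

* the averaged log first incomplete moment (LFIM) of the surviving clones,
* the proportion of tissue colonized by fitness-altered cells,
* the simulation dN/dS of each ensemble.

The neutral LFIM is straight; with 1% drivers it bends at the sizes where
selected clones outgrow drift; with 25% drivers nearly the whole tissue is
driver-colonized and the line straightens again while dN/dS stays > 1 —
straightness does not imply neutrality.

Writes results/scenario_summary.json, results/lfim_curves.tsv and a plot.
"""

import json
import pathlib
import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from epiclone import experiments as exp
from epiclone.stats import average_curves, first_incomplete_moment

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

N_REPLICATES = 50
SEED = 1

summary = {}
curve_rows = []
fig, axes = plt.subplots(1, 3, figsize=(12, 3.6), sharey=True)
for ax, (i, scen) in zip(
    axes, enumerate(["neutral_scaled", "nonneutral_1pct_scaled", "nonneutral_25pct_scaled"])
):
    results = exp.run_experiment(
        exp.ExperimentConfig(scenario=scen, n_replicates=N_REPLICATES, master_seed=SEED + i)
    )
    cfg = exp.SCENARIO_PRESETS[scen]
    a = 1.0 if scen == "neutral_scaled" else cfg.introduced_ns_ratio
    s = exp.summarize(results)
    s["dnds"] = exp.ensemble_dnds(results, a)
    summary[scen] = s

    curves = [
        first_incomplete_moment(r.true_sizes) for r in results if r.true_sizes.size
    ]
    mean_curve = average_curves(curves)
    for n, mu in zip(mean_curve.n, mean_curve.mu1):
        curve_rows.append({"scenario": scen, "size_cells": n, "mu1": mu})
    for c in curves[:15]:
        ax.plot(c.n, c.mu1, color="C0", alpha=0.25, lw=0.7)
    ax.plot(mean_curve.n, mean_curve.mu1, color="k", lw=1.8)
    ax.set_yscale("log")
    ax.set_title(scen.replace("_scaled", ""))
    ax.set_xlabel("clone size (cells)")
axes[0].set_ylabel("first incomplete moment")
fig.tight_layout()
fig.savefig(OUT / "lfim_scenarios.png", dpi=150)

pd.DataFrame(curve_rows).to_csv(OUT / "lfim_curves.tsv", sep="\t", index=False)
(OUT / "scenario_summary.json").write_text(json.dumps(summary, indent=2))

for scen, s in summary.items():
    print(
        f"{scen}: median R2 {s['median_r2_full']:.3f}, "
        f"colonized fraction {s['mean_non_neutral_cell_fraction']:.3f}, "
        f"dN/dS {s['dnds']:.2f}"
    )
print("Neutral and 25%-driver LFIMs are both nearly straight; only the dN/dS "
      "and colonization readouts separate them.")
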