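"""Virtual biopsy and targeted deep-sequencing of simulated tissue.

Mimics the observation layer of punch-biopsy experiments: square patches of
the basal layer are excised (by default a regular grid of 25 spaced 70 × 70
cell squares from a 500 × 500 lattice, roughly 1 mm² of epithelium each),
each mutation's cell fraction ``f`` inside a patch is converted to a true
variant allele fraction (0.5 f for heterozygous mutations, f under LOH), the
observed read count is one binomial draw at constant depth, and mutations
falling below a minimum read count are lost.  Because biopsies are analysed
independently, a clone spanning several biopsies is reported as several
smaller clones — the truncation that makes large non-neutral clones look
neutral in spaced-sample designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kernels
from .tissue import MutationRegistry, TissueState

VAF_OBS_COLUMNS = [
    "biopsy_id",
    "mutation_id",
    "true_f",
    "reads_obs",
    "depth",
    "vaf",
    "inferred_size_cells",
]


@dataclass(frozen=True)
class BiopsyLayout:
    """Placement of square biopsies on the lattice."""

    n_biopsies: int = 25
    side: int = 70  # cells
    placement: str = "regular_grid"  # or "random_nonoverlap"

    def __post_init__(self):
        if self.n_biopsies < 1 or self.side < 1:
            raise ValueError("n_biopsies and side must be positive")
        if self.placement not in ("regular_grid", "random_nonoverlap"):
            raise ValueError(f"unknown placement {self.placement!r}")

    @property
    def cells_per_biopsy(self) -> int:
        return self.side * self.side


@dataclass(frozen=True)
class SequencingModel:
    """Constant-depth binomial sequencing with a minimum-read detection rule."""

    depth: int = 1000
    min_reads: int = 10
    zygosity: str = "heterozygous"  # or "loh"

    def __post_init__(self):
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not 0 <= self.min_reads <= self.depth:
            raise ValueError("min_reads must lie in [0, depth]")
        if self.zygosity not in ("heterozygous", "loh"):
            raise ValueError(f"unknown zygosity {self.zygosity!r}")

    def true_vaf(self, f: np.ndarray) -> np.ndarray:
        f = np.asarray(f, dtype=float)
        return 0.5 * f if self.zygosity == "heterozygous" else f


def place_biopsies(width: int, height: int, layout: BiopsyLayout, rng=None) -> np.ndarray:
    """Anchor (row, col) of each biopsy square; squares are pairwise disjoint
    and never wrap across the torus seam.

    ``regular_grid`` arranges the biopsies on the most even grid that fits,
    with equal spacing (e.g. 25 squares of 70 cells at 100-cell pitch on a
    500-lattice, leaving 30-cell gaps).  ``random_nonoverlap`` places them by
    rejection sampling.
    """
    side, n = layout.side, layout.n_biopsies
    if n * side * side > width * height:
        raise ValueError("biopsies cannot pack into the lattice (area bound)")
    if layout.placement == "regular_grid":
        rows = int(math.floor(math.sqrt(n)))
        while n % rows:
            rows -= 1
        cols = n // rows
        pitch_r, pitch_c = height // rows, width // cols
        if pitch_r < side or pitch_c < side:
            raise ValueError(
                f"regular grid of {rows}x{cols} biopsies of side {side} does not "
                f"fit a {height}x{width} lattice"
            )
        return np.array(
            [(i * pitch_r, j * pitch_c) for i in range(rows) for j in range(cols)],
            dtype=np.int64,
        )
    rng = np.random.default_rng() if rng is None else rng
    anchors: list[tuple[int, int]] = []
    for _ in range(20000):
        if len(anchors) == n:
            break
        r = int(rng.integers(0, height - side + 1))
        c = int(rng.integers(0, width - side + 1))
        if all(abs(r - r0) >= side or abs(c - c0) >= side for r0, c0 in anchors):
            anchors.append((r, c))
    if len(anchors) < n:
        raise ValueError("could not place non-overlapping biopsies (packing too tight)")
    return np.array(anchors, dtype=np.int64)


def biopsy_frequencies(
    state: TissueState, registry: MutationRegistry, anchors: np.ndarray, side: int
) -> pd.DataFrame:
    """Per-biopsy mutant cell fractions: rows of (biopsy_id, mutation_id, f).

    ``f`` is carriers-in-square / side²; mutations absent from a square are
    omitted.  Each biopsy is tabulated independently, so a clone spanning two
    squares contributes one row per square.
    """
    n = registry.n_nodes
    rows: list[pd.DataFrame] = []
    grid = state.genotype.reshape(state.height, state.width)
    area = float(side * side)
    for b, (r, c) in enumerate(anchors):
        if r + side > state.height or c + side > state.width:
            raise ValueError(f"biopsy {b} at {(r, c)} exceeds lattice bounds")
        if n == 0:
            continue
        sub = grid[r : r + side, c : c + side].ravel()
        counts = _kernels.node_counts(sub, registry.parent[:n], n)
        present = np.nonzero(counts)[0]
        if present.size:
            rows.append(
                pd.DataFrame(
                    {
                        "biopsy_id": b,
                        "mutation_id": present,
                        "f": counts[present] / area,
                    }
                )
            )
    if not rows:
        return pd.DataFrame(
            {"biopsy_id": pd.Series(dtype=np.int64),
             "mutation_id": pd.Series(dtype=np.int64),
             "f": pd.Series(dtype=float)}
        )
    return pd.concat(rows, ignore_index=True)


def simulate_sequencing(
    frequencies: pd.DataFrame,
    model: SequencingModel,
    rng: np.random.Generator,
    cells_per_biopsy: int,
) -> pd.DataFrame:
    """Binomial read sampling of per-biopsy mutant fractions.

    For each (mutation, biopsy) pair, reads_obs ~ Binomial(depth, true VAF);
    pairs with reads_obs below the detection minimum are dropped.  Observed
    VAF is reads_obs/depth and the inferred clone size follows the zygosity
    scaling, capped at the biopsy size.
    """
    f = frequencies["f"].to_numpy(dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("cell fractions must lie in [0, 1]")
    reads = rng.binomial(model.depth, model.true_vaf(f))
    keep = reads >= model.min_reads
    vaf = reads[keep] / model.depth
    out = pd.DataFrame(
        {
            "biopsy_id": frequencies["biopsy_id"].to_numpy()[keep],
            "mutation_id": frequencies["mutation_id"].to_numpy()[keep],
            "true_f": f[keep],
            "reads_obs": reads[keep],
            "depth": model.depth,
            "vaf": vaf,
            "inferred_size_cells": infer_clone_size(vaf, cells_per_biopsy, model.zygosity),
        }
    )
    return out[VAF_OBS_COLUMNS]


def infer_clone_size(vaf, cells_per_biopsy: int, zygosity: str = "heterozygous"):
    """Clone size (cells) implied by a VAF: 2·vaf·cells for heterozygous
    mutations, vaf·cells under LOH, capped at the biopsy size."""
    vaf = np.asarray(vaf, dtype=float)
    scale = 2.0 if zygosity == "heterozygous" else 1.0
    return np.minimum(scale * vaf * cells_per_biopsy, cells_per_biopsy)


def apply_size_detection_limit(table: pd.DataFrame, min_size: float, size_column: str = "size_cells") -> pd.DataFrame:
    """Drop clones below the detection limit (clones exactly at it are kept)."""
    if min_size < 0:
        raise ValueError("min_size must be >= 0")
    return table[table[size_column] >= min_size].reset_index(drop=True)


def subsample_to_match(full_table: pd.DataFrame, n: int, rng: np.random.Generator) -> pd.DataFrame:
    """Uniform subsample of ``n`` rows without replacement (to match the
    clone counts that survive biopsy + sequencing)."""
    if n > len(full_table):
        raise ValueError(f"cannot subsample {n} rows from {len(full_table)}")
    idx = rng.choice(len(full_table), size=n, replace=False)
    return full_table.iloc[np.sort(idx)].reset_index(drop=True)
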