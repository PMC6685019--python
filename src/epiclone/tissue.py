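"""Spatial Moran simulator of clonal competition in squamous epithelium.

The basal (proliferative) layer is a fixed population of progenitor cells on
a hexagonal torus.  At every simulation step one cell, chosen uniformly, is
lost to differentiation; a neighbouring cell divides to fill the space, with
fitter neighbours proportionally more likely to divide.  Each division may
introduce one new mutation in the daughter cell.  Non-neutral mutations add a
fitness increment drawn from a configurable distribution (normal by default);
neutral mutations leave fitness unchanged, and a configurable proportion of
them can be *labelled* as non-neutral to permit a dN/dS-style readout from
purely neutral dynamics.

Time is measured in weeks: with division rate ``lambda`` per progenitor per
week on ``N`` sites, one week corresponds to ``lambda * N`` Moran steps, so a
simulation of ``T`` weeks executes ``round(lambda * N * T)`` steps.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _kernels
from ._kernels import (
    LABEL_LABELLED_NEUTRAL,
    LABEL_NEUTRAL,
    LABEL_NON_NEUTRAL,
)

LABEL_NAMES = {
    LABEL_NEUTRAL: "neutral",
    LABEL_NON_NEUTRAL: "non_neutral",
    LABEL_LABELLED_NEUTRAL: "labelled_neutral",
}

_DIST_CODES = {
    "normal": _kernels.DIST_NORMAL,
    "uniform": _kernels.DIST_UNIFORM,
    "exponential": _kernels.DIST_EXPONENTIAL,
    "constant": _kernels.DIST_CONSTANT,
}

#: TSV column order for clone-size tables.
CLONE_TABLE_COLUMNS = [
    "mutation_id",
    "label",
    "fitness_delta",
    "birth_week",
    "snapshot_week",
    "size_cells",
]


@dataclass(frozen=True)
class FitnessEffect:
    """Distribution of the fitness increment of a non-neutral mutation.

    ``family`` is one of ``normal`` (params: mean, std), ``uniform``
    (low, high), ``exponential`` (scale) or ``constant`` (value).
    """

    family: str = "normal"
    params: tuple[float, ...] = (0.1, 0.1)

    def __post_init__(self):
        if self.family not in _DIST_CODES:
            raise ValueError(f"unknown fitness-effect family {self.family!r}")

    def _kernel_args(self) -> tuple[int, float, float]:
        p = tuple(self.params) + (0.0, 0.0)
        return _DIST_CODES[self.family], float(p[0]), float(p[1])


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one spatial Moran simulation.

    Defaults are the neutral full-scale conditions: a 500 × 500 torus run for
    3000 weeks (~58 years) at 0.5 divisions per progenitor per week with
    1e-3 mutations per division.
    """

    width: int = 500
    height: int = 500
    division_rate: float = 0.5  # divisions per progenitor per week
    duration: float = 3000.0  # weeks
    mutation_rate: float = 1e-3  # mutations per cell division
    non_neutral_fraction: float = 0.0
    fitness_effect: FitnessEffect = field(default_factory=FitnessEffect)
    neutral_label_fraction: float = 0.0
    seed: int = 0
    snapshot_times: tuple[float, ...] = ()

    def __post_init__(self):
        if self.width < 3 or self.height < 3:
            raise ValueError("width and height must be >= 3")
        for name in ("division_rate", "duration", "mutation_rate"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")
        for name in ("non_neutral_fraction", "neutral_label_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for t in self.snapshot_times:
            if not 0.0 <= t <= self.duration:
                raise ValueError("snapshot times must lie in [0, duration]")

    @property
    def n_sites(self) -> int:
        return self.width * self.height

    @property
    def total_steps(self) -> int:
        """Moran steps in the run: division_rate × sites × weeks."""
        return int(round(self.division_rate * self.n_sites * self.duration))

    @property
    def introduced_ns_ratio(self) -> float:
        """Known ratio ``a`` of N-labelled to S-labelled mutation intake.

        For non-neutral runs this is p/(1-p) with p the non-neutral
        fraction; for labelled-neutral runs it is q/(1-q) with q the label
        fraction.  Used to normalise the simulation dN/dS.
        """
        p = self.non_neutral_fraction
        if p > 0:
            if p >= 1:
                raise ValueError("N:S ratio undefined when every mutation is non-neutral")
            return p / (1.0 - p)
        q = self.neutral_label_fraction
        if not 0 < q < 1:
            raise ValueError("no labelled mutation classes to form an N:S ratio")
        return q / (1.0 - q)


class MutationRegistry:
    """Growable record of every mutation event in a simulation.

    Backed by flat arrays shared with the kernels; node id == mutation id.
    """

    def __init__(self, capacity: int, steps_per_week: float):
        capacity = max(int(capacity), 16)
        self.parent = np.full(capacity, -1, dtype=np.int64)
        self.label = np.zeros(capacity, dtype=np.int8)
        self.fitness_delta = np.zeros(capacity, dtype=np.float64)
        self.birth_step = np.zeros(capacity, dtype=np.int64)
        self.n_nodes = 0
        self.steps_per_week = steps_per_week

    def __len__(self) -> int:
        return self.n_nodes

    def birth_weeks(self) -> np.ndarray:
        if self.steps_per_week > 0:
            return self.birth_step[: self.n_nodes] / self.steps_per_week
        return np.zeros(self.n_nodes, dtype=float)

    def labels(self) -> np.ndarray:
        return self.label[: self.n_nodes]

    def to_frame(self) -> pd.DataFrame:
        n = self.n_nodes
        return pd.DataFrame(
            {
                "mutation_id": np.arange(n, dtype=np.int64),
                "parent_id": self.parent[:n],
                "label": [LABEL_NAMES[int(v)] for v in self.label[:n]],
                "fitness_delta": self.fitness_delta[:n],
                "birth_step": self.birth_step[:n],
                "birth_week": self.birth_weeks(),
            }
        )


@dataclass
class TissueState:
    """Lattice state: per-site genotype node (−1 = wild type) and fitness."""

    width: int
    height: int
    genotype: np.ndarray  # int64, flat length width*height
    fitness: np.ndarray  # float64, flat
    step: int = 0

    @classmethod
    def wild_type(cls, width: int, height: int) -> "TissueState":
        n = width * height
        return cls(
            width=width,
            height=height,
            genotype=np.full(n, -1, dtype=np.int64),
            fitness=np.ones(n, dtype=np.float64),
        )

    @property
    def n_sites(self) -> int:
        return self.width * self.height


def _capacity_for(steps: int, mutation_rate: float) -> int:
    mean = steps * mutation_rate
    return int(mean + 10.0 * math.sqrt(mean + 1.0) + 1024)


def moran_step(state: TissueState, registry: MutationRegistry, config: SimulationConfig) -> TissueState:
    """Advance the tissue by a single Moran step (in place; returned for
    convenience).  The kernel RNG must have been seeded beforehand."""
    _advance(state, registry, config, 1)
    return state


def _advance(state, registry, config, n_steps):
    dist_code, p1, p2 = config.fitness_effect._kernel_args()
    n_nodes = _kernels.run_steps(
        state.genotype,
        state.fitness,
        state.width,
        state.height,
        n_steps,
        state.step,
        config.mutation_rate,
        config.non_neutral_fraction,
        config.neutral_label_fraction,
        dist_code,
        p1,
        p2,
        registry.parent,
        registry.label,
        registry.fitness_delta,
        registry.birth_step,
        registry.n_nodes,
    )
    if n_nodes < 0:
        raise MemoryError("lineage capacity exhausted")  # caller retries
    registry.n_nodes = n_nodes
    state.step += n_steps


def clone_sizes(
    state: TissueState,
    registry: MutationRegistry,
    snapshot_week: float | None = None,
) -> pd.DataFrame:
    """Clone-size table: one row per mutation with at least one carrier.

    A clone's size is the number of cells whose mutation set contains the
    mutation; nested (passenger) mutations therefore never exceed their
    ancestors.  Extinct mutations (zero carriers) are omitted.
    """
    n = registry.n_nodes
    if snapshot_week is None:
        snapshot_week = (
            state.step / registry.steps_per_week if registry.steps_per_week > 0 else 0.0
        )
    if n == 0:
        return pd.DataFrame(
            {c: pd.Series(dtype=t) for c, t in zip(
                CLONE_TABLE_COLUMNS, [np.int64, object, float, float, float, np.int64]
            )}
        )
    counts = _kernels.node_counts(state.genotype, registry.parent[:n], n)
    alive = counts > 0
    ids = np.nonzero(alive)[0]
    return pd.DataFrame(
        {
            "mutation_id": ids,
            "label": [LABEL_NAMES[int(v)] for v in registry.label[ids]],
            "fitness_delta": registry.fitness_delta[ids],
            "birth_week": registry.birth_weeks()[ids],
            "snapshot_week": float(snapshot_week),
            "size_cells": counts[ids],
        }
    )


def non_neutral_cell_fraction(state: TissueState, registry: MutationRegistry) -> float:
    """Fraction of cells whose fitness is altered by >= 1 non-neutral mutation."""
    n = registry.n_nodes
    if n == 0:
        return 0.0
    flags = _kernels.non_neutral_ancestry(registry.parent[:n], registry.label[:n], n)
    g = state.genotype
    carried = g >= 0
    return float(np.count_nonzero(flags[g[carried]]) / state.n_sites)


def run_simulation(
    config: SimulationConfig,
) -> tuple[TissueState, MutationRegistry, pd.DataFrame]:
    """Run a full simulation; returns (state, registry, clone-size table).

    The returned table stacks one snapshot per requested time (plus the
    endpoint if not requested).  Snapshots are pure reads of the lattice and
    do not perturb the random stream, so two configs differing only in
    ``snapshot_times`` evolve identically.
    """
    total = config.total_steps
    steps_per_week = config.division_rate * config.n_sites
    snap_weeks = sorted(set(config.snapshot_times) | {config.duration})
    snap_steps = [min(int(round(w * steps_per_week)), total) for w in snap_weeks]

    for attempt in range(4):
        capacity = _capacity_for(total, config.mutation_rate) * (2 ** attempt)
        state = TissueState.wild_type(config.width, config.height)
        registry = MutationRegistry(capacity, steps_per_week)
        _kernels.seed_rng(config.seed)
        tables = []
        try:
            for week, target in zip(snap_weeks, snap_steps):
                _advance(state, registry, config, target - state.step)
                tables.append(clone_sizes(state, registry, snapshot_week=week))
        except MemoryError:
            continue
        return state, registry, pd.concat(tables, ignore_index=True)
    raise RuntimeError("could not allocate lineage capacity for simulation")


def neutral_fixation_trial(width: int, height: int, seed: int, max_steps: int = 10**7) -> bool:
    """Plant one neutral mutant in a wild-type tissue and run drift (no new
    mutations) to absorption.  Returns True if the mutant fixes.

    Under neutral drift on ``N`` sites the fixation probability is 1/N.
    """
    config = SimulationConfig(
        width=width, height=height, division_rate=1.0, duration=0.0,
        mutation_rate=0.0, seed=seed,
    )
    state = TissueState.wild_type(width, height)
    registry = MutationRegistry(16, steps_per_week=float(width * height))
    registry.parent[0] = -1
    registry.label[0] = LABEL_NEUTRAL
    registry.n_nodes = 1
    state.genotype[(height // 2) * width + width // 2] = 0
    _kernels.seed_rng(seed)
    n = width * height
    chunk = 8 * n
    while state.step < max_steps:
        _advance(state, registry, config, chunk)
        carriers = int(np.count_nonzero(state.genotype == 0))
        if carriers == 0:
            return False
        if carriers == n:
            return True
    raise RuntimeError("drift did not reach absorption within max_steps")


def scaled_config(config: SimulationConfig, width: int, height: int) -> SimulationConfig:
    """Shrink the lattice while preserving divisions per cell (same rate and
    duration, fewer total steps)."""
    return replace(config, width=width, height=height)
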