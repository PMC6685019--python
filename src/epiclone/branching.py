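"""Non-spatial single-progenitor branching model with fate imbalance.

Each progenitor division yields one of three outcomes: two progenitors
(probability r + d), one progenitor and one differentiated cell
(1 - 2r), or two differentiated cells (r - d), where ``d`` is the fate
imbalance of the dividing cell's clone.  With d = 0 the progenitor count is
a martingale; a persistent positive imbalance gives a mean growth factor of
(1 + 2d) per division, so a population carrying mutations that perpetually
shift fate towards proliferation eventually explodes.  This is the
unconstrained counterpart of the spatial Moran model: without competition
for space, even tiny imbalances compound exponentially.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tissue import FitnessEffect


@dataclass(frozen=True)
class BranchingConfig:
    n_simulations: int = 20
    initial_progenitors: int = 1000
    division_rate: float = 0.5  # divisions per progenitor per week
    duration: float = 3000.0  # weeks
    mutation_rate: float = 1e-3  # mutations per division
    # imbalance deltas in probability units (0.25% = 0.0025)
    imbalance_effect: FitnessEffect = field(
        default_factory=lambda: FitnessEffect("normal", (0.0025, 0.0125))
    )
    symmetric_division_fraction: float = 0.25  # r: balanced two-progenitor prob
    initial_imbalance: float = 0.0  # fate imbalance carried by the founders
    seed: int = 0
    max_population: int = 2_000_000  # explosion guard

    def __post_init__(self):
        if not 0 < self.symmetric_division_fraction < 0.5:
            raise ValueError("symmetric division fraction must lie in (0, 0.5)")
        if self.n_simulations < 1 or self.initial_progenitors < 1:
            raise ValueError("n_simulations and initial_progenitors must be >= 1")


def _draw_effect(rng: np.random.Generator, eff: FitnessEffect, size: int) -> np.ndarray:
    fam, p = eff.family, eff.params
    if fam == "normal":
        return rng.normal(p[0], p[1], size)
    if fam == "uniform":
        return rng.uniform(p[0], p[1], size)
    if fam == "exponential":
        return rng.exponential(p[0], size)
    return np.full(size, p[0])


def branching_population(config: BranchingConfig) -> np.ndarray:
    """Progenitor-count trajectories, shape (n_simulations, weeks + 1).

    Each week every progenitor divides with probability min(rate, 1); on
    division, one daughter may mutate (probability ``mutation_rate``),
    adding an imbalance draw to her clone's cumulative fate imbalance.
    Fate probabilities are clipped to [0, 1] after the shift.  Trajectories
    that hit ``max_population`` are held there (the population has
    "exploded"); extinct trajectories stay at 0.
    """
    rng = np.random.default_rng(config.seed)
    weeks = int(np.ceil(config.duration))
    p_div = min(config.division_rate, 1.0)
    r = config.symmetric_division_fraction
    traj = np.zeros((config.n_simulations, weeks + 1), dtype=np.int64)
    for s in range(config.n_simulations):
        # per-progenitor cumulative fate imbalance of the carrying clone
        imbalance = np.full(config.initial_progenitors, config.initial_imbalance)
        traj[s, 0] = imbalance.size
        for w in range(1, weeks + 1):
            if imbalance.size == 0 or imbalance.size >= config.max_population:
                traj[s, w] = traj[s, w - 1]
                continue
            divides = rng.random(imbalance.size) < p_div
            quiet = imbalance[~divides]
            d = imbalance[divides]
            p_rr = np.clip(r + d, 0.0, 1.0)
            p_dd = np.clip(r - d, 0.0, 1.0)
            u = rng.random(d.size)
            two_prog = u < p_rr
            two_diff = u >= 1.0 - p_dd
            # offspring progenitors: 2, 0 or 1 per dividing cell
            children = np.concatenate([d[two_prog], d[two_prog],
                                       d[~two_prog & ~two_diff]])
            mutates = rng.random(children.size) < config.mutation_rate
            if mutates.any():
                children = children.copy()
                children[mutates] += _draw_effect(rng, config.imbalance_effect,
                                                  int(mutates.sum()))
            imbalance = np.concatenate([quiet, children])
            traj[s, w] = min(imbalance.size, config.max_population)
    return traj
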