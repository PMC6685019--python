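"""Numba inner loops for the spatial Moran simulator.

All randomness inside the kernels uses numba's per-thread NumPy legacy RNG,
seeded once per simulation through :func:`seed_rng`.  The draw order within a
Moran step is fixed (site, neighbour, mutation test, label, fitness effect),
so a given seed reproduces a simulation bit-for-bit.

Genotypes are stored as indices into a persistent lineage forest: node ``m``
represents the clone founded by mutation ``m`` and ``parent[m]`` is the
genotype of the cell in which the mutation arose (``-1`` for wild type).  A
cell carries exactly the mutations on the path from its genotype node to the
root, so clone sizes for every mutation are recovered in one bottom-up sweep.
"""

from __future__ import annotations

import numba as nb
import numpy as np

# fitness-effect distribution family codes
DIST_NORMAL = 0
DIST_UNIFORM = 1
DIST_EXPONENTIAL = 2
DIST_CONSTANT = 3

# mutation label codes
LABEL_NEUTRAL = 0
LABEL_NON_NEUTRAL = 1
LABEL_LABELLED_NEUTRAL = 2


@nb.njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@nb.njit(inline="always")
def _neighbor_flat(idx, k, width, height):
    """k-th hexagonal neighbour (axial embedding) of flat site ``idx``."""
    r = idx // width
    c = idx % width
    if k == 0:
        c += 1
    elif k == 1:
        c -= 1
    elif k == 2:
        r += 1
    elif k == 3:
        r -= 1
    elif k == 4:
        r -= 1
        c += 1
    else:
        r += 1
        c -= 1
    if r == height:
        r = 0
    elif r == -1:
        r = height - 1
    if c == width:
        c = 0
    elif c == -1:
        c = width - 1
    return r * width + c


@nb.njit(inline="always")
def _draw_effect(dist_code, p1, p2):
    if dist_code == DIST_NORMAL:
        return np.random.normal(p1, p2)
    elif dist_code == DIST_UNIFORM:
        return np.random.uniform(p1, p2)
    elif dist_code == DIST_EXPONENTIAL:
        return np.random.exponential(p1)
    return p1  # constant


@nb.njit(inline="always")
def _choose_weighted6(w0, w1, w2, w3, w4, w5):
    """Index in 0..5 chosen with probability proportional to the weights.

    All-zero weights (every candidate clamped to fitness 0) fall back to a
    uniform choice.
    """
    total = w0 + w1 + w2 + w3 + w4 + w5
    if total <= 0.0:
        return np.random.randint(0, 6)
    u = np.random.random() * total
    acc = w0
    if u < acc:
        return 0
    acc += w1
    if u < acc:
        return 1
    acc += w2
    if u < acc:
        return 2
    acc += w3
    if u < acc:
        return 3
    acc += w4
    if u < acc:
        return 4
    return 5


@nb.njit(cache=True)
def sample_weighted_choice(weights, n_draws):
    """Sample the 6-way fitness-proportional choice ``n_draws`` times.

    Exposes the kernel's neighbour-selection rule for statistical testing.
    """
    counts = np.zeros(6, dtype=np.int64)
    for _ in range(n_draws):
        k = _choose_weighted6(
            weights[0], weights[1], weights[2], weights[3], weights[4], weights[5]
        )
        counts[k] += 1
    return counts


@nb.njit(cache=True)
def run_steps(
    genotype,
    fitness,
    width,
    height,
    n_steps,
    step0,
    mutation_rate,
    non_neutral_fraction,
    neutral_label_fraction,
    dist_code,
    dist_p1,
    dist_p2,
    parent,
    label,
    fitness_delta,
    birth_step,
    n_nodes,
):
    """Advance the tissue by ``n_steps`` Moran steps.

    Each step removes one uniformly chosen cell (differentiation) and fills
    the gap with a daughter of one of its six neighbours, chosen with
    probability proportional to fitness.  With probability ``mutation_rate``
    the daughter acquires one new mutation.  Cell fitness is clamped at 0.

    Returns the updated node count, or ``-1`` if the preallocated lineage
    arrays are full (caller retries with more capacity).
    """
    n_sites = width * height
    capacity = parent.shape[0]
    for t in range(n_steps):
        i = np.random.randint(0, n_sites)
        k = _choose_weighted6(
            fitness[_neighbor_flat(i, 0, width, height)],
            fitness[_neighbor_flat(i, 1, width, height)],
            fitness[_neighbor_flat(i, 2, width, height)],
            fitness[_neighbor_flat(i, 3, width, height)],
            fitness[_neighbor_flat(i, 4, width, height)],
            fitness[_neighbor_flat(i, 5, width, height)],
        )
        j = _neighbor_flat(i, k, width, height)
        genotype[i] = genotype[j]
        fitness[i] = fitness[j]
        if mutation_rate > 0.0 and np.random.random() < mutation_rate:
            if n_nodes >= capacity:
                return -1
            delta = 0.0
            if np.random.random() < non_neutral_fraction:
                lab = LABEL_NON_NEUTRAL
                delta = _draw_effect(dist_code, dist_p1, dist_p2)
            elif (
                neutral_label_fraction > 0.0
                and np.random.random() < neutral_label_fraction
            ):
                lab = LABEL_LABELLED_NEUTRAL
            else:
                lab = LABEL_NEUTRAL
            parent[n_nodes] = genotype[i]
            label[n_nodes] = lab
            fitness_delta[n_nodes] = delta
            birth_step[n_nodes] = step0 + t
            genotype[i] = n_nodes
            f = fitness[i] + delta
            fitness[i] = f if f > 0.0 else 0.0
            n_nodes += 1
    return n_nodes


@nb.njit(cache=True)
def node_counts(genotype, parent, n_nodes):
    """Number of cells carrying each mutation (bottom-up lineage sweep).

    ``counts[m]`` is the clone size of mutation ``m``: cells whose genotype
    node is ``m`` or any descendant of ``m``.  Parents always have smaller
    ids than children, so a single reverse pass accumulates correctly.
    """
    counts = np.zeros(n_nodes, dtype=np.int64)
    for s in range(genotype.shape[0]):
        g = genotype[s]
        if g >= 0:
            counts[g] += 1
    for m in range(n_nodes - 1, -1, -1):
        p = parent[m]
        if p >= 0:
            counts[p] += counts[m]
    return counts


@nb.njit(cache=True)
def non_neutral_ancestry(parent, label, n_nodes):
    """Boolean per node: does its mutation set contain a non-neutral one."""
    flags = np.zeros(n_nodes, dtype=np.bool_)
    for m in range(n_nodes):
        p = parent[m]
        flags[m] = (label[m] == LABEL_NON_NEUTRAL) or (p >= 0 and flags[p])
    return flags
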