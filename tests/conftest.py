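import numpy as np
import pytest

from epiclone.tissue import (
    MutationRegistry,
    SimulationConfig,
    TissueState,
    run_simulation,
)


@pytest.fixture(scope="session")
def small_mutated_tissue():
    """A 12x12 tissue run long enough to accumulate a nested lineage."""
    cfg = SimulationConfig(
        width=12, height=12, division_rate=1.0, duration=60.0,
        mutation_rate=0.05, non_neutral_fraction=0.1, seed=424,
    )
    state, registry, table = run_simulation(cfg)
    return cfg, state, registry, table


def mutation_set(registry: MutationRegistry, node: int) -> frozenset[int]:
    """All mutation ids carried by a cell with genotype ``node`` (oracle:
    explicit walk up the lineage tree)."""
    out = set()
    while node >= 0:
        out.add(int(node))
        node = int(registry.parent[node])
    return frozenset(out)


def brute_force_clone_sizes(state: TissueState, registry: MutationRegistry) -> dict[int, int]:
    """Oracle clone sizes: count carriers per mutation by materialising
    every cell's mutation set."""
    counts: dict[int, int] = {}
    for g in state.genotype:
        for m in mutation_set(registry, int(g)):
            counts[m] = counts.get(m, 0) + 1
    return counts
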