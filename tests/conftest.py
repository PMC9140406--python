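import numpy as np
import pytest

from dlplink import BipartiteNetwork, BlockModelSpec, generate_block_bipartite, toy_fixture


@pytest.fixture(scope="session")
def toy():
    """The hand-checkable 4-node path network and its worked example."""
    return toy_fixture()


@pytest.fixture(scope="session")
def planted_net():
    """The default planted 2-block network used by experiment-level tests."""
    return generate_block_bipartite(BlockModelSpec(seed=11))


def random_bipartite(rng: np.random.Generator, max_side: int = 10, p: float = 0.3) -> BipartiteNetwork:
    """A random bipartite graph with 2..max_side nodes per side."""
    n_u = int(rng.integers(2, max_side + 1))
    n_v = int(rng.integers(2, max_side + 1))
    edges = [(u, v) for u in range(n_u) for v in range(n_v) if rng.random() < p]
    return BipartiteNetwork(n_u, n_v, edges)
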