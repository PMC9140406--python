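"""Synthetic bipartite networks with planted, learnable link structure.

The generator is a two-sided stochastic block model: each U node and
each V node carries a block label, and a U x V pair is linked with
probability ``p_in`` when the blocks match and ``p_out`` otherwise.
With ``p_in >> p_out`` matched-block pairs sit inside a dense
sub-biclique and are connected by many short indirect paths, so the
local structure around a candidate pair carries a genuine signal about
whether the link exists — the property the scorer is supposed to learn.

Defaults emulate small dense affiliation networks (tens of nodes per
side, mean degree a few): 40 + 40 nodes, two blocks, p_in 0.25 and
p_out 0.02, giving about 216 expected edges and a mean degree near 5.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np

from .labeling import NodeFeatureMatrix, encode_features
from .local_structure import LocalStructure
from .network_io import BipartiteNetwork


@dataclass
class BlockModelSpec:
    """Parameters of the planted two-sided block model."""

    n_u: int = 40
    n_v: int = 40
    n_blocks: int = 2
    p_in: float = 0.25
    p_out: float = 0.02
    seed: int = 0
    blocks_u: Sequence[int] | None = None  # explicit assignments override n_blocks
    blocks_v: Sequence[int] | None = None

    def __post_init__(self) -> None:
        if self.n_u <= 0 or self.n_v <= 0:
            raise ValueError("partition sizes must be positive")
        if not (0.0 <= self.p_out <= self.p_in <= 1.0):
            raise ValueError("need 0 <= p_out <= p_in <= 1")
        if self.n_blocks < 1:
            raise ValueError("need at least one block")

    def assignments(self) -> tuple[np.ndarray, np.ndarray]:
        """Block label per node; defaults to contiguous equal-size blocks."""
        if self.blocks_u is not None:
            bu = np.asarray(self.blocks_u, dtype=int)
            if len(bu) != self.n_u:
                raise ValueError("blocks_u must cover every U node")
        else:
            bu = (np.arange(self.n_u) * self.n_blocks) // self.n_u
        if self.blocks_v is not None:
            bv = np.asarray(self.blocks_v, dtype=int)
            if len(bv) != self.n_v:
                raise ValueError("blocks_v must cover every V node")
        else:
            bv = (np.arange(self.n_v) * self.n_blocks) // self.n_v
        return bu, bv


def generate_block_bipartite(spec: BlockModelSpec) -> BipartiteNetwork:
    """Draw a bipartite network from the planted block model.

    Every U x V pair is an independent Bernoulli edge with probability
    ``p_in`` inside matched blocks and ``p_out`` across blocks.
    """
    bu, bv = spec.assignments()
    probs = np.where(bu[:, None] == bv[None, :], spec.p_in, spec.p_out)
    rng = np.random.default_rng(spec.seed)
    mask = rng.random((spec.n_u, spec.n_v)) < probs
    edges = [(int(u), int(v)) for u, v in zip(*np.nonzero(mask))]
    return BipartiteNetwork(spec.n_u, spec.n_v, edges)


class ToyFixture(NamedTuple):
    """A hand-checkable worked example shared across module tests."""

    network: BipartiteNetwork
    pair: tuple[int, int]
    k: int
    structure: LocalStructure
    hop_labels: dict
    features: NodeFeatureMatrix


def toy_fixture() -> ToyFixture:
    """The 4-node path network u1 - v1 - u2 - v2 and its worked example.

    For the candidate pair (u1, v2) at depth k=1 the single length-3
    connecting path u1, v1, u2, v2 covers every node, so the structure
    is the whole path (3 edges, none of them (u1, v2)), the pair is a
    non-edge (label 0), hop labels are u1: 0, v2: 0, v1: 1, u2: 1, and
    the one-hot features have dimension 2 + (k + 1) = 4.
    """
    # indices: u1 -> ("u", 0), u2 -> ("u", 1), v1 -> ("v", 0), v2 -> ("v", 1)
    network = BipartiteNetwork(2, 2, [(0, 0), (1, 0), (1, 1)])
    pair = (0, 1)
    k = 1
    nodes = (("u", 0), ("u", 1), ("v", 0), ("v", 1))
    structure = LocalStructure(
        target_u=0,
        target_v=1,
        k=k,
        label=0,
        nodes=nodes,
        edges=frozenset({(0, 0), (1, 0), (1, 1)}),
        n_paths=1,
    )
    hop_labels = {("u", 0): 0, ("v", 1): 0, ("v", 0): 1, ("u", 1): 1}
    type_labels = {("u", 0): 0, ("u", 1): 0, ("v", 0): 1, ("v", 1): 1}
    features = encode_features(type_labels, hop_labels, k)
    return ToyFixture(network, pair, k, structure, hop_labels, features)
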