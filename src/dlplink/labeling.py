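"""Node labeling and one-hot feature encoding for local structures.

Real node attributes are typically unavailable in the affiliation-style
networks this package targets, so nodes are labeled synthetically: a
partition-type label (U -> 0, V -> 1) distinguishing node roles, and a
hop label giving each node's distance to the nearer target, marking its
position relative to the candidate pair.  Both labels are one-hot
encoded and concatenated into a fixed ``k + 3``-dimensional feature
vector, so a single model serves structures of every size.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np

from .local_structure import LocalStructure, NodeId


@dataclass(frozen=True)
class NodeFeatureMatrix:
    """Per-node one-hot features in a fixed node order.

    Each row carries exactly two ones: one in the 2-wide type block and
    one in the ``k + 1``-wide hop block (hops capped at ``k``).
    """

    node_order: tuple[NodeId, ...]
    features: np.ndarray  # shape (n_nodes, k + 3)
    k: int

    @property
    def dim(self) -> int:
        return self.features.shape[1]

    def to_dict(self) -> dict:
        """JSON-ready record, storable alongside a structure's record."""
        return {
            "node_order": [[side, idx] for side, idx in self.node_order],
            "features": self.features.astype(int).tolist(),
            "k": self.k,
        }

    @classmethod
    def from_dict(cls, record: dict) -> "NodeFeatureMatrix":
        return cls(
            node_order=tuple((side, idx) for side, idx in record["node_order"]),
            features=np.asarray(record["features"], dtype=float),
            k=record["k"],
        )


def assign_type_labels(ls: LocalStructure) -> dict[NodeId, int]:
    """Partition-type label per node: U-partition 0, V-partition 1."""
    labels: dict[NodeId, int] = {}
    for node in ls.nodes:
        side = node[0]
        if side == "u":
            labels[node] = 0
        elif side == "v":
            labels[node] = 1
        else:
            raise ValueError(f"node {node!r} has no valid partition tag")
    return labels


def assign_hop_labels(ls: LocalStructure) -> dict[NodeId, int]:
    """Hop label per node: distance to the nearer of the two targets,
    measured inside the local structure (target edge absent).

    Both targets get 0.  A node unreachable from either target — which
    the extraction invariants rule out, but which is handled defensively
    — receives the sentinel ``k + 1``, which the encoder folds into the
    cap at ``k``.
    """
    targets: list[NodeId] = [("u", ls.target_u), ("v", ls.target_v)]
    adj = ls.neighbor_map()
    dist: dict[NodeId, int] = {t: 0 for t in targets}
    queue: deque[NodeId] = deque(targets)
    while queue:
        node = queue.popleft()
        for nb in adj[node]:
            if nb not in dist:
                dist[nb] = dist[node] + 1
                queue.append(nb)
    sentinel = ls.k + 1
    return {node: dist.get(node, sentinel) for node in ls.nodes}


def encode_features(
    type_labels: dict[NodeId, int],
    hop_labels: dict[NodeId, int],
    k: int,
) -> NodeFeatureMatrix:
    """One-hot encode type and hop labels and splice the blocks.

    feature(node) = onehot(type; 2) concat onehot(min(hop, k); k + 1),
    giving dimension ``k + 3`` independent of the structure.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if set(type_labels) != set(hop_labels):
        raise ValueError("type and hop labels must cover the same node set")
    node_order = tuple(sorted(type_labels))
    dim = 2 + (k + 1)
    X = np.zeros((len(node_order), dim))
    for row, node in enumerate(node_order):
        t = type_labels[node]
        h = hop_labels[node]
        if t not in (0, 1):
            raise ValueError(f"type label of {node!r} must be 0 or 1, got {t}")
        if h < 0:
            raise ValueError(f"hop label of {node!r} is negative: {h}")
        X[row, t] = 1.0
        X[row, 2 + min(h, k)] = 1.0
    return NodeFeatureMatrix(node_order=node_order, features=X, k=k)


def features_for_structure(ls: LocalStructure) -> NodeFeatureMatrix:
    """Label a structure's nodes and encode them in one step."""
    return encode_features(assign_type_labels(ls), assign_hop_labels(ls), ls.k)
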