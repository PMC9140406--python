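"""Path-induced local structures around a candidate node pair.

The evidence used to score a candidate link (u, v) is the subgraph of the
observed network induced on every node that lies on at least one simple
connecting path between u and v of a fixed odd length, with the direct
u-v edge (when present) removed.  Bipartite parity forces connecting
paths between partitions to have odd length; a depth parameter ``k``
selects path length ``2k + 1`` by default (k=1 -> 3-hop paths, the
shortest indirect connection), or literally ``k`` edges when
``literal_hops`` is set, in which case the only length-1 path is the
removed target edge itself and the structure degenerates to the bare
pair.
"""

from __future__ import annotations

import json
import logging
from collections import deque
from dataclasses import dataclass
from pathlib import Path

from .network_io import BipartiteNetwork, Edge

logger = logging.getLogger(__name__)

#: A node of a local structure: partition tag plus internal index.
NodeId = tuple[str, int]

DEFAULT_PATH_CAP = 10_000


@dataclass(frozen=True)
class LocalStructure:
    """The enclosing subgraph around a target pair.

    ``edges`` is exactly the subgraph of the source network induced on
    ``nodes`` minus the target edge; ``label`` records whether the target
    pair was an edge of the source network.  The two targets are always
    members of ``nodes`` even when no connecting path exists.
    """

    target_u: int
    target_v: int
    k: int
    label: int
    nodes: tuple[NodeId, ...]
    edges: frozenset[Edge]
    n_paths: int = 0
    truncated: bool = False

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def neighbor_map(self) -> dict[NodeId, set[NodeId]]:
        adj: dict[NodeId, set[NodeId]] = {n: set() for n in self.nodes}
        for u, v in self.edges:
            adj[("u", u)].add(("v", v))
            adj[("v", v)].add(("u", u))
        return adj

    # -- JSON round trip (caching / inspection) ------------------------
    def to_dict(self) -> dict:
        return {
            "target_u": self.target_u,
            "target_v": self.target_v,
            "k": self.k,
            "label": self.label,
            "nodes": [[side, idx] for side, idx in self.nodes],
            "edges": sorted([u, v] for u, v in self.edges),
            "n_paths": self.n_paths,
            "truncated": self.truncated,
        }

    @classmethod
    def from_dict(cls, record: dict) -> "LocalStructure":
        return cls(
            target_u=record["target_u"],
            target_v=record["target_v"],
            k=record["k"],
            label=record["label"],
            nodes=tuple((side, idx) for side, idx in record["nodes"]),
            edges=frozenset((u, v) for u, v in record["edges"]),
            n_paths=record.get("n_paths", 0),
            truncated=record.get("truncated", False),
        )

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), sort_keys=True, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "LocalStructure":
        p = Path(text_or_path) if not str(text_or_path).lstrip().startswith("{") else None
        text = p.read_text() if p is not None and p.exists() else str(text_or_path)
        return cls.from_dict(json.loads(text))


def _distances_from(
    start_side: str,
    start: int,
    u_adj: list[set[int]],
    v_adj: list[set[int]],
    banned: Edge | None,
) -> dict[NodeId, int]:
    """BFS hop distances from one node, optionally ignoring one edge."""
    dist: dict[NodeId, int] = {(start_side, start): 0}
    queue: deque[NodeId] = deque([(start_side, start)])
    while queue:
        side, node = queue.popleft()
        d = dist[(side, node)]
        neighbors = u_adj[node] if side == "u" else v_adj[node]
        other = "v" if side == "u" else "u"
        for nb in neighbors:
            edge = (node, nb) if side == "u" else (nb, node)
            if banned is not None and edge == banned:
                continue
            if (other, nb) not in dist:
                dist[(other, nb)] = d + 1
                queue.append((other, nb))
    return dist


def enumerate_connecting_paths(
    net: BipartiteNetwork,
    u: int,
    v: int,
    length: int,
    path_cap: int = DEFAULT_PATH_CAP,
) -> list[list[NodeId]]:
    """All simple paths from U-node ``u`` to V-node ``v`` with exactly
    ``length`` edges, by depth-first search with a visited set.

    The direct edge (u, v), if present, is never traversed, so positive
    and negative candidate pairs are processed identically.  ``length``
    must be odd: an even-length U-to-V path cannot exist in a bipartite
    graph.  Enumeration stops at ``path_cap`` paths with a logged
    warning (worst-case path counts grow exponentially).
    """
    if not (0 <= u < net.n_u):
        raise ValueError(f"u index {u} outside partition of size {net.n_u}")
    if not (0 <= v < net.n_v):
        raise ValueError(f"v index {v} outside partition of size {net.n_v}")
    if length < 1 or length % 2 == 0:
        raise ValueError(
            f"connecting-path length must be a positive odd integer, got {length}"
        )
    u_adj, v_adj = net.adjacency()
    banned: Edge = (u, v)
    # distance-to-target pruning: a node that cannot reach v within the
    # remaining number of edges can never complete a qualifying path
    dist_v = _distances_from("v", v, u_adj, v_adj, banned)

    paths: list[list[NodeId]] = []
    target: NodeId = ("v", v)
    path: list[NodeId] = [("u", u)]
    visited: set[NodeId] = {("u", u)}

    def dfs(side: str, node: int, remaining: int) -> bool:
        """Returns False once the cap is hit to unwind the search."""
        if remaining == 0:
            if (side, node) == target:
                paths.append(list(path))
                if len(paths) >= path_cap:
                    return False
            return True
        neighbors = u_adj[node] if side == "u" else v_adj[node]
        other = "v" if side == "u" else "u"
        for nb in sorted(neighbors):
            edge = (node, nb) if side == "u" else (nb, node)
            if edge == banned:
                continue
            nxt: NodeId = (other, nb)
            if nxt in visited:
                continue
            if dist_v.get(nxt, length + 1) > remaining - 1:
                continue
            visited.add(nxt)
            path.append(nxt)
            ok = dfs(other, nb, remaining - 1)
            path.pop()
            visited.discard(nxt)
            if not ok:
                return False
        return True

    completed = dfs("u", u, length)
    if not completed:
        logger.warning(
            "path cap %d reached for pair (%d, %d) at length %d; structure truncated",
            path_cap, u, v, length,
        )
    return paths


def extract_local_structure(
    net: BipartiteNetwork,
    u: int,
    v: int,
    k: int,
    literal_hops: bool = False,
    path_cap: int = DEFAULT_PATH_CAP,
) -> LocalStructure:
    """Extract the depth-``k`` local structure around the pair (u, v).

    Connecting paths of length ``2k + 1`` (or literally ``k`` when
    ``literal_hops`` is set) are enumerated with the target edge
    excluded; the union of their nodes, always including the targets
    themselves, induces the subgraph, from which the target edge is then
    removed.  A pair with no qualifying path yields the degenerate
    two-node, zero-edge structure rather than an error, so that every
    candidate pair receives a score.
    """
    if k < 1:
        raise ValueError("depth parameter k must be >= 1")
    length = k if literal_hops else 2 * k + 1
    if length % 2 == 0:
        raise ValueError(
            f"literal hop count {k} is even: no U-to-V path of even length exists"
        )
    paths = enumerate_connecting_paths(net, u, v, length, path_cap=path_cap)
    truncated = len(paths) >= path_cap

    node_set: set[NodeId] = {("u", u), ("v", v)}
    for p in paths:
        node_set.update(p)
    nodes = tuple(sorted(node_set))
    members_u = {i for side, i in nodes if side == "u"}
    members_v = {j for side, j in nodes if side == "v"}
    target_edge = (u, v)
    edges = frozenset(
        e for e in net.edges
        if e != target_edge and e[0] in members_u and e[1] in members_v
    )
    return LocalStructure(
        target_u=u,
        target_v=v,
        k=k,
        label=int(net.has_edge(u, v)),
        nodes=nodes,
        edges=edges,
        n_paths=len(paths),
        truncated=truncated,
    )
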