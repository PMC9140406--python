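"""Bipartite networks: containers, edge-list I/O, splitting and sampling.

A bipartite network has two disjoint node partitions U and V and
unweighted, undirected edges that only cross partitions.  Nodes are held
as dense 0-based indices per partition; the original file identifiers (if
the network was read from disk) are kept alongside so results can be
reported in the input's vocabulary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

Edge = tuple[int, int]


def _round_half_away(x: float) -> int:
    """Round positive x half away from zero (0.5 -> 1, 2.5 -> 3)."""
    return int(math.floor(x + 0.5))


def _stage_seed(seed: int, stage: str) -> int:
    """Derive a reproducible sub-seed (< 2**31) for a named pipeline stage."""
    stage_id = sum(ord(c) * 131 ** i for i, c in enumerate(stage)) % (2**31)
    ss = np.random.SeedSequence([int(seed) % (2**31), stage_id])
    return int(ss.generate_state(1)[0] % (2**31))


class BipartiteNetwork:
    """Two node partitions U (size ``n_u``) and V (size ``n_v``) plus
    cross-partition edges given as ``(u_index, v_index)`` pairs.

    Parameters
    ----------
    n_u, n_v:
        Partition sizes.  Isolated nodes are legal; partition sizes are a
        property of the dataset, not of its edge subset.
    edges:
        Iterable of ``(u, v)`` index pairs; duplicates collapse.
    u_ids, v_ids:
        Optional original identifiers, position ``i`` holding the id of
        internal index ``i``.
    """

    def __init__(
        self,
        n_u: int,
        n_v: int,
        edges: Iterable[Edge],
        u_ids: Sequence[int] | None = None,
        v_ids: Sequence[int] | None = None,
    ) -> None:
        if n_u <= 0 or n_v <= 0:
            raise ValueError("both partitions must be non-empty")
        self.n_u = int(n_u)
        self.n_v = int(n_v)
        edge_set = set()
        for u, v in edges:
            u, v = int(u), int(v)
            if not (0 <= u < self.n_u and 0 <= v < self.n_v):
                raise ValueError(f"edge ({u}, {v}) outside partitions {self.n_u}x{self.n_v}")
            edge_set.add((u, v))
        self.edges: frozenset[Edge] = frozenset(edge_set)
        if u_ids is not None and len(u_ids) != self.n_u:
            raise ValueError("u_ids length does not match n_u")
        if v_ids is not None and len(v_ids) != self.n_v:
            raise ValueError("v_ids length does not match n_v")
        self.u_ids = tuple(u_ids) if u_ids is not None else None
        self.v_ids = tuple(v_ids) if v_ids is not None else None
        self._adj: tuple[list[set[int]], list[set[int]]] | None = None

    # -- basic queries -------------------------------------------------
    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def mean_degree(self) -> float:
        return 2.0 * self.n_edges / (self.n_u + self.n_v)

    def has_edge(self, u: int, v: int) -> bool:
        return (u, v) in self.edges

    def adjacency(self) -> tuple[list[set[int]], list[set[int]]]:
        """Return (u_adj, v_adj): neighbor sets per U index and per V index."""
        if self._adj is None:
            u_adj: list[set[int]] = [set() for _ in range(self.n_u)]
            v_adj: list[set[int]] = [set() for _ in range(self.n_v)]
            for u, v in self.edges:
                u_adj[u].add(v)
                v_adj[v].add(u)
            self._adj = (u_adj, v_adj)
        return self._adj

    def with_edges(self, edges: Iterable[Edge]) -> "BipartiteNetwork":
        """Same partitions and id maps, different edge set."""
        return BipartiteNetwork(self.n_u, self.n_v, edges, self.u_ids, self.v_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BipartiteNetwork):
            return NotImplemented
        return (self.n_u, self.n_v, self.edges) == (other.n_u, other.n_v, other.edges)

    def __hash__(self) -> int:
        return hash((self.n_u, self.n_v, self.edges))

    def __repr__(self) -> str:
        return f"BipartiteNetwork(n_u={self.n_u}, n_v={self.n_v}, n_edges={self.n_edges})"


@dataclass
class EdgeSplit:
    """A train/test partition of observed edges plus sampled non-edges."""

    train_pos: list[Edge]
    test_pos: list[Edge]
    train_neg: list[Edge]
    test_neg: list[Edge]
    seed: int = 0

    def training_network(self, net: BipartiteNetwork) -> BipartiteNetwork:
        """The observed network with the held-out test edges removed."""
        return net.with_edges(self.train_pos)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, format: str = "auto") -> BipartiteNetwork:
    """Read a bipartite edge list.

    Two dialects are accepted and auto-detected: the KONECT style
    (``%``-prefixed comment lines, whitespace-separated ``u v [weight
    [time]]`` columns) and plain two-column TSV with ``#`` comments.  Only
    the first two columns are consumed.  File ids may be arbitrary
    positive integers; they are mapped to dense 0-based indices per
    partition in sorted-id order, and the id maps are retained.

    A comment line of exactly three integers is taken as a
    ``n_edges n_u n_v`` size hint (our writer emits one), which preserves
    isolated nodes through a write/read round trip.
    """
    if format not in {"auto", "konect", "tsv"}:
        raise ValueError(f"unknown format {format!r}")
    path = Path(path)
    raw_edges: set[tuple[int, int]] = set()
    hint: tuple[int, int, int] | None = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith("%") or stripped.startswith("#"):
                tokens = stripped.lstrip("%#").split()
                if len(tokens) == 3 and all(t.lstrip("-").isdigit() for t in tokens):
                    hint = (int(tokens[0]), int(tokens[1]), int(tokens[2]))
                continue
            tokens = stripped.split()
            if len(tokens) < 2:
                raise ValueError(f"{path}:{lineno}: expected at least two columns")
            try:
                u_id, v_id = int(tokens[0]), int(tokens[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer node id in {stripped!r}") from exc
            raw_edges.add((u_id, v_id))
    if not raw_edges:
        raise ValueError(f"{path}: no edges found")

    u_ids = sorted({u for u, _ in raw_edges})
    v_ids = sorted({v for _, v in raw_edges})
    if hint is not None:
        # dense 1-based ids from our writer: honor declared partition sizes
        n_edges_h, n_u_h, n_v_h = hint
        if n_u_h >= len(u_ids) and u_ids[0] >= 1 and u_ids[-1] <= n_u_h:
            u_ids = list(range(1, n_u_h + 1))
        if n_v_h >= len(v_ids) and v_ids[0] >= 1 and v_ids[-1] <= n_v_h:
            v_ids = list(range(1, n_v_h + 1))
    u_index = {uid: i for i, uid in enumerate(u_ids)}
    v_index = {vid: j for j, vid in enumerate(v_ids)}
    edges = {(u_index[u], v_index[v]) for u, v in raw_edges}
    return BipartiteNetwork(len(u_ids), len(v_ids), edges, u_ids=u_ids, v_ids=v_ids)


def write_edge_list(net: BipartiteNetwork, path: str | Path) -> None:
    """Write a KONECT-dialect edge list.

    Node ids are normalized to dense 1-based indices per partition and a
    ``% n_edges n_u n_v`` header records partition sizes so that isolated
    nodes survive the round trip.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("% bip unweighted\n")
        fh.write(f"% {net.n_edges} {net.n_u} {net.n_v}\n")
        for u, v in sorted(net.edges):
            fh.write(f"{u + 1}\t{v + 1}\n")


# ---------------------------------------------------------------------------
# Splitting and sampling
# ---------------------------------------------------------------------------

def sample_negatives(
    net: BipartiteNetwork,
    count: int,
    seed: int,
    exclude: Iterable[Edge] = (),
) -> list[Edge]:
    """Sample ``count`` distinct non-edge U x V pairs uniformly.

    Pairs that are edges of ``net`` or appear in ``exclude`` are never
    returned.  Deterministic for a fixed seed.
    """
    excluded = set(net.edges) | set(exclude)
    eligible = [
        (u, v) for u in range(net.n_u) for v in range(net.n_v) if (u, v) not in excluded
    ]
    if count > len(eligible):
        raise ValueError(
            f"requested {count} negative pairs but only {len(eligible)} non-edges available"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(eligible), size=count, replace=False)
    return [eligible[i] for i in idx]


def split_edges(net: BipartiteNetwork, test_fraction: float, seed: int) -> EdgeSplit:
    """Uniformly hold out ``round(test_fraction * n_edges)`` edges for testing
    and draw matching numbers of negative (non-edge) pairs for both sides.

    ``|train_neg| = |train_pos|`` and ``|test_neg| = |test_pos|``; all
    negatives are mutually distinct and disjoint from the edge set.
    """
    if not (0.0 < test_fraction < 1.0):
        raise ValueError("test_fraction must lie strictly between 0 and 1")
    if net.n_edges < 2:
        raise ValueError("need at least 2 edges to split")
    n_test = _round_half_away(test_fraction * net.n_edges)
    n_test = min(n_test, net.n_edges - 1)  # remainder goes to training
    rng = np.random.default_rng(_stage_seed(seed, "split"))
    edges = sorted(net.edges)
    order = rng.permutation(len(edges))
    test_pos = [edges[i] for i in order[:n_test]]
    train_pos = [edges[i] for i in order[n_test:]]
    negatives = sample_negatives(net, net.n_edges, _stage_seed(seed, "negatives"))
    train_neg = negatives[: len(train_pos)]
    test_neg = negatives[len(train_pos):]
    return EdgeSplit(train_pos, test_pos, train_neg, test_neg, seed=seed)


def subsample_links(
    net: BipartiteNetwork, retain_fraction: float, seed: int
) -> BipartiteNetwork:
    """Keep ``round(retain_fraction * n_edges)`` uniformly chosen edges.

    Node partitions are unchanged: nodes isolated by the thinning stay in
    the network, since partition sizes describe the dataset rather than
    the retained edge subset.
    """
    if not (0.0 < retain_fraction <= 1.0):
        raise ValueError("retain_fraction must lie in (0, 1]")
    if retain_fraction == 1.0:
        return net.with_edges(net.edges)
    n_keep = _round_half_away(retain_fraction * net.n_edges)
    rng = np.random.default_rng(_stage_seed(seed, "subsample"))
    edges = sorted(net.edges)
    idx = rng.choice(len(edges), size=n_keep, replace=False)
    return net.with_edges(edges[i] for i in idx)
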