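"""Core data structures for latent-network epidemics.

Nodes are labelled ``1..m`` in *epidemic order*: node 1 is the index case and
``i < j`` implies node ``i`` was infected no later than node ``j``.  The
contact network is an undirected, simple (hollow, symmetric) graph over those
labels; the transmission tree is a spanning tree of the contact network rooted
at node 1 in which every non-index node has exactly one infector with a
smaller label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import networkx as nx
import numpy as np

__all__ = [
    "Graph",
    "NetworkOrder",
    "Epidemic",
    "GraphObservation",
    "validate_epidemic",
    "tree_subgraph",
    "back_degrees",
]

# Pair-status codes used by GraphObservation.
UNKNOWN = 0
KNOWN_PRESENT = 1
KNOWN_ABSENT = -1


class Graph:
    """Undirected simple graph over nodes ``1..m`` (dense boolean adjacency).

    Supports O(1) edge lookup/flip and O(m) neighbour iteration; ``m`` here is
    a few hundred at most, so a dense matrix is the right container.
    """

    __slots__ = ("adj",)

    def __init__(self, adj: np.ndarray):
        adj = np.asarray(adj, dtype=bool)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be a square matrix")
        if adj.shape[0] < 2:
            raise ValueError("graph needs at least 2 nodes")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if adj.diagonal().any():
            raise ValueError("self-loops are not allowed")
        self.adj = adj

    # -- constructors ------------------------------------------------------
    @classmethod
    def empty(cls, m: int) -> "Graph":
        return cls(np.zeros((m, m), dtype=bool))

    @classmethod
    def from_edges(cls, m: int, edges: Iterable[tuple[int, int]]) -> "Graph":
        """Build from 1-based node-pair labels."""
        adj = np.zeros((m, m), dtype=bool)
        for i, j in edges:
            if i == j:
                raise ValueError(f"self-loop ({i},{j}) not allowed")
            if not (1 <= i <= m and 1 <= j <= m):
                raise ValueError(f"edge ({i},{j}) out of range 1..{m}")
            adj[i - 1, j - 1] = adj[j - 1, i - 1] = True
        return cls(adj)

    @classmethod
    def complete(cls, m: int) -> "Graph":
        adj = np.ones((m, m), dtype=bool)
        np.fill_diagonal(adj, False)
        return cls(adj)

    # -- basic queries -----------------------------------------------------
    @property
    def m(self) -> int:
        return self.adj.shape[0]

    @property
    def edge_count(self) -> int:
        return int(self.adj.sum()) // 2

    def has_edge(self, i: int, j: int) -> bool:
        return bool(self.adj[i - 1, j - 1])

    def flip_edge(self, i: int, j: int) -> None:
        if i == j:
            raise ValueError("cannot flip a self-loop")
        v = not self.adj[i - 1, j - 1]
        self.adj[i - 1, j - 1] = self.adj[j - 1, i - 1] = v

    def degree(self, i: int) -> int:
        return int(self.adj[i - 1].sum())

    def neighbors(self, i: int) -> list[int]:
        return [int(j) + 1 for j in np.flatnonzero(self.adj[i - 1])]

    def edges(self) -> list[tuple[int, int]]:
        """All edges as 1-based pairs with i < j."""
        ii, jj = np.nonzero(np.triu(self.adj, k=1))
        return [(int(a) + 1, int(b) + 1) for a, b in zip(ii, jj)]

    def copy(self) -> "Graph":
        return Graph(self.adj.copy())

    def is_connected(self) -> bool:
        g = nx.from_numpy_array(self.adj.astype(int))
        return nx.is_connected(g)

    def __eq__(self, other) -> bool:
        return isinstance(other, Graph) and np.array_equal(self.adj, other.adj)

    def __repr__(self) -> str:
        return f"Graph(m={self.m}, edges={self.edge_count})"


@dataclass(frozen=True)
class NetworkOrder:
    """Entry order of nodes into the network.

    ``sigma[i-1]`` (1-based σ_i) is the epidemic-order label of the i-th node
    to enter during preferential-attachment growth.  The entry order is a
    latent quantity distinct from the infection order.
    """

    sigma: tuple[int, ...]

    def __post_init__(self):
        m = len(self.sigma)
        if sorted(self.sigma) != list(range(1, m + 1)):
            raise ValueError("sigma must be a permutation of 1..m")

    @classmethod
    def identity(cls, m: int) -> "NetworkOrder":
        return cls(tuple(range(1, m + 1)))

    @classmethod
    def from_array0(cls, order: np.ndarray) -> "NetworkOrder":
        """From a 0-based internal position->node array."""
        return cls(tuple(int(v) + 1 for v in order))

    @property
    def m(self) -> int:
        return len(self.sigma)

    def as_array0(self) -> np.ndarray:
        """0-based position->node array for internal numeric code."""
        return np.asarray(self.sigma, dtype=np.int64) - 1


@dataclass(frozen=True)
class Epidemic:
    """Observed epidemic: shifted infection times and transmission tree.

    ``times[0] == 0`` (index case) and times are strictly increasing in the
    label; ``parents[j]`` is the infector of node ``j`` for j = 2..m
    (1-based), with ``parents[j] < j``.
    """

    times: np.ndarray
    parents: Mapping[int, int]

    def __post_init__(self):
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "parents", dict(self.parents))

    @property
    def m(self) -> int:
        return len(self.times)

    def parent_array0(self) -> np.ndarray:
        """0-based array p of length m with p[0] = -1, p[j] = parent of j."""
        p = np.full(self.m, -1, dtype=np.int64)
        for j, i in self.parents.items():
            p[j - 1] = i - 1
        return p

    def tree_pairs(self) -> list[tuple[int, int]]:
        """Tree edges as sorted 1-based pairs (i < j)."""
        return sorted((min(i, j), max(i, j)) for j, i in self.parents.items())


def validate_epidemic(ep: Epidemic) -> list[str]:
    """Check every Epidemic invariant; return human-readable violations.

    An empty list means the epidemic is valid.
    """
    out: list[str] = []
    m = ep.m
    if m < 2:
        out.append("population must contain at least 2 individuals")
        return out
    if ep.times[0] != 0.0:
        out.append("index case must have shifted infection time 0")
    for j in range(2, m + 1):
        if not ep.times[j - 1] > ep.times[j - 2]:
            out.append(f"times not increasing at j={j}")
    expected = set(range(2, m + 1))
    got = set(ep.parents)
    for j in sorted(expected - got):
        out.append(f"missing infector for j={j}")
    for j in sorted(got - expected):
        out.append(f"unexpected infector entry for j={j}")
    for j in sorted(expected & got):
        i = ep.parents[j]
        if i == j:
            out.append(f"self-infection at j={j}")
        elif not (1 <= i < j):
            out.append(f"infector of j={j} must have a smaller label, got {i}")
    if not out:
        # parent(j) < j for all j with a single root already forces a
        # spanning tree rooted at 1; double-check connectivity explicitly.
        g = nx.Graph(ep.tree_pairs())
        g.add_nodes_from(range(1, m + 1))
        if not nx.is_connected(g):
            out.append("transmission tree does not span all nodes")
    return out


def tree_subgraph(ep: Epidemic, m: int | None = None) -> Graph:
    """Undirected graph whose edges are exactly the transmission-tree pairs."""
    bad = validate_epidemic(ep)
    if bad:
        raise ValueError("invalid epidemic: " + "; ".join(bad))
    m = ep.m if m is None else m
    if m != ep.m:
        raise ValueError("m inconsistent with epidemic size")
    return Graph.from_edges(m, ep.tree_pairs())


def back_degrees(g: Graph, order: NetworkOrder) -> np.ndarray:
    """Edges from each entering node back into the existing network.

    Returns ``x`` of length m-1 where ``x[i-2]`` (math index i = 2..m) counts
    edges from σ_i to {σ_1,...,σ_{i-1}}.  The graph lies in the support of the
    preferential-attachment model for this order iff x_2 = 1 and
    1 <= x_i <= i-1 for i >= 3.
    """
    if g.m != order.m:
        raise ValueError("graph and order sizes differ")
    o = order.as_array0()
    x = np.empty(g.m - 1, dtype=np.int64)
    for i in range(1, g.m):
        x[i - 1] = int(g.adj[o[i], o[:i]].sum())
    return x


def pa_support_ok(g: Graph, order: NetworkOrder) -> bool:
    """True iff the (graph, order) pair has positive PA-model probability."""
    x = back_degrees(g, order)
    if x[0] != 1:
        return False
    return bool(np.all(x[1:] >= 1))


class GraphObservation:
    """Partial knowledge of the contact network.

    Each unordered pair is known-present, known-absent, or unknown.  Pairs
    carrying a transmission (tree edges) are necessarily known-present.
    """

    __slots__ = ("status",)

    def __init__(self, status: np.ndarray):
        status = np.asarray(status, dtype=np.int8)
        if not np.array_equal(status, status.T):
            raise ValueError("status matrix must be symmetric")
        if status.diagonal().any():
            raise ValueError("diagonal must be unknown/zero")
        if not np.isin(status, [UNKNOWN, KNOWN_PRESENT, KNOWN_ABSENT]).all():
            raise ValueError("status codes must be in {-1, 0, 1}")
        self.status = status

    @classmethod
    def unknown(cls, m: int) -> "GraphObservation":
        return cls(np.zeros((m, m), dtype=np.int8))

    @classmethod
    def tree_only(cls, ep: Epidemic) -> "GraphObservation":
        obs = cls.unknown(ep.m)
        for i, j in ep.tree_pairs():
            obs.set_status(i, j, KNOWN_PRESENT)
        return obs

    @classmethod
    def fully_known(cls, g: Graph) -> "GraphObservation":
        status = np.where(g.adj, KNOWN_PRESENT, KNOWN_ABSENT).astype(np.int8)
        np.fill_diagonal(status, UNKNOWN)
        return cls(status)

    @property
    def m(self) -> int:
        return self.status.shape[0]

    def set_status(self, i: int, j: int, value: int) -> None:
        if i == j:
            raise ValueError("pairs are off-diagonal")
        self.status[i - 1, j - 1] = self.status[j - 1, i - 1] = value

    def get_status(self, i: int, j: int) -> int:
        return int(self.status[i - 1, j - 1])

    def free_pairs0(self) -> np.ndarray:
        """Unknown pairs as an (n, 2) array of 0-based indices with i < j."""
        iu, ju = np.triu_indices(self.m, k=1)
        mask = self.status[iu, ju] == UNKNOWN
        return np.stack([iu[mask], ju[mask]], axis=1).astype(np.int64)

    def check_consistent(self, ep: Epidemic) -> None:
        """Raise if a transmission pair is marked absent."""
        for i, j in ep.tree_pairs():
            if self.get_status(i, j) == KNOWN_ABSENT:
                raise ValueError(
                    f"pair ({i},{j}) carries a transmission but is marked absent"
                )
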