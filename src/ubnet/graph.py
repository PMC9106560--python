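"""Uncertain-graph data model and exact probability semantics.

An uncertain (probabilistic) graph is an undirected graph ``G~ = (V, E, p)``
whose edges carry existence probabilities ``p: E -> (0, 1]``.  A certain
(deterministic) graph is the special case with all probabilities equal to 1.
Each *instance* (possible world) of an uncertain graph is a certain graph
obtained by independently realising every probabilistic edge; its probability
is the product of included-edge probabilities and excluded-edge complements.

All networks in a cohort share one node universe, so subgraph patterns are
anchored to specific nodes and containment reduces to edge-set inclusion —
no subgraph-isomorphism search is ever needed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Edge",
    "canonical_edge",
    "UncertainNetwork",
    "SubgraphPattern",
    "Instance",
    "Cohort",
    "subgraph_probability",
    "instance_probability",
    "enumerate_instances",
    "is_connected",
]

#: An edge is an unordered node pair stored in canonical (sorted) order.
Edge = tuple


def canonical_edge(u, v):
    """Return the unordered pair ``{u, v}`` in canonical sorted order.

    Self-loops are rejected: the diagonal of a correlation matrix is
    self-correlation and carries no connectivity information.
    """
    if u == v:
        raise ValueError(f"self-loop on node {u!r} is not a valid edge")
    return (u, v) if _node_key(u) < _node_key(v) else (v, u)


def _node_key(n):
    # Total order over node labels; mixed int/str universes sort by type name
    # first so comparison never raises.
    return (type(n).__name__, n)


def _sorted_nodes(nodes: Iterable):
    return tuple(sorted(set(nodes), key=_node_key))


class UncertainNetwork:
    """Symmetric probabilistic graph over a fixed node universe.

    Parameters
    ----------
    nodes : iterable of node labels
        The node universe.  Stored in sorted order; isolated nodes are
        allowed (and required for cohorts whose subjects differ in edges).
    edge_probs : mapping ``(u, v) -> p``
        Edge existence probabilities.  Entries with ``p <= 0`` are dropped
        (a zero-probability edge is indistinguishable from absence in every
        downstream formula); ``p > 1`` is an error.
    """

    __slots__ = ("nodes", "edge_prob", "_node_set")

    def __init__(self, nodes: Iterable, edge_probs: Mapping[Edge, float]):
        self.nodes = _sorted_nodes(nodes)
        self._node_set = frozenset(self.nodes)
        prob: dict[Edge, float] = {}
        for (u, v), p in edge_probs.items():
            if u not in self._node_set or v not in self._node_set:
                raise ValueError(f"edge ({u!r}, {v!r}) uses a node outside the universe")
            e = canonical_edge(u, v)
            p = float(p)
            if p <= 0.0:
                continue
            if p > 1.0:
                raise ValueError(f"edge {e!r} has probability {p} > 1")
            if e in prob and not math.isclose(prob[e], p, abs_tol=1e-12):
                raise ValueError(f"conflicting probabilities for edge {e!r}")
            prob[e] = p
        self.edge_prob = prob

    # -- basic queries -----------------------------------------------------

    def probability(self, edge: Edge) -> float:
        """Existence probability of ``edge`` (0 for absent edges)."""
        u, v = edge
        return self.edge_prob.get(canonical_edge(u, v), 0.0)

    def edges(self) -> list[Edge]:
        return sorted(self.edge_prob, key=lambda e: (_node_key(e[0]), _node_key(e[1])))

    @property
    def n_edges(self) -> int:
        return len(self.edge_prob)

    def is_certain(self) -> bool:
        return all(p == 1.0 for p in self.edge_prob.values())

    def __contains__(self, edge) -> bool:
        u, v = edge
        return canonical_edge(u, v) in self.edge_prob

    def __repr__(self):
        return f"UncertainNetwork(|V|={len(self.nodes)}, |E|={self.n_edges})"


class SubgraphPattern:
    """A connected, non-empty set of canonical edges over a node universe.

    Hashable and totally ordered by the sorted edge tuple, so pattern sets
    and rankings are deterministic.
    """

    __slots__ = ("edges", "_hash")

    def __init__(self, edges: Iterable[Edge]):
        canon = {canonical_edge(u, v) for u, v in edges}
        if not canon:
            raise ValueError("a subgraph pattern must contain at least one edge")
        self.edges = tuple(sorted(canon, key=lambda e: (_node_key(e[0]), _node_key(e[1]))))
        if not _edges_connected(self.edges):
            raise ValueError("a subgraph pattern must induce a connected graph")
        self._hash = hash(self.edges)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def nodes(self) -> frozenset:
        return frozenset(n for e in self.edges for n in e)

    def sort_key(self):
        return tuple((_node_key(u), _node_key(v)) for u, v in self.edges)

    def __eq__(self, other):
        return isinstance(other, SubgraphPattern) and self.edges == other.edges

    def __lt__(self, other):
        return self.sort_key() < other.sort_key()

    def __hash__(self):
        return self._hash

    def __repr__(self):
        return f"SubgraphPattern({list(self.edges)!r})"


@dataclass(frozen=True)
class Instance:
    """One possible world of an uncertain graph: a realised edge subset."""

    edges: frozenset
    probability: float


@dataclass
class Cohort:
    """Labelled collection of per-subject networks over a shared universe.

    ``labels`` follow the +1 (positive / patient-analog) vs -1 (negative /
    control-analog) convention.
    """

    networks: list[UncertainNetwork]
    labels: np.ndarray
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        if len(self.networks) != len(self.labels):
            raise ValueError("one label per network is required")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1 (positive group) or -1 (negative group)")
        universes = {net.nodes for net in self.networks}
        if len(universes) > 1:
            raise ValueError("all networks in a cohort must share one node universe")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:03d}" for i in range(len(self.networks))]

    @property
    def nodes(self) -> tuple:
        return self.networks[0].nodes

    def group(self, label: int) -> list[UncertainNetwork]:
        return [net for net, y in zip(self.networks, self.labels) if y == label]

    @property
    def positives(self) -> list[UncertainNetwork]:
        return self.group(+1)

    @property
    def negatives(self) -> list[UncertainNetwork]:
        return self.group(-1)

    def __len__(self):
        return len(self.networks)


# -- probability semantics -------------------------------------------------


def subgraph_probability(net: UncertainNetwork, g: SubgraphPattern) -> float:
    """Probability that ``net`` contains every edge of pattern ``g``.

    Equals the product of the pattern's edge probabilities when all edges are
    present in the network, and 0 otherwise (marginalising the possible-world
    distribution over worlds containing ``g``).
    """
    prod = 1.0
    for e in g.edges:
        p = net.edge_prob.get(e, 0.0)
        if p == 0.0:
            return 0.0
        prod *= p
    return prod


def instance_probability(net: UncertainNetwork, included: Iterable[Edge]) -> float:
    """Probability of the possible world realising exactly ``included``."""
    inc = {canonical_edge(u, v) for u, v in included}
    extra = inc - set(net.edge_prob)
    if extra:
        raise ValueError(f"edges {sorted(extra)!r} are not in the network")
    prod = 1.0
    for e, p in net.edge_prob.items():
        prod *= p if e in inc else (1.0 - p)
    return prod


def enumerate_instances(net: UncertainNetwork, max_edges: int = 20) -> list[Instance]:
    """Enumerate all ``2^|E|`` possible worlds of ``net`` with probabilities.

    Guarded by ``max_edges`` since the enumeration is exponential.
    """
    edges = net.edges()
    if len(edges) > max_edges:
        raise ValueError(
            f"network has {len(edges)} edges, above the enumeration guard of {max_edges}"
        )
    out = []
    for r in range(len(edges) + 1):
        for combo in itertools.combinations(edges, r):
            out.append(Instance(frozenset(combo), instance_probability(net, combo)))
    return out


def is_connected(edges: Iterable[Edge] | SubgraphPattern) -> bool:
    """True iff the graph induced by ``edges`` on their incident nodes is
    one connected component.  The empty edge set is rejected."""
    if isinstance(edges, SubgraphPattern):
        return True  # connected by construction
    edge_list = [canonical_edge(u, v) for u, v in edges]
    if not edge_list:
        raise ValueError("connectivity of an empty edge set is undefined")
    return _edges_connected(edge_list)


def _edges_connected(edge_list: Sequence[Edge]) -> bool:
    # Union-find over incident nodes; cheaper than building a networkx graph
    # in the mining hot path.
    parent: dict = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u, v in edge_list:
        parent.setdefault(u, u)
        parent.setdefault(v, v)
        ru, rv = find(u), find(v)
        if ru != rv:
            parent[ru] = rv
    roots = {find(n) for n in parent}
    return len(roots) == 1
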