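"""Frequent-subgraph mining of uncertain networks under expected support.

The miner (unFEPG: *uncertain frequent-edge pattern growth*) seeds one
sub-search space per frequent edge ``m_1 ... m_k`` (edges whose expected
support across the cohort reaches ``minsup``) and grows patterns layer by
layer by appending further frequent edges, retaining a candidate iff it is
connected and its expected support still reaches ``minsup``.  Expected
support of a pattern is the cohort mean of its containment probability
(the product of its edge probabilities in each network, or 0 when an edge
is absent); it is anti-monotone in the pattern, which makes the layerwise
pruning sound.

Two growth modes are provided:

``increasing``
    append only edges whose index exceeds every index already in the
    pattern.  Each pattern is generated at most once, but a pattern whose
    index-sorted prefix is disconnected at some layer is missed — this is
    the approximate behaviour of the published procedure.
``exhaustive``
    append any edge with index above the sub-search space's seed index,
    deduplicating candidates.  Every connected pattern admits a growth
    order that keeps each prefix connected, and prefixes inherit frequency
    by anti-monotonicity, so this mode is exact (verified against
    :func:`mine_oracle`).

Certain (binary) networks are the ``p = 1`` special case: expected support
degenerates to the fraction of networks containing the pattern.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .graph import (
    Edge,
    SubgraphPattern,
    UncertainNetwork,
    _node_key,
    is_connected,
    subgraph_probability,
)

__all__ = [
    "MiningConfig",
    "FrequentSubgraph",
    "FrequentEdgeList",
    "expected_support",
    "frequent_edges",
    "grow_patterns",
    "mine_unfepg",
    "mine_oracle",
    "edge_probability_matrix",
    "increasing_prefixes_connected",
]


@dataclass
class MiningConfig:
    """Mining parameters.

    minsup : expected-support threshold in (0, 1]; a pattern is frequent when
        its expected support is >= minsup.  Default 0.25, the operating point
        at which the reference study mined its cohort.
    growth_mode : 'increasing' (approximate, single-generation) or
        'exhaustive' (exact, deduplicated).
    max_pattern_edges : optional cap on pattern size, for dense inputs whose
        frequent-pattern lattice would otherwise explode.
    oracle_max_nodes : guard for the brute-force oracle miner.
    """

    minsup: float = 0.25
    growth_mode: str = "increasing"
    max_pattern_edges: int | None = None
    oracle_max_nodes: int = 8

    def __post_init__(self):
        if not 0.0 < self.minsup <= 1.0:
            raise ValueError(f"minsup must be in (0, 1], got {self.minsup}")
        if self.growth_mode not in ("increasing", "exhaustive"):
            raise ValueError(f"unknown growth mode {self.growth_mode!r}")
        if self.max_pattern_edges is not None and self.max_pattern_edges < 1:
            raise ValueError("max_pattern_edges must be >= 1 when set")


@dataclass(frozen=True)
class FrequentSubgraph:
    """A mined pattern with its expected support.

    ``layer`` is the pattern's edge count; ``seed_index`` the index (into
    the frequent-edge list) of its minimum edge, i.e. the sub-search space
    it belongs to.
    """

    pattern: SubgraphPattern
    esup: float
    layer: int
    seed_index: int

    def sort_key(self):
        return (self.layer, self.pattern.sort_key())


@dataclass
class FrequentEdgeList:
    """The ordered frequent edges ``m_1 ... m_k`` with their expected supports.

    ``k = len(edges)`` is the number of sub-search spaces of the mining run.
    """

    edges: list[Edge]
    esup: list[float] = field(default_factory=list)

    def index_of(self, edge: Edge) -> int:
        return self.edges.index(edge)

    def __len__(self):
        return len(self.edges)


def _check_cohort(nets: Sequence[UncertainNetwork]):
    if not nets:
        raise ValueError("mining requires a non-empty set of networks")
    universes = {net.nodes for net in nets}
    if len(universes) > 1:
        raise ValueError("all networks must share one node universe")


def expected_support(g: SubgraphPattern, nets: Sequence[UncertainNetwork]) -> float:
    """Mean containment probability of ``g`` over the networks."""
    _check_cohort(nets)
    return sum(subgraph_probability(net, g) for net in nets) / len(nets)


def edge_probability_matrix(
    nets: Sequence[UncertainNetwork], edges: Sequence[Edge]
) -> np.ndarray:
    """Dense (n_networks, n_edges) matrix of edge probabilities, 0 if absent."""
    P = np.zeros((len(nets), len(edges)))
    for i, net in enumerate(nets):
        for j, e in enumerate(edges):
            P[i, j] = net.edge_prob.get(e, 0.0)
    return P


def frequent_edges(nets: Sequence[UncertainNetwork], minsup: float) -> FrequentEdgeList:
    """Edges whose expected support reaches ``minsup``, in canonical order."""
    _check_cohort(nets)
    union: dict[Edge, float] = {}
    for net in nets:
        for e, p in net.edge_prob.items():
            union[e] = union.get(e, 0.0) + p
    n = len(nets)
    kept = [
        (e, s / n)
        for e, s in union.items()
        if s / n >= minsup
    ]
    kept.sort(key=lambda item: (_node_key(item[0][0]), _node_key(item[0][1])))
    return FrequentEdgeList([e for e, _ in kept], [s for _, s in kept])


def _candidate_indices(key: tuple, mode: str, k: int) -> Iterable[int]:
    # Indices of frequent edges eligible to extend the pattern ``key``
    # (a sorted tuple of edge indices).  Sub-search space = key[0].
    if mode == "increasing":
        return range(key[-1] + 1, k)
    present = set(key)
    return (j for j in range(key[0] + 1, k) if j not in present)


def grow_patterns(
    patterns: Iterable[SubgraphPattern | FrequentSubgraph],
    M: FrequentEdgeList,
    mode: str = "increasing",
) -> set[SubgraphPattern]:
    """One pattern-growth step: extend each pattern by eligible frequent
    edges and keep the connected candidates (deduplicated)."""
    if mode not in ("increasing", "exhaustive"):
        raise ValueError(f"unknown growth mode {mode!r}")
    index = {e: i for i, e in enumerate(M.edges)}
    out: set[SubgraphPattern] = set()
    for pat in patterns:
        if isinstance(pat, FrequentSubgraph):
            pat = pat.pattern
        try:
            key = tuple(sorted(index[e] for e in pat.edges))
        except KeyError as err:
            raise ValueError(f"pattern edge {err.args[0]!r} is not a frequent edge") from err
        for j in _candidate_indices(key, mode, len(M)):
            cand = list(pat.edges) + [M.edges[j]]
            if is_connected(cand):
                out.add(SubgraphPattern(cand))
    return out


def mine_unfepg(
    nets: Sequence[UncertainNetwork], config: MiningConfig | None = None
) -> list[FrequentSubgraph]:
    """Mine all frequent subgraph patterns of a cohort by frequent-edge
    pattern growth.

    Returns patterns sorted by (layer, canonical edge tuple); each pattern
    appears once with its expected support.
    """
    config = config or MiningConfig()
    _check_cohort(nets)
    M = frequent_edges(nets, config.minsup)
    k = len(M)
    if k == 0:
        return []
    P = edge_probability_matrix(nets, M.edges)
    # per-edge incident node sets for the incremental connectivity test
    edge_nodes = [frozenset(e) for e in M.edges]

    results: list[FrequentSubgraph] = []
    cap = config.max_pattern_edges or k
    for seed in range(k):
        # sub-search space `seed`, seeded with frequent edge m_seed
        results.append(
            FrequentSubgraph(SubgraphPattern([M.edges[seed]]), M.esup[seed], 1, seed)
        )
        # frontier entries: (key, node set, per-network containment products)
        frontier = [((seed,), edge_nodes[seed], P[:, seed].copy())]
        layer = 1
        while frontier and layer < min(k, cap):
            layer += 1
            nxt: dict[tuple, tuple[frozenset, np.ndarray]] = {}
            for key, nodes, prod in frontier:
                for j in _candidate_indices(key, config.growth_mode, k):
                    if nodes.isdisjoint(edge_nodes[j]):
                        continue  # candidate would be disconnected
                    new_key = tuple(sorted(key + (j,)))
                    if new_key in nxt:
                        continue
                    new_prod = prod * P[:, j]
                    if new_prod.mean() >= config.minsup:
                        nxt[new_key] = (nodes | edge_nodes[j], new_prod)
            frontier = [(key, nodes, prod) for key, (nodes, prod) in nxt.items()]
            for key, nodes, prod in frontier:
                results.append(
                    FrequentSubgraph(
                        SubgraphPattern([M.edges[j] for j in key]),
                        float(prod.mean()),
                        layer,
                        key[0],
                    )
                )
    results.sort(key=FrequentSubgraph.sort_key)
    return results


def mine_oracle(
    nets: Sequence[UncertainNetwork], config: MiningConfig | None = None
) -> list[FrequentSubgraph]:
    """Brute-force reference miner: enumerate every connected edge subset of
    the union graph and keep those whose expected support reaches minsup.

    Exact by construction; exponential, hence guarded by
    ``config.oracle_max_nodes``.  Expected support is computed directly from
    per-network containment probabilities, independently of the pattern-
    growth machinery.
    """
    config = config or MiningConfig()
    _check_cohort(nets)
    if len(nets[0].nodes) > config.oracle_max_nodes:
        raise ValueError(
            f"oracle miner is limited to {config.oracle_max_nodes} nodes "
            f"(got {len(nets[0].nodes)})"
        )
    union = sorted(
        {e for net in nets for e in net.edge_prob},
        key=lambda e: (_node_key(e[0]), _node_key(e[1])),
    )
    M = frequent_edges(nets, config.minsup)
    seed_of = {e: i for i, e in enumerate(M.edges)}
    P = edge_probability_matrix(nets, union)
    cap = min(len(union), config.max_pattern_edges or len(union))
    out: list[FrequentSubgraph] = []
    for size in range(1, cap + 1):
        combos = np.array(list(itertools.combinations(range(len(union)), size)))
        if combos.size == 0:
            continue
        # expected support of every size-`size` subset in one vectorized pass
        esup = P[:, combos].prod(axis=2).mean(axis=0)
        for combo, es in zip(combos[esup >= config.minsup], esup[esup >= config.minsup]):
            edges = [union[j] for j in combo]
            if not is_connected(edges):
                continue
            g = SubgraphPattern(edges)
            # every edge of a frequent pattern is itself frequent
            out.append(
                FrequentSubgraph(g, float(es), size, min(seed_of[e] for e in g.edges))
            )
    out.sort(key=FrequentSubgraph.sort_key)
    return out


def increasing_prefixes_connected(pattern: SubgraphPattern, M: FrequentEdgeList) -> bool:
    """True iff every index-sorted prefix of the pattern's edges is connected.

    Patterns failing this are exactly the ones the ``increasing`` growth mode
    cannot generate (its only loss mechanism).
    """
    index = {e: i for i, e in enumerate(M.edges)}
    ordered = sorted(pattern.edges, key=lambda e: index[e])
    for upto in range(2, len(ordered) + 1):
        if not is_connected(ordered[:upto]):
            return False
    return True
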