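"""Network construction: region time series -> uncertain network -> binary network.

Uncertain functional-connectivity networks are built from Pearson correlation
of region (independent-component) time series; positive correlations become
edge existence probabilities, negative and zero correlations become
non-edges.  Certain (binary) networks are derived by sparsity thresholding:
at sparsity ``s`` the ``round(s * n(n-1)/2)`` highest-probability edges are
kept, the probability of the lowest kept edge being the network's
``min_weight``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .graph import Edge, UncertainNetwork, canonical_edge, _node_key, _sorted_nodes

__all__ = [
    "TimeSeriesMatrix",
    "CorrelationMatrix",
    "CertainNetwork",
    "pearson_correlation_matrix",
    "to_uncertain_network",
    "threshold_by_sparsity",
    "certain_to_uncertain",
]


@dataclass
class TimeSeriesMatrix:
    """Region x time-point signal matrix with ordered region labels."""

    values: np.ndarray
    region_labels: Sequence

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.region_labels = list(self.region_labels)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D regions x timepoints matrix")
        if self.values.shape[0] != len(self.region_labels):
            raise ValueError("one region label per row is required")
        if self.values.shape[1] < 3:
            raise ValueError("at least 3 timepoints are required")
        if np.isnan(self.values).any():
            raise ValueError("time series contain missing values")


@dataclass
class CorrelationMatrix:
    """Symmetric region x region Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    region_labels: Sequence

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.region_labels = list(self.region_labels)
        n = len(self.region_labels)
        if self.values.shape != (n, n):
            raise ValueError("correlation matrix shape must match region labels")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 1.0, atol=1e-10):
            raise ValueError("correlation matrix must have a unit diagonal")


@dataclass
class CertainNetwork:
    """Binary graph from sparsity thresholding of an uncertain network."""

    nodes: tuple
    edges: frozenset
    sparsity: float
    min_weight: float = field(default=float("nan"))

    def __post_init__(self):
        self.nodes = _sorted_nodes(self.nodes)
        self.edges = frozenset(canonical_edge(u, v) for u, v in self.edges)

    def contains(self, edges: Iterable[Edge]) -> bool:
        return all(canonical_edge(u, v) in self.edges for u, v in edges)


def pearson_correlation_matrix(ts: TimeSeriesMatrix) -> CorrelationMatrix:
    """Pearson correlation ``r_ij = cov(i, j) / (sigma_i sigma_j)`` between
    all pairs of region time series."""
    sd = ts.values.std(axis=1)
    zero = np.flatnonzero(sd == 0)
    if zero.size:
        bad = ts.region_labels[zero[0]]
        raise ValueError(f"region {bad!r} has zero-variance time series")
    r = np.corrcoef(ts.values)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return CorrelationMatrix(r, ts.region_labels)


def to_uncertain_network(corr: CorrelationMatrix) -> UncertainNetwork:
    """Map a correlation matrix to an uncertain network: positive
    off-diagonal correlations become edge probabilities, the rest non-edges."""
    labels = corr.region_labels
    probs = {}
    n = len(labels)
    for i in range(n):
        for j in range(i + 1, n):
            r = corr.values[i, j]
            if r > 0.0:
                probs[canonical_edge(labels[i], labels[j])] = float(r)
    return UncertainNetwork(labels, probs)


def threshold_by_sparsity(net: UncertainNetwork, sparsity: float) -> CertainNetwork:
    """Binarize ``net`` keeping its top ``round(sparsity * n(n-1)/2)`` edges.

    Edges are ranked by probability descending, ties broken by canonical edge
    order so exactly the target count survives; when the network has fewer
    present edges than the target, all of them are kept (saturation).
    """
    if not 0.0 < sparsity < 1.0:
        raise ValueError(f"sparsity must be in (0, 1), got {sparsity}")
    n = len(net.nodes)
    possible = n * (n - 1) // 2
    r = int(round(sparsity * possible))
    ranked = sorted(
        net.edge_prob.items(),
        key=lambda item: (-item[1], (_node_key(item[0][0]), _node_key(item[0][1]))),
    )
    kept = ranked[: min(r, len(ranked))]
    min_weight = kept[-1][1] if kept else float("nan")
    return CertainNetwork(
        nodes=net.nodes,
        edges=frozenset(e for e, _ in kept),
        sparsity=sparsity,
        min_weight=min_weight,
    )


def certain_to_uncertain(cnet: CertainNetwork) -> UncertainNetwork:
    """View a binary network as the p=1 special case of an uncertain network
    (each present edge weight is regarded as the edge probability)."""
    return UncertainNetwork(cnet.nodes, {e: 1.0 for e in cnet.edges})
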