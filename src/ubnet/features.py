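"""Classification feature matrices and the threshold / weight conversions.

Uncertain-arm features are containment probabilities (the product of a
pattern's edge probabilities per subject); certain-arm features are binary
presence indicators.  Two mappings carry discriminative patterns between the
two representations:

* ``threshold_map``: patterns selected on uncertain networks, evaluated as
  presence features on each subject's sparsity-binarized network;
* ``weight_map``: patterns selected on binarized networks, evaluated as
  probability features on the uncertain networks (each binary edge weight
  re-read as the edge's existence probability).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .build import CertainNetwork, threshold_by_sparsity
from .graph import SubgraphPattern, UncertainNetwork, subgraph_probability
from .selection import DiscriminativeSubgraph

__all__ = [
    "FeatureMatrix",
    "probability_features",
    "presence_features",
    "threshold_map",
    "weight_map",
]


@dataclass
class FeatureMatrix:
    """Subjects x subgraph-features matrix with its column patterns."""

    values: np.ndarray
    feature_patterns: list[SubgraphPattern]
    kind: str  # 'probability' or 'binary'
    subject_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-D")
        if self.values.shape[1] != len(self.feature_patterns):
            raise ValueError("one column per feature pattern is required")
        if self.kind not in ("probability", "binary"):
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if self.kind == "binary" and not np.isin(self.values, (0.0, 1.0)).all():
            raise ValueError("binary features must be 0/1")
        if self.kind == "probability" and (
            (self.values < 0).any() or (self.values > 1).any()
        ):
            raise ValueError("probability features must lie in [0, 1]")
        if not self.subject_ids:
            self.subject_ids = [f"sub-{i:03d}" for i in range(self.values.shape[0])]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


def _patterns_of(items) -> list[SubgraphPattern]:
    out = []
    for it in items:
        out.append(it.pattern if isinstance(it, DiscriminativeSubgraph) else it)
    return out


def probability_features(
    patterns: Sequence, nets: Sequence[UncertainNetwork]
) -> FeatureMatrix:
    """Entry (i, j) = containment probability of pattern j in subject i."""
    pats = _patterns_of(patterns)
    X = np.empty((len(nets), len(pats)))
    for i, net in enumerate(nets):
        for j, g in enumerate(pats):
            X[i, j] = subgraph_probability(net, g)
    return FeatureMatrix(X, pats, "probability")


def presence_features(
    patterns: Sequence, nets: Sequence[CertainNetwork]
) -> FeatureMatrix:
    """Entry (i, j) = 1 iff subject i's binary network contains pattern j.

    Columns no subject contains are retained as all-zero columns: a mapped
    pattern need not exist in the binarized network.
    """
    pats = _patterns_of(patterns)
    X = np.empty((len(nets), len(pats)))
    for i, net in enumerate(nets):
        for j, g in enumerate(pats):
            X[i, j] = 1.0 if net.contains(g.edges) else 0.0
    return FeatureMatrix(X, pats, "binary")


def threshold_map(
    disc: Sequence[DiscriminativeSubgraph],
    uncertain_nets: Sequence[UncertainNetwork],
    sparsity: float,
) -> FeatureMatrix:
    """Map uncertain-arm discriminative patterns onto sparsity-binarized
    networks and return their presence features."""
    certain = [threshold_by_sparsity(net, sparsity) for net in uncertain_nets]
    return presence_features(disc, certain)


def weight_map(
    disc_certain: Sequence[DiscriminativeSubgraph],
    uncertain_nets: Sequence[UncertainNetwork],
) -> FeatureMatrix:
    """Map certain-arm discriminative patterns back onto the uncertain
    networks and return their containment-probability features."""
    return probability_features(disc_certain, uncertain_nets)
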