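"""Discriminative subgraph selection (dfsSI) and the certain-network scorer.

Each candidate pattern's mean containment probability is computed per group
(patients vs controls); the confidence score

    confidence_pos = mean_pos / (mean_pos + mean_neg)

and its complement rank candidates, and the top-k by each group's confidence
become the discriminative subgraph features (2k at most, fewer after
cross-list deduplication).  For binarized (certain) networks the analogue is
the frequency difference: the gap between the fractions of each group's
networks containing the pattern.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .build import CertainNetwork
from .graph import Cohort, SubgraphPattern, UncertainNetwork, subgraph_probability
from .mining import FrequentSubgraph, expected_support

__all__ = [
    "SelectionConfig",
    "DiscriminativeSubgraph",
    "group_mean_support",
    "confidence_scores",
    "select_discriminative",
    "frequency_difference_scores",
]

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    """top_k: discriminative patterns kept per group (default 15, the
    reference operating point); score: 'confidence' for uncertain networks,
    'frequency_difference' for the binarized arm."""

    top_k: int = 15
    score: str = "confidence"

    def __post_init__(self):
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")
        if self.score not in ("confidence", "frequency_difference"):
            raise ValueError(f"unknown score {self.score!r}")


@dataclass(frozen=True)
class DiscriminativeSubgraph:
    """A selected pattern with its per-group means and confidence scores."""

    pattern: SubgraphPattern
    mean_pos: float
    mean_neg: float
    confidence_pos: float
    confidence_neg: float
    source_group: str  # 'pos' or 'neg': the top-k list it was selected from
    rank: int  # 1-based position within that list


def group_mean_support(g: SubgraphPattern, nets: Sequence[UncertainNetwork]) -> float:
    """Mean containment probability of ``g`` within one group (identical
    machinery to expected support, exposed per group)."""
    return expected_support(g, nets)


def confidence_scores(mean_pos: float, mean_neg: float) -> tuple[float, float]:
    """Confidence pair ``(m+ / (m+ + m-), m- / (m+ + m-))``; sums to 1."""
    total = mean_pos + mean_neg
    if total <= 0.0:
        raise ValueError(
            "both group means are zero; a scored pattern must be frequent in "
            "at least one group"
        )
    return mean_pos / total, mean_neg / total


def frequency_difference_scores(
    g: SubgraphPattern,
    certain_pos: Sequence[CertainNetwork],
    certain_neg: Sequence[CertainNetwork],
) -> tuple[float, float]:
    """Frequency-difference pair for binary networks: ``f_pos - f_neg`` and
    its negation, where ``f`` is the fraction of networks containing ``g``."""
    if not certain_pos or not certain_neg:
        raise ValueError("both groups must be non-empty")
    f_pos = sum(net.contains(g.edges) for net in certain_pos) / len(certain_pos)
    f_neg = sum(net.contains(g.edges) for net in certain_neg) / len(certain_neg)
    return f_pos - f_neg, f_neg - f_pos


def _tie_key(entry):
    # score desc, |mean gap| desc, smaller pattern first, then canonical order
    score, mean_pos, mean_neg, pattern = entry
    return (
        -score,
        -abs(mean_pos - mean_neg),
        pattern.n_edges,
        pattern.sort_key(),
    )


def select_discriminative(
    freq_pos: Sequence[FrequentSubgraph],
    freq_neg: Sequence[FrequentSubgraph],
    cohort: Cohort,
    config: SelectionConfig | None = None,
) -> list[DiscriminativeSubgraph]:
    """Select the top-k discriminative patterns per group.

    The candidate pool is the union of both groups' frequent patterns; for
    every candidate both group means and both confidences are computed.  The
    top-k by positive-group confidence form the 'pos' list, the top-k by
    negative-group confidence the 'neg' list; a pattern landing in both
    lists is kept once, on the side where its confidence is larger.  The
    concatenated result (pos list then neg list) therefore has at most 2k
    entries.
    """
    config = config or SelectionConfig()
    pos_nets, neg_nets = cohort.positives, cohort.negatives
    if not pos_nets or not neg_nets:
        raise ValueError("selection requires both a positive and a negative group")

    pool = sorted(
        {fs.pattern for fs in freq_pos} | {fs.pattern for fs in freq_neg},
        key=SubgraphPattern.sort_key,
    )
    if not pool:
        return []

    scored = []
    for g in pool:
        m_pos = group_mean_support(g, pos_nets)
        m_neg = group_mean_support(g, neg_nets)
        if config.score == "confidence":
            c_pos, c_neg = confidence_scores(m_pos, m_neg)
        else:
            c_pos, c_neg = _frequency_difference_from_probability(g, pos_nets, neg_nets)
        scored.append((g, m_pos, m_neg, c_pos, c_neg))

    def top(side: str) -> list[tuple]:
        idx = 3 if side == "pos" else 4
        ranked = sorted(scored, key=lambda s: _tie_key((s[idx], s[1], s[2], s[0])))
        if len(ranked) < config.top_k:
            logger.warning(
                "only %d candidates available for the %s list (top_k=%d)",
                len(ranked), side, config.top_k,
            )
        return ranked[: config.top_k]

    pos_list, neg_list = top("pos"), top("neg")
    pos_patterns = {s[0] for s in pos_list}
    selected: list[DiscriminativeSubgraph] = []
    for rank, (g, m_pos, m_neg, c_pos, c_neg) in enumerate(pos_list, start=1):
        keep_pos = c_pos >= c_neg or not any(s[0] == g for s in neg_list)
        if keep_pos:
            selected.append(
                DiscriminativeSubgraph(g, m_pos, m_neg, c_pos, c_neg, "pos", rank)
            )
    for rank, (g, m_pos, m_neg, c_pos, c_neg) in enumerate(neg_list, start=1):
        if g in pos_patterns and c_pos >= c_neg:
            continue  # duplicate kept on the pos side
        selected.append(
            DiscriminativeSubgraph(g, m_pos, m_neg, c_pos, c_neg, "neg", rank)
        )
    return selected


def _frequency_difference_from_probability(g, pos_nets, neg_nets):
    # certain networks arrive here as p=1 uncertain views; containment
    # probability is then a 0/1 indicator and the mean a containment fraction
    f_pos = sum(subgraph_probability(n, g) == 1.0 for n in pos_nets) / len(pos_nets)
    f_neg = sum(subgraph_probability(n, g) == 1.0 for n in neg_nets) / len(neg_nets)
    return f_pos - f_neg, f_neg - f_pos
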