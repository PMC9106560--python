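"""Synthetic two-group cohorts of uncertain networks with planted effects.

The generator emulates the geometry of a resting-state functional-
connectivity case/control study: a shared node universe of ~22 regions
(independent components), 38 patient-analog vs 28 control-analog subjects,
per-edge baseline existence probabilities drawn once from a Beta
distribution over a random edge mask, small per-subject jitter, and one or
more *planted* connected subgraph patterns whose edge probabilities are
boosted (or depressed) in one group only.  The planted patterns are the
ground truth against which mining and discriminative selection are
validated.

A companion generator emits region time series whose population correlation
structure induces each subject's target network, so the Pearson-correlation
construction can be exercised end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import beta as beta_dist
from statsmodels.stats.correlation_tools import corr_clipped

from .build import TimeSeriesMatrix
from .graph import Cohort, SubgraphPattern, UncertainNetwork, canonical_edge, is_connected

__all__ = [
    "SyntheticConfig",
    "generate_uncertain_cohort",
    "generate_timeseries_cohort",
    "random_connected_pattern",
]

_CLIP_HIGH = 0.95  # planted boosts saturate here, keeping probabilities < 1


@dataclass
class SyntheticConfig:
    """Cohort geometry and effect configuration.

    Defaults mirror the emulated study: 22 network nodes, 38 positive vs 28
    negative subjects, Beta(2, 4) baseline probabilities over half of the
    possible edges, and 0.05 per-subject jitter — a realistic scale for the
    subject-to-subject variability of correlation estimates.  The Beta(2, 4)
    baseline (mean 1/3, rarely above 0.7) is calibrated so that mining at
    the study's operating point (minsup 0.25) yields frequent-subgraph sets
    of the study's reported order (roughly 150-300 patterns per group);
    stronger baselines make the frequent lattice of a 22-node graph
    combinatorially much larger than anything the emulated analysis
    encountered.

    Planted-pattern edges draw their baselines from the same Beta truncated
    below at ``planted_baseline_min`` (default 0.4): planted group effects
    emulate the modulation of established functional connections, so the
    ground-truth pattern lies inside the estimand of frequency-thresholded
    mining rather than below it.
    """

    n_nodes: int = 22
    n_pos: int = 38
    n_neg: int = 28
    baseline_alpha: float = 2.0
    baseline_beta: float = 4.0
    edge_density: float = 0.5
    planted_patterns: Sequence[tuple] = field(default_factory=list)
    planted_baseline_min: float = 0.4
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_nodes < 2 or self.n_pos < 1 or self.n_neg < 1:
            raise ValueError("cohort geometry must be positive")
        if not 0.0 < self.edge_density <= 1.0:
            raise ValueError("edge_density must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for pattern, delta, group in self.planted_patterns:
            if not isinstance(pattern, SubgraphPattern):
                raise TypeError("planted patterns must be SubgraphPattern instances")
            if group not in ("pos", "neg"):
                raise ValueError(f"target group must be 'pos' or 'neg', got {group!r}")
            if not -1.0 < delta < 1.0:
                raise ValueError("delta must keep probabilities in (0, 1)")


def random_connected_pattern(
    nodes: Sequence,
    n_edges: int,
    rng: np.random.Generator,
    prefix_connected: bool = True,
) -> SubgraphPattern:
    """Draw a random connected pattern by growing a random walk of edges.

    With ``prefix_connected`` (the default) every canonical-order prefix of
    the returned pattern's edges is itself connected.  The default miner's
    approximate growth rule cannot generate patterns violating this, so a
    planted ground truth outside that search space would be unrecoverable
    by construction; pass ``False`` to draw from all connected patterns.
    """
    nodes = list(nodes)
    if n_edges < 1 or n_edges > len(nodes) * (len(nodes) - 1) // 2:
        raise ValueError("infeasible edge count for the node universe")
    while True:
        start = nodes[rng.integers(len(nodes))]
        visited = {start}
        edges: set = set()
        while len(edges) < n_edges:
            u = list(visited)[rng.integers(len(visited))]
            v = nodes[rng.integers(len(nodes))]
            if u == v:
                continue
            e = canonical_edge(u, v)
            if e in edges:
                continue
            edges.add(e)
            visited.update(e)
        g = SubgraphPattern(edges)
        if not prefix_connected:
            return g
        ordered = list(g.edges)
        if all(is_connected(ordered[:k]) for k in range(2, len(ordered) + 1)):
            return g


def _baseline(config: SyntheticConfig, rng: np.random.Generator):
    nodes = tuple(range(config.n_nodes))
    possible = [
        canonical_edge(i, j)
        for i in range(config.n_nodes)
        for j in range(i + 1, config.n_nodes)
    ]
    n_mask = int(round(config.edge_density * len(possible)))
    idx = rng.choice(len(possible), size=n_mask, replace=False)
    mask = {possible[i] for i in idx}
    planted_edges = {e for pattern, _, _ in config.planted_patterns for e in pattern.edges}
    mask.update(planted_edges)  # planted edges always exist at baseline
    base = {e: float(rng.beta(config.baseline_alpha, config.baseline_beta)) for e in sorted(mask)}
    if planted_edges and config.planted_baseline_min > 0.0:
        # Planted group differences model the modulation of established
        # connections, the estimand of frequent-subgraph selection: their
        # baselines are drawn from the same Beta truncated to
        # [planted_baseline_min, 1).
        lo = float(
            beta_dist.cdf(
                config.planted_baseline_min, config.baseline_alpha, config.baseline_beta
            )
        )
        for e in sorted(planted_edges):
            u = lo + rng.random() * (1.0 - lo)
            base[e] = float(
                beta_dist.ppf(u, config.baseline_alpha, config.baseline_beta)
            )
    for pattern, delta, _ in config.planted_patterns:
        for e in pattern.edges:
            if base[e] + delta <= 0.0:
                raise ValueError(
                    f"delta {delta} pushes edge {e!r} (baseline {base[e]:.3f}) "
                    "to a non-positive probability"
                )
    return nodes, base


def generate_uncertain_cohort(config: SyntheticConfig) -> tuple[Cohort, dict]:
    """Generate a labelled cohort of uncertain networks plus ground truth.

    Per subject, each baseline edge probability receives truncated-Gaussian
    jitter and is clipped into (0, 1]; jittered values falling to zero or
    below become non-edges for that subject.  Planted deltas are then added
    on the pattern's edges for subjects of the target group only, saturating
    at 0.95.
    """
    rng = np.random.default_rng(config.seed)
    nodes, base = _baseline(config, rng)
    edges = list(base)
    base_arr = np.array([base[e] for e in edges])

    labels = np.r_[np.ones(config.n_pos, dtype=int), -np.ones(config.n_neg, dtype=int)]
    boosts = {"pos": {}, "neg": {}}
    for pattern, delta, group in config.planted_patterns:
        for e in pattern.edges:
            boosts[group][e] = boosts[group].get(e, 0.0) + delta

    networks = []
    for y in labels:
        p = base_arr + rng.normal(0.0, config.noise_sd, size=len(edges))
        p = np.clip(p, 0.0, 1.0)
        side = "pos" if y == 1 else "neg"
        probs = {}
        for e, val in zip(edges, p):
            if e in boosts[side]:
                val = min(val + boosts[side][e], _CLIP_HIGH)
            if val > 0.0:
                probs[e] = float(val)
        networks.append(UncertainNetwork(nodes, probs))

    cohort = Cohort(networks, labels)
    ground_truth = {
        "baseline": base,
        "planted": [
            {"edges": list(p.edges), "delta": d, "target_group": g}
            for p, d, g in config.planted_patterns
        ],
        "seed": config.seed,
    }
    return cohort, ground_truth


def generate_timeseries_cohort(
    config: SyntheticConfig, n_timepoints: int = 248
) -> tuple[list[TimeSeriesMatrix], dict]:
    """Generate per-subject region time series inducing the target networks.

    Each subject's target correlation matrix places the subject's edge
    probabilities on the corresponding off-diagonal entries (0 elsewhere),
    is repaired to the nearest positive-definite correlation matrix, and
    multivariate-Gaussian series of ``n_timepoints`` samples are drawn from
    it.  Pearson correlation followed by positive clipping then recovers the
    edge probabilities up to sampling error and the PD repair.

    The default of 248 timepoints matches the emulated acquisition length.
    """
    if n_timepoints < 3:
        raise ValueError("at least 3 timepoints are required")
    cohort, ground_truth = generate_uncertain_cohort(config)
    rng = np.random.default_rng((config.seed + 0x5EED) % (2**31))
    nodes = list(cohort.nodes)
    index = {v: i for i, v in enumerate(nodes)}
    series = []
    for net in cohort.networks:
        target = np.eye(len(nodes))
        for (u, v), p in net.edge_prob.items():
            target[index[u], index[v]] = target[index[v], index[u]] = p
        repaired = corr_clipped(target, threshold=1e-5)
        # symmetrize + jitter-free cholesky with a tiny ridge for safety
        repaired = (repaired + repaired.T) / 2.0 + 1e-8 * np.eye(len(nodes))
        L = np.linalg.cholesky(repaired)
        Z = rng.standard_normal((len(nodes), n_timepoints))
        series.append(TimeSeriesMatrix(L @ Z, nodes))
    ground_truth["labels"] = cohort.labels.tolist()
    return series, ground_truth
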