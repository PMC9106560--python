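"""Shared fixtures: tiny hand-checkable graphs and seeded random cohorts."""

from __future__ import annotations

import numpy as np
import pytest

import ubnet as ub


@pytest.fixture
def two_edge_net():
    """Two edges with p = 0.5 and 0.4 on a 3-node path."""
    return ub.UncertainNetwork([1, 2, 3], {(1, 2): 0.5, (2, 3): 0.4})


@pytest.fixture
def certain_triangle_cohort():
    """One all-p=1 triangle network (the certain-graph limit)."""
    net = ub.UncertainNetwork([1, 2, 3], {(1, 2): 1.0, (1, 3): 1.0, (2, 3): 1.0})
    return [net]


def random_network(rng, n_nodes=6, density=0.5, p_low=0.05, p_high=0.95):
    probs = {}
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            if rng.random() < density:
                probs[(i, j)] = rng.uniform(p_low, p_high)
    return ub.UncertainNetwork(range(n_nodes), probs)


def random_cohort(seed, n_nets=10, n_nodes=6, density=0.5):
    rng = np.random.default_rng(seed)
    return [random_network(rng, n_nodes, density) for _ in range(n_nets)]


@pytest.fixture(scope="session")
def planted_setup():
    """Default-geometry cohort with a 3-edge pattern boosted in the positive
    group (the ground truth for recovery and classification tests)."""
    rng = np.random.default_rng(424242)
    pattern = ub.random_connected_pattern(range(22), 3, rng)
    config = ub.SyntheticConfig(planted_patterns=[(pattern, 0.3, "pos")], seed=424242)
    cohort, truth = ub.generate_uncertain_cohort(config)
    return pattern, config, cohort, truth


@pytest.fixture(scope="session")
def null_cohort():
    """Default-geometry cohort with no planted effect."""
    cohort, _ = ub.generate_uncertain_cohort(ub.SyntheticConfig(seed=97))
    return cohort
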