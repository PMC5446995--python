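import numpy as np
import pandas as pd
import pytest

import cellage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_ranking(n, rng, tie_free=True):
    """Random ranking over n genes with distinct (or tied) scores."""
    genes = [f"g{i:04d}" for i in range(n)]
    if tie_free:
        scores = np.sort(rng.normal(size=n))[::-1]
    else:
        scores = np.sort(rng.choice(np.linspace(-2, 2, max(3, n // 3)), size=n))[::-1]
    return cellage.AgeRanking(tuple(genes), scores)


@pytest.fixture
def small_dataset():
    """Structured synthetic dataset shared by several integration tests."""
    cfg = cellage.SimulationConfig(
        n_types=16,
        cells_per_type=3,
        n_genes=300,
        markers_per_type=8,
        marker_effect=4.0,
        noise_sd=1.0,
        seed=7,
    )
    expr, labels, truth = cellage.simulate_single_cell(cfg)
    return cfg, expr, labels, truth


def brute_force_auroc(member_positions, n):
    """All-pairs oracle: count wins + half-ties over member/non-member pairs.

    ``member_positions`` are 1-based positions (1 = most up-regulated) in a
    tie-free ranking of length ``n``.
    """
    members = set(member_positions)
    others = [p for p in range(1, n + 1) if p not in members]
    wins = sum(1 for m in members for o in others if m < o)
    return wins / (len(members) * len(others))


def brute_force_auroc_scores(member_scores, other_scores):
    """All-pairs oracle on raw scores (handles ties with half credit)."""
    wins = 0.0
    for m in member_scores:
        for o in other_scores:
            if m > o:
                wins += 1.0
            elif m == o:
                wins += 0.5
    return wins / (len(member_scores) * len(other_scores))
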