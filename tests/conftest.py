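import numpy as np
import pytest

from weakpoints import PathwayDB, RankedList, SimulationConfig


@pytest.fixture
def toy_ranked() -> RankedList:
    """10 genes with scores 10..1 (rank i has score 10-i)."""
    scores = {f"g{i}": float(10 - i) for i in range(10)}
    return RankedList.from_scores("S1", "drugA", scores)


@pytest.fixture
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11,
        n_genes_universe=400,
        n_screens=3,
        hits_per_screen=150,
        planted_pathways_per_screen=2,
        n_pathways=10,
        pathway_size_range=(8, 20),
        profile_n_genes=60,
        n_mechanism_clusters=6,
        drugs_per_cluster=3,
    )


@pytest.fixture
def tiny_db() -> PathwayDB:
    universe = frozenset(f"g{i}" for i in range(20))
    sets = {
        "SET_A": frozenset({"g0", "g1", "g2", "g3", "g4"}),
        "SET_B": frozenset({"g5", "g6", "g7"}),
        "SET_C": frozenset({"g0", "g5", "g10", "g15"}),
    }
    return PathwayDB(sets=sets, universe=universe)


def brute_force_es(genes, scores, members, weight=1.0):
    """Step-by-step running-sum walk, written independently of the
    vectorized implementation: explicit loop, explicit tie rule."""
    members = set(members)
    n = len(genes)
    hits = [g in members for g in genes]
    n_hits = sum(hits)
    denom = sum(abs(s) ** weight for g, s, h in zip(genes, scores, hits) if h)
    walk = []
    value = 0.0
    for g, s, h in zip(genes, scores, hits):
        if h:
            value += (abs(s) ** weight) / denom if denom > 0 else 1.0 / n_hits
        else:
            value -= 1.0 / (n - n_hits)
        walk.append(value)
    best_pos = max(walk)
    best_neg = min(walk)
    return best_pos if best_pos >= -best_neg else best_neg
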