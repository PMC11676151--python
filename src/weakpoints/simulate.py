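"""Synthetic screens, gene-set databases, drug signatures and synergy sets.

Every generator returns its planted structure as ground truth, so recovery
tests never have to re-infer what was planted. All randomness flows through
``numpy.random.default_rng`` seeded from the config: an identical config
(including seed) reproduces bit-identical outputs.

What is emulated
----------------
* ``simulate_pathway_db``   — an MSigDB-like GMT collection, with one
  designated pathway pair sharing a controlled fraction of members (so
  alias-pathway merging is testable).
* ``simulate_screens``      — per-screen ranked sensitization hit lists:
  Gaussian baseline fold-change noise, plus an additive shift for genes of
  each screen's planted pathways.
* ``simulate_profiles``     — a connectivity-map style genes x drugs
  signature matrix with mechanism-cluster structure.
* ``simulate_synergy_sets`` — curated synergy records whose synergizers are
  drawn from a controlled number of mechanism clusters (the planted
  diversity effect).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .types import DomainError, PathwayDB, ProfileMatrix, RankedList, SynergyRecord

__all__ = [
    "SimulationConfig",
    "ScreenTruth",
    "simulate_pathway_db",
    "simulate_screens",
    "simulate_profiles",
    "simulate_synergy_sets",
]

#: designated pathway pair carrying the controlled member overlap
OVERLAP_PAIR = ("PW_ALIAS_A", "PW_ALIAS_B")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study.

    ``planted_effect`` is the mean upward shift of the |fold change| score
    for genes belonging to a screen's planted pathways, in the same abstract
    units as ``score_noise_sd`` (the screens' fold-change scale is abstract:
    only the ranking feeds the analysis).
    """

    seed: int = 0
    n_genes_universe: int = 2000
    n_screens: int = 8
    hits_per_screen: int = 500
    planted_pathways_per_screen: int = 3
    planted_effect: float = 3.0
    score_noise_sd: float = 1.0
    n_mechanism_clusters: int = 8
    drugs_per_cluster: int = 4
    cluster_center_sd: float = 1.0
    within_cluster_sd: float = 0.2
    profile_n_genes: int = 300
    n_pathways: int = 20
    pathway_size_range: tuple[int, int] = (10, 40)

    def __post_init__(self) -> None:
        counts = {
            "n_genes_universe": self.n_genes_universe,
            "n_screens": self.n_screens,
            "hits_per_screen": self.hits_per_screen,
            "planted_pathways_per_screen": self.planted_pathways_per_screen,
            "n_mechanism_clusters": self.n_mechanism_clusters,
            "drugs_per_cluster": self.drugs_per_cluster,
            "profile_n_genes": self.profile_n_genes,
            "n_pathways": self.n_pathways,
        }
        for name, value in counts.items():
            if value < 1:
                raise DomainError(f"{name} must be >= 1, got {value}")
        if self.hits_per_screen > self.n_genes_universe:
            raise DomainError("hits_per_screen exceeds the gene universe")
        if self.planted_effect < 0:
            raise DomainError("planted_effect must be non-negative")
        for name in ("score_noise_sd", "cluster_center_sd", "within_cluster_sd"):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be non-negative")
        lo, hi = self.pathway_size_range
        if not 1 <= lo <= hi <= self.n_genes_universe:
            raise DomainError("invalid pathway_size_range")
        if self.within_cluster_sd >= self.cluster_center_sd:
            warnings.warn(
                "within_cluster_sd >= cluster_center_sd: mechanism clusters "
                "will not be recoverable from the profiles",
                stacklevel=2,
            )

    def universe(self) -> tuple[str, ...]:
        width = len(str(self.n_genes_universe))
        return tuple(
            f"G{i:0{width}d}" for i in range(1, self.n_genes_universe + 1)
        )


@dataclass(frozen=True)
class ScreenTruth:
    """Planted structure of one simulated screen."""

    screen_id: str
    planted_pathways: tuple[str, ...]
    planted_genes: frozenset[str]


def simulate_pathway_db(
    config: SimulationConfig, overlap_fraction: float = 0.0
) -> PathwayDB:
    """Draw a pathway database from the synthetic gene universe.

    Set sizes are uniform on ``config.pathway_size_range`` (recorded in the
    output metadata). The designated pair ``PW_ALIAS_A`` / ``PW_ALIAS_B``
    is built so its Jaccard index is within 0.05 of ``overlap_fraction``;
    the remaining sets are independent uniform draws, so incidental overlap
    between them is hypergeometric background.
    """
    if not 0.0 <= overlap_fraction <= 1.0:
        raise DomainError(
            f"overlap_fraction must be in [0, 1], got {overlap_fraction}"
        )
    rng = np.random.default_rng(config.seed)
    universe = np.array(config.universe())
    lo, hi = config.pathway_size_range

    sets: dict[str, frozenset[str]] = {}
    # designated alias pair: shared core sized so that c/(2m - c) ~ J
    m = int(rng.integers(lo, hi + 1))
    c = int(round(2 * m * overlap_fraction / (1.0 + overlap_fraction)))
    if overlap_fraction == 1.0:
        c = m
    pool = rng.choice(universe, size=2 * m - c, replace=False)
    shared, only_a, only_b = pool[:c], pool[c : m], pool[m : 2 * m - c]
    sets[OVERLAP_PAIR[0]] = frozenset(shared) | frozenset(only_a)
    sets[OVERLAP_PAIR[1]] = frozenset(shared) | frozenset(only_b)

    n_rest = max(config.n_pathways - 2, 0)
    width = len(str(max(config.n_pathways, 1)))
    for i in range(1, n_rest + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        sets[f"PW_{i:0{width}d}"] = frozenset(members)

    return PathwayDB(
        sets=sets,
        universe=frozenset(universe),
        metadata={
            "pathway_size_range": (lo, hi),
            "overlap_fraction": overlap_fraction,
            "overlap_pair": OVERLAP_PAIR,
        },
    )


def simulate_screens(
    config: SimulationConfig,
    db: PathwayDB,
    planted_pathways: Sequence[str] | None = None,
) -> tuple[list[RankedList], list[ScreenTruth]]:
    """Simulate per-screen ranked sensitization hit lists.

    Each screen scores ``hits_per_screen`` genes: baseline Gaussian noise
    (mean 0, sd ``score_noise_sd``) plus ``planted_effect`` added to genes
    of that screen's planted pathways. Planted-pathway genes are always part
    of the hit list; the remainder is a uniform draw from the rest of the
    universe. Lists are returned sorted by descending score.

    ``planted_pathways`` forces the same pathways into every screen
    (emulating shared weak points); by default each screen draws
    ``planted_pathways_per_screen`` pathways without replacement from the
    database, independently across screens, so recurrence arises by chance
    and by planting alike.
    """
    if config.hits_per_screen > len(db.universe):
        raise DomainError("hits_per_screen exceeds the database universe")
    if planted_pathways is not None:
        missing = [p for p in planted_pathways if p not in db.sets]
        if missing:
            raise DomainError(f"planted pathways not in database: {missing}")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 1]).generate_state(1)[0]
    )
    names = list(db.sets)
    universe = sorted(db.universe)

    screens: list[RankedList] = []
    truths: list[ScreenTruth] = []
    for s in range(config.n_screens):
        screen_id = f"SCREEN_{s + 1}"
        if planted_pathways is None:
            k = min(config.planted_pathways_per_screen, len(names))
            chosen = tuple(str(p) for p in rng.choice(names, size=k, replace=False))
        else:
            chosen = tuple(planted_pathways)
        planted_genes = frozenset().union(*(db.sets[p] for p in chosen))

        non_planted = [g for g in universe if g not in planted_genes]
        n_fill = config.hits_per_screen - len(planted_genes)
        if n_fill < 0:
            raise DomainError(
                "planted pathways contain more genes than hits_per_screen"
            )
        fill = rng.choice(non_planted, size=n_fill, replace=False)
        hit_genes = sorted(planted_genes) + [str(g) for g in fill]

        scores = rng.normal(0.0, config.score_noise_sd, size=len(hit_genes))
        scores[: len(planted_genes)] += config.planted_effect
        screens.append(
            RankedList.from_scores(
                screen_id=screen_id,
                drug_name=f"DRUG_{s + 1}",
                scores=dict(zip(hit_genes, scores)),
            )
        )
        truths.append(
            ScreenTruth(
                screen_id=screen_id,
                planted_pathways=chosen,
                planted_genes=planted_genes,
            )
        )
    return screens, truths


def simulate_profiles(
    config: SimulationConfig,
) -> tuple[ProfileMatrix, dict[str, int]]:
    """Simulate a mechanism-clustered drug-signature matrix.

    Each mechanism cluster gets a center vector with iid N(0,
    cluster_center_sd) entries; each drug's profile is its cluster center
    plus iid N(0, within_cluster_sd) noise. Metadata is fixed to
    cell_line="SYNTH", timepoint_hours=24. Returns the matrix and the
    ground-truth drug -> cluster labels.
    """
    if config.profile_n_genes < 2:
        raise DomainError("profile_n_genes must be >= 2")
    rng = np.random.default_rng(
        np.random.SeedSequence([config.seed, 2]).generate_state(1)[0]
    )
    G = config.profile_n_genes
    centers = rng.normal(
        0.0, config.cluster_center_sd, size=(config.n_mechanism_clusters, G)
    )
    genes = [f"P{i:05d}" for i in range(1, G + 1)]
    columns: dict[str, np.ndarray] = {}
    labels: dict[str, int] = {}
    for c in range(config.n_mechanism_clusters):
        for d in range(config.drugs_per_cluster):
            name = f"DRUG_C{c + 1:02d}_{d + 1:02d}"
            noise = rng.normal(0.0, config.within_cluster_sd, size=G)
            columns[name] = centers[c] + noise
            labels[name] = c
    values = pd.DataFrame(columns, index=genes)
    return (
        ProfileMatrix(values, cell_line="SYNTH", timepoint_hours=24.0),
        labels,
    )


def simulate_synergy_sets(
    cluster_labels: Mapping[str, int],
    n_test: int = 4,
    n_control: int = 4,
    breadth_test: int = 6,
    breadth_control: int = 2,
    drugs_per_set: int = 6,
    seed: int = 0,
) -> list[SynergyRecord]:
    """Plant the diversity effect into curated synergy sets.

    Test therapeutics draw their ``drugs_per_set`` synergizers from
    ``breadth_test`` distinct mechanism clusters, controls from
    ``breadth_control`` (clusters are cycled so every chosen cluster
    contributes). Mechanism annotations are the cluster labels; target
    pathways are distinct from mechanisms, so the exclusion rules are
    planted as no-ops and the score difference reflects breadth alone.
    """
    if drugs_per_set < 2:
        raise DomainError("drugs_per_set must be >= 2")
    clusters: dict[int, list[str]] = {}
    for drug, c in cluster_labels.items():
        clusters.setdefault(int(c), []).append(drug)
    n_clusters = len(clusters)
    for name, breadth in (
        ("breadth_test", breadth_test),
        ("breadth_control", breadth_control),
    ):
        if not 1 <= breadth <= n_clusters:
            raise DomainError(
                f"{name}={breadth} must be in [1, {n_clusters}] "
                "(the number of mechanism clusters)"
            )
    breadths = ([breadth_test] if n_test else []) + (
        [breadth_control] if n_control else []
    )
    per_cluster_need = max(
        (-(-drugs_per_set // b) for b in breadths), default=0
    )
    if per_cluster_need > min(len(v) for v in clusters.values()):
        raise DomainError(
            "not enough drugs per cluster to fill a synergy set "
            f"(need up to {per_cluster_need} from one cluster)"
        )

    rng = np.random.default_rng(seed)
    cluster_ids = sorted(clusters)
    records: list[SynergyRecord] = []
    specs = [("test", i + 1, breadth_test) for i in range(n_test)] + [
        ("control", i + 1, breadth_control) for i in range(n_control)
    ]
    for cls, idx, breadth in specs:
        chosen = rng.choice(cluster_ids, size=breadth, replace=False)
        taken: dict[int, list[str]] = {int(c): [] for c in chosen}
        synergizers = []
        for j in range(drugs_per_set):
            c = int(chosen[j % breadth])
            avail = sorted(set(clusters[c]) - set(taken[c]))
            drug = str(rng.choice(avail))
            taken[c].append(drug)
            synergizers.append((drug, f"MECH_{c + 1:02d}"))
        target = (
            f"WEAKPOINT_{idx}" if cls == "test" else f"CONTROL_TARGET_{idx}"
        )
        records.append(
            SynergyRecord(
                therapeutic=f"{cls.upper()}_{idx}",
                cls=cls,
                target_pathway=target,
                synergizers=tuple(synergizers),
            )
        )
    return records
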