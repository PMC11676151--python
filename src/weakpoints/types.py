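"""Core domain types shared across the pipeline.

The containers here are deliberately thin: ranked screen hit lists, a gene-set
database, drug signature matrices, curated synergy sets, and the result
records produced by the enrichment / integration / diversity stages.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd


class DomainError(ValueError):
    """An input violates a documented precondition."""


@dataclass(frozen=True)
class RankedList:
    """One screen's sensitizing hits, ordered by fold-change score.

    Entries are sorted non-increasing by score; exact score ties are broken
    by ascending lexicographic gene order so ranking is platform-independent.
    """

    screen_id: str
    drug_name: str
    entries: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        genes = [g for g, _ in self.entries]
        if len(set(genes)) != len(genes):
            dupes = sorted({g for g in genes if genes.count(g) > 1})
            raise DomainError(f"duplicate genes in ranked list: {dupes[:5]}")
        for g, s in self.entries:
            if not math.isfinite(s):
                raise DomainError(f"non-finite score for gene {g!r}")
        for (g1, s1), (g2, s2) in zip(self.entries, self.entries[1:]):
            if s1 < s2 or (s1 == s2 and g1 > g2):
                raise DomainError(
                    "entries must be sorted by descending score, "
                    "ties by ascending gene"
                )

    @classmethod
    def from_scores(
        cls, screen_id: str, drug_name: str, scores: Mapping[str, float]
    ) -> "RankedList":
        """Build a ranked list from an unordered gene -> score mapping."""
        entries = tuple(
            sorted(
                ((str(g), float(s)) for g, s in scores.items()),
                key=lambda kv: (-kv[1], kv[0]),
            )
        )
        return cls(screen_id=screen_id, drug_name=drug_name, entries=entries)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(g for g, _ in self.entries)

    @property
    def scores(self) -> np.ndarray:
        return np.array([s for _, s in self.entries], dtype=float)

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class PathwayDB:
    """Named gene sets over a declared gene universe (GMT-backed)."""

    sets: dict[str, frozenset[str]]
    universe: frozenset[str]
    metadata: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise DomainError(f"gene set {name!r} is empty")
            extra = members - self.universe
            if extra:
                raise DomainError(
                    f"gene set {name!r} has members outside the universe: "
                    f"{sorted(extra)[:5]}"
                )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.sets)

    def __len__(self) -> int:
        return len(self.sets)


@dataclass(frozen=True)
class EnrichmentResult:
    """Weighted-KS enrichment of one pathway in one ranked list."""

    pathway: str
    es: float
    nes: float
    p_value: float
    fdr_q: float
    leading_edge: frozenset[str]
    n_overlap: int

    def __post_init__(self) -> None:
        if not -1.0 - 1e-12 <= self.es <= 1.0 + 1e-12:
            raise DomainError(f"ES out of [-1, 1]: {self.es}")
        if not 0.0 <= self.p_value <= 1.0:
            raise DomainError(f"p-value out of [0, 1]: {self.p_value}")
        if self.fdr_q < 0.0:
            raise DomainError(f"negative FDR q: {self.fdr_q}")
        if self.n_overlap < 1:
            raise DomainError("scored pathway must overlap the ranked list")


@dataclass(frozen=True)
class OraResult:
    """Hypergeometric over-representation of one pathway in a gene list."""

    pathway: str
    k_overlap: int
    p_value: float
    q_value: float


@dataclass(frozen=True)
class RecurrenceTable:
    """Per-pathway count (and identity) of screens where it was significant."""

    rows: dict[str, tuple[int, frozenset[str]]]

    def __post_init__(self) -> None:
        for name, (count, screens) in self.rows.items():
            if count != len(screens):
                raise DomainError(f"screen_count mismatch for {name!r}")

    def at_least(self, k: int) -> dict[str, tuple[int, frozenset[str]]]:
        """Rows recurring in at least ``k`` screens."""
        return {n: r for n, r in self.rows.items() if r[0] >= k}


@dataclass(frozen=True)
class MetaPathway:
    """Alias pathways merged on shared evidence genes.

    Mirrors the umbrella groupings one makes when several named gene sets
    fire off the same screen hits (e.g. an Akt-mTOR umbrella over mTOR,
    VEGF- and T-cell-signaling sets).
    """

    name: str
    members: frozenset[str]
    evidence_genes: frozenset[str]
    screens: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.members:
            raise DomainError("MetaPathway needs at least one member")


@dataclass(frozen=True)
class RecurrentGeneSet:
    """Genes hit in at least ``min_screens`` screens, optionally funneled to
    those covered by the pathway database."""

    genes: frozenset[str]
    min_screens: int
    pathway_filtered: bool = False
    counts: Mapping[str, int] = field(default_factory=dict, compare=False)

    def __len__(self) -> int:
        return len(self.genes)


class ProfileMatrix:
    """Genes x drugs signature matrix with cell-line/timepoint metadata.

    Values are continuous signature scores (connectivity-map style), one
    column per drug.
    """

    def __init__(
        self,
        values: pd.DataFrame,
        cell_line: str,
        timepoint_hours: float,
    ) -> None:
        if values.isna().any().any():
            bad = [
                (g, d)
                for g in values.index
                for d in values.columns
                if pd.isna(values.at[g, d])
            ]
            raise DomainError(f"missing values at cells: {bad[:5]}")
        if values.index.duplicated().any():
            raise DomainError("duplicate gene names in profile matrix")
        if values.columns.duplicated().any():
            raise DomainError("duplicate drug names in profile matrix")
        if timepoint_hours <= 0:
            raise DomainError("timepoint_hours must be positive")
        self.values = values.astype(float)
        self.cell_line = cell_line
        self.timepoint_hours = float(timepoint_hours)

    @property
    def genes(self) -> tuple[str, ...]:
        return tuple(self.values.index)

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(self.values.columns)

    def profile(self, drug: str) -> np.ndarray:
        return self.values[drug].to_numpy()

    def subset(self, drugs: Sequence[str]) -> np.ndarray:
        """Profiles for ``drugs`` as a (n_drugs, n_genes) array."""
        missing = [d for d in drugs if d not in self.values.columns]
        if missing:
            raise KeyError(f"drugs absent from profile matrix: {missing}")
        return self.values[list(drugs)].to_numpy().T


@dataclass(frozen=True)
class SynergyRecord:
    """A therapeutic with its literature-curated synergizing drugs."""

    therapeutic: str
    cls: str  # "test" (weak-point inhibitor) or "control"
    target_pathway: str
    synergizers: tuple[tuple[str, str], ...]  # (drug, mechanism)

    def __post_init__(self) -> None:
        if self.cls not in ("test", "control"):
            raise DomainError(f"class must be test/control, got {self.cls!r}")
        if not self.synergizers:
            raise DomainError(
                f"therapeutic {self.therapeutic!r} has no synergizers"
            )

    @property
    def drugs(self) -> tuple[str, ...]:
        return tuple(d for d, _ in self.synergizers)


@dataclass(frozen=True)
class DiversityResult:
    """Per-therapeutic diversity of its synergizing drugs' signatures."""

    therapeutic: str
    cls: str
    included_drugs: tuple[str, ...]
    excluded_drugs: tuple[tuple[str, str], ...]  # (drug, reason)
    coordinates: np.ndarray  # (n_included, n_dims) MDS embedding
    diversity_score: float
    variance_explained: float  # distance variance captured by the embedding

    def __post_init__(self) -> None:
        inc, exc = set(self.included_drugs), {d for d, _ in self.excluded_drugs}
        if inc & exc:
            raise DomainError("a drug cannot be both included and excluded")
        if self.diversity_score < 0:
            raise DomainError("diversity score must be non-negative")


@dataclass(frozen=True)
class GroupComparison:
    """Pooled-variance two-sided Student's t between score groups."""

    t_statistic: float
    degrees_freedom: int
    p_value: float
    mean_test: float
    mean_control: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise DomainError(f"p-value out of [0, 1]: {self.p_value}")
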