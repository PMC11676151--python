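"""Cross-screen integration of enrichment results.

Combines per-screen significant pathways into a recurrence table, merges
alias pathways that fire off the same hit genes, funnels hit genes recurring
across screens through the pathway database, and checks the library-size /
hit-count relationship.
"""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
from scipy import stats

from .types import (
    DomainError,
    EnrichmentResult,
    MetaPathway,
    PathwayDB,
    RankedList,
    RecurrenceTable,
    RecurrentGeneSet,
)

__all__ = [
    "count_pathway_recurrence",
    "merge_alias_pathways",
    "recurrent_genes",
    "filter_genes_to_pathways",
    "library_size_hit_correlation",
]


def count_pathway_recurrence(
    per_screen_significant: Mapping[str, Iterable[str]],
) -> RecurrenceTable:
    """Count, for each pathway, the screens where it passed significance."""
    rows: dict[str, set[str]] = {}
    for screen_id, pathways in per_screen_significant.items():
        for p in pathways:
            rows.setdefault(p, set()).add(screen_id)
    return RecurrenceTable(
        rows={p: (len(s), frozenset(s)) for p, s in sorted(rows.items())}
    )


def merge_alias_pathways(
    results_by_screen: Mapping[str, Sequence[EnrichmentResult]],
    jaccard_threshold: float = 0.5,
) -> list[MetaPathway]:
    """Merge pathways whose screen evidence is the same genes.

    Gene-set collections name overlapping slices of biology, so several
    pathways can be "significant" purely because they contain the same
    screen hits. Pathways become nodes; two are connected when the Jaccard
    index of their pooled leading-edge genes (union over screens) reaches
    ``jaccard_threshold``; connected components become MetaPathways, i.e.
    merging is transitive. Each component is named after the member with
    the largest evidence set (ties broken lexicographically) and carries
    the union of member screens.
    """
    if not 0.0 < jaccard_threshold <= 1.0:
        raise DomainError(
            f"jaccard_threshold must be in (0, 1], got {jaccard_threshold}"
        )
    evidence: dict[str, set[str]] = {}
    screens: dict[str, set[str]] = {}
    for screen_id, results in results_by_screen.items():
        for r in results:
            evidence.setdefault(r.pathway, set()).update(r.leading_edge)
            screens.setdefault(r.pathway, set()).add(screen_id)

    g = nx.Graph()
    g.add_nodes_from(evidence)
    names = sorted(evidence)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            union = evidence[a] | evidence[b]
            if not union:
                continue
            jac = len(evidence[a] & evidence[b]) / len(union)
            if jac >= jaccard_threshold:
                g.add_edge(a, b)

    metas = []
    for comp in nx.connected_components(g):
        members = frozenset(comp)
        name = max(members, key=lambda p: (len(evidence[p]), p))
        metas.append(
            MetaPathway(
                name=name,
                members=members,
                evidence_genes=frozenset().union(*(evidence[p] for p in members)),
                screens=frozenset().union(*(screens[p] for p in members)),
            )
        )
    return sorted(metas, key=lambda m: m.name)


def recurrent_genes(
    screens: Sequence[RankedList | Iterable[str]],
    min_screens: int = 2,
) -> RecurrentGeneSet:
    """Genes appearing as hits in at least ``min_screens`` screens.

    A screen's hits are all genes of its ranked list (the lists hold
    sensitizing hits only). Accepts ranked lists or plain gene collections.
    """
    if min_screens < 2:
        raise DomainError(f"min_screens must be >= 2, got {min_screens}")
    if min_screens > len(screens):
        raise DomainError(
            f"min_screens={min_screens} exceeds the number of screens "
            f"({len(screens)})"
        )
    counts: dict[str, int] = {}
    for screen in screens:
        genes = screen.genes if isinstance(screen, RankedList) else screen
        for g in set(genes):
            counts[g] = counts.get(g, 0) + 1
    kept = frozenset(g for g, c in counts.items() if c >= min_screens)
    return RecurrentGeneSet(
        genes=kept,
        min_screens=min_screens,
        pathway_filtered=False,
        counts={g: counts[g] for g in kept},
    )


def filter_genes_to_pathways(
    genes: RecurrentGeneSet, db: PathwayDB
) -> RecurrentGeneSet:
    """Funnel recurrent genes to those inside at least one database set."""
    covered = frozenset().union(*db.sets.values()) if db.sets else frozenset()
    kept = genes.genes & covered
    return RecurrentGeneSet(
        genes=kept,
        min_screens=genes.min_screens,
        pathway_filtered=True,
        counts={g: c for g, c in genes.counts.items() if g in kept},
    )


def library_size_hit_correlation(
    pairs: Sequence[tuple[int, int]],
) -> tuple[float, float]:
    """Pearson correlation between shRNA library size and hit count.

    Returns ``(r, p)`` with the two-sided p from the t-transform on n - 2
    degrees of freedom. Larger libraries interrogate more genes and are
    expected to yield more hits, roughly linearly.
    """
    if len(pairs) < 3:
        raise DomainError("need at least 3 (library_size, n_hits) pairs")
    x = np.array([a for a, _ in pairs], dtype=float)
    y = np.array([b for _, b in pairs], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DomainError("correlation undefined for a constant vector")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)
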