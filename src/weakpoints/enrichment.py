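"""Pre-ranked gene-set enrichment and over-representation analysis.

The enrichment statistic is the classic weighted Kolmogorov-Smirnov running
sum: walking down the ranked list, the sum rises by |score|^weight
(normalized over the set's members in the list) at member genes and falls by
1/(N - n_hits) elsewhere, so it starts and ends at zero; the enrichment
score (ES) is the extremum of largest magnitude. Significance comes from a
gene-label permutation null — the standard choice for pre-ranked input,
where no per-sample phenotype exists to permute — with a normalized ES (NES)
and a sign-stratified, pooled-null FDR in the style of the original GSEA
procedure. Over-representation of a plain gene list uses the hypergeometric
upper tail with Benjamini-Hochberg correction.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import DomainError, EnrichmentResult, OraResult, PathwayDB, RankedList

__all__ = [
    "enrichment_score",
    "permutation_null",
    "significant_pathways",
    "overrepresentation_test",
]

logger = logging.getLogger(__name__)


def _hit_weights(scores_w: np.ndarray, hit: np.ndarray) -> np.ndarray:
    """Per-position increments over member genes, normalized to sum to 1.

    If every member score is exactly zero (possible only with pathological
    input), members fall back to equal increments — the unweighted KS walk.
    """
    hw = np.where(hit, scores_w, 0.0)
    total = hw.sum()
    if total == 0.0:
        return np.where(hit, 1.0 / hit.sum(), 0.0)
    return hw / total


def enrichment_score(
    ranked: RankedList,
    gene_set: Iterable[str],
    weight: float = 1.0,
) -> tuple[float, np.ndarray, frozenset[str]]:
    """Weighted-KS enrichment of ``gene_set`` in a ranked list.

    Returns ``(es, running_sum, leading_edge)``. On an exact magnitude tie
    between the positive and negative extremum, the positive one wins. The
    leading edge holds the member genes at or before the positive peak (at
    or after the negative trough when the ES is negative).

    Raises ``DomainError`` if the set does not intersect the ranked genes
    or covers it entirely (the miss decrement is then undefined), or if
    ``weight`` is negative.
    """
    if weight < 0:
        raise DomainError(f"weight must be non-negative, got {weight}")
    members = frozenset(gene_set)
    genes = ranked.genes
    hit = np.fromiter((g in members for g in genes), dtype=bool, count=len(genes))
    n_hits = int(hit.sum())
    N = len(genes)
    if n_hits == 0:
        raise DomainError("gene set does not intersect the ranked list")
    if n_hits == N:
        raise DomainError("gene set covers the entire ranked list")

    scores_w = np.abs(ranked.scores) ** weight
    inc = _hit_weights(scores_w, hit)
    dec = np.where(hit, 0.0, 1.0 / (N - n_hits))
    running = np.cumsum(inc - dec)

    i_max = int(np.argmax(running))
    i_min = int(np.argmin(running))
    if running[i_max] >= -running[i_min]:
        es = float(running[i_max])
        leading = frozenset(g for i, g in enumerate(genes) if hit[i] and i <= i_max)
    else:
        es = float(running[i_min])
        leading = frozenset(g for i, g in enumerate(genes) if hit[i] and i >= i_min)
    return es, running, leading


def _null_es(
    scores_w: np.ndarray, set_size: int, perm: np.ndarray
) -> np.ndarray:
    """ES of random same-size gene draws, one per permutation row.

    ``perm`` holds permuted position indices; row ``i``'s first ``set_size``
    entries are that permutation's member positions. Exploits that the
    running sum is piecewise linear between member positions: maxima can
    only occur at a member, minima just before one (or at the terminal zero).
    """
    N = scores_w.shape[0]
    pos = np.sort(perm[:, :set_size], axis=1)  # (P, s) member positions
    w = scores_w[pos]
    cw = np.cumsum(w, axis=1)
    total = cw[:, -1:]
    eq = np.arange(1, set_size + 1) / set_size  # zero-score fallback
    frac = np.where(total > 0, cw / np.where(total == 0, 1.0, total), eq)
    miss = 1.0 / (N - set_size)
    j = np.arange(set_size)
    at_hit = frac - (pos - j) * miss           # value at each member
    before = at_hit - (frac - np.concatenate(
        [np.zeros((len(pos), 1)), frac[:, :-1]], axis=1
    ))                                          # value just before each member
    max_es = at_hit.max(axis=1)
    min_es = np.minimum(before.min(axis=1), 0.0)
    return np.where(max_es >= -min_es, max_es, min_es)


def permutation_null(
    ranked: RankedList,
    db: PathwayDB,
    n_perm: int = 1000,
    weight: float = 1.0,
    seed: int = 0,
) -> tuple[list[EnrichmentResult], dict[str, str]]:
    """Score every database pathway against one ranked list.

    For each pathway the null is ``n_perm`` random draws of the same number
    of genes from the ranked list (gene-label permutation). The p-value is
    two-sided on magnitude — the frequency of a null |ES| at least as large
    as the observed |ES|, with a +1 pseudo-count so no p is exactly zero
    (both enrichment directions are of interest, and magnitude
    exchangeability keeps the null p uniform). NES
    divides the ES by the mean magnitude of same-sign null ES values; the
    FDR q is the GSEA-style sign-stratified ratio of the pooled-null tail
    fraction to the observed tail fraction, made monotone in |NES|.

    Returns ``(results, skipped)`` where ``skipped`` maps pathway names that
    could not be scored (no overlap with the list, or covering it entirely)
    to a reason code; they take no part in the FDR.
    """
    if n_perm < 100:
        raise DomainError(f"n_perm must be >= 100, got {n_perm}")
    rng = np.random.default_rng(seed)
    N = len(ranked)
    scores_w = np.abs(ranked.scores) ** weight
    gene_index = {g: i for i, g in enumerate(ranked.genes)}

    # one permutation matrix shared by all sets: row i, first s entries =
    # member positions of permutation i for a set of size s
    perm = np.argsort(rng.random((n_perm, N)), axis=1)

    observed: list[tuple[str, float, frozenset[str], int]] = []
    skipped: dict[str, str] = {}
    null_by_set: dict[str, np.ndarray] = {}
    for name, members in db.sets.items():
        overlap = [g for g in members if g in gene_index]
        if not overlap:
            skipped[name] = "no_overlap"
            continue
        if len(overlap) == N:
            skipped[name] = "covers_entire_list"
            continue
        es, _, leading = enrichment_score(ranked, members, weight=weight)
        observed.append((name, es, leading, len(overlap)))
        null_by_set[name] = _null_es(scores_w, len(overlap), perm)

    if not observed:
        return [], skipped

    # per-set p and NES; normalized null ES pooled for the FDR
    nes_obs: dict[str, float] = {}
    p_obs: dict[str, float] = {}
    pooled_null: list[np.ndarray] = []
    for name, es, _, _ in observed:
        null = null_by_set[name]
        pos, neg = null[null >= 0], null[null < 0]
        r = int(np.sum(np.abs(null) >= abs(es)))
        p_obs[name] = (r + 1) / (n_perm + 1)
        mean_pos = pos.mean() if len(pos) else np.nan
        mean_neg = np.abs(neg).mean() if len(neg) else np.nan
        scale = mean_pos if es >= 0 else mean_neg
        nes_obs[name] = float(es / scale) if np.isfinite(scale) and scale > 0 else 0.0
        null_nes = np.concatenate(
            [
                pos / mean_pos if len(pos) and mean_pos > 0 else pos[:0],
                neg / mean_neg if len(neg) and mean_neg > 0 else neg[:0],
            ]
        )
        pooled_null.append(null_nes)

    q_obs = _gsea_fdr(
        np.array([nes_obs[name] for name, *_ in observed]),
        np.concatenate(pooled_null),
    )

    results = [
        EnrichmentResult(
            pathway=name,
            es=es,
            nes=nes_obs[name],
            p_value=p_obs[name],
            fdr_q=float(q),
            leading_edge=leading,
            n_overlap=n_overlap,
        )
        for (name, es, leading, n_overlap), q in zip(observed, q_obs)
    ]
    return results, skipped


def _gsea_fdr(nes: np.ndarray, pooled_null: np.ndarray) -> np.ndarray:
    """Sign-stratified pooled-null FDR over observed NES values.

    For a positive NES*: q = [frac of positive pooled-null NES >= NES*] /
    [frac of positive observed NES >= NES*], clipped to [0, 1]; mirrored for
    negative NES. A cumulative minimum from the most extreme NES inward
    enforces monotonicity in significance rank.
    """
    q = np.ones_like(nes, dtype=float)
    for sign in (1, -1):
        mask = nes >= 0 if sign > 0 else nes < 0
        if not mask.any():
            continue
        null_wing = pooled_null[pooled_null >= 0] if sign > 0 else pooled_null[pooled_null < 0]
        obs_wing = nes[mask]
        for i in np.flatnonzero(mask):
            v = abs(nes[i])
            num = (
                np.mean(np.abs(null_wing) >= v) if len(null_wing) else 1.0
            )
            den = np.mean(np.abs(obs_wing) >= v)
            q[i] = min(1.0, num / den) if den > 0 else 1.0
        # monotone: a more extreme NES never has a larger q — cumulative
        # minimum from the least extreme inward, as in Benjamini-Hochberg
        idx = np.flatnonzero(mask)
        order = idx[np.argsort(np.abs(nes[idx]))]  # ascending extremity
        q[order] = np.minimum.accumulate(q[order])
    return q


def significant_pathways(
    results: Sequence[EnrichmentResult],
    n_hits_in_screen: int,
    p_max: float = 0.05,
    q_max: float = 0.25,
    relaxed_q_max: float = 0.40,
    relax_below: int = 300,
) -> list[EnrichmentResult]:
    """Nominal-p and FDR filter with the small-screen relaxation.

    Keeps results with p < ``p_max`` and q <= ``q_max``. Screens with fewer
    than ``relax_below`` hits carry reduced statistical power, so their FDR
    cutoff is relaxed to ``relaxed_q_max``.
    """
    q_cut = relaxed_q_max if n_hits_in_screen < relax_below else q_max
    return [r for r in results if r.p_value < p_max and r.fdr_q <= q_cut]


def overrepresentation_test(
    genes: Iterable[str], db: PathwayDB
) -> list[OraResult]:
    """Hypergeometric upper-tail over-representation of a gene list.

    For each database set of size K in a universe of N genes, with a query
    list of n genes overlapping it in k, p = P(X >= k) for X ~
    Hypergeom(N, K, n); q-values are Benjamini-Hochberg across all sets.
    Query genes outside the universe are dropped with a logged warning.
    """
    query = set(genes)
    if not query:
        raise DomainError("empty gene list")
    outside = query - db.universe
    if outside:
        logger.warning(
            "dropping %d query genes outside the universe (e.g. %s)",
            len(outside),
            sorted(outside)[:3],
        )
        query -= outside
    if not query:
        raise DomainError("no query genes left inside the universe")

    N = len(db.universe)
    n = len(query)
    names, pvals, ks = [], [], []
    for name, members in db.sets.items():
        K = len(members)
        k = len(query & members)
        # upper tail P(X >= k) = sf(k - 1)
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        names.append(name)
        pvals.append(min(p, 1.0))
        ks.append(k)
    qvals = multipletests(pvals, method="fdr_bh")[1]
    return [
        OraResult(pathway=name, k_overlap=k, p_value=p, q_value=float(q))
        for name, k, p, q in zip(names, ks, pvals, qvals)
    ]
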