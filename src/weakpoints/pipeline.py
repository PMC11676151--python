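"""End-to-end orchestration of the weak-points analysis.

Stages: per-screen pre-ranked enrichment -> significance filtering ->
cross-screen recurrence, alias merging and recurrent-gene funneling (with an
over-representation test of the funneled genes) -> synergy-set diversity
scoring. Each stage writes tidy TSVs with provenance headers.
"""

from __future__ import annotations

import logging
import time
from pathlib import Path
from typing import Sequence

import numpy as np

from . import io
from .config import PipelineConfig
from .diversity import run_diversity_analysis
from .enrichment import overrepresentation_test, permutation_null, significant_pathways
from .integration import (
    count_pathway_recurrence,
    filter_genes_to_pathways,
    merge_alias_pathways,
    recurrent_genes,
)
from .types import EnrichmentResult, PathwayDB, RankedList

logger = logging.getLogger(__name__)


def derive_seeds(seed: int, n: int) -> list[int]:
    """Deterministic per-stage seeds below 2^31 from one global seed."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) & 0x7FFFFFFF]


def enrich_screens(
    screens: Sequence[RankedList],
    db: PathwayDB,
    config: PipelineConfig,
) -> dict[str, list[EnrichmentResult]]:
    """Permutation GSEA of every screen; returns all (unfiltered) results."""
    seeds = derive_seeds(config.seed, len(screens))
    results: dict[str, list[EnrichmentResult]] = {}
    for ranked, seed in zip(screens, seeds):
        t0 = time.perf_counter()
        res, skipped = permutation_null(
            ranked, db, n_perm=config.n_perm, weight=config.weight, seed=seed
        )
        logger.info(
            "enriched %s: %d genes, %d pathways scored, %d skipped "
            "(%.2fs)",
            ranked.screen_id,
            len(ranked),
            len(res),
            len(skipped),
            time.perf_counter() - t0,
        )
        results[ranked.screen_id] = res
    return results


def significant_by_screen(
    all_results: dict[str, list[EnrichmentResult]],
    screens: Sequence[RankedList],
    config: PipelineConfig,
) -> dict[str, list[EnrichmentResult]]:
    sizes = {s.screen_id: len(s) for s in screens}
    return {
        screen_id: significant_pathways(
            res,
            n_hits_in_screen=sizes[screen_id],
            p_max=config.p_max,
            q_max=config.q_max,
            relaxed_q_max=config.relaxed_q_max,
            relax_below=config.relax_below,
        )
        for screen_id, res in all_results.items()
    }


def run_all(config: PipelineConfig, outdir: str | Path) -> dict[str, object]:
    """Run every configured stage; returns the in-memory results.

    Writes, under ``outdir``: per-screen enrichment tables, the recurrence
    table, merged meta-pathways, recurrent and pathway-funneled gene lists
    with their over-representation test, and (when profiles and synergy
    sets are configured) the per-therapeutic diversity table, coordinates
    and the group comparison.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    meta = {"config_hash": io.config_hash(config.to_dict()), "seed": config.seed}

    if not config.screens or not config.gmt:
        raise io.ParseError("run_all needs 'screens' and 'gmt' configured")
    db = io.read_gmt(config.gmt)
    screens = [io.read_rnk(p) for p in config.screens]
    logger.info("loaded %d screens and %d gene sets", len(screens), len(db))

    all_results = enrich_screens(screens, db, config)
    for screen_id, res in all_results.items():
        io.write_table(
            io.enrichment_frame(res), outdir / f"enrichment_{screen_id}.tsv", meta
        )
    significant = significant_by_screen(all_results, screens, config)

    recurrence = count_pathway_recurrence(
        {sid: [r.pathway for r in res] for sid, res in significant.items()}
    )
    io.write_table(io.recurrence_frame(recurrence), outdir / "recurrence.tsv", meta)

    metas = merge_alias_pathways(significant, jaccard_threshold=config.jaccard_threshold)
    io.write_table(io.metapathway_frame(metas), outdir / "metapathways.tsv", meta)

    recurrent = recurrent_genes(screens, min_screens=config.min_screens)
    funneled = filter_genes_to_pathways(recurrent, db)
    io.write_table(
        io.gene_list_frame(recurrent), outdir / "recurrent_genes.tsv", meta
    )
    io.write_table(
        io.gene_list_frame(funneled), outdir / "recurrent_genes_in_pathways.tsv", meta
    )
    ora = (
        overrepresentation_test(funneled.genes, db) if funneled.genes else []
    )
    io.write_table(io.ora_frame(ora), outdir / "recurrent_gene_ora.tsv", meta)

    out: dict[str, object] = {
        "enrichment": all_results,
        "significant": significant,
        "recurrence": recurrence,
        "metapathways": metas,
        "recurrent_genes": recurrent,
        "funneled_genes": funneled,
        "ora": ora,
    }

    if config.profiles and config.synergy_sets:
        if not config.profiles_metadata:
            raise io.ParseError("profiles_metadata is required with profiles")
        profiles = io.read_profiles(config.profiles, config.profiles_metadata)
        records = io.read_synergy_sets(config.synergy_sets)
        weak = {r.target_pathway for r in records if r.cls == "test"}
        results, comparison, skipped = run_diversity_analysis(
            profiles,
            records,
            weak_point_pathways=weak,
            n_dims=config.n_dims,
            distance_space=config.distance_space,
            normalize=config.normalize_profiles,
        )
        io.write_table(io.diversity_frame(results), outdir / "diversity.tsv", meta)
        io.write_table(
            io.comparison_frame(comparison), outdir / "group_comparison.tsv", meta
        )
        import pandas as pd

        for r in results:
            coords = pd.DataFrame(
                r.coordinates,
                columns=[f"dim{i + 1}" for i in range(r.coordinates.shape[1])],
            )
            coords.insert(0, "drug", list(r.included_drugs))
            io.write_table(
                coords, outdir / f"coordinates_{r.therapeutic}.tsv", meta
            )
        out["diversity"] = results
        out["comparison"] = comparison
        out["diversity_skipped"] = skipped
        logger.info(
            "diversity: t=%.3f df=%d p=%.3g",
            comparison.t_statistic,
            comparison.degrees_freedom,
            comparison.p_value,
        )
    return out
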