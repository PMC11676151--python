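"""Readers and writers for the pipeline's plain-text formats.

GMT and RNK follow the de facto standards, so real MSigDB exports and GSEA
ranked lists can be dropped in unmodified. Profile matrices are TSV (first
column gene, header row drug names) with a key/value sidecar for cell line
and timepoint; synergy sets are tidy TSV, one row per (therapeutic,
synergizer). Output tables carry ``#``-prefixed provenance header lines
(config hash, seed) which all readers skip.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .types import (
    DiversityResult,
    DomainError,
    EnrichmentResult,
    GroupComparison,
    MetaPathway,
    OraResult,
    PathwayDB,
    ProfileMatrix,
    RankedList,
    RecurrenceTable,
    RecurrentGeneSet,
    SynergyRecord,
)


class ParseError(ValueError):
    """A file violates its format; the message carries the line number."""


# ---------------------------------------------------------------- provenance


def provenance_header(meta: Mapping[str, object] | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}={v}\n" for k, v in meta.items())


def config_hash(config: Mapping[str, object]) -> str:
    """Stable short hash of a configuration mapping, for output headers."""
    blob = json.dumps(
        {k: config[k] for k in sorted(config)}, sort_keys=True, default=str
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:12]


def write_table(
    df: pd.DataFrame, path: str | Path, meta: Mapping[str, object] | None = None
) -> None:
    """Write a TSV with optional ``#`` provenance header lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(provenance_header(meta))
        df.to_csv(fh, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


# ----------------------------------------------------------------- GMT / RNK


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> PathwayDB:
    """Read a GMT gene-set file (name, description, members per line).

    The universe defaults to the union of all members unless one is given.
    """
    sets: dict[str, frozenset[str]] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member ({len(fields)} field(s) found)"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set {name!r} is empty")
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            sets[name] = frozenset(members)
    full = frozenset(universe) if universe is not None else frozenset().union(*sets.values())
    return PathwayDB(sets=sets, universe=full)


def write_gmt(db: PathwayDB, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, members in db.sets.items():
            fh.write("\t".join([name, "na", *sorted(members)]) + "\n")


def read_rnk(
    path: str | Path, screen_id: str | None = None, drug_name: str = ""
) -> RankedList:
    """Read a two-column RNK file (gene <TAB> score).

    The list is re-sorted by descending score (ties by ascending gene)
    regardless of the file's order.
    """
    scores: dict[str, float] = {}
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, "
                    f"got {len(fields)}"
                )
            gene, raw = fields
            if gene in scores:
                raise ParseError(f"{path}:{lineno}: duplicate gene {gene!r}")
            try:
                scores[gene] = float(raw)
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric score {raw!r}"
                ) from exc
    if not scores:
        raise ParseError(f"{path}: empty ranked list")
    return RankedList.from_scores(
        screen_id=screen_id or Path(path).stem,
        drug_name=drug_name,
        scores=scores,
    )


def write_rnk(ranked: RankedList, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for gene, score in ranked.entries:
            fh.write(f"{gene}\t{score!r}\n")


# ------------------------------------------------------------------ profiles


def read_profiles(path: str | Path, metadata_path: str | Path) -> ProfileMatrix:
    """Read a genes x drugs TSV and its key/value metadata sidecar."""
    with Path(path).open() as fh:
        header = next(
            (l for l in fh if l.strip() and not l.startswith("#")), ""
        ).rstrip("\n")
    drug_names = header.split("\t")[1:]
    if len(set(drug_names)) != len(drug_names):
        dupes = sorted({d for d in drug_names if drug_names.count(d) > 1})
        raise ParseError(f"{path}: duplicated drug column(s) {dupes}")
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.index.name = None
    df.columns.name = None
    if df.isna().any().any():
        cells = [
            f"({g}, {d})"
            for g in df.index
            for d in df.columns
            if pd.isna(df.at[g, d])
        ]
        raise ParseError(f"{path}: missing values at {', '.join(cells[:5])}")
    if df.columns.duplicated().any():
        dupes = sorted(set(df.columns[df.columns.duplicated()]))
        raise ParseError(f"{path}: duplicated drug column(s) {dupes}")
    if df.index.duplicated().any():
        dupes = sorted(set(df.index[df.index.duplicated()]))
        raise ParseError(f"{path}: duplicated gene row(s) {dupes}")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric matrix entry ({exc})") from exc

    meta: dict[str, str] = {}
    with Path(metadata_path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if "\t" not in line:
                raise ParseError(
                    f"{metadata_path}:{lineno}: expected key<TAB>value"
                )
            key, value = line.split("\t", 1)
            meta[key] = value
    try:
        return ProfileMatrix(
            df,
            cell_line=meta["cell_line"],
            timepoint_hours=float(meta["timepoint_hours"]),
        )
    except KeyError as exc:
        raise ParseError(f"{metadata_path}: missing metadata key {exc}") from exc


def write_profiles(
    profiles: ProfileMatrix, path: str | Path, metadata_path: str | Path
) -> None:
    df = profiles.values.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t")
    with Path(metadata_path).open("w") as fh:
        fh.write(f"cell_line\t{profiles.cell_line}\n")
        fh.write(f"timepoint_hours\t{profiles.timepoint_hours!r}\n")


# -------------------------------------------------------------- synergy sets

_SYNERGY_COLUMNS = ["therapeutic", "class", "target_pathway", "drug", "drug_mechanism"]


def read_synergy_sets(path: str | Path) -> list[SynergyRecord]:
    """Read curated synergy sets (tidy TSV, one synergizer per row)."""
    df = read_table(path)
    missing = [c for c in _SYNERGY_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")
    records: list[SynergyRecord] = []
    for (ther, cls, target), group in df.groupby(
        ["therapeutic", "class", "target_pathway"], sort=False
    ):
        records.append(
            SynergyRecord(
                therapeutic=str(ther),
                cls=str(cls),
                target_pathway=str(target),
                synergizers=tuple(
                    (str(r.drug), str(r.drug_mechanism))
                    for r in group.itertuples()
                ),
            )
        )
    return records


def write_synergy_sets(
    records: Sequence[SynergyRecord],
    path: str | Path,
    meta: Mapping[str, object] | None = None,
) -> None:
    rows = [
        {
            "therapeutic": r.therapeutic,
            "class": r.cls,
            "target_pathway": r.target_pathway,
            "drug": drug,
            "drug_mechanism": mechanism,
        }
        for r in records
        for drug, mechanism in r.synergizers
    ]
    write_table(pd.DataFrame(rows, columns=_SYNERGY_COLUMNS), path, meta)


# ------------------------------------------------------------- result tables


def enrichment_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "es": r.es,
                "nes": r.nes,
                "p_value": r.p_value,
                "fdr_q": r.fdr_q,
                "n_overlap": r.n_overlap,
                "leading_edge": ",".join(sorted(r.leading_edge)),
            }
            for r in results
        ],
        columns=["pathway", "es", "nes", "p_value", "fdr_q", "n_overlap", "leading_edge"],
    )


def ora_frame(results: Sequence[OraResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "pathway": r.pathway,
                "k_overlap": r.k_overlap,
                "p_value": r.p_value,
                "q_value": r.q_value,
            }
            for r in results
        ],
        columns=["pathway", "k_overlap", "p_value", "q_value"],
    )


def recurrence_frame(table: RecurrenceTable) -> pd.DataFrame:
    rows = [
        {"pathway": name, "screen_count": count, "screens": ",".join(sorted(screens))}
        for name, (count, screens) in sorted(
            table.rows.items(), key=lambda kv: (-kv[1][0], kv[0])
        )
    ]
    return pd.DataFrame(rows, columns=["pathway", "screen_count", "screens"])


def metapathway_frame(metas: Sequence[MetaPathway]) -> pd.DataFrame:
    rows = [
        {
            "metapathway": m.name,
            "n_members": len(m.members),
            "members": ",".join(sorted(m.members)),
            "screen_count": len(m.screens),
            "screens": ",".join(sorted(m.screens)),
            "n_evidence_genes": len(m.evidence_genes),
        }
        for m in metas
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "metapathway",
            "n_members",
            "members",
            "screen_count",
            "screens",
            "n_evidence_genes",
        ],
    )


def gene_list_frame(genes: RecurrentGeneSet) -> pd.DataFrame:
    rows = [
        {"gene": g, "screen_count": genes.counts.get(g, "")}
        for g in sorted(genes.genes)
    ]
    return pd.DataFrame(rows, columns=["gene", "screen_count"])


def diversity_frame(results: Sequence[DiversityResult]) -> pd.DataFrame:
    rows = [
        {
            "therapeutic": r.therapeutic,
            "class": r.cls,
            "n_included": len(r.included_drugs),
            "n_excluded": len(r.excluded_drugs),
            "diversity_score": r.diversity_score,
            "variance_explained_2d": r.variance_explained,
        }
        for r in results
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "therapeutic",
            "class",
            "n_included",
            "n_excluded",
            "diversity_score",
            "variance_explained_2d",
        ],
    )


def comparison_frame(comparison: GroupComparison) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "t_statistic": comparison.t_statistic,
                "degrees_freedom": comparison.degrees_freedom,
                "p_value": comparison.p_value,
                "mean_test": comparison.mean_test,
                "mean_control": comparison.mean_control,
            }
        ]
    )
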