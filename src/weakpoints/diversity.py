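"""Synergy-set diversity from drug transcriptomic signatures.

For each therapeutic, the synergizing drugs' signature profiles are compared
by Euclidean distance; a classical (Torgerson) multidimensional scaling
embedding provides plot-ready coordinates, and the therapeutic's diversity
score is the mean pairwise distance among its drugs. Test therapeutics
(weak-point pathway inhibitors) and controls are then compared with a
pooled-variance Student's t-test.

Exclusion rules guard the comparison against built-in bias: a control's
synergizers hitting the control's own target pathway would deflate its
diversity, and a test therapeutic's synergizers hitting *other* weak-point
pathways would inflate it; both are dropped, with reason codes.

By default the diversity score uses distances in the full signature space.
The 2-D MDS embedding is always computed (it is the plot), and can be made
the scoring space via ``distance_space="mds"``; note that when drugs spread
over four or more roughly equidistant mechanisms, a plane retains only a
fraction of their separation and can flatten real diversity differences —
the per-result ``variance_explained`` makes that loss auditable.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .types import (
    DiversityResult,
    DomainError,
    GroupComparison,
    ProfileMatrix,
    SynergyRecord,
)

__all__ = [
    "apply_exclusions",
    "distance_matrix",
    "classical_mds",
    "diversity_score",
    "polygon_area",
    "compare_groups",
    "run_diversity_analysis",
]

logger = logging.getLogger(__name__)


class AnalysisError(ValueError):
    """A record or group cannot be analyzed (too few usable points)."""


def apply_exclusions(
    record: SynergyRecord, weak_point_pathways: Iterable[str]
) -> tuple[list[str], list[tuple[str, str]]]:
    """Split a record's synergizers into included and excluded-with-reason.

    control: drop synergizers whose mechanism equals the record's own
    target pathway (reason ``same_pathway_as_control``).
    test: drop synergizers whose mechanism is another weak-point pathway
    (reason ``other_weak_point``).
    """
    weak = frozenset(weak_point_pathways)
    included: list[str] = []
    excluded: list[tuple[str, str]] = []
    for drug, mechanism in record.synergizers:
        if record.cls == "control" and mechanism == record.target_pathway:
            excluded.append((drug, "same_pathway_as_control"))
        elif (
            record.cls == "test"
            and mechanism in weak
            and mechanism != record.target_pathway
        ):
            excluded.append((drug, "other_weak_point"))
        else:
            included.append(drug)
    return included, excluded


def distance_matrix(
    profiles: ProfileMatrix, drugs: Sequence[str]
) -> np.ndarray:
    """Pairwise Euclidean distances between drug signature columns.

    d(a, b) = sqrt(sum_i (a_i - b_i)^2) over the profile genes; the result
    is symmetric with a zero diagonal, ordered as ``drugs``.
    """
    X = profiles.subset(drugs)
    return squareform(pdist(X, metric="euclidean"))


def classical_mds(
    distances: np.ndarray, n_dims: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Torgerson's classical scaling of a distance matrix.

    Double-centers -D^2/2 with J = I - 11'/n, eigendecomposes, and returns
    coordinates built from the top ``n_dims`` eigenvectors scaled by the
    square roots of their (non-negative) eigenvalues, along with the full
    eigenvalue spectrum (descending) so embedding quality is auditable.
    Axis orientation is fixed by making each axis's largest-magnitude
    coordinate positive.
    """
    D = np.asarray(distances, dtype=float)
    if n_dims < 1:
        raise DomainError(f"n_dims must be >= 1, got {n_dims}")
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise DomainError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise DomainError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise DomainError("distance matrix must have a zero diagonal")
    if (D < -1e-12).any():
        raise DomainError("distances must be non-negative")

    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    eigval, eigvec = np.linalg.eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]

    k = min(n_dims, n)
    top = eigval[:k]
    if np.all(top <= 0):
        raise DomainError("no positive eigenvalue: degenerate configuration")
    coords = eigvec[:, :k] * np.sqrt(np.clip(top, 0.0, None))
    if k < n_dims:
        coords = np.hstack([coords, np.zeros((n, n_dims - k))])
    for axis in range(coords.shape[1]):
        col = coords[:, axis]
        if len(col) and col[np.argmax(np.abs(col))] < 0:
            coords[:, axis] = -col
    return coords, eigval


def diversity_score(coordinates: np.ndarray) -> float:
    """Mean pairwise Euclidean distance among embedded points."""
    X = np.atleast_2d(np.asarray(coordinates, dtype=float))
    if X.shape[0] < 2:
        raise AnalysisError("diversity needs at least 2 points")
    return float(pdist(X).mean())


def polygon_area(coordinates: np.ndarray) -> float:
    """Convex-hull area of a 2-D embedding (secondary diversity metric)."""
    X = np.asarray(coordinates, dtype=float)
    if X.ndim != 2 or X.shape[1] != 2:
        raise DomainError("polygon area is defined for 2-D coordinates")
    if X.shape[0] < 3:
        return 0.0
    from scipy.spatial import ConvexHull, QhullError

    try:
        return float(ConvexHull(X).volume)  # 2-D "volume" is the area
    except QhullError:  # collinear points span no area
        return 0.0


def compare_groups(
    test_scores: Sequence[float], control_scores: Sequence[float]
) -> GroupComparison:
    """Two-sample pooled-variance two-sided Student's t-test."""
    a = np.asarray(test_scores, dtype=float)
    b = np.asarray(control_scores, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise AnalysisError("each group needs at least 2 scores")
    df = len(a) + len(b) - 2
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        if a.mean() == b.mean():
            return GroupComparison(0.0, df, 1.0, float(a.mean()), float(b.mean()))
        raise AnalysisError(
            "zero pooled variance with unequal means: t undefined"
        )
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return GroupComparison(
        t_statistic=float(t),
        degrees_freedom=df,
        p_value=float(p),
        mean_test=float(a.mean()),
        mean_control=float(b.mean()),
    )


def _zscore_rows(profiles: ProfileMatrix) -> ProfileMatrix:
    vals = profiles.values
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=0).replace(0.0, 1.0)
    return ProfileMatrix(
        vals.sub(mu, axis=0).div(sd, axis=0),
        cell_line=profiles.cell_line,
        timepoint_hours=profiles.timepoint_hours,
    )


def run_diversity_analysis(
    profiles: ProfileMatrix,
    records: Sequence[SynergyRecord],
    weak_point_pathways: Iterable[str],
    n_dims: int = 2,
    distance_space: str = "full",
    normalize: bool = False,
) -> tuple[list[DiversityResult], GroupComparison, dict[str, str]]:
    """Score every synergy record and compare test vs control diversity.

    Per record: apply the exclusion rules, compute the Euclidean distance
    matrix of the included drugs' signatures, embed it with classical MDS
    (per therapeutic, so each plot stands alone), and score diversity as
    the mean pairwise distance — in the full signature space by default, or
    in the ``n_dims``-D embedding with ``distance_space="mds"``. Records
    left with fewer than 2 drugs are skipped and reported. Returns the
    per-record results, the group comparison, and the skipped map.
    """
    if distance_space not in ("full", "mds"):
        raise DomainError(f"unknown distance_space: {distance_space!r}")
    if normalize:
        profiles = _zscore_rows(profiles)
    weak = frozenset(weak_point_pathways)

    results: list[DiversityResult] = []
    skipped: dict[str, str] = {}
    for record in records:
        included, excluded = apply_exclusions(record, weak)
        if len(included) < 2:
            skipped[record.therapeutic] = "fewer_than_2_drugs_after_exclusion"
            logger.warning(
                "skipping %s: %d drug(s) left after exclusions",
                record.therapeutic,
                len(included),
            )
            continue
        D = distance_matrix(profiles, included)
        coords, eigval = classical_mds(D, n_dims=n_dims)
        pos = np.clip(eigval, 0.0, None)
        var_frac = float(pos[:n_dims].sum() / pos.sum()) if pos.sum() > 0 else 0.0
        score = (
            diversity_score(coords)
            if distance_space == "mds"
            else float(D[np.triu_indices_from(D, k=1)].mean())
        )
        results.append(
            DiversityResult(
                therapeutic=record.therapeutic,
                cls=record.cls,
                included_drugs=tuple(included),
                excluded_drugs=tuple(excluded),
                coordinates=coords,
                diversity_score=score,
                variance_explained=var_frac,
            )
        )

    test = [r.diversity_score for r in results if r.cls == "test"]
    control = [r.diversity_score for r in results if r.cls == "control"]
    if len(test) < 2 or len(control) < 2:
        raise AnalysisError(
            f"need >= 2 usable records per class, got {len(test)} test / "
            f"{len(control)} control"
        )
    comparison = compare_groups(test, control)
    return results, comparison, skipped
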