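"""Distance geometry, classical MDS, diversity scoring, group comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.spatial.distance import pdist, squareform

import weakpoints as wp
from weakpoints import DomainError, ProfileMatrix, SynergyRecord
from weakpoints.diversity import AnalysisError, polygon_area


def matrix(cols, genes=None):
    genes = genes or [f"p{i}" for i in range(len(next(iter(cols.values()))))]
    return ProfileMatrix(
        pd.DataFrame(cols, index=genes), cell_line="SYNTH", timepoint_hours=24
    )


class TestExclusions:
    def test_control_drops_own_pathway_synergizer(self):
        record = SynergyRecord(
            therapeutic="irinotecan",
            cls="control",
            target_pathway="topoisomerase_I",
            synergizers=(("drugA", "topoisomerase_I"), ("drugB", "EGFR")),
        )
        included, excluded = wp.apply_exclusions(record, {"proteasome"})
        assert included == ["drugB"]
        assert excluded == [("drugA", "same_pathway_as_control")]

    def test_test_drops_other_weak_point_inhibitor(self):
        record = SynergyRecord(
            therapeutic="bortezomib",
            cls="test",
            target_pathway="proteasome",
            synergizers=(
                ("drugA", "spliceosome"),
                ("drugB", "proteasome"),
                ("drugC", "EGFR"),
            ),
        )
        weak = {"proteasome", "spliceosome", "cell_cycle"}
        included, excluded = wp.apply_exclusions(record, weak)
        # an inhibitor of the therapeutic's own pathway stays; another
        # weak point's inhibitor would inflate diversity and is dropped
        assert included == ["drugB", "drugC"]
        assert excluded == [("drugA", "other_weak_point")]

    def test_no_matching_rule_keeps_everything(self):
        record = SynergyRecord(
            therapeutic="t", cls="test", target_pathway="proteasome",
            synergizers=(("a", "EGFR"), ("b", "microtubule")),
        )
        included, excluded = wp.apply_exclusions(record, {"proteasome"})
        assert included == ["a", "b"]
        assert excluded == []


class TestDistanceMatrix:
    def test_identical_profiles_distance_zero(self):
        m = matrix({"d1": [1.0, 2.0], "d2": [1.0, 2.0]})
        D = wp.distance_matrix(m, ["d1", "d2"])
        assert D[0, 1] == 0.0

    def test_three_four_five_triangle(self):
        m = matrix({"d1": [0.0, 0.0], "d2": [3.0, 4.0]})
        D = wp.distance_matrix(m, ["d1", "d2"])
        assert D[0, 1] == pytest.approx(5.0, abs=1e-12)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(7)
        vals = rng.normal(size=(10, 6))
        m = matrix({f"d{j}": vals[:, j] for j in range(6)})
        drugs = [f"d{j}" for j in range(6)]
        D = wp.distance_matrix(m, drugs)
        for i in range(6):
            for j in range(6):
                d = np.sqrt(sum((vals[g, i] - vals[g, j]) ** 2 for g in range(10)))
                assert D[i, j] == pytest.approx(d, abs=1e-12)
        assert np.allclose(D, D.T)
        assert np.all(np.diag(D) == 0)

    def test_unknown_drug_listed_in_error(self):
        m = matrix({"d1": [0.0, 1.0]})
        with pytest.raises(KeyError, match="nope"):
            wp.distance_matrix(m, ["d1", "nope"])

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_triangle_inequality(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.normal(size=(5, 4))
        m = matrix({f"d{j}": vals[:, j] for j in range(4)})
        D = wp.distance_matrix(m, [f"d{j}" for j in range(4)])
        for i in range(4):
            for j in range(4):
                for k in range(4):
                    assert D[i, j] <= D[i, k] + D[k, j] + 1e-9


class TestClassicalMDS:
    def test_equilateral_triangle_exact_in_2d(self):
        D = np.ones((3, 3)) - np.eye(3)
        coords, eigval = wp.classical_mds(D, n_dims=2)
        rec = squareform(pdist(coords))
        np.testing.assert_allclose(rec, D, atol=1e-9)

    def test_collinear_points_have_one_positive_eigenvalue(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        D = np.abs(x[:, None] - x[None, :])
        coords, eigval = wp.classical_mds(D, n_dims=1)
        assert np.sum(eigval > 1e-9) == 1
        rec = squareform(pdist(coords))
        np.testing.assert_allclose(rec, D, atol=1e-9)

    def test_planted_2d_configuration_recovered(self):
        """Distances from a genuine 2-D configuration are reconstructed,
        and the embedding matches the original points up to isometry
        (Procrustes residual ~ 0)."""
        rng = np.random.default_rng(0)
        X = rng.normal(size=(7, 2))
        D = squareform(pdist(X))
        coords, _ = wp.classical_mds(D, n_dims=2)
        np.testing.assert_allclose(squareform(pdist(coords)), D, atol=1e-9)
        from scipy.spatial import procrustes

        _, _, disparity = procrustes(X, coords)
        assert disparity < 1e-12

    def test_axis_orientation_deterministic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(5, 2))
        D = squareform(pdist(X))
        coords, _ = wp.classical_mds(D, n_dims=2)
        for axis in range(2):
            col = coords[:, axis]
            assert col[np.argmax(np.abs(col))] > 0

    def test_agrees_with_scikit_bio_pcoa(self):
        """Independent cross-check against scikit-bio's principal
        coordinate analysis on the same distance matrix."""
        skbio = pytest.importorskip("skbio")
        rng = np.random.default_rng(3)
        X = rng.normal(size=(6, 4))
        D = squareform(pdist(X))
        coords, eigval = wp.classical_mds(D, n_dims=2)
        ref = skbio.stats.ordination.pcoa(skbio.DistanceMatrix(D))
        np.testing.assert_allclose(
            np.abs(coords),
            np.abs(ref.samples.values[:, :2]),
            atol=1e-8,
        )
        np.testing.assert_allclose(eigval[:2], ref.eigvals.values[:2], atol=1e-8)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(DomainError):
            wp.classical_mds(np.array([[0.0, 1.0], [2.0, 0.0]]))  # asymmetric
        with pytest.raises(DomainError):
            wp.classical_mds(np.array([[1.0, 1.0], [1.0, 1.0]]))  # diagonal
        with pytest.raises(DomainError):
            wp.classical_mds(np.zeros((3, 3)))  # no positive eigenvalue


class TestDiversityScore:
    def test_coincident_points_score_zero(self):
        assert wp.diversity_score(np.zeros((2, 2))) == 0.0

    def test_unit_square(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        expected = (4 * 1 + 2 * np.sqrt(2)) / 6
        assert wp.diversity_score(square) == pytest.approx(expected, abs=1e-12)

    def test_isometry_invariance_and_dilation_linearity(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(6, 2))
        base = wp.diversity_score(X)
        theta = 1.1
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        assert wp.diversity_score(X @ R + [3.0, -2.0]) == pytest.approx(
            base, abs=1e-12
        )
        assert wp.diversity_score(2.5 * X) == pytest.approx(2.5 * base, rel=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(AnalysisError):
            wp.diversity_score(np.zeros((1, 2)))

    def test_polygon_area_secondary_metric(self):
        square = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        assert polygon_area(square) == pytest.approx(1.0, abs=1e-12)
        line = np.array([[0, 0], [1, 1], [2, 2]], float)
        assert polygon_area(line) == 0.0


class TestCompareGroups:
    def test_symmetric_groups_give_t_zero(self):
        cmp = wp.compare_groups([0.0, 1.0], [0.0, 1.0])
        assert cmp.t_statistic == 0.0
        assert cmp.p_value == 1.0

    def test_textbook_example(self):
        """Groups (1,2,3,4) vs (5,6,7,8): pooled var 5/3, t = -4/sqrt(5/6)."""
        cmp = wp.compare_groups([1, 2, 3, 4], [5, 6, 7, 8])
        t_hand = -4.0 / np.sqrt((5.0 / 3.0) * (1 / 4 + 1 / 4))
        assert cmp.degrees_freedom == 6
        assert cmp.t_statistic == pytest.approx(t_hand, abs=1e-12)
        p_hand = 2 * stats.t.sf(abs(t_hand), 6)
        assert cmp.p_value == pytest.approx(p_hand, rel=1e-12)

    def test_zero_variance_conventions(self):
        cmp = wp.compare_groups([2.0, 2.0], [2.0, 2.0])
        assert cmp.p_value == 1.0
        with pytest.raises(AnalysisError):
            wp.compare_groups([1.0, 1.0], [2.0, 2.0])

    def test_groups_too_small_rejected(self):
        with pytest.raises(AnalysisError):
            wp.compare_groups([1.0], [2.0, 3.0])


class TestRunDiversityAnalysis:
    @pytest.fixture
    def study(self):
        cfg = wp.SimulationConfig(seed=8, profile_n_genes=80)
        profiles, labels = wp.simulate_profiles(cfg)
        records = wp.simulate_synergy_sets(labels, seed=8)
        weak = {r.target_pathway for r in records if r.cls == "test"}
        return profiles, records, weak

    def test_four_vs_four_design_df(self, study):
        profiles, records, weak = study
        _, comparison, _ = wp.run_diversity_analysis(profiles, records, weak)
        assert comparison.degrees_freedom == 6  # 4 + 4 - 2

    def test_identical_records_across_classes_give_t_zero(self, study):
        profiles, records, weak = study
        test = [r for r in records if r.cls == "test"][:2]
        mirrored = [
            SynergyRecord(
                therapeutic=f"ctrl_{r.therapeutic}",
                cls="control",
                target_pathway="other",
                synergizers=r.synergizers,
            )
            for r in test
        ]
        _, comparison, _ = wp.run_diversity_analysis(
            profiles, list(test) + mirrored, weak
        )
        assert comparison.t_statistic == pytest.approx(0.0, abs=1e-12)

    def test_underfilled_record_skipped_and_reported(self, study):
        profiles, records, weak = study
        bad = SynergyRecord(
            therapeutic="starved", cls="control", target_pathway="X",
            synergizers=(("DRUG_C01_01", "X"), ("DRUG_C01_02", "X")),
        )
        results, _, skipped = wp.run_diversity_analysis(
            profiles, list(records) + [bad], weak
        )
        assert skipped == {"starved": "fewer_than_2_drugs_after_exclusion"}
        assert all(r.therapeutic != "starved" for r in results)

    def test_mds_space_scores_match_embedding(self, study):
        profiles, records, weak = study
        results, _, _ = wp.run_diversity_analysis(
            profiles, records, weak, distance_space="mds"
        )
        for r in results:
            assert r.diversity_score == pytest.approx(
                wp.diversity_score(r.coordinates), abs=1e-12
            )

    def test_breadth_gap_monotone(self):
        """Widening the planted breadth gap never shrinks the median
        test-control score gap (3-point grid)."""
        medians = []
        for breadth_test in (2, 4, 6):
            gaps = []
            for seed in range(50):
                cfg = wp.SimulationConfig(seed=seed, profile_n_genes=100)
                profiles, labels = wp.simulate_profiles(cfg)
                records = wp.simulate_synergy_sets(
                    labels, breadth_test=breadth_test, breadth_control=2,
                    seed=seed,
                )
                weak = {r.target_pathway for r in records if r.cls == "test"}
                _, cmp_, _ = wp.run_diversity_analysis(profiles, records, weak)
                gaps.append(cmp_.mean_test - cmp_.mean_control)
            medians.append(float(np.median(gaps)))
        assert medians[0] <= medians[1] <= medians[2]

    def test_pipeline_deterministic(self, study):
        profiles, records, weak = study
        a = wp.run_diversity_analysis(profiles, records, weak)
        b = wp.run_diversity_analysis(profiles, records, weak)
        assert [r.diversity_score for r in a[0]] == [
            r.diversity_score for r in b[0]
        ]
        assert a[1] == b[1]
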