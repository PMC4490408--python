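import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score, silhouette_score

from glycosurf import (
    CtTable,
    SimulationConfig,
    average_replicates,
    category_dispersion,
    cluster_trajectories,
    discover_markers,
    down_up_overlap,
    fold_changes,
    hierarchical_cluster,
    normalize,
    rank_markers,
    relative_expression_ddct,
    run_pca,
    select_fclass_clusters,
    simulate_counts,
    simulate_timecourse,
)
from conftest import make_averaged


def brute_force_overlap(values, early, late, theta, c):
    """Independent two-pass set computation of the down-then-up overlap."""
    late_up, early_down = set(), set()
    for g in values.index:
        if (values.loc[g, late[1]] + c) / (values.loc[g, late[0]] + c) >= theta:
            late_up.add(g)
        if (values.loc[g, early[1]] + c) / (values.loc[g, early[0]] + c) <= 1 / theta:
            early_down.add(g)
    if not late_up:
        return None
    return 100.0 * len(late_up & early_down) / len(late_up)


class TestFoldChanges:
    def test_pseudocounted_ratio_and_flag_rule(self):
        m = make_averaged([[10.0, 5.0], [10.0, 4.0]], ["a", "b"])
        fc = fold_changes(m, [("a", "b")], theta=2.0, pseudocount=0.5)
        # (5 + 0.5) / (10 + 0.5) = 0.524 sits just above the 1/2 cutoff,
        # so the pseudocounted ratio does not flag as down
        assert fc.ratio.iloc[0] == pytest.approx(5.5 / 10.5)
        assert fc.flag.iloc[0] == "none"
        assert fc.ratio.iloc[1] == pytest.approx(4.5 / 10.5)
        assert fc.flag.iloc[1] == "down"

    def test_equal_values_flag_none(self):
        m = make_averaged([[4.0, 4.0]], ["a", "b"])
        fc = fold_changes(m, [("a", "b")])
        assert fc.ratio.iloc[0] == 1.0 and fc.flag.iloc[0] == "none"

    def test_double_zero_is_ratio_one_via_pseudocount(self):
        m = make_averaged([[0.0, 0.0]], ["a", "b"])
        fc = fold_changes(m, [("a", "b")])
        assert fc.ratio.iloc[0] == 1.0 and fc.flag.iloc[0] == "none"

    def test_theta_at_most_one_rejected(self):
        m = make_averaged([[1.0, 1.0]], ["a", "b"])
        with pytest.raises(ValueError, match="theta"):
            fold_changes(m, [("a", "b")], theta=1.0)


class TestDownUpOverlap:
    def _matrix(self):
        # columns: e0 -> e1 (early pair), l0 -> l1 (late pair)
        vals = [
            [20, 5, 2, 10],   # early down, late up
            [20, 4, 3, 20],   # early down, late up
            [20, 2, 5, 30],   # early down, late up
            [10, 10, 2, 10],  # late up only
            [30, 5, 8, 8],    # early down only
        ]
        return make_averaged(vals, ["e0", "e1", "l0", "l1"])

    def test_three_of_four_late_up_were_early_down(self):
        m = self._matrix()
        got = down_up_overlap(m, ("e0", "e1"), ("l0", "l1"))
        assert got == pytest.approx(75.0)
        assert got == pytest.approx(
            brute_force_overlap(m.values, ("e0", "e1"), ("l0", "l1"), 2.0, 0.5)
        )

    def test_no_early_down_gives_zero(self):
        m = make_averaged([[5, 5, 2, 10]], ["e0", "e1", "l0", "l1"])
        assert down_up_overlap(m, ("e0", "e1"), ("l0", "l1")) == 0.0

    def test_all_late_up_early_down_gives_hundred(self):
        m = make_averaged([[20, 5, 2, 10], [40, 9, 1, 9]],
                          ["e0", "e1", "l0", "l1"])
        assert down_up_overlap(m, ("e0", "e1"), ("l0", "l1")) == 100.0

    def test_empty_late_up_set_is_an_error(self):
        m = make_averaged([[5, 5, 10, 10]], ["e0", "e1", "l0", "l1"])
        with pytest.raises(ValueError, match="undefined"):
            down_up_overlap(m, ("e0", "e1"), ("l0", "l1"))

    @pytest.mark.parametrize("seed", range(100))
    def test_matches_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        vals = rng.integers(0, 12, size=(rng.integers(3, 15), 4)).astype(float)
        m = make_averaged(vals, ["e0", "e1", "l0", "l1"])
        expected = brute_force_overlap(
            m.values, ("e0", "e1"), ("l0", "l1"), 2.0, 0.5
        )
        if expected is None:
            with pytest.raises(ValueError):
                down_up_overlap(m, ("e0", "e1"), ("l0", "l1"))
        else:
            assert down_up_overlap(m, ("e0", "e1"), ("l0", "l1")) == pytest.approx(
                expected
            )


class TestCategoryDispersion:
    def test_identical_composition_has_zero_dispersion(self):
        m = make_averaged(np.ones((6, 3)), ["a", "b", "c"])
        ann = {g: ("receptor" if i < 3 else "enzyme")
               for i, g in enumerate(m.values.index)}
        _, sd, mean_sd = category_dispersion(m, ann)
        assert mean_sd == 0.0 and (sd == 0).all()

    def test_sixty_forty_swing_gives_expected_sd(self):
        # category X holds 60% of detected groups at t0, 40% at t1
        vals = np.array([
            [1, 1], [1, 1], [1, 0],   # X (g2 drops out at t1)
            [1, 1], [1, 1], [0, 1],   # Y (g5 appears at t1)
        ])
        m = make_averaged(vals, ["t0", "t1"])
        ann = {"g0": "X", "g1": "X", "g2": "X", "g3": "Y", "g4": "Y", "g5": "Y"}
        table, sd, _ = category_dispersion(m, ann)
        assert table.loc["X"].tolist() == [60.0, 40.0]
        # sample s.d. of {60, 40} = 10 * sqrt(2) = 14.142...
        assert sd["X"] == pytest.approx(np.sqrt(200.0))

    def test_percentages_sum_to_hundred(self):
        rng = np.random.default_rng(0)
        m = make_averaged(rng.integers(0, 3, size=(10, 4)), list("abcd"))
        ann = {g: rng.choice(["r", "e", "t"]) for g in m.values.index}
        table, _, _ = category_dispersion(m, ann)
        assert np.allclose(table.sum(axis=0), 100.0)

    def test_single_time_point_reports_zero_with_warning(self):
        m = make_averaged([[1.0], [1.0]], ["only"])
        with pytest.warns(UserWarning, match="fewer than two"):
            _, _, mean_sd = category_dispersion(m, {})
        assert mean_sd == 0.0


@pytest.fixture(scope="module")
def synthetic_avg():
    cfg = SimulationConfig(n_groups=120, seed=5)
    ab, truth = simulate_timecourse(cfg)
    raw = simulate_counts(ab, cfg, truth.design)
    return average_replicates(normalize(raw)), truth


class TestRunPca:
    def test_identical_samples_have_identical_scores(self):
        rng = np.random.default_rng(2)
        col = rng.uniform(0, 20, size=12)
        vals = np.column_stack([col, col, rng.uniform(0, 20, size=12)])
        m = make_averaged(vals, ["a", "b", "c"])
        pca = run_pca(m)
        assert np.allclose(pca.scores.loc["a"], pca.scores.loc["b"], atol=1e-8)

    def test_scores_preserve_pairwise_distances(self):
        rng = np.random.default_rng(4)
        m = make_averaged(rng.uniform(0, 30, size=(15, 6)), list("abcdef"))
        pca = run_pca(m)
        X = np.log2(m.values.to_numpy().T + 1)
        X = X - X.mean(axis=0)
        assert np.allclose(pdist(pca.scores.to_numpy()), pdist(X), atol=1e-8)

    def test_variance_ratios_non_increasing_and_sum_to_one(self, synthetic_avg):
        m, _ = synthetic_avg
        pca = run_pca(m)
        ve = pca.variance_explained
        assert (np.diff(ve) <= 1e-12).all()
        assert ve.sum() == pytest.approx(1.0)

    def test_archetype_states_separate_in_first_two_components(self, synthetic_avg):
        m, truth = synthetic_avg
        pca = run_pca(m)
        labels, cols = [], []
        for col, (day, cond) in m.column_points.items():
            if cond == "MEF":
                lab = "mef"
            elif cond == "ESC":
                lab = "esc"
            elif cond == "DOXH" and day >= 18:
                lab = "fclass"
            else:
                continue
            labels.append(lab)
            cols.append(col)
        scores = pca.scores.loc[cols, ["PC1", "PC2"]].to_numpy()
        assert silhouette_score(scores, labels) > 0

    def test_constant_matrix_rejected(self):
        m = make_averaged(np.full((5, 4), 3.0), list("abcd"))
        with pytest.raises(ValueError, match="constant"):
            run_pca(m)


class TestClusterTrajectories:
    def test_recovers_planted_archetypes(self, synthetic_avg):
        m, truth = synthetic_avg
        keep = [g for g, a in truth.archetypes.items()
                if a in ("early_down", "fclass_up", "esc_like")]
        sub = make_averaged(
            m.values.loc[keep].to_numpy(), list(m.values.columns),
            points=dict(m.column_points), groups=keep,
        )
        clusters = cluster_trajectories(sub, k=3, seed=0, restarts=10)
        truth_labels = [truth.archetypes[g] for g in keep]
        assert adjusted_rand_score(truth_labels, clusters.tolist()) >= 0.9

    def test_k_below_two_rejected(self):
        m = make_averaged(np.eye(4), list("abcd"))
        with pytest.raises(ValueError):
            cluster_trajectories(m, k=1, seed=0)

    def test_k_above_group_count_rejected(self):
        m = make_averaged(np.eye(4), list("abcd"))
        with pytest.raises(ValueError, match="exceeds"):
            cluster_trajectories(m, k=5, seed=0)

    def test_duplicated_rows_cluster_together(self):
        rng = np.random.default_rng(8)
        base = rng.uniform(0, 10, size=(3, 5))
        vals = np.vstack([base, base[0]])  # g3 duplicates g0
        m = make_averaged(vals, list("abcde"))
        clusters = cluster_trajectories(m, k=2, seed=1)
        assert clusters["g0"] == clusters["g3"]

    def test_deterministic_for_fixed_seed(self, synthetic_avg):
        m, _ = synthetic_avg
        a = cluster_trajectories(m, k=6, seed=3)
        b = cluster_trajectories(m, k=6, seed=3)
        assert (a == b).all()


class TestSelectFclassClusters:
    def _matrix(self):
        points = {
            "d00_MEF": (0, "MEF"), "d02_DOXH": (2, "DOXH"),
            "d18_DOXH": (18, "DOXH"), "d30_DOXH": (30, "DOXH"),
            "d30_ESC": (30, "ESC"),
        }
        vals = np.array([
            [1, 4, 8, 10, 1],    # rises post-DOX, peaks at F-class end
            [1, 4, 8, 10.5, 1],
            [10, 5, 2, 1, 1],    # peaks at day 0
            [10, 8, 5, 2, 1],    # monotone down
            [1, 10, 2, 1, 1],    # transient: rises but peaks early
        ], dtype=float)
        cols = list(points)
        return make_averaged(vals, cols, points=points)

    def test_selection_rule(self):
        m = self._matrix()
        clusters = pd.Series([0, 0, 1, 2, 3], index=m.values.index)
        assert select_fclass_clusters(clusters, m) == {0}

    def test_no_doxh_arm_is_an_error(self):
        points = {"d00_MEF": (0, "MEF"), "d30_ESC": (30, "ESC")}
        m = make_averaged([[1, 2], [2, 1]], list(points), points=points)
        clusters = pd.Series([0, 1], index=m.values.index)
        with pytest.raises(ValueError, match="DOXH"):
            select_fclass_clusters(clusters, m)


class TestRankMarkers:
    def test_zero_loading_scores_zero(self):
        scores = pd.DataFrame(
            {"PC1": [0.0, 10.0, -10.0], "PC2": [5.0, -5.0, 0.0]},
            index=["f", "e", "m"],
        )
        loadings = pd.DataFrame(
            {"PC1": [0.8, 0.0], "PC2": [0.5, 0.0]}, index=["g0", "g1"]
        )
        from glycosurf.marker_discovery import PCAResult

        pca = PCAResult(scores, loadings, np.array([0.7, 0.3]))
        table, comps = rank_markers(
            pca, ["g0", "g1"], {"fclass": ["f"], "esc": ["e"], "mef": ["m"]}
        )
        assert table.loc["g1", "score"] == 0.0
        assert table.loc["g0", "rank"] == 1

    def test_identical_trajectories_tie_deterministically(self):
        vals = np.vstack([
            np.array([1, 2, 8, 9, 1.0]),
            np.array([1, 2, 8, 9, 1.0]),
            np.random.default_rng(1).uniform(0, 5, 5),
        ])
        points = {
            "d00_MEF": (0, "MEF"), "d02_DOXH": (2, "DOXH"),
            "d18_DOXH": (18, "DOXH"), "d30_DOXH": (30, "DOXH"),
            "d30_ESC": (30, "ESC"),
        }
        m = make_averaged(vals, list(points), points=points,
                          groups=["gB", "gA", "gC"])
        pca = run_pca(m)
        table, _ = rank_markers(
            pca, ["gA", "gB", "gC"],
            {"fclass": ["d30_DOXH"], "esc": ["d30_ESC"], "mef": ["d00_MEF"]},
        )
        assert table.loc["gA", "score"] == pytest.approx(table.loc["gB", "score"])
        # tie broken by primary_id, ascending
        assert table.loc["gA", "rank"] < table.loc["gB", "rank"]

    def test_empty_state_rejected(self):
        m = make_averaged(np.random.default_rng(0).uniform(0, 5, (4, 3)),
                          list("abc"))
        pca = run_pca(m)
        with pytest.raises(ValueError, match="esc"):
            rank_markers(pca, ["g0"], {"fclass": ["a"], "esc": [], "mef": ["b"]})

    def test_planted_marker_ranks_first_on_synthetic_data(self, synthetic_avg):
        m, truth = synthetic_avg
        result = discover_markers(m, k=8, seed=5)
        assert result.ranking.index[0] == truth.planted_marker_id
        assert set(result.ranking.index) <= set(
            result.clusters.index[result.clusters.isin(result.selected_clusters)]
        )
        assert ((result.ranking.score >= 0) & (result.ranking.score <= 1)).all()


class TestDeltaDeltaCt:
    def _table(self, rows, calibrator="cal"):
        df = pd.DataFrame(rows, columns=["gene", "sample_id", "ct_target",
                                         "ct_reference"])
        return CtTable(values=df, calibrator=calibrator)

    def test_calibrator_self_comparison_is_one(self):
        ct = self._table([("cd24", "cal", 25.0, 18.0)])
        assert relative_expression_ddct(ct).loc["cd24", "cal"] == 1.0

    def test_one_cycle_earlier_doubles_expression(self):
        ct = self._table([
            ("cd24", "cal", 25.0, 18.0),
            ("cd24", "s", 24.0, 18.0),  # ΔΔCt = -1
        ])
        assert relative_expression_ddct(ct).loc["cd24", "s"] == pytest.approx(2.0)

    def test_two_cycles_later_quarters_expression(self):
        ct = self._table([
            ("cd24", "cal", 25.0, 18.0),
            ("cd24", "s", 27.0, 18.0),  # ΔΔCt = +2
        ])
        assert relative_expression_ddct(ct).loc["cd24", "s"] == pytest.approx(0.25)

    def test_missing_calibrator_rejected(self):
        ct = self._table([("cd24", "s", 25.0, 18.0)])
        with pytest.raises(ValueError, match="calibrator"):
            relative_expression_ddct(ct)

    def test_nonpositive_ct_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            self._table([("cd24", "cal", -1.0, 18.0)])


class TestHierarchicalCluster:
    def test_identical_rows_merge_at_height_zero(self):
        df = pd.DataFrame([[1.0, 2.0], [1.0, 2.0], [9.0, 9.0]],
                          index=["a", "b", "c"])
        order, Z = hierarchical_cluster(df)
        assert Z[0, 2] == 0.0
        assert abs(order.index("a") - order.index("b")) == 1

    def test_outlier_merges_last(self):
        df = pd.DataFrame([[0.0, 0.0], [1.0, 0.0], [50.0, 50.0]],
                          index=["a", "b", "out"])
        order, Z = hierarchical_cluster(df)
        # final merge joins the outlier; heights non-decreasing
        assert order[0] == "out" or order[-1] == "out"
        assert (np.diff(Z[:, 2]) >= 0).all()

    def test_nan_rejected(self):
        df = pd.DataFrame([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="NaN"):
            hierarchical_cluster(df)
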