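"""Correlations, PCA, contribution threshold, Ward and k-means grouping."""
import itertools

import numpy as np
import pandas as pd
import pytest

from quinoaphen.multivariate import (contribution_threshold,
                                     correlation_matrix, group_summary,
                                     kmeans_cluster, pca, ward_cluster)


class TestCorrelations:
    def test_perfect_linear_relation_pearson(self):
        x = np.arange(10.0)
        res = correlation_matrix(pd.DataFrame({"a": x, "b": 2 * x + 3}))
        assert res.r.loc["a", "b"] == pytest.approx(1.0)
        assert res.r.loc["a", "a"] == 1.0

    def test_monotone_nonlinear_relation_spearman(self):
        x = np.arange(1.0, 11.0)
        res = correlation_matrix(pd.DataFrame({"a": x, "b": np.exp(x)}),
                                 method="spearman")
        assert res.r.loc["a", "b"] == pytest.approx(1.0)

    def test_six_point_hand_computation(self):
        a = np.array([1.0, 2.0, 4.0, 4.5, 7.0, 9.0])
        b = np.array([2.0, 1.0, 5.0, 4.0, 8.0, 7.5])
        res = correlation_matrix(pd.DataFrame({"a": a, "b": b}))
        # direct covariance formula
        r_hand = (np.sum((a - a.mean()) * (b - b.mean()))
                  / np.sqrt(np.sum((a - a.mean()) ** 2)
                            * np.sum((b - b.mean()) ** 2)))
        assert res.r.loc["a", "b"] == pytest.approx(r_hand, abs=1e-12)
        # spearman via hand ranks (no ties)
        ra = a.argsort().argsort().astype(float)
        rb = b.argsort().argsort().astype(float)
        rho_hand = (np.sum((ra - ra.mean()) * (rb - rb.mean()))
                    / np.sqrt(np.sum((ra - ra.mean()) ** 2)
                              * np.sum((rb - rb.mean()) ** 2)))
        res_s = correlation_matrix(pd.DataFrame({"a": a, "b": b}),
                                   method="spearman")
        assert res_s.r.loc["a", "b"] == pytest.approx(rho_hand, abs=1e-12)

    def test_pairwise_complete_counts(self):
        df = pd.DataFrame({"a": [1, 2, 3, 4, np.nan],
                           "b": [2.0, 1.0, 4.0, np.nan, 5.0]})
        res = correlation_matrix(df)
        assert res.n.loc["a", "b"] == 3

    def test_constant_column_flagged_nan(self):
        df = pd.DataFrame({"a": [1.0, 2.0, 3.0], "b": [5.0, 5.0, 5.0]})
        res = correlation_matrix(df)
        assert np.isnan(res.r.loc["a", "b"])

    def test_significance_mask(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({"a": rng.normal(size=50)})
        df["b"] = df["a"] + rng.normal(scale=0.1, size=50)   # strong
        df["c"] = rng.normal(size=50)                        # noise
        res = correlation_matrix(df)
        sig = res.significant(alpha=0.05)
        assert bool(sig.loc["a", "b"])


class TestPCA:
    def test_explained_variance_sums_to_100(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(40, 5)),
                          columns=list("abcde"))
        res = pca(df)
        assert res.explained_pct.sum() == pytest.approx(100.0)
        for pc in res.contributions.columns:
            assert res.contributions[pc].sum() == pytest.approx(100.0)

    def test_isotropic_two_traits_split_evenly(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(4000, 2)), columns=["a", "b"])
        res = pca(df)
        assert res.explained_pct.iloc[0] == pytest.approx(50.0, abs=3.0)

    def test_matches_eigendecomposition_oracle(self):
        x = np.array([[1.0, 2.0, 0.5], [2.0, 1.0, 0.7], [3.0, 5.0, 0.2],
                      [4.0, 3.0, 0.9], [5.0, 6.0, 0.1]])
        df = pd.DataFrame(x, columns=["a", "b", "c"])
        res = pca(df)
        corr = np.corrcoef(x, rowvar=False)
        w, v = np.linalg.eig(corr)
        order = np.argsort(w)[::-1]
        w, v = w[order].real, v[:, order].real
        assert np.allclose(res.explained_pct.to_numpy(), 100 * w / 3, atol=1e-8)
        for j in range(3):  # match up to sign
            got = res.loadings.iloc[:, j].to_numpy()
            assert (np.allclose(got, v[:, j], atol=1e-8)
                    or np.allclose(got, -v[:, j], atol=1e-8))

    def test_scores_covariance_is_diagonal_eigenvalues(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(60, 2))
        df = pd.DataFrame(np.hstack([base, base @ rng.normal(size=(2, 2))]),
                          columns=list("abcd"))
        res = pca(df)
        cov = np.cov(res.scores.to_numpy(), rowvar=False)
        eig = res.explained_pct.to_numpy() / 100 * 4
        assert np.allclose(cov, np.diag(eig), atol=1e-8)

    def test_sign_convention_largest_loading_positive(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        res = pca(df)
        for pc in res.loadings.columns:
            col = res.loadings[pc]
            assert col.iloc[np.argmax(np.abs(col.to_numpy()))] > 0

    def test_rows_with_missing_values_dropped_and_logged(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(10, 3)), columns=list("abc"))
        df.loc[3, "b"] = np.nan
        res = pca(df)
        assert res.dropped == [3]
        assert 3 not in res.scores.index


class TestContributionThreshold:
    def test_eighteen_trait_panel(self):
        assert contribution_threshold(18) == pytest.approx(5.56, abs=0.005)

    def test_single_trait(self):
        assert contribution_threshold(1) == 100.0

    def test_four_traits(self):
        assert contribution_threshold(4) == 25.0

    def test_zero_traits_rejected(self):
        with pytest.raises(ValueError):
            contribution_threshold(0)


def _ward_oracle_merges(points):
    """Greedy Ward by explicit within-cluster sum of squares, from scratch."""
    clusters = [[i] for i in range(len(points))]

    def ess(idx):
        p = points[idx]
        return float(((p - p.mean(axis=0)) ** 2).sum())

    merges = []
    while len(clusters) > 1:
        best, best_cost = None, np.inf
        for i, j in itertools.combinations(range(len(clusters)), 2):
            cost = (ess(clusters[i] + clusters[j])
                    - ess(clusters[i]) - ess(clusters[j]))
            if cost < best_cost:
                best, best_cost = (i, j), cost
        i, j = best
        merged = clusters[i] + clusters[j]
        merges.append(frozenset(merged))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)]
        clusters.append(merged)
    return merges


class TestWard:
    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(6)
        a = rng.normal(loc=0.0, scale=0.3, size=(15, 2))
        b = rng.normal(loc=8.0, scale=0.3, size=(15, 2))
        df = pd.DataFrame(np.vstack([a, b]), columns=["x", "y"])
        res = ward_cluster(df, k=2, standardize=False)
        labels = res.labels.to_numpy()
        assert len(set(labels[:15])) == 1 and len(set(labels[15:])) == 1
        assert labels[0] != labels[-1]

    def test_five_point_merge_sequence_matches_exhaustive_oracle(self):
        points = np.array([[0.0, 0.0], [0.3, 0.1], [4.0, 4.2],
                           [4.1, 3.9], [10.0, 0.0]])
        df = pd.DataFrame(points, columns=["x", "y"])
        res = ward_cluster(df, k=2, standardize=False)
        lm = res.linkage_matrix
        # reconstruct the sets merged by scipy at each step
        members = {i: frozenset([i]) for i in range(5)}
        scipy_merges = []
        for step, (i, j, _, _) in enumerate(lm):
            merged = members[int(i)] | members[int(j)]
            members[5 + step] = merged
            scipy_merges.append(merged)
        assert scipy_merges == _ward_oracle_merges(points)

    def test_duplicated_points_merge_first_at_height_zero(self):
        points = np.array([[1.0, 1.0], [1.0, 1.0], [5.0, 5.0], [9.0, 1.0]])
        res = ward_cluster(pd.DataFrame(points, columns=["x", "y"]), k=2,
                           standardize=False)
        lm = res.linkage_matrix
        assert lm[0, 2] == 0.0
        assert {int(lm[0, 0]), int(lm[0, 1])} == {0, 1}

    def test_merge_heights_nondecreasing(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame(rng.normal(size=(25, 3)), columns=["x", "y", "z"])
        res = ward_cluster(df, k=3)
        heights = res.linkage_matrix[:, 2]
        assert np.all(np.diff(heights) >= -1e-12)

    def test_rows_with_missing_inputs_left_unassigned(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(rng.normal(size=(10, 2)), columns=["x", "y"],
                          index=[f"acc{i}" for i in range(10)])
        df.loc["acc4", "x"] = np.nan
        res = ward_cluster(df, k=2)
        assert res.unassigned == ["acc4"]
        assert "acc4" not in res.labels.index

    def test_k_larger_than_rows_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [0.0, 1.0]})
        with pytest.raises(ValueError):
            ward_cluster(df, k=5)


class TestKMeans:
    def test_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(9)
        a = rng.normal(loc=0.0, scale=0.3, size=(12, 2))
        b = rng.normal(loc=9.0, scale=0.3, size=(12, 2))
        df = pd.DataFrame(np.vstack([a, b]), columns=["x", "y"])
        res = kmeans_cluster(df, k=2, seed=1)
        labels = res.labels.to_numpy()
        assert len(set(labels[:12])) == 1 and labels[0] != labels[-1]

    def test_k_equal_n_gives_zero_inertia(self):
        df = pd.DataFrame({"x": [0.0, 2.0, 5.0, 9.0]})
        res = kmeans_cluster(df, k=4, seed=1, standardize=False)
        assert res.inertia == pytest.approx(0.0, abs=1e-12)

    def test_eight_point_1d_optimum_matches_enumeration(self):
        x = np.array([0.0, 0.4, 1.1, 1.3, 7.9, 8.4, 8.8, 9.6])
        df = pd.DataFrame({"x": x})
        res = kmeans_cluster(df, k=2, seed=1, standardize=False)

        best_cost, best_groups = np.inf, None
        for assign in itertools.product([0, 1], repeat=8):
            if len(set(assign)) < 2:
                continue
            cost = 0.0
            for g in (0, 1):
                vals = x[np.array(assign) == g]
                cost += ((vals - vals.mean()) ** 2).sum()
            if cost < best_cost - 1e-12:
                best_cost, best_groups = cost, assign
        got = res.labels.to_numpy()
        partition = frozenset(
            frozenset(np.flatnonzero(got == g)) for g in set(got))
        oracle = frozenset(
            frozenset(np.flatnonzero(np.array(best_groups) == g))
            for g in (0, 1))
        assert partition == oracle
        assert res.inertia == pytest.approx(best_cost)

    def test_deterministic_under_fixed_seed(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(30, 3)), columns=["x", "y", "z"])
        a = kmeans_cluster(df, k=3, seed=5)
        b = kmeans_cluster(df, k=3, seed=5)
        assert (a.labels == b.labels).all()


class TestGroupSummary:
    def test_single_group_reproduces_overall_stats(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame({"x": rng.normal(size=20)})
        labels = pd.Series(1, index=df.index)
        out = group_summary(df, labels)
        assert out.loc[1, ("x", "mean")] == pytest.approx(df["x"].mean())
        assert out.loc[1, ("x", "sd")] == pytest.approx(df["x"].std(ddof=1))

    def test_constant_groups_have_zero_sd(self):
        df = pd.DataFrame({"x": [1.0, 1.0, 4.0, 4.0]})
        labels = pd.Series([1, 1, 2, 2], index=df.index)
        out = group_summary(df, labels)
        assert (out[("x", "sd")] == 0).all()

    def test_weighted_group_means_reproduce_grand_mean(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame({"x": rng.normal(size=40)})
        labels = pd.Series(rng.integers(1, 4, size=40), index=df.index)
        out = group_summary(df, labels)
        weighted = (out[("x", "mean")] * out["n"]).sum() / out["n"].sum()
        assert weighted == pytest.approx(df["x"].mean())
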