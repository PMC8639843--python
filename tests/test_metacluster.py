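import numpy as np
import pandas as pd
import pytest

from cifu import (
    cluster_covariate_means,
    correspond_metaclusters,
    cut_tree,
    sparse_hclust,
)
from cifu.metacluster import ClusterCovariateMatrix, MetaclusterResult
from cifu.profiles import COVARIATE_NAMES, CovariateTable


def make_table(values: dict[str, list[float]], ids=None) -> CovariateTable:
    df = pd.DataFrame(values)
    df.index = pd.Index(
        ids if ids is not None else [f"s{i}" for i in range(len(df))],
        name="sample_id",
    )
    return CovariateTable(df)


def bare_matrix(X: np.ndarray, columns, scale=None) -> ClusterCovariateMatrix:
    means = pd.DataFrame(X, columns=list(columns))
    return ClusterCovariateMatrix(
        means=means,
        sizes=pd.Series(10, index=means.index),
        scale=scale,
    )


class TestClusterCovariateMeans:
    def test_two_clusters_mean_rows(self):
        table = make_table({"iop": [1.0, 3.0, 10.0, 12.0],
                            "cct": [500.0, 502.0, 520.0, 522.0]})
        M = cluster_covariate_means(
            np.array(["s0", "s1", "s2", "s3"]), np.array([0, 0, 1, 1]), table,
            ("iop", "cct"),
        )
        np.testing.assert_allclose(M.means.loc[0], [2.0, 501.0])
        np.testing.assert_allclose(M.means.loc[1], [11.0, 521.0])
        assert list(M.sizes) == [2, 2]
        assert M.scale is not None and (M.scale > 0).all()

    def test_single_cluster_is_global_mean(self):
        table = make_table({"iop": [1.0, 3.0], "cct": [10.0, 20.0]})
        M = cluster_covariate_means(
            np.array(["s0", "s1"]), np.array([0, 0]), table, ("iop", "cct")
        )
        np.testing.assert_allclose(M.means.loc[0], [2.0, 15.0])

    def test_sample_order_invariance(self):
        rng = np.random.default_rng(0)
        vals = {c: rng.uniform(0, 1, 12).tolist() for c in COVARIATE_NAMES}
        table = make_table(vals)
        ids = np.array([f"s{i}" for i in range(12)])
        labels = rng.integers(0, 3, 12)
        M1 = cluster_covariate_means(ids, labels, table)
        perm = rng.permutation(12)
        M2 = cluster_covariate_means(ids[perm], labels[perm], table)
        pd.testing.assert_frame_equal(M1.means, M2.means)


class TestSparseWeights:
    def test_symmetric_pair_at_the_constraint_boundary(self):
        # two covariates carrying identical structure -> equal weights 1/sqrt(2)
        X = np.array([[0.0, 0.0], [1.0, 1.0], [3.0, 3.0], [4.0, 4.0]])
        res = sparse_hclust(bare_matrix(X, ["average_cdr", "cup_volume"]),
                            wbound=np.sqrt(2))
        np.testing.assert_allclose(res.weights.to_numpy(),
                                   [1 / np.sqrt(2)] * 2, atol=1e-6)
        # grid-search oracle over the constraint set w=(cos t, sin t)
        D = (X[np.triu_indices(4, 1)[0]] - X[np.triu_indices(4, 1)[1]]) ** 2
        Xs = (X - X.mean(0)) / X.std(0)
        iu, ju = np.triu_indices(4, 1)
        D = (Xs[iu] - Xs[ju]) ** 2
        best, best_obj = None, -np.inf
        for t in np.linspace(0, np.pi / 2, 2001):
            w = np.array([np.cos(t), np.sin(t)])
            if w.sum() > np.sqrt(2) + 1e-9:
                continue
            dw = D @ w
            obj = np.linalg.norm(dw)
            if obj > best_obj:
                best_obj, best = obj, w
        np.testing.assert_allclose(res.weights.to_numpy(), best, atol=1e-3)

    def test_zero_variance_covariate_gets_zero_weight(self):
        X = np.array([[0.0, 5.0], [1.0, 5.0], [3.0, 5.0]])
        res = sparse_hclust(bare_matrix(X, ["iop", "cct"]), wbound=1.2)
        assert res.weights["cct"] == 0.0

    def test_constraints_hold_at_convergence(self):
        rng = np.random.default_rng(1)
        X = rng.normal(0, 1, (7, 9))
        for wbound in (1.5, 2.0, 3.0):
            res = sparse_hclust(bare_matrix(X, COVARIATE_NAMES), wbound)
            w = res.weights.to_numpy()
            assert np.all(w >= 0)
            assert np.linalg.norm(w) <= 1 + 1e-8
            assert w.sum() <= wbound + 1e-6

    def test_objective_nondecreasing(self):
        rng = np.random.default_rng(2)
        X = rng.normal(0, 1, (8, 9))
        res = sparse_hclust(bare_matrix(X, COVARIATE_NAMES), wbound=2.0)
        diffs = np.diff(res.objective_trace)
        assert np.all(diffs >= -1e-8)

    def test_unsparse_bound_recovers_equal_signal_weighting(self):
        # all features carry the same structure: full-bound weights are equal,
        # so the weighted dissimilarity is proportional to the unweighted one
        base = np.array([0.0, 1.0, 3.0, 4.0, 7.0])
        X = np.tile(base[:, None], (1, 4))
        M = bare_matrix(X, COVARIATE_NAMES[:4])
        res = sparse_hclust(M, wbound=2.0)  # = sqrt(q), inactive constraint
        np.testing.assert_allclose(res.weights.to_numpy(), 0.5, atol=1e-8)
        Xs = (X - X.mean(0)) / X.std(0)
        iu, ju = np.triu_indices(5, 1)
        unweighted = ((Xs[iu] - Xs[ju]) ** 2).sum(axis=1)
        ratio = res.dissimilarity / unweighted
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-8)

    def test_planted_two_covariate_signal_takes_top_weights(self):
        # only average CDR and cup volume separate the two metagroups
        rng = np.random.default_rng(3)
        group = np.array([0, 0, 0, 1, 1, 1, 1, 0])
        X = rng.normal(0, 0.03, (8, 9))
        cols = list(COVARIATE_NAMES)
        X[:, cols.index("average_cdr")] = 0.45 + 0.15 * group \
            + rng.normal(0, 0.01, 8)
        X[:, cols.index("cup_volume")] = 0.10 + 0.20 * group \
            + rng.normal(0, 0.01, 8)
        M = bare_matrix(X, cols, scale=pd.Series(0.1, index=cols))
        for wbound in (2.0, 3.0, 4.0, 5.0):
            res = sparse_hclust(M, wbound)
            assert set(res.weights.index[:2]) == {"average_cdr", "cup_volume"}

    def test_wbound_below_one_rejected(self):
        X = np.random.default_rng(4).normal(size=(4, 3))
        with pytest.raises(ValueError):
            sparse_hclust(bare_matrix(X, COVARIATE_NAMES[:3]), wbound=0.5)


class TestCutTree:
    def _three_leaf_result(self, h1, h2):
        Z = np.array([[0.0, 1.0, h1, 2.0], [2.0, 3.0, h2, 3.0]])
        return MetaclusterResult(
            weights=pd.Series([1.0], index=["iop"]),
            dissimilarity=np.array([h1, h2, h2]),
            linkage_matrix=Z,
            wbound=2.0,
            objective=1.0,
            objective_trace=[1.0],
            cluster_ids=np.array([1, 2, 3]),
            sizes=pd.Series([5, 5, 5], index=[1, 2, 3]),
        )

    def test_one_merge_below_cut_gives_two_groups(self):
        res = self._three_leaf_result(0.05, 1.0)
        labels = cut_tree(res, height=0.1)
        assert labels.nunique() == 2
        assert labels.loc[1] == labels.loc[2] != labels.loc[3]

    def test_cut_above_root_gives_one_group(self):
        res = self._three_leaf_result(0.4, 1.0)
        assert cut_tree(res, height=1.5).nunique() == 1

    def test_cut_below_all_merges_gives_singletons(self):
        res = self._three_leaf_result(0.4, 1.0)
        assert cut_tree(res, height=0.01).nunique() == 3


class TestCorrespondence:
    def _result_for(self, X, cols=("average_cdr", "cup_volume")):
        return sparse_hclust(bare_matrix(np.asarray(X), cols), wbound=1.4)

    def test_matched_in_order(self):
        A = [[0.45, 0.10], [0.45, 0.11], [0.55, 0.20], [0.56, 0.21]]
        B = [[0.46, 0.12], [0.46, 0.13], [0.57, 0.22], [0.58, 0.23]]
        rA, rB = self._result_for(A), self._result_for(B)
        MA = bare_matrix(np.asarray(A), ["average_cdr", "cup_volume"])
        MB = bare_matrix(np.asarray(B), ["average_cdr", "cup_volume"])
        mapping = correspond_metaclusters(
            {1: rA, 2: rB}, {1: MA, 2: MB}, height=0.5
        )
        labsA = cut_tree(rA, 0.5)
        labsB = cut_tree(rB, 0.5)
        assert labsA.nunique() == 2 and labsB.nunique() == 2
        # the low-CDR metaclusters map to each other (brute-force check of
        # the 2 possible matchings: ascending distance forces this one)
        lowA = labsA.iloc[0]
        lowB = labsB.iloc[0]
        assert mapping[2][lowB] == mapping[1][lowA]
        assert set(mapping[2].values()) == set(mapping[1].values())

    def test_extra_metacluster_is_distinct(self):
        A = [[0.45, 0.10], [0.55, 0.20], [0.70, 0.40]]
        B = [[0.45, 0.10], [0.55, 0.20]]
        rA, rB = self._result_for(A), self._result_for(B)
        MA = bare_matrix(np.asarray(A), ["average_cdr", "cup_volume"])
        MB = bare_matrix(np.asarray(B), ["average_cdr", "cup_volume"])
        mapping = correspond_metaclusters(
            {1: rA, 2: rB}, {1: MA, 2: MB}, height=0.01
        )
        globalsA = set(mapping[1].values())
        globalsB = set(mapping[2].values())
        assert len(globalsA - globalsB) == 1  # exactly one unmatched

    def test_single_stratum_rejected(self):
        A = [[0.45, 0.10], [0.55, 0.20]]
        rA = self._result_for(A)
        MA = bare_matrix(np.asarray(A), ["average_cdr", "cup_volume"])
        with pytest.raises(ValueError):
            correspond_metaclusters({1: rA}, {1: MA})
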