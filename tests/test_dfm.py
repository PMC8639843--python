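import numpy as np
import pytest
from scipy.stats import multivariate_normal
from sklearn.metrics import adjusted_rand_score

from cifu import count_params, criteria, em_fit, select_K
from cifu.dfm import (
    ALL_VARIANTS,
    DFMVariant,
    _component_logpdf,
    _log_resp,
    predict_responsibilities,
)


def two_blob_gamma(n=200, p=5, sep=10.0, sd=0.1, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    gamma = rng.normal(0, sd, (n, p))
    gamma[:half, 0] += sep
    gamma[half:, 0] -= sep
    labels = np.array([0] * half + [1] * (n - half))
    return gamma, labels


class TestVariants:
    def test_exactly_twelve(self):
        assert len(ALL_VARIANTS) == 12
        assert len({v.code for v in ALL_VARIANTS}) == 12

    @pytest.mark.parametrize(
        "variant,K,p,d,expected",
        [
            (DFMVariant("full", False, False), 3, 11, 2, 39),
            (DFMVariant("iso", True, True), 2, 11, 1, 15),
        ],
    )
    def test_parameter_counts(self, variant, K, p, d, expected):
        assert count_params(variant, K, p, d) == expected

    def test_count_increases_with_K(self):
        for variant in ALL_VARIANTS:
            ms = [count_params(variant, K, 11, K - 1) for K in range(2, 8)]
            assert all(b > a for a, b in zip(ms, ms[1:]))


class TestDensities:
    @pytest.mark.parametrize("p,d", [(3, 1), (4, 2)])
    def test_subspace_decomposition_matches_direct_gaussian(self, p, d):
        rng = np.random.default_rng(42)
        U, _ = np.linalg.qr(rng.standard_normal((p, d)))
        mu = rng.standard_normal(d)
        A = rng.standard_normal((d, d))
        Sigma = A @ A.T + 0.5 * np.eye(d)
        beta = 0.3
        cov = U @ Sigma @ U.T + beta * (np.eye(p) - U @ U.T)
        gamma = rng.standard_normal((50, p))
        ours = _component_logpdf(gamma, U, mu, Sigma, beta)
        direct = multivariate_normal(U @ mu, cov).logpdf(gamma)
        np.testing.assert_allclose(ours, direct, atol=1e-6)

    def test_equidistant_point_splits_evenly(self):
        # symmetric two-component model, a point on the symmetry plane
        p, d = 4, 1
        U = np.eye(p)[:, :1]
        mu = np.array([[3.0], [-3.0]])
        Sigma = np.array([[[1.0]], [[1.0]]])
        beta = np.array([0.5, 0.5])
        pi = np.array([0.5, 0.5])
        point = np.zeros((1, p))
        log_r, _ = _log_resp(point, (U, pi, mu, Sigma, beta))
        np.testing.assert_allclose(np.exp(log_r), [[0.5, 0.5]], atol=1e-12)


class TestEMFit:
    def test_separable_blobs_recovered_exactly(self):
        gamma, labels = two_blob_gamma()
        model = em_fit(gamma, K=2, d=1, seed=0)
        assert adjusted_rand_score(labels, model.labels) == 1.0
        # brute-force nearest-mean oracle agrees
        means = np.array([gamma[labels == k].mean(axis=0) for k in (0, 1)])
        oracle = np.argmin(
            ((gamma[:, None, :] - means[None]) ** 2).sum(axis=2), axis=1
        )
        assert adjusted_rand_score(oracle, model.labels) == 1.0

    @pytest.mark.parametrize("variant", ALL_VARIANTS)
    def test_loglik_nondecreasing_for_every_variant(self, variant):
        gamma, _ = two_blob_gamma(n=120, sd=1.0, sep=3.0, seed=1)
        model = em_fit(gamma, K=2, variant=variant, d=1, seed=1, n_restarts=2)
        diffs = np.diff(model.loglik_trace)
        assert np.all(diffs >= -1e-6)

    def test_responsibilities_are_simplex_rows(self):
        gamma, _ = two_blob_gamma(seed=2)
        model = em_fit(gamma, K=2, d=1, seed=2)
        assert np.all(model.responsibilities >= 0)
        np.testing.assert_allclose(model.responsibilities.sum(axis=1), 1.0,
                                   atol=1e-9)
        np.testing.assert_allclose(model.U.T @ model.U, np.eye(model.d),
                                   atol=1e-8)
        assert model.pi.sum() == pytest.approx(1.0)

    def test_label_permutation_leaves_loglik_and_criteria_unchanged(self):
        gamma, _ = two_blob_gamma(seed=3)
        model = em_fit(gamma, K=2, d=1, seed=3)
        import copy

        permuted = copy.deepcopy(model)
        perm = [1, 0]
        permuted.pi = permuted.pi[perm]
        permuted.mu = permuted.mu[perm]
        permuted.Sigma = permuted.Sigma[perm]
        permuted.beta = permuted.beta[perm]
        permuted.responsibilities = permuted.responsibilities[:, perm]
        _, norm = _log_resp(
            gamma - permuted.center,
            (permuted.U, permuted.pi, permuted.mu, permuted.Sigma, permuted.beta),
        )
        assert norm.sum() == pytest.approx(model.loglik, rel=1e-12)
        permuted.loglik = float(norm.sum())
        np.testing.assert_allclose(
            criteria(permuted, len(gamma)), criteria(model, len(gamma)),
            rtol=1e-12,
        )

    def test_parameter_recovery_at_large_n(self):
        rng = np.random.default_rng(9)
        n, p, d = 2000, 4, 1
        U = np.eye(p)[:, :1]
        true_mu, true_sd, true_beta = 4.0, 1.5, 0.25
        z = rng.choice(2, size=n, p=[0.5, 0.5])
        eta = np.where(z == 0, true_mu, -true_mu) + rng.normal(0, true_sd, n)
        gamma = eta[:, None] @ U.T
        gamma += rng.normal(0, np.sqrt(true_beta), (n, p)) @ (np.eye(p) - U @ U.T)
        model = em_fit(gamma, K=2, d=1, seed=9)
        mus = np.sort(np.abs(model.mu.ravel()))
        assert np.all(np.abs(mus - true_mu) / true_mu < 0.1)
        assert np.all(np.abs(model.pi - 0.5) < 0.05)
        sds = np.sqrt([model.Sigma[k, 0, 0] for k in range(2)])
        assert np.all(np.abs(sds - true_sd) / true_sd < 0.1)
        assert np.all(np.abs(model.beta - true_beta) / true_beta < 0.1)

    def test_predict_matches_training_responsibilities(self):
        gamma, _ = two_blob_gamma(seed=4)
        model = em_fit(gamma, K=2, d=1, seed=4)
        np.testing.assert_allclose(
            predict_responsibilities(model, gamma),
            model.responsibilities, atol=1e-9,
        )


class TestCriteria:
    def _hard_model(self, loglik, m_variant, n_resp):
        gamma, _ = two_blob_gamma(n=n_resp, seed=5)
        model = em_fit(gamma, K=2, d=1, seed=5)
        return model

    def test_stated_arithmetic(self):
        gamma, _ = two_blob_gamma(n=30, seed=6)
        model = em_fit(gamma, K=2, variant=DFMVariant("full", False, False),
                       d=1, seed=6)
        model.loglik = -100.0
        model.responsibilities = np.zeros_like(model.responsibilities)
        model.responsibilities[:, 0] = 1.0
        m = model.n_params
        aic, bic, icl = criteria(model, 100)
        assert aic == pytest.approx(-100 - m)
        assert bic == pytest.approx(-100 - 0.5 * m * np.log(100))
        assert icl == pytest.approx(bic)  # hard responsibilities: zero entropy

    def test_maximal_entropy_gap(self):
        gamma, _ = two_blob_gamma(n=40, seed=7)
        model = em_fit(gamma, K=2, d=1, seed=7)
        model.responsibilities = np.full_like(model.responsibilities, 0.5)
        _, bic, icl = criteria(model, 40)
        assert icl == pytest.approx(bic - 40 * np.log(2))

    def test_icl_never_exceeds_bic(self):
        gamma, _ = two_blob_gamma(n=80, sd=1.5, sep=2.0, seed=8)
        model = em_fit(gamma, K=2, d=1, seed=8)
        _, bic, icl = criteria(model, 80)
        assert icl <= bic + 1e-9


class TestSelectK:
    def test_recovers_three_planted_clusters(self):
        rng = np.random.default_rng(10)
        centers = np.array([[8, 0, 0, 0, 0], [-8, 0, 0, 0, 0], [0, 8, 0, 0, 0]],
                           dtype=float)
        labels = np.repeat([0, 1, 2], 60)
        gamma = centers[labels] + rng.normal(0, 0.8, (180, 5))
        sol = select_K(gamma, K_range=range(2, 6), seed=0, n_restarts=2)
        assert sol.chosen_K == 3
        assert adjusted_rand_score(labels, sol.labels) >= 0.95

    def test_single_gaussian_cloud_prefers_smallest_K(self):
        rng = np.random.default_rng(12)
        gamma = rng.normal(0, 1.0, (150, 4))
        sol = select_K(gamma, K_range=range(2, 5), seed=0, n_restarts=2)
        assert sol.chosen_K == 2
        bic = sol.trace.groupby("K")["BIC"].max()
        assert bic.idxmax() == 2  # no larger K improves

    def test_trace_covers_all_fitted_pairs(self):
        gamma, _ = two_blob_gamma(n=60, seed=13)
        variants = ALL_VARIANTS[:3]
        sol = select_K(gamma, K_range=range(2, 4), variants=variants,
                       seed=0, n_restarts=1)
        assert set(sol.trace["K"]) == {2, 3}
        assert set(sol.trace["variant"]) <= {v.code for v in variants}
        assert {"AIC", "BIC", "ICL", "loglik", "m"} <= set(sol.trace.columns)
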