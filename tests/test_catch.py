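"""Estimation and prediction of the covariate-adjusted tensor discriminant."""

import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from radcatch import SimConfig, generate_model_exact
from radcatch.catch import (
    CatchError,
    CatchSettings,
    adjust_tensor,
    estimate_alpha,
    estimate_mode_covariances,
    fit_B,
    fit_catch,
    predict,
    rank_selected_features,
)
from radcatch._solver import cd_solve, lambda_path, penalized_objective
from radcatch.simulate import ar1_covariance
from radcatch.tensorize import FeatureIndexMap, tensorize_table


def _random_spd(rng, p):
    A = rng.standard_normal((p, p))
    return A @ A.T + p * np.eye(p)


def _labels(n1, n2):
    return np.r_[np.ones(n1, int), np.full(n2, 2)]


class TestAlpha:
    def test_noiseless_linear_system_recovered_exactly(self, rng):
        n, p1, p2, q = 50, 3, 4, 2
        alpha = rng.standard_normal((p1, p2, q))
        U = rng.standard_normal((n, q))
        X = np.einsum("ijl,nl->nij", alpha, U)
        est = estimate_alpha(X, U, _labels(25, 25))
        np.testing.assert_allclose(est, alpha, atol=1e-8)

    def test_scalar_case_matches_hand_ols(self, rng):
        """p1 = p2 = q = 1: alpha is the centered covariance/variance ratio."""
        n = 30
        labels = _labels(12, 18)
        u = rng.standard_normal(n)
        x = 0.7 * u + rng.standard_normal(n)
        X = x.reshape(n, 1, 1)
        est = estimate_alpha(X, u.reshape(n, 1), labels)
        uc, xc = u.copy(), x.copy()
        for k in (1, 2):
            m = labels == k
            uc[m] -= u[m].mean()
            xc[m] -= x[m].mean()
        assert est[0, 0, 0] == pytest.approx(np.dot(uc, xc) / np.dot(uc, uc))

    def test_null_alpha_estimates_within_simulation_noise(self, rng):
        n, p1, p2, q = 1000, 4, 4, 3
        U = rng.standard_normal((n, q))
        X = rng.standard_normal((n, p1, p2))
        est = estimate_alpha(X, U, _labels(500, 500))
        # each entry is approximately N(0, 1/n); allow 3 sigma with a
        # Bonferroni-ish margin over 48 entries
        assert np.abs(est).max() < 4.5 / np.sqrt(n)

    def test_rank_deficient_covariates_suggest_ridge(self, rng):
        n, q = 20, 3
        U = rng.standard_normal((n, q))
        U[:, 2] = U[:, 0]  # exact collinearity
        X = rng.standard_normal((n, 2, 2))
        with pytest.raises(CatchError, match="ridge"):
            estimate_alpha(X, U, _labels(10, 10))
        est = estimate_alpha(X, U, _labels(10, 10), ridge=1e-4)
        assert np.isfinite(est).all()


class TestAdjust:
    def test_zero_alpha_is_identity(self, rng):
        X = rng.standard_normal((5, 3, 3))
        U = rng.standard_normal((5, 2))
        np.testing.assert_array_equal(adjust_tensor(X, U, np.zeros((3, 3, 2))), X)

    def test_all_ones_alpha_subtracts_covariate(self):
        X = np.arange(4.0).reshape(1, 2, 2)
        out = adjust_tensor(X, np.array([[3.0]]), np.ones((2, 2, 1)))
        np.testing.assert_array_equal(out, X - 3.0)

    def test_adjustment_is_invertible(self, rng):
        X = rng.standard_normal((6, 3, 2))
        U = rng.standard_normal((6, 4))
        alpha = rng.standard_normal((3, 2, 4))
        back = adjust_tensor(X, U, alpha) + np.einsum("ijl,nl->nij", alpha, U)
        np.testing.assert_allclose(back, X, atol=1e-12)

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(CatchError, match="shape"):
            adjust_tensor(
                rng.standard_normal((5, 3, 3)),
                rng.standard_normal((5, 2)),
                rng.standard_normal((2, 3, 2)),
            )


class TestModeCovariances:
    @staticmethod
    def _tensor_normal(rng, n, S1, S2):
        L1, L2 = np.linalg.cholesky(S1), np.linalg.cholesky(S2)
        Z = rng.standard_normal((n, S1.shape[0], S2.shape[0]))
        return np.einsum("ij,njk,lk->nil", L1, Z, L2)

    def test_identity_truth_recovered(self, rng):
        n = 2000
        X = self._tensor_normal(rng, n, np.eye(5), np.eye(4))
        S1, S2 = estimate_mode_covariances(X, _labels(1000, 1000))
        assert np.linalg.norm(S1 - np.eye(5)) < 0.1
        assert np.linalg.norm(S2 - np.eye(4)) < 0.1

    def test_ar1_correlation_structure_recovered(self, rng):
        n = 2000
        T1, T2 = ar1_covariance(5, 0.5), ar1_covariance(4, 0.3)
        X = self._tensor_normal(rng, n, T1, T2)
        S1, S2 = estimate_mode_covariances(X, _labels(1000, 1000))

        def corr(S):
            d = np.sqrt(np.diag(S))
            return S / np.outer(d, d)

        assert np.abs(corr(S1) - T1).max() < 0.05
        assert np.abs(corr(S2) - T2).max() < 0.05

    def test_scale_identifiability_convention(self, rng):
        X = self._tensor_normal(rng, 100, 2.0 * np.eye(3), np.eye(3))
        S1, S2 = estimate_mode_covariances(X, _labels(50, 50))
        assert S1[0, 0] == pytest.approx(1.0)

    def test_degenerate_second_mode_reduces_to_pooled_variance(self, rng):
        n = 400
        x = rng.standard_normal((n, 3, 1)) * 1.7
        labels = _labels(200, 200)
        S1, S2 = estimate_mode_covariances(x, labels)
        # Sigma2 is scalar within-class variance; Sigma1 a correlation-like
        # matrix with the identifiability scale
        E = x[:, :, 0] - np.array([x[labels == k, :, 0].mean(axis=0) for k in (1, 2)])[
            (labels == 2).astype(int)
        ]
        pooled = (E[:, 0] ** 2).mean()
        assert S1[0, 0] == pytest.approx(1.0)
        assert S2[0, 0] * S1[0, 0] == pytest.approx(pooled, rel=0.05)


class TestFitB:
    def test_lambda_max_gives_exact_zero(self, rng):
        X = rng.standard_normal((20, 3, 3))
        labels = _labels(10, 10)
        D = X[:10].mean(axis=0) - X[10:].mean(axis=0)
        B = fit_B(X, labels, np.eye(3), np.eye(3), lam=np.abs(D).max())
        assert np.count_nonzero(B) == 0

    @pytest.mark.parametrize("shape", [(4, 3), (5, 5)])
    def test_tiny_penalty_matches_kronecker_solve(self, rng, shape):
        p1, p2 = shape
        S1, S2 = _random_spd(rng, p1), _random_spd(rng, p2)
        D = rng.standard_normal((p1, p2))
        B, _ = cd_solve(D, S1, S2, 1e-10, tol=1e-12)
        oracle = np.linalg.solve(S1, D) @ np.linalg.inv(S2)
        assert np.abs(B - oracle).max() < 1e-6

    def test_identity_covariance_is_entrywise_soft_threshold(self, rng):
        D = rng.standard_normal((4, 4))
        lam = 0.4
        B, _ = cd_solve(D, np.eye(4), np.eye(4), lam)
        np.testing.assert_allclose(
            B, np.sign(D) * np.maximum(np.abs(D) - lam, 0.0), atol=1e-12
        )

    def test_objective_non_increasing_over_sweeps(self, rng):
        S1, S2 = _random_spd(rng, 4), _random_spd(rng, 3)
        D = rng.standard_normal((4, 3))
        lam = 0.1 * np.abs(D).max()
        objs = []
        for k in range(1, 8):
            B, _ = cd_solve(D, S1, S2, lam, max_sweeps=k, tol=0.0)
            objs.append(penalized_objective(B, D, S1, S2, lam))
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_kkt_conditions_at_solution(self, rng):
        for _ in range(5):
            p1, p2 = rng.integers(2, 6), rng.integers(2, 6)
            S1, S2 = _random_spd(rng, p1), _random_spd(rng, p2)
            D = rng.standard_normal((p1, p2))
            lam = 0.3 * np.abs(D).max()
            B, _ = cd_solve(D, S1, S2, lam, tol=1e-12)
            grad = S1 @ B @ S2 - D
            zero = B == 0.0
            assert np.all(np.abs(grad[zero]) <= lam + 1e-6)
            np.testing.assert_allclose(grad[~zero], -lam * np.sign(B[~zero]), atol=1e-6)

    def test_warm_path_is_consistent_with_cold_solves(self, rng):
        S1, S2 = _random_spd(rng, 3), _random_spd(rng, 3)
        D = rng.standard_normal((3, 3))
        lams = lambda_path(D, 10, 0.05)
        B_warm = np.zeros_like(D)
        for lam in lams:
            B_warm, _ = cd_solve(D, S1, S2, lam, B0=B_warm, tol=1e-12)
            B_cold, _ = cd_solve(D, S1, S2, lam, tol=1e-12)
            np.testing.assert_allclose(B_warm, B_cold, atol=1e-8)


def _scalar_lda_oracle(x_train, labels, grid):
    """Plug-in univariate LDA with MLE pooled variance, priors from counts."""
    m1 = x_train[labels == 1].mean()
    m2 = x_train[labels == 2].mean()
    resid = np.where(labels == 1, x_train - m1, x_train - m2)
    var = np.mean(resid**2)
    pi1 = np.mean(labels == 1)
    s = np.log(pi1 / (1 - pi1)) + (m1 - m2) / var * grid - (m1**2 - m2**2) / (2 * var)
    return np.where(s > 0, 1, 2)


class TestFitCatch:
    def test_scalar_no_covariate_fit_equals_closed_form_lda(self, rng):
        n = 40
        labels = _labels(15, 25)
        x = np.where(labels == 1, 1.3, 0.0) + rng.standard_normal(n)
        model = fit_catch(
            x.reshape(n, 1, 1), None, labels,
            settings=CatchSettings(lambda_rule="fixed", fixed_lambda=1e-10),
        )
        grid = rng.uniform(-4, 4, size=200)
        _, classes, _ = predict(model, grid.reshape(-1, 1, 1))
        np.testing.assert_array_equal(classes, _scalar_lda_oracle(x, labels, grid))

    def test_support_recovery_on_model_exact_data(self):
        hits = 0
        for seed in range(3):
            config = SimConfig(
                n=600, p1=8, p2=8, n_features=64, q=5, g_total=20, g_de=5,
                s_true=5, b_scale=0.8, alpha_scale=0.3, alpha_links=10,
                gamma_scale=1.0, prevalence=0.4, exact_prevalence=True,
                seed=100 + seed,
            )
            bundle, truth = generate_model_exact(config)
            stack = tensorize_table(bundle.radiomics, 8, 8)
            model = fit_catch(
                stack.values, truth.U, truth.labels,
                settings=CatchSettings(lambda_rule="sparsity", s_target=5),
            )
            est = {(int(i), int(j)) for i, j in np.argwhere(model.B != 0)}
            hits += est == truth.support()
        assert hits >= 2

    def test_permuted_labels_give_chance_level_auc(self, small_model_exact):
        config, bundle, truth, stack = small_model_exact
        rng = np.random.default_rng(1)
        labels = rng.permutation(truth.labels)
        tr, te = np.arange(0, 150), np.arange(150, 200)
        model = fit_catch(
            stack.values[tr], truth.U[tr], labels[tr],
            settings=CatchSettings(lambda_rule="sparsity", s_target=3),
        )
        scores, _, _ = predict(model, stack.values[te], truth.U[te])
        auc = roc_auc_score(labels[te] == 1, scores)
        assert 0.3 < auc < 0.7

    def test_covariate_only_signal_is_not_forced_into_tensor(self):
        """With B_true = 0 the covariate term alone must carry the signal."""
        config = SimConfig(
            n=400, p1=5, p2=4, n_features=20, q=4, g_total=10, g_de=4,
            s_true=0, b_scale=0.0, alpha_scale=0.0, alpha_links=0,
            gamma_scale=2.0, prevalence=0.4, exact_prevalence=True, seed=9,
        )
        bundle, truth = generate_model_exact(config)
        stack = tensorize_table(bundle.radiomics, 5, 4)
        tr, te = np.arange(300), np.arange(300, 400)
        model = fit_catch(
            stack.values[tr], truth.U[tr], truth.labels[tr],
            settings=CatchSettings(lambda_rule="cv", cv_seed=0),
        )
        scores, _, _ = predict(model, stack.values[te], truth.U[te])
        assert roc_auc_score(truth.labels[te] == 1, scores) > 0.8

    def test_gamma_recovers_sign_and_strong_entries(self, small_model_exact):
        config, bundle, truth, stack = small_model_exact
        model = fit_catch(
            stack.values, truth.U, truth.labels,
            settings=CatchSettings(lambda_rule="sparsity", s_target=3),
        )
        strong = np.abs(truth.gamma_true) > 0.1
        assert np.all(np.sign(model.gamma[strong]) == np.sign(truth.gamma_true[strong]))

    def test_single_class_and_excess_covariates_rejected(self, rng):
        X = rng.standard_normal((10, 2, 2))
        with pytest.raises(CatchError):
            fit_catch(X, None, np.ones(10, int))
        with pytest.raises(CatchError, match="fewer covariates"):
            fit_catch(X, rng.standard_normal((10, 12)), _labels(5, 5))

    def test_json_round_trip(self, small_model_exact, tmp_path):
        from radcatch.catch import CatchModel

        config, bundle, truth, stack = small_model_exact
        model = fit_catch(
            stack.values, truth.U, truth.labels,
            settings=CatchSettings(lambda_rule="sparsity", s_target=3),
            index_map=stack.index_map,
        )
        path = tmp_path / "model.json"
        model.to_json(path)
        back = CatchModel.from_json(path)
        np.testing.assert_allclose(back.B, model.B)
        np.testing.assert_allclose(back.gamma, model.gamma)
        assert back.index_map == model.index_map
        s1, _, _ = predict(model, stack.values[:5], truth.U[:5])
        s2, _, _ = predict(back, stack.values[:5], truth.U[:5])
        np.testing.assert_allclose(s1, s2)


class TestPredict:
    @staticmethod
    def _null_model(pi1=0.5):
        from radcatch.catch import CatchModel

        return CatchModel(
            alpha=np.zeros((2, 2, 0)), gamma=np.zeros(0), B=np.zeros((2, 2)),
            intercept=float(np.log(pi1 / (1 - pi1))), pi1=pi1, pi2=1 - pi1,
            phi1=np.zeros(0), phi2=np.zeros(0), psi=np.zeros((0, 0)),
            mu1=np.zeros((2, 2)), mu2=np.zeros((2, 2)),
            sigma1=np.eye(2), sigma2=np.eye(2), lam=1.0,
        )

    def test_symmetric_null_scores_half_posterior(self, rng):
        model = self._null_model()
        scores, classes, post = predict(model, rng.standard_normal((7, 2, 2)))
        np.testing.assert_array_equal(scores, 0.0)
        np.testing.assert_array_equal(post, 0.5)
        np.testing.assert_array_equal(classes, 2)  # ties -> non-recurrent

    def test_prior_shift_moves_scores_affinely(self, rng):
        X = rng.standard_normal((5, 2, 2))
        base = self._null_model()
        shifted = self._null_model()
        shifted.intercept = base.intercept + 0.75
        s0, _, _ = predict(base, X)
        s1, _, _ = predict(shifted, X)
        np.testing.assert_allclose(s1 - s0, 0.75)

    def test_posterior_monotone_in_score(self, small_model_exact):
        config, bundle, truth, stack = small_model_exact
        model = fit_catch(
            stack.values, truth.U, truth.labels,
            settings=CatchSettings(lambda_rule="sparsity", s_target=3),
        )
        scores, _, post = predict(model, stack.values, truth.U)
        order = np.argsort(scores)
        assert (np.diff(post[order]) >= 0).all()
        assert ((post > 0) & (post < 1)).all()


class TestRanking:
    def test_extreme_coefficients_ranked_with_signs(self):
        model = TestPredict._null_model()
        model.B = np.array([[6.57, 0.0], [0.0, -5.71]])
        model.index_map = FeatureIndexMap(("fA", "fB", "fC", "fD"), 2, 2)
        ranking = rank_selected_features(model)
        assert list(ranking["feature_name"]) == ["fA", "fD"]
        assert list(ranking["coefficient"]) == [6.57, -5.71]

    def test_zero_tensor_gives_empty_ranking(self):
        ranking = rank_selected_features(TestPredict._null_model())
        assert len(ranking) == 0

    def test_ranking_length_equals_nonzero_count(self, rng):
        for _ in range(5):
            model = TestPredict._null_model()
            B = rng.standard_normal((2, 2))
            B[rng.random((2, 2)) < 0.5] = 0.0
            model.B = B
            assert len(rank_selected_features(model)) == np.count_nonzero(B)
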