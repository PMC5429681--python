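"""QIF estimation: bases, unbalanced-panel selectors, objective, fit, SEs."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from conftest import make_binary_design
from pqifgene.qif import (
    LongitudinalDesign,
    QIFError,
    basis_matrices,
    extended_score,
    extended_scores,
    fit_qif,
    qif_objective,
    qif_stderr,
    transformation_matrix,
)


class TestBasisMatrices:
    def test_independent_is_identity_only(self):
        b = basis_matrices("independent", 3)
        assert b.matrices == [] and b.n_blocks == 1

    def test_exchangeable_t2(self):
        b = basis_matrices("exchangeable", 2)
        np.testing.assert_array_equal(b.matrices[0], [[0, 1], [1, 0]])

    def test_ar1_t3_tridiagonal(self):
        b = basis_matrices("ar1", 3)
        np.testing.assert_array_equal(
            b.matrices[0], [[0, 1, 0], [1, 0, 1], [0, 1, 0]]
        )

    def test_symmetry_and_errors(self):
        for s in ("ar1", "exchangeable"):
            m = basis_matrices(s, 5).matrices[0]
            np.testing.assert_array_equal(m, m.T)
        with pytest.raises(ValueError):
            basis_matrices("toeplitz", 3)
        with pytest.raises(ValueError):
            basis_matrices("ar1", 1)


class TestTransformationMatrix:
    def test_full_mask_is_identity(self):
        np.testing.assert_array_equal(transformation_matrix({1, 2, 3}, 3), np.eye(3))

    def test_third_visit_missing(self):
        np.testing.assert_array_equal(
            transformation_matrix({1, 2}, 3), [[1, 0, 0], [0, 1, 0]]
        )

    def test_single_visit(self):
        np.testing.assert_array_equal(transformation_matrix({2}, 3), [[0, 1, 0]])

    def test_empty_mask_signalled(self):
        with pytest.raises(QIFError):
            transformation_matrix(set(), 3)


class TestExtendedScore:
    def test_zero_residual_gives_zero_score(self):
        # identity link lets the response equal the fitted mean exactly
        rng = np.random.default_rng(0)
        n, T = 6, 3
        X = np.concatenate([np.ones((n, T, 1)), rng.normal(size=(n, T, 1))], axis=2)
        beta = np.array([0.3, -0.2])
        d = LongitudinalDesign(
            y=X @ beta, X=X, mask=np.ones((n, T), bool),
            columns=["intercept", "x"], link="identity",
        )
        psi = extended_scores(d, basis_matrices("ar1", T), beta)
        np.testing.assert_allclose(psi, 0.0, atol=1e-14)

    def test_t1_reduces_to_logistic_score(self):
        rng = np.random.default_rng(1)
        n = 10
        X = np.concatenate([np.ones((n, 1, 1)), rng.normal(size=(n, 1, 1))], axis=2)
        beta = np.array([0.1, 0.4])
        mu = 1 / (1 + np.exp(-(X @ beta)))
        y = (rng.random((n, 1)) < mu).astype(float)
        d = LongitudinalDesign(y=y, X=X, mask=np.ones((n, 1), bool),
                               columns=["intercept", "x"])
        psi = extended_scores(d, basis_matrices("independent", 1), beta)
        expected = X[:, 0, :] * (y - mu)[:, 0, None]
        np.testing.assert_allclose(psi, expected, rtol=1e-12)

    def test_unbalanced_matches_explicit_h_reduction(self):
        """The masked computation equals applying H_i to the padded quantities."""
        rng = np.random.default_rng(2)
        n, T = 5, 3
        X = np.concatenate([np.ones((n, T, 1)), rng.normal(size=(n, T, 2))], axis=2)
        beta = np.array([0.2, 0.5, -0.3])
        mu = 1 / (1 + np.exp(-(X @ beta)))
        y = (rng.random((n, T)) < mu).astype(float)
        mask = np.ones((n, T), bool)
        mask[0, 2] = False          # subject 0 misses visit 3
        mask[1, 0] = False          # subject 1 misses visit 1
        y = np.where(mask, y, np.nan)
        d = LongitudinalDesign(y=y, X=X, mask=mask,
                               columns=["intercept", "x1", "x2"])
        basis = basis_matrices("ar1", T)
        M = basis.matrices[0]
        for i in range(n):
            H = transformation_matrix(np.flatnonzero(mask[i]) + 1, T)
            Xi, mui = X[i], mu[i]
            Ai = np.diag(mui * (1 - mui))
            mudot = Ai @ Xi
            ys, mus, mudots = H @ np.nan_to_num(y[i]), H @ mui, H @ mudot
            As = H @ Ai @ H.T
            Asr = np.linalg.inv(np.sqrt(As))
            Ms = H @ M @ H.T
            expected = np.concatenate([
                mudots.T @ np.linalg.inv(As) @ (ys - mus),
                mudots.T @ Asr @ Ms @ Asr @ (ys - mus),
            ])
            np.testing.assert_allclose(
                extended_score(d, basis, beta, i), expected, rtol=1e-10
            )

    def test_degenerate_fitted_mean_errors_with_subject(self):
        d, beta = make_binary_design(seed=3, n=5, p=2)
        with pytest.raises(QIFError, match="subject"):
            extended_scores(d, basis_matrices("ar1", 3), np.array([50.0, 50.0]))


class TestObjective:
    def test_zero_at_perfect_fit(self):
        rng = np.random.default_rng(4)
        n, T = 8, 2
        X = np.concatenate([np.ones((n, T, 1)), rng.normal(size=(n, T, 1))], axis=2)
        beta = np.array([0.1, 0.2])
        d = LongitudinalDesign(y=X @ beta, X=X, mask=np.ones((n, T), bool),
                               columns=["intercept", "x"], link="identity")
        assert qif_objective(d, basis_matrices("independent", T), beta) == pytest.approx(0.0, abs=1e-16)

    def test_nonnegative(self, small_design):
        basis = basis_matrices("exchangeable", 3)
        rng = np.random.default_rng(5)
        for _ in range(5):
            beta = rng.normal(scale=0.3, size=small_design.p)
            assert qif_objective(small_design, basis, beta) >= 0.0

    def test_matches_hand_quadratic_form(self):
        """n=2 subjects, T=1, identity link: psi_i = x_i (y_i - x_i b)."""
        X = np.array([[[1.0]], [[2.0]]])
        y = np.array([[1.0], [1.0]])
        d = LongitudinalDesign(y=y, X=X, mask=np.ones((2, 1), bool),
                               columns=["x"], link="identity")
        b = np.array([0.25])
        psi = np.array([1 * (1 - 0.25), 2 * (1 - 0.5)])        # (0.75, 1.0)
        cbar = np.mean(psi**2)
        expected = np.mean(psi) ** 2 / cbar
        got = qif_objective(d, basis_matrices("independent", 1), b)
        assert got == pytest.approx(expected, rel=1e-6)

    def test_invariance_under_relabeling_and_column_reordering(self):
        d, beta = make_binary_design(seed=6, n=40, p=3)
        basis = basis_matrices("ar1", 3)
        q0 = qif_objective(d, basis, beta)
        rng = np.random.default_rng(7)
        perm = rng.permutation(d.n)
        d_perm = LongitudinalDesign(y=d.y[perm], X=d.X[perm], mask=d.mask[perm],
                                    columns=d.columns)
        assert qif_objective(d_perm, basis, beta) == pytest.approx(q0, rel=1e-12)
        cperm = [0, 2, 1]
        d_cols = LongitudinalDesign(y=d.y, X=d.X[:, :, cperm], mask=d.mask,
                                    columns=[d.columns[j] for j in cperm])
        assert qif_objective(d_cols, basis, beta[cperm]) == pytest.approx(q0, rel=1e-12)


class TestFitQif:
    @pytest.mark.parametrize("seed", range(5))
    def test_independence_equals_pooled_logistic(self, seed):
        d, _ = make_binary_design(seed=seed, n=70, p=3)
        fit = fit_qif(d, basis_matrices("independent", 3), init=np.zeros(3))
        ref = sm.Logit(d.y.reshape(-1), d.X.reshape(-1, 3)).fit(disp=0, tol=1e-10)
        np.testing.assert_allclose(fit.beta, np.asarray(ref.params), atol=1e-6)

    def test_ar1_recovery_within_mc_error(self):
        """Parameter recovery on correlated binary panels."""
        truth = np.array([0.2, 0.6, -0.5])
        reps = 15
        est = []
        for r in range(reps):
            d, _ = make_binary_design(seed=100 + r, n=300, p=3, beta=truth, rho=0.4)
            est.append(fit_qif(d, basis_matrices("ar1", 3)).beta)
        est = np.array(est)
        se = est.std(axis=0, ddof=1) / np.sqrt(reps)
        np.testing.assert_array_less(np.abs(est.mean(axis=0) - truth), 3 * se + 1e-12)

    def test_misspecified_working_structure_still_consistent(self):
        # data exchangeable, fitted with the AR(1) basis
        truth = np.array([0.0, 0.5, -0.5])
        est = []
        for r in range(10):
            d, _ = make_binary_design(seed=300 + r, n=300, p=3, beta=truth, rho=0.5)
            est.append(fit_qif(d, basis_matrices("ar1", 3)).beta)
        est = np.array(est)
        se = est.std(axis=0, ddof=1) / np.sqrt(len(est))
        np.testing.assert_array_less(np.abs(est.mean(axis=0) - truth), 3 * se + 1e-12)

    def test_chi_square_scale_at_truth(self):
        """n Q_n at the generating beta has mean ~ rank(psi) - 0 over replicates."""
        truth = np.array([0.1, 0.4, -0.3])
        basis = basis_matrices("ar1", 3)
        vals = []
        for r in range(20):
            d, _ = make_binary_design(seed=500 + r, n=250, p=3, beta=truth, rho=0.3)
            vals.append(d.n * qif_objective(d, basis, truth))
        vals = np.array(vals)
        dim = 2 * 3  # (1+S) p moment conditions
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - dim) < 3 * se

    def test_unbalanced_panel_fits(self):
        d, beta = make_binary_design(seed=8, n=120, p=3)
        mask = d.mask.copy()
        rng = np.random.default_rng(9)
        drop = rng.random((d.n, d.T)) < 0.2
        drop[:, 0] = False
        mask &= ~drop
        du = LongitudinalDesign(y=np.where(mask, d.y, np.nan), X=d.X, mask=mask,
                                columns=d.columns)
        fit = fit_qif(du, basis_matrices("ar1", 3))
        assert fit.converged
        assert np.all(np.abs(fit.beta - beta) < 1.0)


class TestStderr:
    def test_independent_close_to_logistic_model_se(self):
        d, _ = make_binary_design(seed=21, n=400, p=3)
        basis = basis_matrices("independent", 3)
        fit = fit_qif(d, basis)
        se = qif_stderr(fit, d, basis)
        ref = sm.Logit(d.y.reshape(-1), d.X.reshape(-1, 3)).fit(disp=0)
        np.testing.assert_allclose(se, np.asarray(ref.bse), rtol=0.10)

    def test_intercept_only_matches_binomial_closed_form(self):
        """Independence truth: SE(logit-hat) ~ sqrt(1 / (n T mu (1-mu)))."""
        rng = np.random.default_rng(23)
        n, T = 500, 3
        y = (rng.random((n, T)) < 0.4).astype(float)
        d = LongitudinalDesign(y=y, X=np.ones((n, T, 1)),
                               mask=np.ones((n, T), bool), columns=["intercept"])
        basis = basis_matrices("independent", T)
        fit = fit_qif(d, basis)
        se = qif_stderr(fit, d, basis)[0]
        mu_hat = y.mean()
        closed = np.sqrt(1.0 / (n * T * mu_hat * (1 - mu_hat)))
        assert se == pytest.approx(closed, rel=0.05)

    def test_duplicating_subjects_shrinks_se_by_sqrt2(self):
        d, _ = make_binary_design(seed=22, n=100, p=3)
        basis = basis_matrices("ar1", 3)
        fit = fit_qif(d, basis)
        se1 = qif_stderr(fit, d, basis)
        d2 = LongitudinalDesign(
            y=np.vstack([d.y, d.y]), X=np.vstack([d.X, d.X]),
            mask=np.vstack([d.mask, d.mask]), columns=d.columns,
        )
        fit2 = fit_qif(d2, basis, init=fit.beta)
        se2 = qif_stderr(fit2, d2, basis)
        np.testing.assert_allclose(se2, se1 / np.sqrt(2), rtol=1e-6)


class TestFromLong:
    def test_roundtrip_and_standardization(self):
        rng = np.random.default_rng(30)
        rows = []
        for i in range(20):
            for t in (1, 2, 3):
                if i == 0 and t == 3:
                    continue  # a missing visit
                rows.append({"subject_id": f"s{i}", "visit": t,
                             "response": int(rng.random() < 0.5),
                             "age": 50 + rng.normal(), "score": rng.normal()})
        df = pd.DataFrame(rows)
        d = LongitudinalDesign.from_long(df)
        assert d.n == 20 and d.T == 3 and d.p == 3
        assert not d.mask[0, 2] and d.mask[1, 2]
        obs_cov = d.X[d.mask][:, 1:]
        np.testing.assert_allclose(obs_cov.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(obs_cov.std(axis=0), 1.0, atol=1e-10)
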