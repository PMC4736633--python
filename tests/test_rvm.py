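"""Sparse Bayesian RVM: kernels, posterior, hyperparameter loop, prediction."""

import numpy as np
import pytest

from toxqsar import rvm, synthdata
from toxqsar.rvm import (
    KernelSpec,
    RVMOptions,
    build_design_matrix,
    fit,
    hyperparameter_step,
    kernel_eval,
    load_model,
    posterior_update,
    predict,
    save_model,
)


def _marginal_log_likelihood(Phi, t, alpha, beta):
    """Direct log-determinant evaluation of the marginal likelihood (oracle)."""
    n = len(t)
    C = np.eye(n) / beta + Phi @ np.diag(1.0 / alpha) @ Phi.T
    sign, logdet = np.linalg.slogdet(C)
    assert sign > 0
    return -0.5 * (n * np.log(2 * np.pi) + logdet + t @ np.linalg.solve(C, t))


class TestKernels:
    def test_zero_distance_is_one(self):
        for family in ("laplacian", "rbf"):
            spec = KernelSpec(family, 0.7)
            x = np.array([1.0, -2.0, 3.0])
            assert kernel_eval(spec, x, x) == pytest.approx(1.0)

    def test_divide_form_at_one_width(self):
        spec = KernelSpec("laplacian", 2.0, "divide")
        assert kernel_eval(spec, [0.0], [2.0]) == pytest.approx(np.exp(-1))

    def test_multiply_form_documented_width(self):
        spec = KernelSpec("laplacian", 0.044, "multiply")
        assert kernel_eval(spec, [0.0], [1.0]) == pytest.approx(0.95695, abs=1e-4)

    def test_symmetry_and_range(self, rng):
        spec = KernelSpec("laplacian", 0.3)
        x, y = rng.standard_normal(5), rng.standard_normal(5)
        k = kernel_eval(spec, x, y)
        assert k == pytest.approx(kernel_eval(spec, y, x))
        assert 0 < k <= 1

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimension"):
            kernel_eval(KernelSpec(), [1.0, 2.0], [1.0])


class TestDesignMatrix:
    def test_shape_and_bias_column(self):
        X = np.array([[0.0], [1.0]])
        phi = build_design_matrix(X, KernelSpec())
        assert phi.shape == (2, 3)
        assert (phi[:, 0] == 1.0).all()

    def test_self_similarity_diagonal(self, rng):
        X = rng.standard_normal((6, 3))
        phi = build_design_matrix(X, KernelSpec("laplacian", 0.5))
        assert np.allclose(np.diag(phi[:, 1:]), 1.0)

    def test_matches_double_loop_oracle(self, rng):
        X = rng.standard_normal((5, 2))
        spec = KernelSpec("rbf", 0.8, "divide")
        phi = build_design_matrix(X, spec)
        for i in range(5):
            for j in range(5):
                assert phi[i, j + 1] == pytest.approx(
                    kernel_eval(spec, X[i], X[j]), abs=1e-12
                )


class TestPosterior:
    def test_scalar_case_by_hand(self):
        Sigma, mu = posterior_update(np.array([[1.0]]), np.array([2.0]), [1.0], 1.0)
        assert Sigma[0, 0] == pytest.approx(0.5)
        assert mu[0] == pytest.approx(1.0)

    def test_matches_dense_solve_oracle(self, rng):
        Phi = rng.standard_normal((10, 5))
        t = rng.standard_normal(10)
        alpha = rng.uniform(0.1, 2.0, 5)
        beta = 1.7
        Sigma, mu = posterior_update(Phi, t, alpha, beta)
        H = beta * Phi.T @ Phi + np.diag(alpha)
        mu_ref = np.linalg.solve(H, beta * Phi.T @ t)
        assert np.allclose(mu, mu_ref, atol=1e-8)
        assert np.allclose(Sigma @ H, np.eye(5), atol=1e-7)
        # symmetric positive definite
        assert np.allclose(Sigma, Sigma.T)
        assert (np.linalg.eigvalsh(Sigma) > 0).all()

    def test_huge_alpha_kills_weight(self, rng):
        Phi = rng.standard_normal((8, 3))
        t = rng.standard_normal(8)
        alpha = np.array([1.0, 1e12, 1.0])
        _, mu = posterior_update(Phi, t, alpha, 2.0)
        assert abs(mu[1]) < 1e-6

    def test_nonpositive_hyperparameters_rejected(self):
        with pytest.raises(ValueError):
            posterior_update(np.eye(2), np.ones(2), [1.0, -1.0], 1.0)


class TestHyperparameterStep:
    def test_scalar_case_by_hand(self):
        Phi = np.array([[1.0]])
        t = np.array([2.0])
        Sigma, mu = posterior_update(Phi, t, [1.0], 1.0)
        alpha_new, beta_new, gamma = hyperparameter_step(mu, Sigma, np.array([1.0]), 1.0, t, Phi)
        assert gamma[0] == pytest.approx(0.5)  # 1 - 1*0.5
        assert alpha_new[0] == pytest.approx(0.5)  # 0.5 / 1^2

    def test_beta_denominator_is_residual_sum_of_squares(self, rng):
        Phi = rng.standard_normal((12, 4))
        t = rng.standard_normal(12)
        alpha = rng.uniform(0.5, 2.0, 4)
        beta = 1.3
        Sigma, mu = posterior_update(Phi, t, alpha, beta)
        alpha_new, beta_new, gamma = hyperparameter_step(mu, Sigma, alpha, beta, t, Phi)
        resid = float(np.sum((t - Phi @ mu) ** 2))
        assert beta_new == pytest.approx((12 - gamma.sum()) / resid)
        assert ((gamma >= 0) & (gamma <= 1)).all()
        assert (alpha_new > 0).all()

    def test_zero_residual_clamps_beta(self):
        Phi = np.eye(3)
        t = np.array([1.0, 2.0, 3.0])
        mu = t.copy()  # perfect fit
        Sigma = 1e-12 * np.eye(3)
        _, beta_new, _ = hyperparameter_step(mu, Sigma, np.ones(3), 1.0, t, Phi)
        assert beta_new >= 1e6


class TestFit:
    def test_constant_target_predicts_constant(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((30, 2))
        t = np.full(30, 3.7)
        model = fit(X, t, KernelSpec("laplacian", 0.5))
        mean, _ = predict(model, rng.standard_normal((10, 2)))
        assert np.allclose(mean, 3.7, atol=1e-6)

    def test_sinc_accuracy_and_sparsity(self):
        X, t = synthdata.gen_sinc(100, 0.05, seed=3)
        model = fit(X, t, KernelSpec("rbf", 0.5, "divide"))
        Xte, tte = synthdata.gen_sinc(400, 0.0, seed=103)
        mean, _ = predict(model, Xte)
        assert np.sqrt(np.mean((mean - tte) ** 2)) <= 0.10
        assert model.n_relevance_vectors <= 0.3 * 100

    def test_deterministic_refits(self):
        X, t = synthdata.gen_sinc(60, 0.05, seed=9)
        m1 = fit(X, t, KernelSpec("rbf", 0.5, "divide"))
        m2 = fit(X, t, KernelSpec("rbf", 0.5, "divide"))
        assert (m1.basis_idx == m2.basis_idx).all()
        assert np.array_equal(m1.mu, m2.mu)
        assert m1.beta == m2.beta

    def test_sparsity_monotone_and_marginal_likelihood_improves(self):
        X, t = synthdata.gen_sinc(80, 0.05, seed=5)
        spec = KernelSpec("rbf", 0.5, "divide")
        model = fit(X, t, spec)
        assert model.n_relevance_vectors + 1 <= 81
        # recompute ML at iteration-1 vs final hyperparameters (oracle)
        Xs = (X - model.x_mean) / model.x_scale
        Phi = build_design_matrix(Xs, spec)
        n = len(t)
        alpha0 = np.full(n + 1, 1.0 / n**2)
        beta0 = 1.0 / (0.1 * np.var(t))
        ml_start = _marginal_log_likelihood(Phi, t, alpha0, beta0)
        Phi_final = Phi[:, model.basis_idx]
        ml_final = _marginal_log_likelihood(Phi_final, t, model.alpha, model.beta)
        assert ml_final >= ml_start

    def test_standardization_contract(self):
        X, t = synthdata.gen_sinc(50, 0.05, seed=11)
        X_scaled = (X - X.mean()) / X.std()
        spec = KernelSpec("rbf", 0.5, "divide")
        m_auto = fit(X, t, spec, RVMOptions(standardize=True))
        m_pre = fit(X_scaled, t, spec, RVMOptions(standardize=False))
        p_auto, _ = predict(m_auto, X)
        p_pre, _ = predict(m_pre, X_scaled)
        assert np.allclose(p_auto, p_pre, atol=1e-8)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit(np.array([[1.0]]), np.array([1.0]))


class TestPredict:
    def test_variance_at_least_noise_floor(self):
        X, t = synthdata.gen_sinc(60, 0.05, seed=2)
        model = fit(X, t, KernelSpec("rbf", 0.5, "divide"))
        _, var = predict(model, np.linspace(-12, 12, 50)[:, None])
        assert (var >= 1.0 / model.beta - 1e-12).all()

    def test_training_points_reproduced_within_noise(self):
        X, t = synthdata.gen_sinc(80, 0.05, seed=7)
        model = fit(X, t, KernelSpec("rbf", 0.5, "divide"))
        mean, _ = predict(model, X)
        sd = 1.0 / np.sqrt(model.beta)
        assert np.mean(np.abs(mean - t) < 3 * sd) > 0.95

    def test_dimension_mismatch_raises(self):
        X, t = synthdata.gen_sinc(20, 0.05, seed=1)
        model = fit(X, t)
        with pytest.raises(ValueError, match="dimension"):
            predict(model, np.ones((3, 2)))


class TestSerialization:
    def test_bit_exact_roundtrip(self, tmp_path):
        X, t = synthdata.gen_sinc(40, 0.05, seed=4)
        model = fit(X, t, KernelSpec("rbf", 0.5, "divide"))
        path = tmp_path / "model.json"
        save_model(model, path)
        back = load_model(path)
        assert np.array_equal(back.mu, model.mu)
        assert np.array_equal(back.Sigma, model.Sigma)
        assert np.array_equal(back.alpha, model.alpha)
        assert back.beta == model.beta
        assert (back.basis_idx == model.basis_idx).all()
        Xq = np.linspace(-10, 10, 17)[:, None]
        assert np.array_equal(predict(back, Xq)[0], predict(model, Xq)[0])

    def test_version_check(self, tmp_path):
        path = tmp_path / "bad.json"
        path.write_text('{"format_version": 99}')
        with pytest.raises(ValueError, match="format"):
            load_model(path)
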