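import numpy as np
import pytest

from dracp import (
    KernelSpec,
    classify_rvm,
    design_matrix,
    fit_rvm,
    gaussian_kernel,
    predict_rvm,
)
from dracp.rvm import RVMModel, posterior_stats


def make_blobs(rng, n_per_class=40, sep=4.0):
    X = np.vstack(
        [rng.normal(0.0, 1.0, size=(n_per_class, 2)),
         rng.normal(sep, 1.0, size=(n_per_class, 2))]
    )
    t = np.r_[np.zeros(n_per_class), np.ones(n_per_class)]
    return X, t


class TestKernel:
    def test_self_similarity_is_one(self, rng):
        x = rng.standard_normal(5)
        assert gaussian_kernel(x, x) == 1.0

    def test_monotone_decay_with_distance(self):
        x = np.zeros(2)
        values = [gaussian_kernel(x, np.array([d, 0.0])) for d in (1, 2, 5, 10, 50)]
        assert all(a > b for a, b in zip(values, values[1:]))
        assert values[-1] < 1e-10

    def test_hand_evaluated_example(self):
        # ||(0,0)-(3,4)||^2 = 25; width 6 -> exp(-25/36)
        got = gaussian_kernel(np.array([0.0, 0.0]), np.array([3.0, 4.0]), width=6)
        assert got == pytest.approx(np.exp(-25 / 36))

    def test_invalid_width(self):
        with pytest.raises(ValueError):
            gaussian_kernel(np.zeros(2), np.ones(2), width=0.0)
        with pytest.raises(ValueError):
            KernelSpec(width=-1.0)


class TestDesignMatrix:
    def test_single_training_point_self_query(self):
        x = np.array([[1.5, 2.5]])
        Phi = design_matrix(x, x, KernelSpec())
        np.testing.assert_allclose(Phi, [[1.0, 1.0]])

    def test_structure_bias_column_first(self, rng):
        X = rng.standard_normal((6, 3))
        Phi = design_matrix(X, X, KernelSpec())
        assert Phi.shape == (6, 7)
        np.testing.assert_array_equal(Phi[:, 0], 1.0)

    def test_entries_match_pairwise_kernel_oracle(self, rng):
        X = rng.standard_normal((3, 2))
        Q = rng.standard_normal((4, 2))
        spec = KernelSpec(width=2.5)
        Phi = design_matrix(X, Q, spec)
        for i in range(4):
            for j in range(3):
                assert Phi[i, j + 1] == pytest.approx(
                    gaussian_kernel(Q[i], X[j], width=2.5)
                )

    def test_empty_training_set_rejected(self):
        with pytest.raises(ValueError):
            design_matrix(np.empty((0, 2)), np.zeros((1, 2)), KernelSpec())


class TestPosterior:
    def test_matches_independent_ridge_solve(self, rng):
        # N=5: (mu, Sigma) from the update must equal the closed form
        # (sigma^-2 Phi'Phi + diag(alpha))^-1 computed by an independent solver.
        X = rng.standard_normal((5, 2))
        t = rng.standard_normal(5)
        Phi = design_matrix(X, X, KernelSpec(width=2.0))
        alpha = rng.uniform(0.5, 2.0, size=6)
        sigma2 = 0.3
        mu, Sigma = posterior_stats(Phi, t, alpha, sigma2, jitter=0.0)
        H = Phi.T @ Phi / sigma2 + np.diag(alpha)
        Sigma_ref = np.linalg.inv(H)
        mu_ref = Sigma_ref @ Phi.T @ t / sigma2
        np.testing.assert_allclose(Sigma, Sigma_ref, atol=1e-10)
        np.testing.assert_allclose(mu, mu_ref, atol=1e-10)

    def test_fixed_alpha_limit_equals_kernel_ridge(self, rng):
        # With a single shared alpha and no pruning, the posterior mean is
        # ridge regression on the kernel design with penalty alpha*sigma^2.
        X = rng.standard_normal((12, 2))
        t = rng.standard_normal(12)
        Phi = design_matrix(X, X, KernelSpec(width=2.0))
        alpha, sigma2 = 2.0, 0.5
        mu, _ = posterior_stats(Phi, t, np.full(13, alpha), sigma2, jitter=0.0)
        lam = alpha * sigma2
        w_ridge = np.linalg.solve(Phi.T @ Phi + lam * np.eye(13), Phi.T @ t)
        np.testing.assert_allclose(Phi @ mu, Phi @ w_ridge, atol=1e-8)


class TestFitRVM:
    def test_constant_targets_recovered_by_bias(self, rng):
        X = rng.standard_normal((20, 2))
        t = np.full(20, 0.7)
        model = fit_rvm(X, t)
        mean, _ = predict_rvm(model, rng.standard_normal((10, 2)) * 3)
        np.testing.assert_allclose(mean, 0.7, atol=1e-3)

    def test_sinc_recovery_sparse_and_accurate(self):
        x = np.linspace(-10, 10, 100)[:, None]
        t = np.sinc(x.ravel() / np.pi)  # sin(x)/x
        model = fit_rvm(x, t, kernel=KernelSpec(width=3.0))
        xq = np.linspace(-10, 10, 211)[:, None]
        mean, _ = predict_rvm(model, xq)
        rmse = np.sqrt(np.mean((mean - np.sinc(xq.ravel() / np.pi)) ** 2))
        assert rmse < 0.05
        assert model.n_relevance_vectors < 50

    def test_separable_blobs_perfect_training_accuracy(self, rng):
        X, t = make_blobs(rng)
        model = fit_rvm(X, t, kernel=KernelSpec(width=2.0))
        labels, _ = classify_rvm(model, X)
        assert (labels == t).all()

    def test_identical_inputs_fall_back_to_bias_only(self):
        X = np.ones((10, 3))
        t = np.r_[np.zeros(5), np.ones(5)]
        with pytest.warns(UserWarning, match="bias-only"):
            model = fit_rvm(X, t)
        assert model.n_relevance_vectors == 0
        mean, _ = predict_rvm(model, np.ones((2, 3)))
        np.testing.assert_allclose(mean, 0.5)

    def test_non_finite_inputs_rejected(self, rng):
        X = rng.standard_normal((5, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError):
            fit_rvm(X, np.zeros(5))

    def test_fit_is_deterministic(self, rng):
        X, t = make_blobs(rng, n_per_class=20)
        m1 = fit_rvm(X, t)
        m2 = fit_rvm(X, t)
        assert m1.to_dict() == m2.to_dict()

    def test_retained_basis_count_non_increasing(self, rng):
        X, t = make_blobs(rng, n_per_class=25)
        model = fit_rvm(X, t, kernel=KernelSpec(width=2.0))
        hist = model.n_active_history
        assert len(hist) >= 2
        assert all(a >= b for a, b in zip(hist, hist[1:]))


class TestPredict:
    def test_interpolation_at_relevance_vector(self):
        x = np.linspace(-10, 10, 100)[:, None]
        t = np.sinc(x.ravel() / np.pi)
        model = fit_rvm(x, t, kernel=KernelSpec(width=3.0))
        rv = model.relevance_vectors[:1]
        mean, _ = predict_rvm(model, rv)
        idx = model.rv_indices[0]
        assert mean[0] == pytest.approx(t[idx], abs=0.02)

    def test_variance_never_below_noise_floor(self, rng):
        X, t = make_blobs(rng, n_per_class=15)
        model = fit_rvm(X, t, kernel=KernelSpec(width=2.0))
        _, var = predict_rvm(model, rng.standard_normal((50, 2)) * 5)
        assert (var >= model.sigma2 - 1e-12).all()

    def test_far_query_reverts_to_bias_weight(self, rng):
        # With every kernel column vanishing, the predictive mean collapses
        # to the bias weight (or 0 if the bias basis was pruned away).
        X, t = make_blobs(rng, n_per_class=15)
        model = fit_rvm(X, t, kernel=KernelSpec(width=2.0))
        mean, _ = predict_rvm(model, np.array([[1e4, 1e4]]))
        expected = model.weights[0] if model.bias_included else 0.0
        assert mean[0] == pytest.approx(expected, abs=1e-8)

    def test_dimension_mismatch_rejected(self, rng):
        X, t = make_blobs(rng, n_per_class=10)
        model = fit_rvm(X, t)
        with pytest.raises(ValueError):
            predict_rvm(model, np.zeros((3, 5)))


class TestClassify:
    def test_threshold_and_tie_rule(self):
        # A hand-built bias-only model whose predictive mean is exactly the
        # bias weight lets the 0.5 tie rule be checked directly.
        def bias_model(w0):
            return RVMModel(
                relevance_vectors=np.empty((0, 2)),
                rv_indices=np.empty(0, dtype=int),
                bias_included=True,
                weights=np.array([w0]),
                alpha=np.array([1.0]),
                sigma2=1e-6,
                Sigma=np.array([[1e-6]]),
                kernel=KernelSpec(),
                converged=True,
                n_iter=0,
                n_train=2,
            )

        q = np.zeros((1, 2))
        assert classify_rvm(bias_model(0.9), q)[0][0] == 1
        assert classify_rvm(bias_model(0.5), q)[0][0] == 1  # tie goes positive
        assert classify_rvm(bias_model(0.49), q)[0][0] == 0

    def test_scores_clipped_to_unit_interval(self, rng):
        X, t = make_blobs(rng, n_per_class=15)
        model = fit_rvm(X, t, kernel=KernelSpec(width=2.0))
        _, scores = classify_rvm(model, rng.standard_normal((50, 2)) * 6)
        assert scores.min() >= 0.0 and scores.max() <= 1.0

    def test_held_out_blob_accuracy(self, rng):
        X, t = make_blobs(rng, n_per_class=40)
        Xq, tq = make_blobs(np.random.default_rng(99), n_per_class=40)
        model = fit_rvm(X, t, kernel=KernelSpec(width=2.0))
        labels, _ = classify_rvm(model, Xq)
        assert (labels == tq).mean() > 0.95


class TestSerialization:
    def test_roundtrip_preserves_predictions(self, rng):
        X, t = make_blobs(rng, n_per_class=15)
        model = fit_rvm(X, t, kernel=KernelSpec(width=2.0))
        clone = RVMModel.from_dict(model.to_dict())
        q = rng.standard_normal((20, 2)) * 3
        np.testing.assert_array_equal(predict_rvm(model, q)[0],
                                      predict_rvm(clone, q)[0])
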