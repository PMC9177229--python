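import numpy as np
import pytest
import scipy.optimize

import lmlssrc as lm
from lmlssrc.solver import l21_norm


def random_instance(seed, d=6, m=8, N=10, K=3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((d, N))
    D = rng.standard_normal((d, m))
    D /= np.linalg.norm(D, axis=0)
    labels = rng.integers(0, K, size=N)
    labels[:K] = np.arange(K)
    Y = (labels[None, :] == np.arange(K)[:, None]).astype(float)
    W = rng.standard_normal((K, m))
    A = rng.standard_normal((m, N))
    margin = lm.build_margin_graph(labels)
    locality = lm.build_locality_graph(X, k_neighbors=3)
    return X, D, A, W, Y, labels, margin.S_sym, locality.L


def coefficient_subproblem(Avec, X, D, W, Y, Omega, S_sym, L, hp):
    """The Omega-fixed smooth objective in A, for the numerical oracle."""
    A = Avec.reshape(D.shape[1], X.shape[1])
    return (
        np.linalg.norm(X - D @ A) ** 2
        + hp.lambda1 * np.trace(A.T @ Omega @ A)
        + hp.lambda2 * np.trace(A @ S_sym @ A.T)
        + hp.lambda3 * np.trace(A @ L @ A.T)
        + hp.lambda4 * np.linalg.norm(W @ A - Y) ** 2
    )


class TestRowWeights:
    def test_half_norm_row(self):
        A = np.zeros((2, 4))
        A[0, 0] = 0.5
        Omega = lm.update_row_weights(A)
        assert Omega[0, 0] == pytest.approx(1.0)

    def test_zero_row_floored(self):
        Omega = lm.update_row_weights(np.zeros((1, 3)), eps_row=1e-8)
        assert Omega[0, 0] == pytest.approx(5e7)

    def test_weighted_trace_identity(self):
        # tr(A.T Omega A) = sum_i ||A_i|| / 2 at the current weights
        rng = np.random.default_rng(2)
        A = rng.standard_normal((5, 7))
        Omega = lm.update_row_weights(A)
        assert np.trace(A.T @ Omega @ A) == pytest.approx(l21_norm(A) / 2)


class TestCoefficientUpdate:
    def test_orthonormal_unregularized(self):
        rng = np.random.default_rng(3)
        Q, _ = np.linalg.qr(rng.standard_normal((6, 6)))
        X = rng.standard_normal((6, 5))
        hp = lm.Hyperparameters(lambda1=0, lambda2=0, lambda3=0, lambda4=0)
        Z = np.zeros((5, 5))
        A = lm.update_coefficients(X, Q, np.zeros((2, 6)), np.zeros((2, 5)),
                                   np.eye(6), Z, Z, hp)
        np.testing.assert_allclose(A, Q.T @ X, atol=1e-10)

    def test_scalar_ridge(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((4, 6))
        c = 0.7
        hp = lm.Hyperparameters(lambda1=0.3, lambda2=0, lambda3=0, lambda4=0)
        Z = np.zeros((6, 6))
        A = lm.update_coefficients(X, np.eye(4), np.zeros((2, 4)),
                                   np.zeros((2, 6)), c * np.eye(4), Z, Z, hp)
        np.testing.assert_allclose(A, X / (1 + 0.3 * c), atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_numerical_minimizer(self, seed):
        X, D, A0, W, Y, labels, S_sym, L = random_instance(seed, d=5, m=8, N=6)
        S_sym = lm.build_margin_graph(labels[:6]).S_sym
        hp = lm.Hyperparameters(lambda1=0.5, lambda2=0.2, lambda3=0.3, lambda4=0.4)
        Omega = lm.update_row_weights(A0)
        A = lm.update_coefficients(X, D, W, Y, Omega, S_sym, L, hp)
        res = scipy.optimize.minimize(
            coefficient_subproblem,
            A0.ravel(),
            args=(X, D, W, Y, Omega, S_sym, L, hp),
            method="L-BFGS-B",
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-12},
        )
        ours = coefficient_subproblem(A.ravel(), X, D, W, Y, Omega, S_sym, L, hp)
        assert ours <= res.fun + 1e-6

    def test_stationarity_residual(self):
        X, D, A0, W, Y, labels, S_sym, L = random_instance(11)
        hp = lm.Hyperparameters()
        Omega = lm.update_row_weights(A0)
        A = lm.update_coefficients(X, D, W, Y, Omega, S_sym, L, hp)
        M = D.T @ D + hp.lambda1 * Omega + hp.lambda4 * W.T @ W
        G = hp.lambda2 * S_sym + hp.lambda3 * L
        R = D.T @ X + hp.lambda4 * W.T @ Y
        resid = np.linalg.norm(M @ A + A @ G - R) / np.linalg.norm(R)
        assert resid < 1e-8

    def test_indefinite_system_raises_actionable_error(self):
        X, D, A0, W, Y, labels, S_sym, L = random_instance(12)
        hp = lm.Hyperparameters(lambda1=1e-12, lambda2=50.0, lambda3=0, lambda4=0)
        Omega = lm.update_row_weights(A0)
        with pytest.raises(lm.NumericalError, match="lambda1"):
            lm.update_coefficients(X, D, W, Y, Omega, S_sym, L, hp)

    def test_scale_consistency(self):
        # scaling X, Y by c scales A by c at fixed D: the quadratic terms
        # are homogeneous, while the l2,1 term is linear in A, so its
        # weight scales by c (and the IRLS weights of cA are Omega/c)
        X, D, A0, W, Y, labels, S_sym, L = random_instance(13)
        c = 2.5
        hp = lm.Hyperparameters(lambda2=0.1, lambda3=0.1, lambda4=0.3)
        hp_scaled = lm.Hyperparameters(lambda1=c * hp.lambda1, lambda2=0.1,
                                       lambda3=0.1, lambda4=0.3)
        Omega = lm.update_row_weights(A0)
        A1 = lm.update_coefficients(X, D, W, Y, Omega, S_sym, L, hp)
        A2 = lm.update_coefficients(c * X, D, W, c * Y, Omega / c, S_sym, L,
                                    hp_scaled)
        np.testing.assert_allclose(A2, c * A1, rtol=1e-8)


class TestDictionaryUpdate:
    def test_feasible_unconstrained_optimum(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((4, 4))
        X /= 2 * np.linalg.norm(X, axis=0).max()  # inside the unit ball
        D = lm.update_dictionary(X, rng.standard_normal((4, 4)), np.eye(4))
        np.testing.assert_allclose(D, X, atol=1e-10)

    def test_exact_recovery_from_noiseless_data(self):
        rng = np.random.default_rng(6)
        D0 = rng.standard_normal((6, 5))
        D0 /= np.linalg.norm(D0, axis=0)
        A = rng.standard_normal((5, 40))
        X = D0 @ A
        D = lm.update_dictionary(X, rng.standard_normal((6, 5)), A, n_sweeps=20)
        np.testing.assert_allclose(D, D0, atol=1e-6)

    def test_constraint_and_monotonicity(self):
        rng = np.random.default_rng(7)
        for seed in range(5):
            X, D, A, *_ = random_instance(seed + 20)
            before = np.linalg.norm(X - D @ A) ** 2
            D_new = lm.update_dictionary(X, D, A)
            after = np.linalg.norm(X - D_new @ A) ** 2
            assert after <= before + 1e-12
            assert np.max(np.sum(D_new**2, axis=0)) <= 1 + 1e-8

    def test_zero_coefficient_row_leaves_atom(self):
        rng = np.random.default_rng(8)
        X = rng.standard_normal((4, 6))
        D = rng.standard_normal((4, 3))
        A = rng.standard_normal((3, 6))
        A[1, :] = 0.0
        D_new = lm.update_dictionary(X, D, A)
        np.testing.assert_array_equal(D_new[:, 1], D[:, 1])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_projected_gradient_oracle(self, seed):
        rng = np.random.default_rng(seed + 40)
        X = rng.standard_normal((6, 10))
        A = rng.standard_normal((8, 10))
        D_init = rng.standard_normal((6, 8))
        ours = lm.update_dictionary(X, D_init, A, n_sweeps=5000, tol=1e-12)
        # independent oracle: projected gradient descent on vec(D)
        D = D_init.copy()
        step = 1.0 / (2 * np.linalg.eigvalsh(A @ A.T).max())
        for _ in range(20000):
            D -= step * (2 * (D @ A - X) @ A.T)
            norms = np.linalg.norm(D, axis=0)
            D /= np.maximum(norms, 1.0)
        f_ours = np.linalg.norm(X - ours @ A) ** 2
        f_pg = np.linalg.norm(X - D @ A) ** 2
        assert f_ours <= f_pg + 1e-5

    def test_kkt_dual_form_at_fixed_point(self):
        # at the solution, D = X A.T (A A.T + Theta)^{-1} for a nonnegative
        # diagonal Theta supported on the active (unit-norm) atoms
        rng = np.random.default_rng(9)
        X = rng.standard_normal((5, 12))
        A = rng.standard_normal((6, 12))
        D = lm.update_dictionary(X, rng.standard_normal((5, 6)), A, n_sweeps=100)
        # recover Theta from stationarity: grad = 2(DA - X)A.T + 2 D Theta = 0
        Gmat = (X - D @ A) @ A.T  # = D Theta
        theta = np.array([
            D[:, i] @ Gmat[:, i] / max(D[:, i] @ D[:, i], 1e-12)
            for i in range(D.shape[1])
        ])
        norms2 = np.sum(D**2, axis=0)
        assert np.all(theta > -1e-8)
        # multipliers vanish on inactive atoms, off-axis residual vanishes too
        for i in range(D.shape[1]):
            if norms2[i] < 1 - 1e-6:
                assert abs(theta[i]) < 1e-6
            np.testing.assert_allclose(
                Gmat[:, i], theta[i] * D[:, i], atol=1e-6
            )


class TestClassifierUpdate:
    def test_identity_codes(self):
        Y = np.array([[1.0, 0.0], [0.0, 1.0]])
        W = lm.update_classifier(np.eye(2), Y, 1.0, 1.0)
        np.testing.assert_allclose(W, Y / 2)

    def test_interpolation_limit(self):
        rng = np.random.default_rng(10)
        A = rng.standard_normal((4, 4)) + 4 * np.eye(4)
        Y = rng.standard_normal((2, 4))
        W = lm.update_classifier(A, Y, 1.0, 1e-12)
        np.testing.assert_allclose(W @ A, Y, atol=1e-8)

    def test_zero_targets(self):
        W = lm.update_classifier(np.eye(3), np.zeros((2, 3)), 1.0, 1.0)
        np.testing.assert_array_equal(W, 0.0)

    def test_unregularized_degenerate_rejected(self):
        with pytest.raises(ValueError):
            lm.update_classifier(np.eye(2), np.eye(2), 0.0, 0.0)

    def test_is_exact_ridge_minimizer(self):
        rng = np.random.default_rng(11)
        A = rng.standard_normal((5, 9))
        Y = rng.standard_normal((3, 9))
        l4, l5 = 0.7, 0.2
        W = lm.update_classifier(A, Y, l4, l5)
        grad = 2 * l4 * (W @ A - Y) @ A.T + 2 * l5 * W
        assert np.linalg.norm(grad) < 1e-8 * (1 + np.linalg.norm(W))


class TestObjective:
    def test_zero_codes(self):
        rng = np.random.default_rng(12)
        X = rng.standard_normal((3, 4))
        Z4 = np.zeros((4, 4))
        F, terms = lm.evaluate_objective(
            X, np.eye(3), np.zeros((3, 4)), np.zeros((2, 3)),
            np.zeros((2, 4)), Z4, Z4, lm.Hyperparameters()
        )
        assert F == pytest.approx(np.linalg.norm(X) ** 2)

    def test_all_zero_inputs(self):
        Z4 = np.zeros((4, 4))
        F, _ = lm.evaluate_objective(
            np.zeros((3, 4)), np.zeros((3, 2)), np.zeros((2, 4)),
            np.zeros((2, 2)), np.zeros((2, 4)), Z4, Z4, lm.Hyperparameters()
        )
        assert F == 0.0

    def test_termwise_bruteforce(self):
        from conftest import locality_sum_bruteforce, margin_sum_bruteforce

        X, D, A, W, Y, labels, S_sym, L = random_instance(30)
        P = lm.build_locality_graph(X, k_neighbors=3).P
        hp = lm.Hyperparameters(lambda1=0.3, lambda2=0.4, lambda3=0.5,
                                lambda4=0.6, lambda5=0.7)
        F, terms = lm.evaluate_objective(X, D, A, W, Y, S_sym, L, hp)
        assert terms["margin"] == pytest.approx(
            margin_sum_bruteforce(A, labels), abs=1e-10
        )
        assert terms["locality"] == pytest.approx(
            locality_sum_bruteforce(A, P) / 2, abs=1e-10
        )
        expected = (
            np.linalg.norm(X - D @ A) ** 2
            + 0.3 * sum(np.linalg.norm(A[i]) for i in range(A.shape[0]))
            + 0.4 * terms["margin"]
            + 0.5 * terms["locality"]
            + 0.6 * np.linalg.norm(W @ A - Y) ** 2
            + 0.7 * np.linalg.norm(W) ** 2
        )
        assert F == pytest.approx(expected, rel=1e-12)

    def test_shape_mismatch_rejected(self):
        Z = np.zeros((4, 4))
        with pytest.raises(ValueError):
            lm.evaluate_objective(np.zeros((3, 4)), np.zeros((3, 2)),
                                  np.zeros((5, 4)), np.zeros((2, 2)),
                                  np.zeros((2, 4)), Z, Z, lm.Hyperparameters())


class TestFitLoop:
    def test_converges_on_blob_data(self):
        ds = lm.generate(lm.SyntheticSpec(mode="blob", n_classes=3, seed=7))
        margin = lm.build_margin_graph(ds.labels)
        locality = lm.build_locality_graph(ds.X)
        hp = lm.Hyperparameters(delta=1e-4, maxiter=50, seed=7)
        D, A, W, trace = lm.fit_lmls(ds.X, ds.labels, hp, margin.S_sym, locality.L)
        assert trace.converged
        assert np.max(np.sum(D**2, axis=0)) <= 1 + 1e-8

    @pytest.mark.parametrize("seed", range(8))
    def test_monotone_descent(self, seed):
        ds = lm.generate(lm.SyntheticSpec(n_classes=3, n_per_class=15,
                                          feature_dim=16, seed=seed))
        margin = lm.build_margin_graph(ds.labels)
        locality = lm.build_locality_graph(ds.X)
        hp = lm.Hyperparameters(seed=seed)
        _, _, _, trace = lm.fit_lmls(ds.X, ds.labels, hp, margin.S_sym, locality.L)
        obj = np.asarray(trace.objective_values)
        assert np.all(np.diff(obj) <= 1e-8 * obj[:-1])

    def test_reduces_to_alternating_least_squares(self):
        # with lambda1 = lambda2 = lambda3 = 0 the loop is plain alternating
        # least squares with a ridge classifier: compare per-iteration F
        # against an independent ALS implementation from the same init
        rng = np.random.default_rng(21)
        ds = lm.generate(lm.SyntheticSpec(n_classes=2, n_per_class=10,
                                          feature_dim=6, seed=21))
        X, labels = ds.X, ds.labels
        N = X.shape[1]
        Z = np.zeros((N, N))
        hp = lm.Hyperparameters(lambda1=0, lambda2=0, lambda3=0,
                                lambda4=0.5, lambda5=0.2, maxiter=5, delta=1e-15)
        m = 8
        D0 = rng.standard_normal((6, m))
        D0 /= np.linalg.norm(D0, axis=0)
        A0 = np.linalg.lstsq(D0, X, rcond=None)[0]
        W0 = np.eye(2, m)
        Y = (labels[None, :] == np.unique(labels)[:, None]).astype(float)
        _, _, _, trace = lm.fit_lmls(X, labels, hp, Z, Z, n_atoms=m,
                                     init=(D0, A0, W0))

        def objective(D, A, W):
            return (np.linalg.norm(X - D @ A) ** 2
                    + 0.5 * np.linalg.norm(W @ A - Y) ** 2
                    + 0.2 * np.linalg.norm(W) ** 2)

        D, A, W = D0.copy(), A0.copy(), W0.copy()
        expected = [objective(D, A, W)]
        for _ in range(5):
            D = lm.update_dictionary(X, D, A)
            A = np.linalg.solve(D.T @ D + 0.5 * W.T @ W,
                                D.T @ X + 0.5 * W.T @ Y)
            W = np.linalg.solve(0.5 * A @ A.T + 0.2 * np.eye(m),
                                0.5 * A @ Y.T).T
            expected.append(objective(D, A, W))
        np.testing.assert_allclose(trace.objective_values, expected, rtol=1e-8)

    def test_block_optimality_after_each_update(self):
        # partial gradients of the Omega-fixed smooth objective vanish at
        # each block's own update
        X, D, A, W, Y, labels, S_sym, L = random_instance(33)
        hp = lm.Hyperparameters()
        Omega = lm.update_row_weights(A)
        A1 = lm.update_coefficients(X, D, W, Y, Omega, S_sym, L, hp)
        gA = (2 * D.T @ (D @ A1 - X) + 2 * hp.lambda1 * Omega @ A1
              + 2 * hp.lambda2 * A1 @ S_sym + 2 * hp.lambda3 * A1 @ L
              + 2 * hp.lambda4 * W.T @ (W @ A1 - Y))
        assert np.linalg.norm(gA) <= 1e-6 * (1 + np.linalg.norm(A1))
        W1 = lm.update_classifier(A1, Y, hp.lambda4, hp.lambda5)
        gW = 2 * hp.lambda4 * (W1 @ A1 - Y) @ A1.T + 2 * hp.lambda5 * W1
        assert np.linalg.norm(gW) <= 1e-6 * (1 + np.linalg.norm(W1))
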