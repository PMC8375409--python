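import numpy as np
import pytest

from mtsccar import (
    GroupStructure,
    Hyperparameters,
    fit,
    fit_mtscca,
    objective,
    penalty_group,
    penalty_l11,
    penalty_l21,
    reweighting_diagonals,
    simulate,
    update_u,
    update_v,
)
from mtsccar.solver import _initial_weights

from conftest import random_dataset


class TestDiagonals:
    def test_row_norm_reciprocal(self):
        V = np.array([[3.0, 4.0], [0.5, 0.5]])
        d = reweighting_diagonals(V=V, eps=0.0)
        assert d.d_v1[0] == pytest.approx(0.1)  # 1 / (2 * 5)
        assert d.d_v2[0, 0] == pytest.approx(1 / 6)

    def test_zero_row_guarded_by_eps(self):
        d = reweighting_diagonals(V=np.zeros((3, 2)), eps=1e-6)
        assert np.all(np.isfinite(d.d_v1))
        assert d.d_v1[0] == pytest.approx(1 / 2e-6)

    def test_singleton_group_diagonal_equals_row_diagonal(self, rng):
        U = rng.standard_normal((8, 2))
        gs = GroupStructure.singletons(range(8))
        d = reweighting_diagonals(U=U, groups=gs, eps=1e-6)
        np.testing.assert_allclose(d.d_u3, d.d_u1, atol=1e-15)


class TestObjective:
    def test_zero_weights_leave_only_regression_residual(self):
        ds = random_dataset(n=20, p=10, q=8, M=2, C=3, seed=1)
        X, Ys, Z = ds.to_arrays()
        hyper = Hyperparameters(lambda_u1=0, lambda_u2=0, lambda_v1=0, lambda_v2=0)
        val = objective(X, Ys, Z, np.zeros((10, 2)), np.zeros((8, 2)), hyper)
        assert val == pytest.approx(2 * np.sum(Z**2))

    def test_matches_term_wise_recomputation(self, rng):
        ds = random_dataset(n=20, p=10, q=8, M=2, C=3, seed=2)
        X, Ys, Z = ds.to_arrays()
        U = rng.standard_normal((10, 2))
        V = rng.standard_normal((8, 2))
        gs = GroupStructure(labels=tuple(["a"] * 5 + ["b"] * 5))
        hyper = Hyperparameters(
            lambda_u1=0.3, lambda_u2=0.7, lambda_u3=0.2, lambda_v1=1.1, lambda_v2=0.5
        )
        expected = 0.0
        for m in range(2):
            proj = Ys[m] @ V[:, m]
            for c in range(3):
                expected += np.sum((proj - Z[:, c]) ** 2)
            expected += np.sum((X @ U[:, m] - proj) ** 2)
        expected += 1.1 * penalty_l21(V) + 0.5 * penalty_l11(V)
        expected += 0.3 * penalty_l21(U) + 0.7 * penalty_l11(U)
        expected += 0.2 * penalty_group(U, gs)
        val = objective(X, Ys, Z, U, V, hyper, groups=gs)
        assert val == pytest.approx(expected, abs=1e-10)

    def test_regression_off_reduces_to_scca_residual(self, rng):
        ds = random_dataset(seed=3)
        X, Ys, Z = ds.to_arrays()
        U = rng.standard_normal((ds.p, 2))
        V = rng.standard_normal((ds.q, 2))
        hyper = Hyperparameters(
            lambda_u1=0, lambda_u2=0, lambda_v1=0, lambda_v2=0, regression_on=False
        )
        expected = sum(
            np.sum((X @ U[:, m] - Ys[m] @ V[:, m]) ** 2) for m in range(2)
        )
        assert objective(X, Ys, Z, U, V, hyper) == pytest.approx(expected, abs=1e-10)

    def test_sign_gauge_of_scca_objective(self, rng):
        """Jointly flipping (u_m, v_m) leaves the unsupervised objective
        unchanged; the regression term breaks the gauge by design."""
        ds = random_dataset(seed=4)
        X, Ys, Z = ds.to_arrays()
        U = rng.standard_normal((ds.p, 2))
        V = rng.standard_normal((ds.q, 2))
        U2, V2 = U.copy(), V.copy()
        U2[:, 0] *= -1
        V2[:, 0] *= -1
        off = Hyperparameters(regression_on=False)
        assert objective(X, Ys, Z, U, V, off) == pytest.approx(
            objective(X, Ys, Z, U2, V2, off), rel=1e-12
        )
        on = Hyperparameters()
        assert objective(X, Ys, Z, U, V, on) != pytest.approx(
            objective(X, Ys, Z, U2, V2, on), rel=1e-6
        )


class TestUpdateV:
    def _instance(self, seed=0, q=10):
        ds = random_dataset(n=30, p=15, q=q, M=2, C=3, seed=seed)
        X, Ys, Z = ds.to_arrays()
        U, V = _initial_weights(X, Ys, 2, "constant", None)
        return X, Ys, Z, U, V

    def test_scalar_closed_form_exact_mode(self):
        X, Ys, Z, U, V = self._instance(q=1)
        hyper = Hyperparameters(lambda_v1=0, lambda_v2=0)
        V_new, pre = update_v(
            X, Ys, Z, U, V, hyper, return_prenorm=True, cov_mode="exact"
        )
        for m, Y in enumerate(Ys):
            y = Y[:, 0]
            num = sum(y @ Z[:, c] for c in range(3)) + y @ (X @ U[:, m])
            den = (hyper.gamma_v + 2.0) * (y @ y)
            assert pre[0, m] == pytest.approx(num / den, rel=1e-10)
            assert abs(V_new[0, m]) == pytest.approx(1 / np.linalg.norm(y), rel=1e-10)

    @pytest.mark.parametrize("cov_mode", ["exact", "identity"])
    def test_prenorm_zeroes_fixed_d_surrogate_gradient(self, cov_mode):
        X, Ys, Z, U, V = self._instance(seed=5)
        hyper = Hyperparameters(lambda_v1=0.4, lambda_v2=0.6)
        _, pre = update_v(
            X, Ys, Z, U, V, hyper, return_prenorm=True, cov_mode=cov_mode
        )
        d = reweighting_diagonals(V=V)
        for m, Y in enumerate(Ys):
            G = Y.T @ Y if cov_mode == "exact" else np.eye(Y.shape[1])
            A = (hyper.gamma_v + 2.0) * G + np.diag(
                hyper.lambda_v1 * d.d_v1 + hyper.lambda_v2 * d.d_v2[:, m]
            )
            b = Y.T @ Z.sum(axis=1) + Y.T @ (X @ U[:, m])
            grad = A @ pre[:, m] - b
            assert np.max(np.abs(grad)) < 1e-8
            np.testing.assert_allclose(pre[:, m], np.linalg.solve(A, b), atol=1e-8)

    def test_regression_off_matches_mtscca_update(self):
        X, Ys, Z, U, V = self._instance(seed=6)
        hyper = Hyperparameters(lambda_v1=0.4, lambda_v2=0.6, regression_on=False)
        _, pre = update_v(
            X, Ys, Z, U, V, hyper, return_prenorm=True, cov_mode="exact"
        )
        d = reweighting_diagonals(V=V)
        for m, Y in enumerate(Ys):
            A = (hyper.gamma_v + 1.0) * (Y.T @ Y) + np.diag(
                hyper.lambda_v1 * d.d_v1 + hyper.lambda_v2 * d.d_v2[:, m]
            )
            b = Y.T @ (X @ U[:, m])  # no cognitive pull
            np.testing.assert_allclose(pre[:, m], np.linalg.solve(A, b), atol=1e-8)

    def test_derived_regression_hessian_scales_with_score_count(self):
        X, Ys, Z, U, V = self._instance(seed=7)
        hyper = Hyperparameters(lambda_v1=0.4, lambda_v2=0.6)
        _, pre = update_v(
            X, Ys, Z, U, V, hyper, return_prenorm=True,
            regression_hessian="derived", cov_mode="exact",
        )
        d = reweighting_diagonals(V=V)
        C = Z.shape[1]
        A = (hyper.gamma_v + 1.0 + C) * (Ys[0].T @ Ys[0]) + np.diag(
            hyper.lambda_v1 * d.d_v1 + hyper.lambda_v2 * d.d_v2[:, 0]
        )
        b = Ys[0].T @ Z.sum(axis=1) + Ys[0].T @ (X @ U[:, 0])
        np.testing.assert_allclose(pre[:, 0], np.linalg.solve(A, b), atol=1e-8)


class TestUpdateU:
    def _instance(self, seed=0, p=15):
        ds = random_dataset(n=30, p=p, q=10, M=2, C=3, seed=seed)
        X, Ys, Z = ds.to_arrays()
        U, V = _initial_weights(X, Ys, 2, "constant", None)
        return X, Ys, U, V

    def test_scalar_normalization(self):
        X, Ys, U, V = self._instance(p=1)
        hyper = Hyperparameters(lambda_u1=0.2, lambda_u2=0.2)
        U_new = update_u(X, Ys, V, U, hyper, cov_mode="exact")
        x = X[:, 0]
        for m in range(2):
            assert abs(U_new[0, m]) == pytest.approx(1 / np.linalg.norm(x), rel=1e-10)

    @pytest.mark.parametrize("cov_mode", ["exact", "identity"])
    def test_prenorm_zeroes_fixed_d_surrogate_gradient(self, cov_mode):
        X, Ys, U, V = self._instance(seed=8, p=30)
        gs = GroupStructure(labels=tuple(np.repeat(list("abcde"), 6)))
        hyper = Hyperparameters(lambda_u1=0.3, lambda_u2=0.5, lambda_u3=0.2)
        _, pre = update_u(
            X, Ys, V, U, hyper, groups=gs, return_prenorm=True, cov_mode=cov_mode
        )
        d = reweighting_diagonals(U=U, groups=gs)
        for m, Y in enumerate(Ys):
            G = X.T @ X if cov_mode == "exact" else np.eye(X.shape[1])
            A = (hyper.gamma_u + 1.0) * G + np.diag(
                hyper.lambda_u1 * d.d_u1
                + hyper.lambda_u2 * d.d_u2[:, m]
                + hyper.lambda_u3 * d.d_u3
            )
            b = X.T @ (Y @ V[:, m])
            assert np.max(np.abs(A @ pre[:, m] - b)) < 1e-8
            np.testing.assert_allclose(pre[:, m], np.linalg.solve(A, b), atol=1e-8)

    def test_group_map_irrelevant_when_group_penalty_off(self):
        X, Ys, U, V = self._instance(seed=9)
        hyper = Hyperparameters(lambda_u1=0.3, lambda_u2=0.5, lambda_u3=0.0)
        out_a = update_u(X, Ys, V, U, hyper, groups=GroupStructure.singletons(range(15)))
        out_b = update_u(X, Ys, V, U, hyper, groups=GroupStructure(labels=("g",) * 15))
        np.testing.assert_array_equal(out_a, out_b)

    def test_missing_groups_with_group_penalty_rejected(self):
        X, Ys, U, V = self._instance()
        with pytest.raises(ValueError, match="group"):
            update_u(X, Ys, V, U, Hyperparameters(lambda_u3=0.5), groups=None)


class TestFit:
    def test_converges_on_reference_design(self, unit_noise_sim):
        ds, _ = unit_noise_sim
        res = fit(ds)
        assert res.converged and res.n_iterations <= 200
        assert res.final_delta_u <= 1e-5 and res.final_delta_v <= 1e-5

    def test_projection_constraints_hold(self, unit_noise_sim):
        ds, _ = unit_noise_sim
        res = fit(ds)
        X, Ys, _ = ds.to_arrays()
        for m in range(ds.M):
            assert abs(np.linalg.norm(X @ res.weights.U[:, m]) ** 2 - 1) < 1e-8
            assert abs(np.linalg.norm(Ys[m] @ res.weights.V[:, m]) ** 2 - 1) < 1e-8
        assert res.max_constraint_violation < 1e-8

    def test_bitwise_deterministic(self, unit_noise_sim):
        ds, _ = unit_noise_sim
        r1, r2 = fit(ds), fit(ds)
        assert r1.n_iterations == r2.n_iterations
        np.testing.assert_array_equal(r1.weights.U, r2.weights.U)
        np.testing.assert_array_equal(r1.weights.V, r2.weights.V)

    def test_random_init_is_seeded(self, small_dataset):
        r1 = fit(small_dataset, init="random", seed=11)
        r2 = fit(small_dataset, init="random", seed=11)
        np.testing.assert_array_equal(r1.weights.U, r2.weights.U)

    def test_training_ccc_is_high_at_unit_noise(self, unit_noise_sim):
        ds, _ = unit_noise_sim
        res = fit(ds)
        assert np.all(res.per_task_training_ccc > 0.9)

    def test_objective_trace_recorded(self, small_dataset):
        res = fit(small_dataset, max_iter=20)
        assert len(res.objective_trace) == res.n_iterations
        assert np.all(np.isfinite(res.objective_trace))

    def test_exact_mode_also_converges(self, unit_noise_sim):
        ds, _ = unit_noise_sim
        res = fit(ds, cov_mode="exact")
        assert res.max_constraint_violation < 1e-8
        assert res.n_iterations <= 200


class TestAblation:
    def test_mtscca_equals_fit_with_regression_off(self, small_dataset):
        hyper = Hyperparameters(lambda_u1=0.3, lambda_v1=0.3)
        a = fit_mtscca(small_dataset, hyper)
        b = fit(small_dataset, hyper.replace(regression_on=False))
        assert a.n_iterations == b.n_iterations
        np.testing.assert_array_equal(a.weights.U, b.weights.U)
        np.testing.assert_array_equal(a.weights.V, b.weights.V)

    def test_recovers_loadings_on_noiseless_rank_one_data(self):
        from mtsccar import recovery_score

        ds, truth = simulate(sigma2=1e-8, seed=0, scale=False)
        hyper = Hyperparameters(
            lambda_u1=1e-3, lambda_u2=1e-3, lambda_v1=1e-3, lambda_v2=1e-3
        )
        res = fit_mtscca(ds, hyper)
        scores = recovery_score(res.weights, truth)
        for score in scores.values():
            assert score["correlation"] >= 0.99
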