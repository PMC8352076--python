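"""Group elastic net solver tests, including independent-oracle checks.

The independent oracle for the optimum is a from-scratch FISTA
proximal-gradient solver (a different algorithm family from the ADMM
implementation under test); the single-wavelength lasso case is additionally
cross-checked against scikit-learn's coordinate-descent Lasso.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.linear_model import Lasso

import kinenet as kn
from kinenet.solver import ADMMSettings, _as_lists, group_shrink


# ---------------------------------------------------------------------------
# FISTA oracle (independent of the ADMM path)


def fista_genp(As, bs, lam, omega, n_iter=30000):
    """Accelerated proximal gradient on the group elastic net objective."""
    n = As[0].shape[1]
    p = len(bs)
    L = sum(np.linalg.norm(A, 2) ** 2 for A in As) / p + lam * omega
    L = max(L, max(np.linalg.norm(A, 2) ** 2 for A in As) + lam * omega)
    X = np.zeros((n, p))
    Y = X.copy()
    t = 1.0
    for _ in range(n_iter):
        G = np.column_stack(
            [A.T @ (A @ Y[:, k] - b) for k, (A, b) in enumerate(zip(As, bs))]
        )
        V = Y - (G + lam * omega * Y) / L
        Xn = group_shrink(V, lam * (1 - omega) / L)
        tn = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
        Y = Xn + ((t - 1) / tn) * (Xn - X)
        X, t = Xn, tn
    return X


def random_instance(rng, m=12, n=8, p=2):
    As = [rng.normal(size=(m, n)) for _ in range(p)]
    bs = [rng.normal(size=m) for _ in range(p)]
    return As, bs


class TestGroupShrink:
    @pytest.mark.parametrize(
        "v,kappa,expected",
        [
            ([3.0, 4.0], 2.5, [1.5, 2.0]),
            ([3.0, 4.0], 5.0, [0.0, 0.0]),
            ([1.0, -2.0], 0.0, [1.0, -2.0]),
        ],
    )
    def test_values(self, v, kappa, expected):
        np.testing.assert_allclose(group_shrink(np.array(v), kappa), expected)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(st.floats(-10, 10), min_size=1, max_size=5),
        st.floats(0, 5),
    )
    def test_nonexpansive_and_norm_reduction(self, v, kappa):
        v = np.asarray(v)
        out = group_shrink(v, kappa)
        assert np.linalg.norm(out) <= np.linalg.norm(v) + 1e-12
        # the shrinkage reduces the norm by exactly min(kappa, ||v||)
        np.testing.assert_allclose(
            np.linalg.norm(out), max(np.linalg.norm(v) - kappa, 0.0), atol=1e-9
        )


class TestLambdaMax:
    def test_column_of_ones(self):
        A = np.ones((2, 1))
        b = np.array([1.0, 1.0])
        assert kn.lambda_max(A, b, 0.0) == pytest.approx(2.0)

    def test_zero_data(self):
        A = np.ones((3, 2))
        assert kn.lambda_max(A, np.zeros(3), 0.0) == 0.0

    def test_solution_zero_at_lambda_max(self, rng):
        As, bs = random_instance(rng)
        lmax = kn.lambda_max(As, bs, 0.0)
        sol = kn.solve_genp(As, bs, 1.01 * lmax, 0.0)
        assert np.all(sol.X == 0)
        # and nonzero just below
        sol2 = kn.solve_genp(As, bs, 0.9 * lmax, 0.0)
        assert np.any(sol2.X != 0)

    def test_undefined_for_pure_ridge(self, rng):
        with pytest.raises(ValueError):
            kn.lambda_max(np.ones((2, 2)), np.ones(2), 1.0)


class TestSolveGenp:
    def test_tiny_lambda_recovers_least_squares(self, rng):
        A = rng.normal(size=(6, 6)) + 3 * np.eye(6)
        b = rng.normal(size=6)
        sol = kn.solve_genp(
            A, b, 1e-10, 0.0,
            ADMMSettings(eps_abs=1e-12, eps_rel=1e-10, max_iter=50000),
        )
        np.testing.assert_allclose(
            sol.X.ravel(), np.linalg.solve(A, b), atol=1e-6
        )

    def test_objective_matches_fista_oracle(self, rng):
        """ADMM optimum agrees with an independent proximal-gradient solver
        to 1e-6 relative objective on random small instances."""
        worst = 0.0
        for i in range(20):
            As, bs = random_instance(rng, m=12, n=8, p=2)
            lmax = kn.lambda_max(As, bs, 0.1)
            lam = lmax * 10 ** rng.uniform(-2, -0.3)
            sol = kn.solve_genp(As, bs, lam, 0.1)
            X_or = fista_genp(As, bs, lam, 0.1)
            f_admm = kn.genp_objective(As, bs, sol.X, lam, 0.1)
            f_or = kn.genp_objective(As, bs, X_or, lam, 0.1)
            rel = abs(f_admm - f_or) / abs(f_or)
            worst = max(worst, rel)
            assert f_admm <= f_or * (1 + 1e-6) + 1e-12
        assert worst < 1e-6

    def test_lasso_case_matches_coordinate_descent(self, rng):
        """p=1, omega=0 is the plain lasso; compare with sklearn."""
        for _ in range(5):
            A = rng.normal(size=(25, 15))
            b = rng.normal(size=25)
            lam = 0.3 * kn.lambda_max(A, b, 0.0)
            sol = kn.solve_genp(A, b, lam, 0.0)
            sk = Lasso(
                alpha=lam / A.shape[0], fit_intercept=False, tol=1e-14,
                max_iter=1_000_000,
            ).fit(A, b)
            np.testing.assert_allclose(sol.X.ravel(), sk.coef_, atol=2e-6)

    def test_kkt_certificate(self, rng):
        As, bs = random_instance(rng, m=20, n=12, p=3)
        for omega in [0.0, 0.3]:
            lam = 0.2 * kn.lambda_max(As, bs, omega)
            sol = kn.solve_genp(As, bs, lam, omega)
            stat, zero_excess = kn.kkt_residuals(As, bs, sol.X, lam, omega)
            scale = max(np.linalg.norm(b) for b in bs)
            assert stat < 1e-4 * scale
            assert zero_excess < 1e-4 * lam

    def test_objective_nondecreasing_in_lambda(self, rng):
        As, bs = random_instance(rng)
        lmax = kn.lambda_max(As, bs, 0.0)
        objs = []
        for lam in lmax * np.array([1e-3, 1e-2, 1e-1, 0.5, 1.0]):
            sol = kn.solve_genp(As, bs, lam, 0.0)
            objs.append(kn.genp_objective(As, bs, sol.X, lam, 0.0))
        assert np.all(np.diff(objs) > -1e-10)

    def test_rows_jointly_zero(self, rng):
        """Grouping: a row is never partially zero across wavelengths."""
        As, bs = random_instance(rng, m=15, n=10, p=4)
        lam = 0.6 * kn.lambda_max(As, bs, 0.0)
        sol = kn.solve_genp(As, bs, lam, 0.0)
        row_zero = np.all(sol.X == 0, axis=1)
        row_nonzero = np.all(sol.X != 0, axis=1)
        assert np.all(row_zero | row_nonzero)
        assert row_zero.sum() > 0  # actually sparse at this lambda

    def test_nan_rejected(self):
        A = np.ones((3, 2))
        b = np.array([1.0, np.nan, 0.0])
        with pytest.raises(ValueError, match="NaN|inf"):
            kn.solve_genp(A, b, 1.0, 0.0)

    def test_nonconvergence_warns(self, rng):
        As, bs = random_instance(rng)
        lam = 0.01 * kn.lambda_max(As, bs, 0.0)
        est = kn.GroupElasticNet(lam=lam, omega=0.0, max_iter=3)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            est.fit(As, bs)
        assert not est.converged_


class TestEstimatorInterface:
    def test_sklearn_params_roundtrip(self):
        est = kn.GroupElasticNet(lam=2.0, omega=0.5)
        params = est.get_params()
        assert params["lam"] == 2.0 and params["omega"] == 0.5
        est.set_params(lam=3.0)
        assert est.lam == 3.0

    def test_fit_predict_shapes(self, rng):
        A = rng.normal(size=(10, 6))
        B = rng.normal(size=(10, 3))
        est = kn.GroupElasticNet(lam=0.1, omega=0.2).fit(A, B)
        assert est.coef_.shape == (6, 3)
        assert est.predict(A).shape == (10, 3)
        assert est.n_iter_ >= 1

    def test_warm_start_reproduces_solution(self, rng):
        A = rng.normal(size=(15, 10))
        B = rng.normal(size=(15, 2))
        lam = 0.2 * kn.lambda_max(A, B, 0.0)
        cold = kn.GroupElasticNet(lam=lam).fit(A, B)
        warm = kn.GroupElasticNet(lam=2 * lam, warm_start=True).fit(A, B)
        warm.set_params(lam=lam)
        warm.fit(A, B)
        f_cold = kn.genp_objective(A, B, cold.coef_, lam, 0.0)
        f_warm = kn.genp_objective(A, B, warm.coef_, lam, 0.0)
        assert abs(f_cold - f_warm) <= 1e-6 * max(abs(f_cold), 1e-12)

    def test_invalid_hyperparams(self, rng):
        A, B = np.ones((4, 2)), np.ones(4)
        with pytest.raises(ValueError):
            kn.GroupElasticNet(lam=-1.0).fit(A, B)
        with pytest.raises(ValueError):
            kn.GroupElasticNet(lam=1.0, omega=1.5).fit(A, B)


class TestObjectiveAndMse:
    def test_objective_at_zero(self, rng):
        As, bs = random_instance(rng)
        expected = 0.5 * sum(float(b @ b) for b in bs)
        assert kn.genp_objective(As, bs, np.zeros((8, 2)), 1.0, 0.5) == pytest.approx(
            expected
        )

    def test_objective_hand_computed(self):
        # zero data, X with a single unit row, lam=1, omega=0:
        # 1/2||A x||^2 + group norm of the row = 1/2*m + 1
        A = np.ones((3, 2))
        X = np.array([[1.0], [0.0]])
        b = np.zeros(3)
        val = kn.genp_objective(A, b, X, 1.0, 0.0)
        assert val == pytest.approx(0.5 * 3 + 1.0)

    def test_lambda_zero_is_pure_misfit(self, rng):
        As, bs = random_instance(rng)
        X = rng.normal(size=(8, 2))
        misfit = 0.5 * sum(
            float(np.sum((b - A @ X[:, k]) ** 2))
            for k, (A, b) in enumerate(zip(As, bs))
        )
        assert kn.genp_objective(As, bs, X, 0.0, 0.7) == pytest.approx(misfit)

    def test_fit_mse(self):
        A = np.array([[1.0]])
        assert kn.fit_mse(A, np.array([2.0]), np.array([[0.0]])) == pytest.approx(4.0)
        assert kn.fit_mse(A, np.array([2.0]), np.array([[2.0]])) == pytest.approx(0.0)
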