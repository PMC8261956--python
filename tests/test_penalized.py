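import numpy as np
import pytest
from sklearn.linear_model import Lasso

from microstd import bic_select, fit_lasso, fit_scad, lambda_grid
from microstd.penalized import bic_of, lambda_max, scad_derivative

from conftest import orthonormal_design


def soft(z, t):
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def scad_threshold(z, lam, a=3.7):
    """Closed-form SCAD solution on an orthonormal design."""
    z = np.asarray(z, dtype=float)
    out = np.where(np.abs(z) <= 2 * lam, soft(z, lam),
                   np.where(np.abs(z) <= a * lam,
                            ((a - 1) * z - np.sign(z) * a * lam) / (a - 2), z))
    return out


class TestLasso:
    def test_zero_lambda_is_ols(self, rng):
        X = rng.normal(size=(40, 5))
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 3.0]) + rng.normal(0, 0.5, 40)
        fit = fit_lasso(X, y, 0.0)
        A = np.column_stack([np.ones(40), X])
        ols = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coef, ols[1:], atol=1e-7)
        np.testing.assert_allclose(fit.intercept, ols[0], atol=1e-7)

    def test_lambda_above_max_gives_all_zero(self, rng):
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        lam = lambda_max(X, y)
        fit = fit_lasso(X, y, lam * 1.0000001)
        assert (fit.coef == 0).all()

    def test_orthonormal_design_matches_soft_threshold(self, rng):
        X = orthonormal_design(rng, 100, 6)
        y = X @ np.array([2.0, -1.0, 0.4, 0.0, 0.1, -0.6]) + rng.normal(0, 0.3, 100)
        z = X.T @ (y - y.mean()) / 100
        for lam in (0.05, 0.3, 0.8):
            fit = fit_lasso(X, y, lam)
            np.testing.assert_allclose(fit.coef, soft(z, lam), atol=1e-8)

    def test_kkt_conditions_hold(self, rng):
        X = rng.normal(size=(50, 12))
        y = X[:, 0] * 2 + rng.normal(0, 1, 50)
        lam = 0.2
        fit = fit_lasso(X, y, lam)
        Xc = X - X.mean(axis=0)
        grad = Xc.T @ (y - fit.predict(X)) / 50
        active = fit.coef != 0
        assert np.all(np.abs(grad[~active]) <= lam + 1e-6)
        np.testing.assert_allclose(np.abs(grad[active]), lam, atol=1e-6)

    def test_matches_sklearn_on_random_problems(self, rng):
        X = rng.normal(size=(60, 10))
        y = X[:, :3] @ np.array([1.5, -1.0, 0.5]) + rng.normal(0, 0.4, 60)
        for lam in (0.05, 0.2):
            mine = fit_lasso(X, y, lam)
            ref = Lasso(alpha=lam, fit_intercept=True, tol=1e-12, max_iter=100000)
            ref.fit(X, y)
            np.testing.assert_allclose(mine.coef, ref.coef_, atol=1e-6)

    def test_response_scaling_equivariance(self, rng):
        X = rng.normal(size=(40, 6))
        y = X[:, 0] - X[:, 3] + rng.normal(0, 0.3, 40)
        c = 3.7
        a = fit_lasso(X, y, 0.1)
        b = fit_lasso(X, c * y, c * 0.1)
        np.testing.assert_allclose(b.coef, c * a.coef, atol=1e-7)

    def test_unpenalized_column_stays_active(self, rng):
        X = rng.normal(size=(50, 5))
        y = 0.3 * X[:, 0] + rng.normal(0, 1, 50)
        fit = fit_lasso(X, y, 5.0, unpenalized=[0])
        assert (fit.coef[1:] == 0).all()
        assert fit.coef[0] != 0  # small but unpenalized -> kept at its LS value

    def test_nonfinite_input_is_error(self):
        X = np.ones((10, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            fit_lasso(X, np.ones(10), 0.1)


class TestScad:
    def test_zero_lambda_is_ols(self, rng):
        X = rng.normal(size=(40, 4))
        y = X @ np.array([1.0, 0.0, -1.0, 2.0]) + rng.normal(0, 0.4, 40)
        fit = fit_scad(X, y, 0.0)
        A = np.column_stack([np.ones(40), X])
        ols = np.linalg.lstsq(A, y, rcond=None)[0]
        np.testing.assert_allclose(fit.coef, ols[1:], atol=1e-7)

    def test_orthonormal_matches_closed_form_all_regions(self, rng):
        # coefficients placed in the three SCAD regions: |z|<=2l, (2l, al], >al
        X = orthonormal_design(rng, 200, 6)
        beta = np.array([3.0, -3.0, 0.45, -0.45, 0.12, 0.0])
        y = X @ beta + rng.normal(0, 0.05, 200)
        lam, a = 0.2, 3.7
        z = X.T @ (y - y.mean()) / 200
        fit = fit_scad(X, y, lam, a=a)
        np.testing.assert_allclose(fit.coef, scad_threshold(z, lam, a), atol=1e-8)

    def test_unbiasedness_region_returns_z(self, rng):
        X = orthonormal_design(rng, 150, 3)
        y = X @ np.array([2.5, -2.5, 0.0]) + rng.normal(0, 0.1, 150)
        lam = 0.3
        z = X.T @ (y - y.mean()) / 150
        fit = fit_scad(X, y, lam)
        assert np.all(np.abs(z[:2]) > 3.7 * lam)
        np.testing.assert_allclose(fit.coef[:2], z[:2], atol=1e-8)

    def test_small_z_region_returns_zero(self, rng):
        X = orthonormal_design(rng, 150, 3)
        y = rng.normal(0, 0.05, 150)
        z = X.T @ (y - y.mean()) / 150
        lam = float(np.abs(z).max()) * 1.5
        fit = fit_scad(X, y, lam)
        assert (fit.coef == 0).all()

    def test_a_below_two_is_error(self, rng):
        with pytest.raises(ValueError, match="a > 2"):
            fit_scad(np.ones((10, 2)), np.ones(10), 0.1, a=1.5)

    def test_derivative_definition(self):
        lam, a = 0.5, 3.7
        t = np.array([0.1, 0.5, 1.0, 1.6, 2.0])
        expect = np.array([lam, lam,
                           lam * (a * lam - 1.0) / ((a - 1) * lam),
                           lam * (a * lam - 1.6) / ((a - 1) * lam),
                           0.0])
        np.testing.assert_allclose(scad_derivative(t, lam, a), expect, atol=1e-12)


class TestBruteForce:
    @pytest.mark.parametrize("penalty", ["lasso", "scad"])
    def test_agrees_with_grid_minimizer_on_tiny_problems(self, rng, penalty):
        X = rng.normal(size=(25, 2))
        y = X @ np.array([1.2, -0.4]) + rng.normal(0, 0.5, 25)
        lam, a = 0.25, 3.7
        fit = fit_lasso(X, y, lam) if penalty == "lasso" else fit_scad(X, y, lam, a=a)

        def scad_pen(t):
            t = abs(t)
            if t <= lam:
                return lam * t
            if t <= a * lam:
                return (2 * a * lam * t - t**2 - lam**2) / (2 * (a - 1))
            return lam**2 * (a + 1) / 2

        def objective(b):
            r = y - y.mean() - (X - X.mean(0)) @ b
            pen = (lam * np.abs(b).sum() if penalty == "lasso"
                   else sum(scad_pen(t) for t in b))
            return r @ r / (2 * 25) + pen

        grid = np.linspace(-2, 2, 401)
        best = min(((objective(np.array([b1, b2])), (b1, b2))
                    for b1 in grid for b2 in grid))[1]
        # refine around the grid winner
        fine1 = np.linspace(best[0] - 0.01, best[0] + 0.01, 201)
        fine2 = np.linspace(best[1] - 0.01, best[1] + 0.01, 201)
        best = min(((objective(np.array([b1, b2])), (b1, b2))
                    for b1 in fine1 for b2 in fine2))[1]
        np.testing.assert_allclose(fit.coef, best, atol=1e-4)
        assert objective(fit.coef) <= objective(np.array(best)) + 1e-10


class TestBicSelect:
    def test_single_lambda_grid_returns_that_fit(self, rng):
        X = rng.normal(size=(30, 4))
        y = X[:, 0] + rng.normal(0, 0.5, 30)
        fit = bic_select(X, y, lambda_path=np.array([0.17]))
        assert fit.lam == 0.17
        assert np.isfinite(fit.bic)

    def test_bic_formula(self, rng):
        X = rng.normal(size=(30, 3))
        y = X[:, 0] + rng.normal(0, 0.5, 30)
        fit = fit_lasso(X, y, 0.1)
        fit.bic = bic_of(fit)
        expect = 30 * np.log(fit.rss / 30) + fit.df * np.log(30)
        assert fit.bic == pytest.approx(expect)

    def test_pure_noise_mostly_selects_empty_model(self):
        """BIC selection consistency under the null.

        With plain BIC the per-feature inclusion threshold is z^2 > log n,
        so P(empty) ~ (1 - P(chi2_1 > log n))^p ~ 0.94 at n=2000, p=10 (and
        only ~0.8 at n=200 -- consistency is asymptotic).
        """
        hits = 0
        for seed in range(30):
            g = np.random.default_rng(seed)
            X = g.normal(size=(2000, 10))
            y = g.normal(size=2000)
            fit = bic_select(X, y, penalty="lasso")
            hits += len(fit.active_set) == 0
        assert hits >= 24  # >= 80% of seeds

    def test_strong_single_signal_recovered(self):
        # beta = 3, sigma = 0.25: the signal is always kept and noise is
        # excluded with probability ~0.94 at n=2000
        hits = 0
        for seed in range(30):
            g = np.random.default_rng(1000 + seed)
            X = g.normal(size=(2000, 10))
            y = 3.0 * X[:, 4] + g.normal(0, 0.25, 2000)
            fit = bic_select(X, y, penalty="lasso")
            hits += set(fit.active_set) == {4}
        assert hits >= 25  # >= ~85% of seeds

    def test_objective_never_increases_along_solver_iterations(self, rng):
        # monotonicity of coordinate descent, checked via objective at
        # progressively tighter tolerances
        X = rng.normal(size=(40, 8))
        y = X[:, 0] * 2 + rng.normal(0, 0.6, 40)
        lam = 0.15

        def objective(fit):
            r = y - fit.predict(X)
            return r @ r / (2 * 40) + lam * np.abs(fit.coef).sum()

        loose = fit_lasso(X, y, lam, tol=1e-2, max_iter=3)
        tight = fit_lasso(X, y, lam, tol=1e-10)
        assert objective(tight) <= objective(loose) + 1e-12

    def test_ties_resolve_to_larger_lambda(self, rng):
        X = rng.normal(size=(30, 3))
        y = rng.normal(size=30)
        lmax = lambda_max(X, y)
        # both lambdas above lambda_max give the identical empty fit
        fit = bic_select(X, y, lambda_path=np.array([2 * lmax, 3 * lmax]))
        assert fit.lam == 3 * lmax

    def test_grid_spans_lambda_max(self, rng):
        X = rng.normal(size=(30, 5))
        y = X[:, 0] + rng.normal(0, 0.3, 30)
        grid = lambda_grid(X, y, n_lambda=25, min_ratio=1e-2)
        assert grid[0] == pytest.approx(lambda_max(X, y))
        assert grid[-1] == pytest.approx(1e-2 * grid[0])
        assert len(grid) == 25
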