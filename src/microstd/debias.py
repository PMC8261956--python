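"""Debiased (desparsified) LASSO estimates and homoscedastic standard errors.

Given a screened design X (n x m, columns centered) and an initial
BIC-tuned lasso fit beta_hat, the debiased estimate is the one-step
correction

    b_hat = beta_hat + Theta_hat X'(y - X beta_hat) / n,

where Theta_hat is a relaxed inverse of Sigma_hat = X'X/n constructed by
nodewise lasso regressions: each column X_j is lasso-regressed on the
others, with lambda_j chosen by 10-fold cross-validation on a fold split
fixed by the run seed, giving rows Theta_j = (1, -gamma_j)/tau_j^2 with
tau_j^2 = X_j'(X_j - X_{-j} gamma_j)/n.  Standard errors assume
homoscedastic noise:

    se_j = sigma_hat * sqrt([Theta Sigma_hat Theta']_jj / n),

with sigma_hat the residual SD of the initial lasso fit using denominator
n - |active set| - 1 (floored at 1).  In the low-dimensional full-rank
case with Theta = (X'X/n)^{-1}, b_hat reproduces OLS exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.linear_model import lasso_path
from sklearn.model_selection import KFold

from .penalized import PenalizedFit


@dataclass
class DebiasedFit:
    """Debiased estimates over a stratum's screened feature set."""

    estimates: np.ndarray       # b_hat over the screened columns
    se: np.ndarray              # matching standard errors
    sigma_hat: float            # residual noise scale
    theta: np.ndarray           # relaxed inverse, rows = screened columns
    lambda_nodewise: np.ndarray  # per-row tuning values
    features: Optional[np.ndarray] = None  # original feature indices of the columns

    def __post_init__(self) -> None:
        if self.estimates.shape != self.se.shape:
            raise ValueError("estimates and se must share an index set")


def _cv_lasso_alpha(A, b, fold_indices, n_alphas=100, eps=1e-3):
    """10-fold CV choice of the lasso penalty for one nodewise regression.

    Uses the low-level :func:`sklearn.linear_model.lasso_path` on
    pre-centered fortran-ordered arrays (the validating estimator wrapper
    dominates runtime at post-screening problem sizes).  Returns the
    alpha minimizing mean validation MSE; ties go to the larger alpha.
    """
    n = A.shape[0]
    Ac = A - A.mean(axis=0)
    bc = b - b.mean()
    alpha_max = np.max(np.abs(Ac.T @ bc)) / n
    if alpha_max <= 0:
        return np.geomspace(1.0, eps, n_alphas)[-1:], np.zeros((1,))
    alphas = np.geomspace(alpha_max, eps * alpha_max, n_alphas)
    mse = np.zeros(n_alphas)
    for train, val in fold_indices:
        At = A[train]
        mu_A, mu_b = At.mean(axis=0), b[train].mean()
        At = np.asfortranarray(At - mu_A, dtype=np.float64)
        bt = np.ascontiguousarray(b[train] - mu_b, dtype=np.float64)
        _, coefs, _ = lasso_path(At, bt, alphas=alphas, precompute=False,
                                 max_iter=10_000, check_input=False)
        resid = (A[val] - mu_A) @ coefs - (b[val] - mu_b)[:, None]
        mse += (resid ** 2).mean(axis=0)
    return alphas, mse


def nodewise_lasso(X, cv_folds: int = 10, seed: int = 0,
                   tau_tol: float = 1e-10):
    """Relaxed inverse of the Gram matrix by nodewise lasso regressions.

    Returns ``(theta, lambdas)``.  A zero-variance column or a duplicate
    column (tau^2 below tolerance) is an error.  The CV fold split is
    identical for every column and fixed by ``seed``.
    """
    from .penalized import fit_lasso

    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if m < 2:
        raise ValueError("nodewise lasso requires at least 2 columns")
    if np.any(X.std(axis=0) == 0):
        raise ValueError("zero-variance column in nodewise design")
    corr = np.corrcoef(X, rowvar=False)
    np.fill_diagonal(corr, 0.0)
    if np.nanmax(np.abs(corr)) >= 1 - 1e-8:
        i, j = np.unravel_index(np.nanargmax(np.abs(corr)), corr.shape)
        raise ValueError(
            f"columns {i} and {j} are (numerically) collinear; "
            "nodewise design is degenerate")
    folds = KFold(n_splits=min(cv_folds, n), shuffle=True, random_state=seed)
    fold_indices = list(folds.split(X))
    theta = np.zeros((m, m))
    lambdas = np.zeros(m)
    for j in range(m):
        others = np.delete(np.arange(m), j)
        alphas, mse = _cv_lasso_alpha(X[:, others], X[:, j], fold_indices)
        best = alphas[int(np.argmin(mse))]  # alphas descend: first min = largest
        fit = fit_lasso(X[:, others], X[:, j], best)
        gamma = fit.coef
        resid = X[:, j] - fit.predict(X[:, others])
        tau2 = float(X[:, j] @ resid) / n
        if tau2 < tau_tol:
            raise ValueError(
                f"nodewise residual variance {tau2:.3e} below tolerance for column {j}; "
                "design is (near-)degenerate"
            )
        theta[j, j] = 1.0 / tau2
        theta[j, others] = -gamma / tau2
        lambdas[j] = float(best)
    return theta, lambdas


def scaled_lasso_sigma(X, y, tol: float = 1e-6, max_iter: int = 50) -> float:
    """Joint noise-scale estimate by the scaled lasso.

    Alternates a lasso fit at lambda = sigma_hat * lambda_0 with the update
    sigma_hat^2 = RSS/n, where lambda_0 = sqrt(2 log(m)/n) is the universal
    penalty level.  Self-tuning: the estimate does not inherit the overfit
    of whatever lambda a model-selection criterion preferred, which matters
    when screening has recruited noise columns.
    """
    from .penalized import fit_lasso  # deferred: avoids an import cycle at build

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    lam0 = np.sqrt(2.0 * np.log(max(m, 2)) / n)
    sigma = float(np.std(y, ddof=1))
    if sigma == 0:
        raise ValueError("zero-variance response")
    warm = None
    for _ in range(max_iter):
        fit = fit_lasso(X, y, sigma * lam0, warm_start=warm)
        warm = fit.coef.copy()
        new_sigma = float(np.sqrt(fit.rss / n))
        if new_sigma <= 0:
            return max(new_sigma, 1e-12)
        if abs(new_sigma - sigma) < tol * sigma:
            return new_sigma
        sigma = new_sigma
    return sigma


def scaled_lasso_refit_sigma(X, y) -> float:
    """Noise scale by least squares on the scaled-lasso active set.

    The plain scaled-lasso estimate sqrt(RSS/n) inflates sigma when a few
    coefficients are large (their shrinkage bias enters the RSS); the
    refitted variant removes that bias by OLS on the selected columns,
    with denominator n - |active| - 1 (floored at 1).
    """
    from .penalized import fit_lasso

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    lam0 = np.sqrt(2.0 * np.log(max(m, 2)) / n)
    sigma = scaled_lasso_sigma(X, y)
    fit = fit_lasso(X, y, sigma * lam0)
    active = fit.active_set
    if active.size == 0:
        return sigma
    A = np.column_stack([np.ones(n), X[:, active]])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    dof = max(n - active.size - 1, 1)
    return float(np.sqrt(resid @ resid / dof))


def debias(X, y, lasso_fit: PenalizedFit, theta: np.ndarray,
           lambda_nodewise: Optional[np.ndarray] = None,
           features: Optional[np.ndarray] = None,
           sigma_method: str = "scaled_lasso") -> DebiasedFit:
    """One-step debiasing of a lasso fit on the screened design.

    ``sigma_method`` selects the homoscedastic noise-scale estimator:
    "scaled_lasso_refit" (default; self-tuned and free of large-coefficient
    shrinkage bias), "scaled_lasso", or "lasso_df" (residual SD of
    ``lasso_fit`` with denominator n - |active set| - 1, floored at 1).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = X.shape
    theta = np.asarray(theta, dtype=float)
    if lasso_fit.coef.shape[0] != m or theta.shape != (m, m):
        raise ValueError("dimension mismatch between design, fit, and theta")
    resid = y - lasso_fit.predict(X)
    Xc = X - X.mean(axis=0)
    b = lasso_fit.coef + theta @ (Xc.T @ resid) / n
    Sigma = Xc.T @ Xc / n
    omega = theta @ Sigma @ theta.T
    if sigma_method == "scaled_lasso_refit":
        sigma_hat = scaled_lasso_refit_sigma(X, y)
    elif sigma_method == "scaled_lasso":
        sigma_hat = scaled_lasso_sigma(X, y)
    elif sigma_method == "lasso_df":
        dof = max(n - len(lasso_fit.active_set) - 1, 1)
        sigma_hat = float(np.sqrt(lasso_fit.rss / dof))
    else:
        raise ValueError(f"unknown sigma_method {sigma_method!r}")
    se = sigma_hat * np.sqrt(np.clip(np.diag(omega), 0.0, None) / n)
    if np.any(se <= 0):
        raise ValueError("nonpositive standard error in debiased fit")
    if lambda_nodewise is None:
        lambda_nodewise = np.full(m, np.nan)
    return DebiasedFit(estimates=b, se=se, sigma_hat=sigma_hat, theta=theta,
                       lambda_nodewise=np.asarray(lambda_nodewise, dtype=float),
                       features=None if features is None else np.asarray(features))


def single_column_theta(X) -> np.ndarray:
    """Relaxed inverse for a 1-column design: 1 / (x'x/n) on the centered column."""
    X = np.asarray(X, dtype=float)
    xc = X[:, 0] - X[:, 0].mean()
    v = float(xc @ xc) / X.shape[0]
    if v <= 0:
        raise ValueError("zero-variance column")
    return np.array([[1.0 / v]])
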