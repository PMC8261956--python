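"""Penalized least squares with LASSO and SCAD penalties, tuned by BIC.

The objective is the penalized residual sum of squares in its
1/(2n)-normalized form,

    (1/2n) * sum_i (y_i - b0 - x_i'beta)^2  +  sum_j p_lambda(beta_j),

with the intercept (and any designated confounder columns) excluded from
the penalty.  LASSO uses p_lambda(t) = lambda*|t|; SCAD uses the folded
concave penalty with derivative

    p'_lambda(t) = lambda * [ I(t <= lambda)
                   + (a*lambda - t)_+ / ((a-1)*lambda) * I(t > lambda) ]

for t >= 0 and a > 2, solved by iterating a local linear approximation
around the current coefficients.  The solver is coordinate descent on the
precomputed Gram matrix, which is fast at post-screening problem sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np


@dataclass
class PenalizedFit:
    """A fitted penalized regression at one value of lambda."""

    intercept: float
    coef: np.ndarray            # all design columns, penalized and not
    penalized: np.ndarray       # boolean mask over design columns
    penalty: str                # "lasso" | "scad"
    lam: float
    scad_a: float | None
    rss: float
    n: int
    bic: float = field(default=np.nan)

    @property
    def active_set(self) -> np.ndarray:
        """Indices of penalized columns with a nonzero coefficient."""
        return np.where(self.penalized & (self.coef != 0))[0]

    @property
    def df(self) -> int:
        """Model degrees of freedom: active set + unpenalized terms + intercept."""
        return int(len(self.active_set) + (~self.penalized).sum() + 1)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.coef


def _soft(z: float, t: float) -> float:
    if z > t:
        return z - t
    if z < -t:
        return z + t
    return 0.0


def _cd_weighted_lasso(G, c, lam_vec, beta, tol, max_iter):
    """Coordinate descent for (1/2) beta'G beta - c'beta + sum_j lam_j |beta_j|.

    ``G = X'X/n`` and ``c = X'y/n`` on centered data; ``lam_vec`` holds the
    per-coordinate penalty level (0 for unpenalized columns).  ``beta`` is
    updated in place (warm start).  Returns the iteration count.
    """
    m = G.shape[0]
    diag = np.diag(G).copy()
    fixed = diag <= 0  # zero-variance columns stay at 0
    beta[fixed] = 0.0
    # residual correlation vector: r = c - G @ beta, maintained incrementally
    r = c - G @ beta
    for it in range(max_iter):
        delta_max = 0.0
        for j in range(m):
            if fixed[j]:
                continue
            bj_old = beta[j]
            zj = r[j] + diag[j] * bj_old
            bj_new = _soft(zj, lam_vec[j]) / diag[j]
            if bj_new != bj_old:
                d = bj_new - bj_old
                r -= G[:, j] * d
                beta[j] = bj_new
                delta_max = max(delta_max, abs(d))
        if delta_max < tol:
            return it + 1
    return max_iter


def _prepare(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in design or response")
    n = X.shape[0]
    xbar = X.mean(axis=0)
    ybar = y.mean()
    Xc = X - xbar
    yc = y - ybar
    G = (Xc.T @ Xc) / n
    c = (Xc.T @ yc) / n
    return X, y, n, xbar, ybar, Xc, yc, G, c


def _finalize(X, y, n, xbar, ybar, beta, penalized, penalty, lam, scad_a):
    # snap numerical dust to exact zero: the active set (and hence the BIC
    # df) must not pick up coefficients created by float rounding at the
    # soft-threshold boundary
    scale = max(1.0, float(np.max(np.abs(beta))) if beta.size else 1.0)
    beta[np.abs(beta) < 1e-10 * scale] = 0.0
    intercept = ybar - float(xbar @ beta)
    resid = y - intercept - X @ beta
    rss = float(resid @ resid)
    return PenalizedFit(intercept=intercept, coef=beta, penalized=penalized,
                        penalty=penalty, lam=lam, scad_a=scad_a, rss=rss, n=n)


def _penalized_mask(m: int, unpenalized: Optional[Sequence[int]]) -> np.ndarray:
    mask = np.ones(m, dtype=bool)
    if unpenalized is not None:
        mask[np.asarray(unpenalized, dtype=int)] = False
    return mask


def fit_lasso(X, y, lam: float, unpenalized: Optional[Sequence[int]] = None,
              tol: float = 1e-8, max_iter: int = 100_000,
              warm_start: Optional[np.ndarray] = None) -> PenalizedFit:
    """LASSO fit at a single lambda.

    ``unpenalized`` lists design columns excluded from the penalty (the
    intercept is always unpenalized).  At lambda=0 on a full-rank design
    this is ordinary least squares.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X, y, n, xbar, ybar, Xc, yc, G, c = _prepare(X, y)
    m = X.shape[1]
    penalized = _penalized_mask(m, unpenalized)
    beta = np.zeros(m) if warm_start is None else np.asarray(warm_start, dtype=float).copy()
    lam_vec = np.where(penalized, lam, 0.0)
    _cd_weighted_lasso(G, c, lam_vec, beta, tol, max_iter)
    return _finalize(X, y, n, xbar, ybar, beta, penalized, "lasso", lam, None)


def scad_derivative(t: np.ndarray, lam: float, a: float) -> np.ndarray:
    """SCAD penalty derivative p'_lambda(t) for t >= 0."""
    t = np.asarray(t, dtype=float)
    small = t <= lam
    taper = np.clip(a * lam - t, 0.0, None) / ((a - 1.0) * lam) if lam > 0 else np.zeros_like(t)
    return np.where(small, lam, lam * taper)


def fit_scad(X, y, lam: float, a: float = 3.7,
             unpenalized: Optional[Sequence[int]] = None,
             tol: float = 1e-8, max_iter: int = 100_000,
             lla_max_iter: int = 50,
             warm_start: Optional[np.ndarray] = None) -> PenalizedFit:
    """SCAD fit at a single lambda via iterated local linear approximation.

    Each LLA step solves a weighted LASSO with per-coordinate penalty
    p'_lambda(|beta_j|) evaluated at the previous iterate, starting from
    the LASSO solution at the same lambda.
    """
    if a <= 2:
        raise ValueError("SCAD requires a > 2")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    X, y, n, xbar, ybar, Xc, yc, G, c = _prepare(X, y)
    m = X.shape[1]
    penalized = _penalized_mask(m, unpenalized)
    if warm_start is None:
        beta = np.zeros(m)
        _cd_weighted_lasso(G, c, np.where(penalized, lam, 0.0), beta, tol, max_iter)
    else:
        beta = np.asarray(warm_start, dtype=float).copy()
    for _ in range(lla_max_iter):
        lam_vec = np.where(penalized, scad_derivative(np.abs(beta), lam, a), 0.0)
        beta_old = beta.copy()
        _cd_weighted_lasso(G, c, lam_vec, beta, tol, max_iter)
        if np.max(np.abs(beta - beta_old)) < tol:
            break
    return _finalize(X, y, n, xbar, ybar, beta, penalized, "scad", lam, a)


def lambda_max(X, y, unpenalized: Optional[Sequence[int]] = None) -> float:
    """Smallest lambda at which all penalized LASSO coefficients are zero.

    With unpenalized columns present, the response is first projected off
    them (grid construction only; the fits themselves never residualize).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    penalized = _penalized_mask(X.shape[1], unpenalized)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    if (~penalized).any():
        U = Xc[:, ~penalized]
        coef, *_ = np.linalg.lstsq(U, yc, rcond=None)
        yc = yc - U @ coef
    scores = np.abs(Xc[:, penalized].T @ yc) / n
    return float(scores.max()) if scores.size else 0.0


def lambda_grid(X, y, unpenalized: Optional[Sequence[int]] = None,
                n_lambda: int = 100, min_ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced lambda path from lambda_max down to min_ratio*lambda_max."""
    lmax = lambda_max(X, y, unpenalized)
    if lmax <= 0:
        return np.array([0.0])
    return np.geomspace(lmax, min_ratio * lmax, n_lambda)


def bic_of(fit: PenalizedFit) -> float:
    """BIC(lambda) = n*log(RSS/n) + df*log(n)."""
    if fit.rss <= 0:
        raise ValueError("saturated fit: RSS is 0, BIC undefined")
    n = fit.n
    return float(n * np.log(fit.rss / n) + fit.df * np.log(n))


def bic_select(X, y, penalty: str = "lasso",
               lambda_path: Optional[np.ndarray] = None,
               unpenalized: Optional[Sequence[int]] = None,
               scad_a: float = 3.7, n_lambda: int = 100,
               min_ratio: float = 1e-3, tol: float = 1e-8) -> PenalizedFit:
    """Fit the penalty path and return the BIC-minimizing fit.

    Ties in BIC resolve to the larger lambda (sparser fit).  The path is
    solved descending in lambda with warm starts.
    """
    if penalty not in ("lasso", "scad"):
        raise ValueError(f"unknown penalty {penalty!r}")
    if lambda_path is None:
        lambda_path = lambda_grid(X, y, unpenalized, n_lambda, min_ratio)
    lambda_path = np.asarray(lambda_path, dtype=float)
    if lambda_path.size == 0:
        raise ValueError("empty lambda grid")
    order = np.argsort(lambda_path)[::-1]
    best: PenalizedFit | None = None
    warm = None
    for lam in lambda_path[order]:
        if penalty == "lasso":
            fit = fit_lasso(X, y, lam, unpenalized, tol=tol, warm_start=warm)
        else:
            fit = fit_scad(X, y, lam, a=scad_a, unpenalized=unpenalized, tol=tol,
                           warm_start=warm)
        warm = fit.coef.copy()
        fit.bic = bic_of(fit)
        if best is None or fit.bic < best.bic:
            best = fit
    assert best is not None
    return best
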