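"""(Iterative) sure independence screening.

Marginal screening ranks features by |Pearson correlation with the
response| and keeps the top d = floor(n / log n).  The iterative variant
alternates (a) a penalized fit on the currently recruited set, (b)
deletion of features the fit zeroes out, and (c) recruitment of the
features most correlated with the current residuals, until the retained
set stabilizes, reaches the budget, or the iteration cap is hit.  Plain
marginal screening can be badly misled when irrelevant features are more
correlated with the response marginally than relevant ones — the typical
situation when a confounder shifts many feature means at once — which is
why the iterative variant is the default here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .penalized import PenalizedFit, bic_select


@dataclass
class ScreenResult:
    """Outcome of a screening pass."""

    retained: np.ndarray            # ordered (ascending) feature indices, |.| <= budget
    budget: int
    iterations: int
    log: list = field(default_factory=list)   # per-iteration (recruited, deleted) records
    fit: Optional[PenalizedFit] = None        # final penalized fit on the recruited set


def screening_budget(n_samples: int) -> int:
    """Maximum model size d = floor(n / log n), natural log."""
    if n_samples < 3:
        raise ValueError("screening budget requires n >= 3")
    return int(math.floor(n_samples / math.log(n_samples)))


def _marginal_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """|Pearson correlation| of each column with y.

    On a column-standardized design this is |X_j'(y - ybar)| / ((n-1) sd_y);
    unstandardized columns (e.g. stratum-interaction blocks) are divided by
    their own SD, and constant columns score 0.
    """
    yc = y - y.mean()
    sy = yc.std(ddof=1)
    if sy == 0:
        raise ValueError("response has zero variance; screening is undefined")
    n = X.shape[0]
    sx = X.std(axis=0, ddof=1)
    cov = np.abs((X - X.mean(axis=0)).T @ yc) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        scores = np.where(sx > 0, cov / (sx * sy), 0.0)
    return scores


def sis_rank(X, y) -> np.ndarray:
    """Rank features by decreasing |marginal correlation| with y.

    Ties break by ascending feature index.  ``X`` must be
    column-standardized.  Returns the full permutation of feature indices.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    scores = _marginal_scores(X, y)
    # lexsort: primary key -scores (descending), secondary ascending index
    return np.lexsort((np.arange(scores.size), -scores))


def isis_select(X, y, penalty: str = "lasso", d: Optional[int] = None,
                max_iter: int = 5, unpenalized_design: Optional[np.ndarray] = None,
                **fit_kwargs) -> ScreenResult:
    """Iterative sure independence screening with penalized recruit/delete.

    Parameters
    ----------
    X : (n, p) column-standardized design of screenable features.
    y : response.
    penalty : "lasso" or "scad", used in the recruit/delete fits (BIC-tuned).
    d : screening budget; default floor(n / log n).
    max_iter : recruit/fit cycles; ``max_iter=1`` is plain SIS (screen to d)
        followed by a single penalized fit.
    unpenalized_design : optional columns (e.g. a required confounder
        indicator) always present and unpenalized in every internal fit;
        marginal utilities are then correlations with the residual of y on
        these columns ("screening given L").

    Returns a :class:`ScreenResult` whose ``retained`` is the active set of
    the final penalized fit (at most d features) and whose ``fit`` is that
    final fit (coefficient order follows the recruited-set order recorded
    in the log).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if d is None:
        d = screening_budget(n)
    if d < 1:
        raise ValueError("screening budget must be >= 1")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    U = None if unpenalized_design is None else np.asarray(unpenalized_design, dtype=float)

    def _residual_for_screening(target: np.ndarray) -> np.ndarray:
        if U is None:
            return target
        Uc = np.column_stack([np.ones(n), U])
        coef, *_ = np.linalg.lstsq(Uc, target, rcond=None)
        return target - Uc @ coef

    def _fit_on(idx: np.ndarray) -> PenalizedFit:
        if U is None:
            return bic_select(X[:, idx], y, penalty=penalty, **fit_kwargs)
        design = np.column_stack([U, X[:, idx]])
        unpen = list(range(U.shape[1]))
        return bic_select(design, y, penalty=penalty, unpenalized=unpen, **fit_kwargs)

    def _active_features(fit: PenalizedFit, idx: np.ndarray) -> np.ndarray:
        offset = 0 if U is None else U.shape[1]
        nz = np.where(fit.coef[offset:] != 0)[0]
        return np.sort(idx[nz])

    log: list = []
    init_size = min(p, d if max_iter == 1 else math.ceil(2 * d / 3))
    ranking = sis_rank(X, _residual_for_screening(y))
    recruited = np.sort(ranking[:init_size])
    fit = _fit_on(recruited)
    retained = _active_features(fit, recruited)
    log.append({"iteration": 1, "recruited": recruited.tolist(),
                "deleted": sorted(set(recruited) - set(retained))})
    iterations = 1

    for it in range(2, max_iter + 1):
        if retained.size >= d:
            break
        # rank features outside the retained set by |corr with residuals|
        resid = y - fit.predict(
            X[:, recruited] if U is None else np.column_stack([U, X[:, recruited]]))
        outside = np.setdiff1d(np.arange(p), retained)
        if outside.size == 0:
            break
        scores = _marginal_scores(X[:, outside], resid) if np.std(resid, ddof=1) > 0 else None
        if scores is None:
            break
        order = np.lexsort((outside, -scores))
        recruits = np.sort(outside[order][: d - retained.size])
        recruited = np.sort(np.concatenate([retained, recruits]))
        fit = _fit_on(recruited)
        new_retained = _active_features(fit, recruited)
        log.append({"iteration": it, "recruited": recruits.tolist(),
                    "deleted": sorted(set(recruited) - set(new_retained))})
        iterations = it
        if np.array_equal(new_retained, retained):
            retained = new_retained
            break
        retained = new_retained

    return ScreenResult(retained=retained, budget=d, iterations=iterations,
                        log=log, fit=fit)
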