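"""Model classes: the conditional-standardization estimator and its pooled competitors.

:class:`ConditionalStandardization` implements the proposed procedure:
within each confounder stratum, center/scale features, screen with
(iterative) sure independence screening to a budget d_l = floor(n_l/log n_l),
fit a BIC-tuned penalized regression, and debias the lasso fit for
inference; then standardize estimates and standard errors to the
confounder distribution and control FDR with Benjamini-Hochberg over all
p features.

:class:`PooledPenalizedModel` fits the six pooled-data comparison designs
(select/require/ignore the confounder, each with or without effect
modification) through the same screening/penalization/debiasing
machinery, with budget d = floor(n/log n) on the pooled data.

Both ``fit()`` methods return :class:`StandardizationResults`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .data_io import StratifiedDataset, StratumWeights, build_dataset, write_results
from .debias import debias, nodewise_lasso, single_column_theta
from .designs import ModelSpec, build_design, population_effects_from_effmod
from .penalized import bic_select
from .preprocess import center_scale
from .screening import isis_select, screening_budget, sis_rank
from .standardize import (
    PopulationResult,
    bh_adjust,
    estimate_stratum_weights,
    population_pvalues,
    standardize_debiased,
    standardize_effects,
)


def _derive_seed(seed: int, k: int) -> int:
    """Deterministic child seed (< 2^31) for stratum/component k."""
    return int(np.random.SeedSequence([int(seed), int(k)]).generate_state(1)[0] & 0x7FFFFFFF)


@dataclass
class StandardizationResults:
    """Fitted population-level results with per-stratum components.

    Attributes follow the statsmodels convention: ``params`` are the
    standardized debiased estimates (per one-SD change in the feature),
    ``bse`` their standard errors, ``pvalues``/``qvalues`` the two-sided
    normal p-values and BH-adjusted q-values (NaN for features screened
    out everywhere), ``selected`` the q < alpha discovery flags.
    ``selection_params`` are the standardized penalized (variable
    selection) estimates.
    """

    population: PopulationResult
    model_name: str
    penalty: str
    screen: str
    seed: int
    diagnostics: dict = field(default_factory=dict)

    @property
    def feature_ids(self) -> list[str]:
        return self.population.feature_ids

    @property
    def params(self) -> pd.Series:
        return pd.Series(self.population.estimate, index=self.feature_ids, name="estimate")

    @property
    def bse(self) -> pd.Series:
        return pd.Series(self.population.se, index=self.feature_ids, name="se")

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(self.population.p_value, index=self.feature_ids, name="p_value")

    @property
    def qvalues(self) -> pd.Series:
        return pd.Series(self.population.q_value, index=self.feature_ids, name="q_value")

    @property
    def selected(self) -> pd.Series:
        return pd.Series(self.population.selected, index=self.feature_ids, name="selected")

    @property
    def selection_params(self) -> pd.Series:
        return pd.Series(self.population.selection_estimate, index=self.feature_ids,
                         name="selection_estimate")

    def to_frame(self) -> pd.DataFrame:
        return self.population.to_frame()

    def to_tsv(self, path) -> None:
        write_results(self.population, path)

    def run_record(self) -> dict:
        from . import __version__
        return {
            "model": self.model_name,
            "penalty": self.penalty,
            "screen": self.screen,
            "seed": self.seed,
            "alpha": self.population.alpha,
            "version": __version__,
            "diagnostics": self.diagnostics,
        }

    def summary(self) -> str:
        pop = self.population
        n_tested = int(pop.tested.sum())
        lines = [
            "Population-standardized microbiome feature effects",
            "=" * 58,
            f"model: {self.model_name}   penalty: {self.penalty}   screen: {self.screen}",
            f"features: {len(pop.feature_ids)}   tested: {n_tested}   "
            f"discoveries (q < {pop.alpha:g}): {int(pop.selected.sum())}",
        ]
        for lev, diag in self.diagnostics.get("strata", {}).items():
            lines.append(
                f"  stratum {lev}: n={diag['n']} budget={diag['budget']} "
                f"retained={diag['retained']} lambda={diag.get('lambda', float('nan')):.4g} "
                f"sigma={diag.get('sigma_hat', float('nan')):.4g}"
            )
        lines.append("-" * 58)
        lines.append(f"{'feature':<20}{'estimate':>10}{'se':>9}{'p':>10}{'q':>10}  sel")
        order = np.argsort(np.where(np.isnan(pop.q_value), np.inf, pop.q_value))
        shown = 0
        for j in order:
            if not pop.selected[j] and shown >= 10:
                break
            p = pop.p_value[j]
            q = pop.q_value[j]
            lines.append(
                f"{pop.feature_ids[j]:<20}{pop.estimate[j]:>10.3f}{pop.se[j]:>9.3f}"
                f"{(f'{p:.2e}' if np.isfinite(p) else '--'):>10}"
                f"{(f'{q:.2e}' if np.isfinite(q) else '--'):>10}"
                f"  {'*' if pop.selected[j] else ''}"
            )
            shown += 1
        lines.append("=" * 58)
        lines.append("estimates are per one within-stratum SD of the feature")
        return "\n".join(lines)


def _stratum_machinery(X, y, penalty, screen, d, max_screen_iter, seed,
                       nodewise_cv_folds, unpenalized_design=None,
                       sigma_method="scaled_lasso"):
    """screen -> BIC penalized fit -> debiased lasso on one design.

    Returns (retained_local, fit, debiased_fit_or_None, diag).  ``X`` is
    the (standardized) screenable design; ``unpenalized_design`` holds any
    always-included unpenalized columns.
    """
    n, p = X.shape
    diag: dict = {"n": n, "budget": d}
    if screen == "isis":
        sres = isis_select(X, y, penalty=penalty, d=d, max_iter=max_screen_iter,
                           unpenalized_design=unpenalized_design)
        retained = sres.retained
        diag["screen_iterations"] = sres.iterations
    elif screen == "sis":
        retained = np.sort(sis_rank(X, y if unpenalized_design is None else
                                    _residualize(y, unpenalized_design))[:d])
    elif screen == "none":
        retained = np.arange(p)
    else:
        raise ValueError(f"unknown screening method {screen!r}")
    diag["retained"] = int(retained.size)

    unpen_idx = None
    if retained.size:
        if unpenalized_design is None:
            D = X[:, retained]
        else:
            D = np.column_stack([unpenalized_design, X[:, retained]])
            unpen_idx = list(range(unpenalized_design.shape[1]))
        fit = bic_select(D, y, penalty=penalty, unpenalized=unpen_idx)
        lasso_fit = fit if penalty == "lasso" else bic_select(
            D, y, penalty="lasso", unpenalized=unpen_idx)
        diag["lambda"] = fit.lam
        if D.shape[1] == 1:
            theta, lam_nw = single_column_theta(D), np.full(1, np.nan)
        else:
            theta, lam_nw = nodewise_lasso(D, cv_folds=nodewise_cv_folds, seed=seed)
        db = debias(D, y, lasso_fit, theta, lambda_nodewise=lam_nw,
                    sigma_method=sigma_method)
        diag["sigma_hat"] = db.sigma_hat
    else:
        fit, db = None, None
    return retained, fit, db, diag


def _residualize(y, U):
    n = len(y)
    Uc = np.column_stack([np.ones(n), U])
    coef, *_ = np.linalg.lstsq(Uc, y, rcond=None)
    return y - Uc @ coef


class ConditionalStandardization:
    """Per-stratum screening/selection/inference with population standardization.

    Parameters
    ----------
    dataset : StratifiedDataset
        Counts, outcome, and confounder labels (already filtered/rarefied
        as desired; preprocessing is outcome-blind and happens upstream).
    weights : StratumWeights, optional
        Target-population confounder prevalences; defaults to the
        empirical proportions n_l / n.
    penalty : {"lasso", "scad"}
        Penalty for the selection fit.  Inference always debiases a lasso
        fit on the screened set.
    screen : {"isis", "sis", "none"}
    budget : int or None
        Screening budget per stratum; None means floor(n_l / log n_l).
    alpha : float
        Nominal FDR level for the BH selection flag.
    require_all_strata : bool
        If True, only features retained in *every* stratum are tested
        (the strict reading); default tests features retained in at least
        one stratum.
    """

    def __init__(self, dataset: StratifiedDataset, weights: Optional[StratumWeights] = None,
                 penalty: str = "lasso", screen: str = "isis",
                 budget: Optional[int] = None, max_screen_iter: int = 5,
                 alpha: float = 0.05, require_all_strata: bool = False,
                 nodewise_cv_folds: int = 10, sigma_method: str = "scaled_lasso"):
        self.data = dataset
        self.user_weights = weights
        self.penalty = penalty
        self.screen = screen
        self.budget = budget
        self.max_screen_iter = max_screen_iter
        self.alpha = alpha
        self.require_all_strata = require_all_strata
        self.nodewise_cv_folds = nodewise_cv_folds
        self.sigma_method = sigma_method

    @classmethod
    def from_dataframe(cls, counts: pd.DataFrame, metadata: pd.DataFrame,
                       outcome: str, confounder: str, **kwargs):
        """Build from a samples x features count DataFrame and metadata table."""
        meta = pd.DataFrame({
            "outcome": pd.to_numeric(metadata[outcome]),
            "confounder": metadata[confounder].astype(str),
        }, index=metadata.index.astype(str))
        data = build_dataset(counts.to_numpy(), [str(s) for s in counts.index],
                             [str(f) for f in counts.columns], meta)
        return cls(data, **kwargs)

    def fit(self, seed: int = 0) -> StandardizationResults:
        data = self.data
        p = data.n_features
        for lev in data.levels:
            if data.stratum(lev).size < 5:
                raise ValueError(
                    f"stratum {lev!r} has only {data.stratum(lev).size} samples; "
                    "per-stratum fitting needs >= 5 — consider a pooled analysis"
                )
        scaled = center_scale(np.asarray(data.counts, dtype=float), strata=data.confounder)
        weights = estimate_stratum_weights(data.confounder, self.user_weights)

        stratum_beta: dict = {}
        stratum_db: dict = {}
        diagnostics: dict = {"strata": {}}
        for li, lev in enumerate(data.levels):
            idx = data.stratum(lev)
            y = data.outcome[idx]
            usable = np.where(~scaled.zero_variance[lev])[0]
            X = scaled.values[np.ix_(idx, usable)]
            d = self.budget if self.budget is not None else screening_budget(idx.size)
            seed_l = _derive_seed(seed, li)
            retained_local, fit, db, diag = _stratum_machinery(
                X, y, self.penalty, self.screen, d, self.max_screen_iter,
                seed_l, self.nodewise_cv_folds, sigma_method=self.sigma_method)
            beta_l = np.zeros(p)
            if fit is not None:
                global_retained = usable[retained_local]
                beta_l[global_retained] = fit.coef
                db.features = global_retained
            stratum_beta[lev] = beta_l
            stratum_db[lev] = db
            diagnostics["strata"][str(lev)] = diag

        beta_pop = standardize_effects(stratum_beta, weights)
        b, se, tested = standardize_debiased(stratum_db, weights, p,
                                             self.require_all_strata)
        pvals = population_pvalues(b, se, tested)
        qvals, selected = bh_adjust(pvals, p_total=p, alpha=self.alpha)

        stratum_est = {}
        stratum_se = {}
        stratum_ret = {}
        for lev in data.levels:
            est = np.zeros(p)
            ses = np.zeros(p)
            ret = np.zeros(p, dtype=bool)
            db = stratum_db[lev]
            if db is not None:
                est[db.features] = db.estimates
                ses[db.features] = db.se
                ret[db.features] = True
            stratum_est[lev] = est
            stratum_se[lev] = ses
            stratum_ret[lev] = ret

        pop = PopulationResult(
            feature_ids=list(data.feature_ids),
            selection_estimate=beta_pop, estimate=b, se=se,
            p_value=pvals, q_value=qvals, selected=selected, alpha=self.alpha,
            stratum_estimates=stratum_est, stratum_se=stratum_se,
            stratum_retained=stratum_ret, weights=weights,
        )
        return StandardizationResults(population=pop, model_name="conditional_std",
                                      penalty=self.penalty, screen=self.screen,
                                      seed=seed, diagnostics=diagnostics)


class PooledPenalizedModel:
    """One of the six pooled comparison designs, fitted on all samples at once.

    Shares the screening, BIC-tuned penalization, and debiasing machinery
    with the conditional estimator, but screens on the pooled data with
    budget d = floor(n / log n) (Table-style "screening given L" for the
    require-L designs: marginal utilities are correlations with the
    residual of the outcome on the confounder).  Effect-modification
    designs report population effects by standardizing their per-stratum
    coefficient blocks.
    """

    def __init__(self, dataset: StratifiedDataset, model: str = "select_l",
                 weights: Optional[StratumWeights] = None, penalty: str = "lasso",
                 screen: str = "isis", budget: Optional[int] = None,
                 max_screen_iter: int = 5, alpha: float = 0.05,
                 require_all_strata: bool = False, nodewise_cv_folds: int = 10,
                 sigma_method: str = "scaled_lasso"):
        self.data = dataset
        self.spec = ModelSpec(model)
        if self.spec.name == "conditional_std":
            raise ValueError("use ConditionalStandardization for conditional_std")
        self.user_weights = weights
        self.penalty = penalty
        self.screen = screen
        self.budget = budget
        self.max_screen_iter = max_screen_iter
        self.alpha = alpha
        self.require_all_strata = require_all_strata
        self.nodewise_cv_folds = nodewise_cv_folds
        self.sigma_method = sigma_method

    def fit(self, seed: int = 0) -> StandardizationResults:
        data = self.data
        p = data.n_features
        design = build_design(self.spec, data)
        weights = estimate_stratum_weights(data.confounder, self.user_weights)
        y = data.outcome
        d = self.budget if self.budget is not None else screening_budget(data.n_samples)

        pen_cols = np.where(design.penalized)[0]
        unpen_cols = np.where(~design.penalized)[0]
        U = design.X[:, unpen_cols] if unpen_cols.size else None
        Xp = design.X[:, pen_cols]
        retained_local, fit, db, diag = _stratum_machinery(
            Xp, y, self.penalty, self.screen, d, self.max_screen_iter,
            _derive_seed(seed, 0), self.nodewise_cv_folds, unpenalized_design=U,
            sigma_method=self.sigma_method)
        diagnostics = {"strata": {"pooled": diag}}

        coef_design = np.zeros(design.X.shape[1])
        if fit is not None:
            offset = 0 if U is None else U.shape[1]
            coef_design[unpen_cols] = fit.coef[:offset]
            coef_design[pen_cols[retained_local]] = fit.coef[offset:]
        beta_pop = population_effects_from_effmod(coef_design, design, weights, p)

        # per-feature debiased estimates and SEs from the screened design
        b = np.zeros(p)
        var = np.zeros(p)
        retained_any = np.zeros(p, dtype=bool)
        retained_all = np.ones(p, dtype=bool) if self.spec.effmod else retained_any
        if db is not None:
            offset = 0 if U is None else U.shape[1]
            cols = pen_cols[retained_local]
            feat = design.col_feature[cols]
            levl = design.col_level[cols]
            if self.spec.effmod:
                per_level_mask = {lev: np.zeros(p, dtype=bool) for lev in design.levels}
                for k in range(cols.size):
                    j = feat[k]
                    if j < 0:
                        continue  # confounder indicator column
                    w = weights[levl[k]]
                    b[j] += w * db.estimates[offset + k]
                    var[j] += (w * db.se[offset + k]) ** 2
                    per_level_mask[levl[k]][j] = True
                retained_any = np.zeros(p, dtype=bool)
                retained_all = np.ones(p, dtype=bool)
                for lev in design.levels:
                    retained_any |= per_level_mask[lev]
                    retained_all &= per_level_mask[lev]
            else:
                for k in range(cols.size):
                    j = feat[k]
                    if j < 0:
                        continue
                    b[j] = db.estimates[offset + k]
                    var[j] = db.se[offset + k] ** 2
                    retained_any[j] = True
                retained_all = retained_any
        se = np.sqrt(var)
        tested = (retained_all if (self.spec.effmod and self.require_all_strata)
                  else retained_any) & (se > 0)
        pvals = population_pvalues(b, se, tested)
        qvals, selected = bh_adjust(pvals, p_total=p, alpha=self.alpha)

        pop = PopulationResult(
            feature_ids=list(data.feature_ids),
            selection_estimate=beta_pop, estimate=b, se=se,
            p_value=pvals, q_value=qvals, selected=selected, alpha=self.alpha,
            weights=weights,
        )
        return StandardizationResults(population=pop, model_name=self.spec.name,
                                      penalty=self.penalty, screen=self.screen,
                                      seed=seed, diagnostics=diagnostics)


def fit_model(dataset: StratifiedDataset, model: str = "conditional_std",
              **kwargs) -> StandardizationResults:
    """Dispatch helper: fit any of the seven models by name."""
    seed = kwargs.pop("seed", 0)
    if model == "conditional_std":
        return ConditionalStandardization(dataset, **kwargs).fit(seed=seed)
    return PooledPenalizedModel(dataset, model=model, **kwargs).fit(seed=seed)
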