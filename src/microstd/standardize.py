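"""Population standardization of stratum-specific effects, p-values, and FDR.

The population effect of feature j is the confounder-prevalence-weighted
average of its stratum-specific effects,

    beta_j = sum_l beta_j^l * Pr(L = l),

and the standardized debiased estimate and its standard error combine as

    b_j  = sum_l b_j^l * Pr(L = l),
    se_j = sqrt( sum_l [ se_j^l * Pr(L = l) ]^2 ),

the variance formula following from independence of the strata.  A
feature screened out in stratum l contributes (0, 0) there.  Two-sided
normal p-values p_j = 2[1 - Phi(|b_j|/se_j)] are computed for features
retained in at least one stratum (a strict variant requires every
stratum), and Benjamini-Hochberg adjustment runs over all p features,
entering screened-out features at p = 1 — multiplicity is charged for
every feature examined, not only the survivors.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import StratumWeights
from .debias import DebiasedFit


@dataclass
class PopulationResult:
    """Per-feature population-level estimates, inference, and selection flags."""

    feature_ids: list[str]
    selection_estimate: np.ndarray      # standardized penalized estimate beta_hat_j
    estimate: np.ndarray                # standardized debiased estimate b_hat_j
    se: np.ndarray                      # se(b_hat_j); 0 where untested
    p_value: np.ndarray                 # NaN where untested
    q_value: np.ndarray                 # NaN where untested
    selected: np.ndarray                # q < alpha
    alpha: float
    stratum_estimates: dict = field(default_factory=dict)   # level -> full-p vector
    stratum_se: dict = field(default_factory=dict)          # level -> full-p vector
    stratum_retained: dict = field(default_factory=dict)    # level -> bool mask
    weights: Optional[StratumWeights] = None

    @property
    def tested(self) -> np.ndarray:
        return ~np.isnan(self.p_value)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "feature_id": self.feature_ids,
            "estimate": self.estimate,
            "se": self.se,
            "p_value": self.p_value,
            "q_value": self.q_value,
            "selected": self.selected,
        })
        for lev in self.stratum_estimates:
            df[f"estimate_{lev}"] = self.stratum_estimates[lev]
            df[f"se_{lev}"] = self.stratum_se[lev]
        return df


def estimate_stratum_weights(confounder, user_weights: Optional[StratumWeights] = None
                             ) -> StratumWeights:
    """Empirical prevalences n_l/n, or user-supplied target-population weights."""
    confounder = np.asarray(confounder)
    if confounder.size == 0:
        raise ValueError("empty confounder labels")
    levels: dict = {}
    for lev in confounder:
        levels[lev] = levels.get(lev, 0) + 1
    if user_weights is not None:
        user_weights.validate_levels(list(levels))
        return user_weights
    n = confounder.size
    return StratumWeights({lev: cnt / n for lev, cnt in levels.items()})


def standardize_effects(stratum_estimates: Mapping, weights: StratumWeights) -> np.ndarray:
    """Elementwise weighted average of stratum-specific coefficient vectors."""
    weights.validate_levels(list(stratum_estimates))
    out = None
    for lev, vec in stratum_estimates.items():
        vec = np.asarray(vec, dtype=float)
        term = weights[lev] * vec
        out = term if out is None else out + term
    return out


def standardize_debiased(stratum_fits: Mapping, weights: StratumWeights,
                         n_features: int, require_all_strata: bool = False):
    """Combine per-stratum debiased fits into population (b_hat, se, tested).

    ``stratum_fits`` maps level -> DebiasedFit (or None when nothing was
    retained in that stratum); each fit's ``features`` indexes the full
    feature list.  Screened-out features contribute estimate 0 and se 0.
    ``tested`` marks features retained in at least one stratum (all strata
    when ``require_all_strata``) whose combined se is positive.
    """
    weights.validate_levels(list(stratum_fits))
    b = np.zeros(n_features)
    var = np.zeros(n_features)
    retained_any = np.zeros(n_features, dtype=bool)
    retained_all = np.ones(n_features, dtype=bool)
    for lev, fit in stratum_fits.items():
        mask = np.zeros(n_features, dtype=bool)
        if fit is not None:
            if fit.features is None:
                raise ValueError("DebiasedFit.features must index the full feature list")
            idx = np.asarray(fit.features, dtype=int)
            mask[idx] = True
            w = weights[lev]
            b[idx] += w * fit.estimates
            var[idx] += (w * fit.se) ** 2
        retained_any |= mask
        retained_all &= mask
    se = np.sqrt(var)
    tested = (retained_all if require_all_strata else retained_any) & (se > 0)
    return b, se, tested


def population_pvalues(b: np.ndarray, se: np.ndarray,
                       tested: Optional[np.ndarray] = None) -> np.ndarray:
    """Two-sided normal p-values; NaN for untested features."""
    b = np.asarray(b, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(se < 0):
        raise ValueError("negative standard error")
    if tested is None:
        tested = se > 0
    p = np.full(b.shape, np.nan)
    z = np.abs(b[tested]) / se[tested]
    p[tested] = 2.0 * stats.norm.sf(z)
    return p


def bh_adjust(p_values: np.ndarray, p_total: Optional[int] = None,
              alpha: float = 0.05):
    """Benjamini-Hochberg step-up over all ``p_total`` features.

    ``p_values`` may contain NaN for untested features; those (and the
    implicit ``p_total - len(p_values)`` extra hypotheses) enter the
    adjustment at p = 1.  Returns ``(q_values, selected)`` aligned with the
    input, with NaN q for untested features and ``selected = q < alpha``.
    """
    p_values = np.asarray(p_values, dtype=float)
    tested = ~np.isnan(p_values)
    pv = p_values[tested]
    if np.any((pv < 0) | (pv > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p_values.size if p_total is None else int(p_total)
    if m < p_values.size:
        raise ValueError("p_total smaller than the number of features supplied")
    n_extra = m - p_values.size + int((~tested).sum())
    full = np.concatenate([pv, np.ones(n_extra)])
    order = np.argsort(full, kind="stable")
    ranked = full[order]
    q_sorted = ranked * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q_sorted = np.clip(q_sorted, 0.0, 1.0)
    q_unsorted = np.empty(m)
    q_unsorted[order] = q_sorted
    q = np.full(p_values.shape, np.nan)
    q[tested] = q_unsorted[: pv.size]  # first entries of `full` are the tested p-values
    selected = np.zeros(p_values.shape, dtype=bool)
    selected[tested] = q[tested] < alpha
    return q, selected
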