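"""Design matrices for the pooled comparison models.

Six pooled-data competitors to the conditional-standardization estimator,
defined by two choices: how the confounder enters the model (screened and
penalized like any feature: "select_l"; forced in without penalty:
"require_l"; omitted: "ignore_l"), and whether feature effects may differ
by stratum (suffix "_effmod", giving one within-stratum-scaled coefficient
block per confounder level — for a binary confounder, 2p penalized
feature columns — with population effects recovered by the standardization
average).  Non-effmod designs use pooled-scaled features and a single
coefficient per feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .data_io import StratifiedDataset, StratumWeights
from .preprocess import ScaledFeatures, center_scale

MODEL_NAMES = (
    "conditional_std",
    "select_l",
    "select_l_effmod",
    "require_l",
    "require_l_effmod",
    "ignore_l",
    "ignore_l_effmod",
)

POOLED_NAMES = tuple(m for m in MODEL_NAMES if m != "conditional_std")


@dataclass
class ModelSpec:
    """One comparison-model definition."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model name {self.name!r}; choose from {MODEL_NAMES}")

    @property
    def effmod(self) -> bool:
        return self.name.endswith("_effmod") or self.name == "conditional_std"

    @property
    def l_role(self) -> str:
        """How the confounder column enters: 'penalized', 'unpenalized', or 'none'."""
        if self.name.startswith("select_l"):
            return "penalized"
        if self.name.startswith("require_l"):
            return "unpenalized"
        return "none"

    @property
    def scaling(self) -> str:
        return "within-stratum" if self.effmod else "pooled"


@dataclass
class Design:
    """A built design matrix with column roles.

    ``col_feature[k]`` is the original feature index of column k (-1 for
    confounder indicator columns); ``col_level[k]`` is the stratum whose
    block column k belongs to (None for shared columns).  ``penalized``
    marks the screenable/penalizable columns.
    """

    X: np.ndarray
    penalized: np.ndarray
    col_feature: np.ndarray
    col_level: np.ndarray
    scaled: ScaledFeatures
    levels: list

    @property
    def unpenalized_indices(self) -> Optional[list[int]]:
        idx = np.where(~self.penalized)[0].tolist()
        return idx or None


def _indicator_columns(data: StratifiedDataset) -> np.ndarray:
    """One 0/1 indicator per non-reference confounder level (binary L -> 1 column)."""
    levels = data.levels
    cols = [(data.confounder == lev).astype(float) for lev in levels[1:]]
    return np.column_stack(cols) if cols else np.empty((data.n_samples, 0))


def build_design(spec: ModelSpec, data: StratifiedDataset) -> Design:
    """Map a dataset to the pooled design matrix of one comparison model.

    The conditional-standardization model is fitted stratum by stratum and
    has no single pooled design; requesting it here is an error.
    """
    if spec.name == "conditional_std":
        raise ValueError(
            "conditional_std is fitted per stratum (use ConditionalStandardization), "
            "not via a pooled design"
        )
    levels = data.levels
    # With a single confounder level the effmod block degenerates to the plain
    # feature matrix and the indicator set is empty, so all designs coincide.

    counts = np.asarray(data.counts, dtype=float)
    if spec.effmod:
        scaled = center_scale(counts, strata=data.confounder)
        blocks, feats, levs = [], [], []
        for lev in levels:
            usable = np.where(~scaled.zero_variance[lev])[0]
            block = np.zeros((data.n_samples, usable.size))
            idx = data.stratum(lev)
            block[idx] = scaled.values[np.ix_(idx, usable)]
            blocks.append(block)
            feats.append(usable)
            levs.append(np.full(usable.size, lev, dtype=object))
        X = np.hstack(blocks)
        col_feature = np.concatenate(feats)
        col_level = np.concatenate(levs)
    else:
        scaled = center_scale(counts, strata=None)
        usable = np.where(~scaled.zero_variance[None])[0]
        X = scaled.values[:, usable]
        col_feature = usable.copy()
        col_level = np.full(usable.size, None, dtype=object)

    penalized = np.ones(X.shape[1], dtype=bool)
    if spec.l_role != "none":
        L = _indicator_columns(data)
        X = np.hstack([X, L])
        col_feature = np.concatenate([col_feature, -np.ones(L.shape[1], dtype=int)])
        col_level = np.concatenate([col_level, np.full(L.shape[1], None, dtype=object)])
        penalized = np.concatenate(
            [penalized, np.full(L.shape[1], spec.l_role == "penalized")])
    return Design(X=X, penalized=penalized, col_feature=col_feature.astype(int),
                  col_level=col_level, scaled=scaled, levels=levels)


def population_effects_from_effmod(coef: np.ndarray, design: Design,
                                   weights: StratumWeights, n_features: int) -> np.ndarray:
    """Standardize an effmod fit's stratum blocks to population effects.

    For a non-effmod design the shared feature coefficients are passed
    through unchanged.  Features excluded from a stratum's block (zero
    variance there) contribute 0 in that stratum; features absent from all
    blocks get 0.
    """
    out = np.zeros(n_features)
    feature_cols = design.col_feature >= 0
    if design.col_level[feature_cols].tolist() and design.col_level[feature_cols][0] is not None:
        for k in np.where(feature_cols)[0]:
            out[design.col_feature[k]] += weights[design.col_level[k]] * coef[k]
    else:
        for k in np.where(feature_cols)[0]:
            out[design.col_feature[k]] = coef[k]
    return out
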