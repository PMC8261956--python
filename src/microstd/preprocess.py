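"""Low-abundance filtering, rarefaction, and feature centering/scaling.

Centering and scaling can be done either within each confounder stratum
(used by the conditional estimator and the effect-modification designs)
or pooled across all samples (used by the common-effect pooled designs).
Effects estimated on the scaled features are per one-standard-deviation
change in the feature.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np


@dataclass
class ScaledFeatures:
    """A centered/scaled feature matrix plus the transform that produced it.

    ``mode`` is "within-stratum" or "pooled".  ``centers`` and ``scales``
    map scaling group -> per-feature vectors (a single group ``None`` in
    pooled mode).  ``zero_variance`` maps group -> boolean mask of features
    that were constant in that group; such features are set to 0 there and
    must be excluded from that group's model fit (they are collinear with
    the intercept).
    """

    values: np.ndarray
    mode: str
    centers: dict
    scales: dict
    zero_variance: dict
    group_index: dict

    def usable(self, group=None) -> np.ndarray:
        """Boolean mask of features with positive variance in ``group``."""
        key = group if self.mode == "within-stratum" else None
        return ~self.zero_variance[key]

    def inverse(self) -> np.ndarray:
        """Reconstruct the raw values from the stored transform."""
        raw = np.empty_like(self.values)
        for key, idx in self.group_index.items():
            raw[idx] = self.values[idx] * self.scales[key] + self.centers[key]
        return raw


def filter_low_abundance(counts: np.ndarray, min_nonzero: int = 4):
    """Drop features observed (count > 0) in fewer than ``min_nonzero`` samples.

    Returns ``(reduced_counts, kept_index)`` where ``kept_index`` maps the
    retained columns back to their original positions.  Idempotent.
    """
    counts = np.asarray(counts)
    n = counts.shape[0]
    if min_nonzero < 1:
        raise ValueError("min_nonzero must be >= 1")
    if min_nonzero > n:
        raise ValueError(f"min_nonzero={min_nonzero} exceeds the number of samples ({n})")
    nonzero = (counts > 0).sum(axis=0)
    kept = np.where(nonzero >= min_nonzero)[0]
    return counts[:, kept], kept


def rarefy(counts: np.ndarray, depth: int, seed) -> np.ndarray:
    """Subsample each sample's reads without replacement to a common depth.

    Each row is replaced by a multivariate-hypergeometric draw of exactly
    ``depth`` reads from its observed reads, so row sums equal ``depth``
    and no count increases.  Deterministic under ``seed``.
    """
    counts = np.asarray(counts, dtype=np.int64)
    totals = counts.sum(axis=1)
    short = np.where(totals < depth)[0]
    if short.size:
        raise ValueError(
            f"library size below rarefaction depth {depth} for sample rows {short.tolist()} "
            f"(sizes {totals[short].tolist()})"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(counts)
    for i in range(counts.shape[0]):
        out[i] = rng.multivariate_hypergeometric(counts[i], depth)
    return out


def center_scale(values: np.ndarray, strata: Optional[np.ndarray] = None,
                 ddof: int = 1) -> ScaledFeatures:
    """Center to mean 0 and scale to variance 1, per stratum or pooled.

    Within each scaling group every non-constant feature column is
    transformed to sample mean 0 and sample variance 1 (denominator
    ``n - ddof``).  Constant columns are flagged zero-variance and set to 0
    in that group.  Groups of fewer than 2 samples are an error.
    """
    X = np.asarray(values, dtype=float)
    n = X.shape[0]
    if strata is not None:
        strata = np.asarray(strata)
        groups: dict = {}
        for lev in strata:
            if lev not in groups:
                groups[lev] = np.where(strata == lev)[0]
        mode = "within-stratum"
    else:
        groups = {None: np.arange(n)}
        mode = "pooled"

    out = np.empty_like(X)
    centers, scales, zero_var = {}, {}, {}
    for key, idx in groups.items():
        if idx.size < 2:
            raise ValueError(f"scaling group {key!r} has {idx.size} sample(s); need >= 2")
        block = X[idx]
        mu = block.mean(axis=0)
        sd = block.std(axis=0, ddof=ddof)
        zv = sd == 0
        safe_sd = np.where(zv, 1.0, sd)
        out[idx] = (block - mu) / safe_sd
        out[np.ix_(idx, np.where(zv)[0])] = 0.0
        centers[key] = mu
        scales[key] = safe_sd
        zero_var[key] = zv
    return ScaledFeatures(values=out, mode=mode, centers=centers, scales=scales,
                          zero_variance=zero_var, group_index=groups)
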