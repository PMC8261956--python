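"""Reading count tables and sample metadata; writing per-feature results.

The on-disk formats are plain tab-delimited text: a count table with one
header row and one id column (samples as rows or features as rows), and a
metadata table keyed by sample id with one continuous outcome column and
one categorical confounder column.  Samples are always matched by id,
never by row order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class StratifiedDataset:
    """A sample x feature count matrix with outcome and confounder labels.

    Parameters
    ----------
    counts : (n, p) int ndarray
        Nonnegative read counts, samples as rows.
    sample_ids, feature_ids : sequences of str
        Unique identifiers; ``feature_ids`` must be unique.
    outcome : (n,) float ndarray
        Continuous response Y_i.
    confounder : (n,) array of labels
        Categorical confounder L_i with a finite level set; every level
        must contain at least 2 samples so within-stratum variances exist.
    """

    counts: np.ndarray
    sample_ids: list[str]
    feature_ids: list[str]
    outcome: np.ndarray
    confounder: np.ndarray
    level_index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.outcome = np.asarray(self.outcome, dtype=float)
        self.confounder = np.asarray(self.confounder)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.feature_ids = [str(f) for f in self.feature_ids]
        n, p = self.counts.shape
        if (self.counts < 0).any():
            raise DataError("count matrix has negative entries")
        if len(self.sample_ids) != n or len(self.outcome) != n or len(self.confounder) != n:
            raise DataError("counts, sample_ids, outcome and confounder disagree on n")
        if len(self.feature_ids) != p:
            raise DataError("feature_ids length does not match counts")
        if len(set(self.feature_ids)) != p:
            raise DataError("feature_ids are not unique")
        if not np.all(np.isfinite(self.outcome)):
            bad = [self.sample_ids[i] for i in np.where(~np.isfinite(self.outcome))[0]]
            raise DataError(f"non-finite outcome for samples {bad}")
        self.level_index = {}
        for lev in self.levels:
            idx = np.where(self.confounder == lev)[0]
            if idx.size < 2:
                raise DataError(
                    f"confounder level {lev!r} has {idx.size} sample(s); at least 2 required"
                )
            self.level_index[lev] = idx

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_features(self) -> int:
        return self.counts.shape[1]

    @property
    def levels(self) -> list:
        # stable order of first appearance
        seen: dict = {}
        for lev in self.confounder:
            seen.setdefault(lev, None)
        return list(seen)

    def stratum(self, level) -> np.ndarray:
        """Row indices of the samples in one confounder stratum."""
        return self.level_index[level]

    def with_counts(self, counts: np.ndarray, feature_ids: Sequence[str]) -> "StratifiedDataset":
        """Copy of this dataset with a replaced count matrix (e.g. after filtering)."""
        return StratifiedDataset(
            counts=counts,
            sample_ids=list(self.sample_ids),
            feature_ids=list(feature_ids),
            outcome=self.outcome.copy(),
            confounder=self.confounder.copy(),
        )


@dataclass
class StratumWeights:
    """Target-population confounder prevalences Pr(L = l)."""

    weights: dict

    def __post_init__(self) -> None:
        w = np.array(list(self.weights.values()), dtype=float)
        if (w < 0).any():
            raise DataError("stratum weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-8:
            raise DataError(f"stratum weights sum to {w.sum()!r}, not 1")

    def __getitem__(self, level) -> float:
        return self.weights[level]

    @property
    def levels(self) -> list:
        return list(self.weights)

    def validate_levels(self, levels: Sequence) -> None:
        if set(self.weights) != set(levels):
            raise DataError(
                f"weight levels {sorted(map(str, self.weights))} do not match "
                f"dataset levels {sorted(map(str, levels))}"
            )


def read_count_table(path, orientation: str = "samples-as-rows"):
    """Read a tab-delimited count table.

    Returns ``(counts, sample_ids, feature_ids)`` with counts always in
    samples x features orientation.  The first column holds ids; the header
    row holds the ids of the other axis.
    """
    if orientation not in ("samples-as-rows", "features-as-rows"):
        raise ValueError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates or df.columns.has_duplicates:
        raise DataError(f"{path}: duplicate row or column ids")
    mat = np.empty(df.shape, dtype=np.int64)
    for j, col in enumerate(df.columns):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.isna() | (vals != np.floor(vals.fillna(0)))
        if bad.any():
            i = int(np.argmax(bad.to_numpy()))
            raise DataError(
                f"{path}: non-integer count {df[col].iloc[i]!r} "
                f"at row {df.index[i]!r}, column {col!r}"
            )
        if (vals < 0).any():
            i = int(np.argmax((vals < 0).to_numpy()))
            raise DataError(
                f"{path}: negative count {int(vals.iloc[i])} "
                f"at row {df.index[i]!r}, column {col!r}"
            )
        mat[:, j] = vals.to_numpy(dtype=np.int64)
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    if orientation == "samples-as-rows":
        return mat, row_ids, col_ids
    return mat.T, col_ids, row_ids


def read_metadata(path, outcome_col: str, confounder_col: str) -> pd.DataFrame:
    """Read sample metadata keyed by sample id.

    Returns a DataFrame indexed by sample id with columns ``outcome``
    (float) and ``confounder`` (str).  Missing values are errors: silently
    dropping samples would change the stratum sizes and hence the
    standardization weights.
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        raise DataError(f"{path}: duplicate sample ids")
    for col in (outcome_col, confounder_col):
        if col not in df.columns:
            raise DataError(f"{path}: missing column {col!r}")
    out = pd.DataFrame(index=df.index.astype(str))
    outcome = pd.to_numeric(df[outcome_col], errors="coerce")
    bad = df.index[outcome.isna()].tolist()
    if bad:
        raise DataError(f"{path}: non-numeric or missing outcome for samples {bad}")
    conf = df[confounder_col]
    bad = df.index[conf.isna()].tolist()
    if bad:
        raise DataError(f"{path}: missing confounder for samples {bad}")
    out["outcome"] = outcome.to_numpy(dtype=float)
    out["confounder"] = conf.astype(str).to_numpy()
    if out["confounder"].nunique() < 2:
        raise DataError(f"{path}: confounder column {confounder_col!r} has fewer than 2 levels")
    return out


def build_dataset(counts, sample_ids, feature_ids, metadata: pd.DataFrame) -> StratifiedDataset:
    """Align a count table with metadata by sample id and build the dataset.

    Metadata may be a superset of the count samples (study-wide files are
    common); extra metadata rows are ignored with a warning.  Count samples
    missing from the metadata are a hard error.
    """
    meta_ids = set(metadata.index)
    missing = [s for s in sample_ids if s not in meta_ids]
    if missing:
        raise DataError(f"samples missing from metadata: {missing}")
    extra = sorted(meta_ids - set(sample_ids))
    if extra:
        logger.warning("ignoring %d metadata sample(s) absent from count table: %s", len(extra), extra)
    aligned = metadata.loc[list(sample_ids)]
    return StratifiedDataset(
        counts=np.asarray(counts),
        sample_ids=list(sample_ids),
        feature_ids=list(feature_ids),
        outcome=aligned["outcome"].to_numpy(dtype=float),
        confounder=aligned["confounder"].to_numpy(),
    )


def load_dataset(counts_path, metadata_path, outcome_col, confounder_col,
                 orientation="samples-as-rows") -> StratifiedDataset:
    counts, sample_ids, feature_ids = read_count_table(counts_path, orientation)
    meta = read_metadata(metadata_path, outcome_col, confounder_col)
    return build_dataset(counts, sample_ids, feature_ids, meta)


def write_results(result, path) -> None:
    """Write a per-feature results table (one row for each of the p features).

    Columns: feature_id, estimate, se, p_value, q_value, selected, and one
    ``estimate_<level>`` / ``se_<level>`` pair per confounder stratum.
    Features screened out in every stratum have empty p/q cells.  Values
    are written with 12 significant digits so a re-read reproduces them.
    """
    df = result.to_frame()
    float_cols = [c for c in df.columns if c not in ("feature_id", "selected")]
    out = df.copy()
    for c in float_cols:
        out[c] = [("" if pd.isna(v) else format(v, ".12g")) for v in df[c]]
    out["selected"] = df["selected"].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    """Read back a results table written by :func:`write_results`."""
    df = pd.read_csv(path, sep="\t", dtype={"feature_id": str})
    df["selected"] = df["selected"].map({"true": True, "false": False, True: True, False: False})
    return df
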