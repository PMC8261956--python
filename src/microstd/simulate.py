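"""Synthetic confounded microbiome studies and the evaluation benchmark.

The generator emulates an amplicon study with a balanced binary
confounder L (first n/2 samples have L=1): feature counts are negative
binomial with Var = mu + phi*mu^2 (gamma-Poisson mixture; phi=1e-6
approximates Poisson), baseline mean gamma_0j = 5 for the s relevant
features and log-normal(1/2, 9/4) otherwise, and a multiplicative
confounder shift gamma_1j ~ log-normal(+-1/4, 9/4) on the first 30% of
features (the rest are unaffected, gamma_1j = 1).  The outcome is
Gaussian around a sparse linear model on the within-stratum standardized
features,

    mu_i = beta_0 + sum_j Atilde_ij beta_j              if L_i = 0,
    mu_i = beta_0 + beta_ell + sum_j Atilde_ij delta beta_j   if L_i = 1,

with sigma^2 = 1/16, nonzero effects (3, -3, 3, -3, 3), and delta = 1 (no
effect modification) or delta = -0.9 (strong effect modification: large
conditional effects, small population effects).  Three scenarios place
all, three, or none of the relevant features in the confounder-affected
block.  The full factorial — 2 dimensionalities x 2 sample sizes x 2
count distributions x 2 effect-modification levels x 3 scenarios — gives
48 settings; each is evaluated over replicated datasets with TPR, FPR,
FDP(alpha), and AUC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from itertools import product
from typing import Iterable, Optional, Sequence

import numpy as np
from sklearn.metrics import roc_auc_score

from .data_io import StratifiedDataset

DEFAULT_ALPHA_GRID = tuple(round(0.01 * k, 2) for k in range(1, 11))


@dataclass
class SimulationConfig:
    """Parameters of one simulation setting (defaults: the base study conditions)."""

    n: int = 100
    p: int = 50
    phi: float = 1e-1               # NB dispersion; 1e-6 approximates Poisson
    delta: float = 1.0              # effect-modification multiplier (-0.9 = strong)
    beta_l: float = 1.0             # direct (additive) confounder effect on the outcome
    beta0: float = 0.0
    sigma2: float = 1.0 / 16.0
    s: int = 5
    beta_values: tuple = (3.0, -3.0, 3.0, -3.0, 3.0)
    prop_affected: float = 0.30     # fraction of features shifted by the confounder
    scenario: float = 1.0           # fraction of relevant features confounded {0, 0.6, 1}
    gamma1_sign: str = "random"     # {'random', 'all_plus', 'all_minus'} for +-1/4
    gamma0_log_mean: float = 0.5
    gamma0_log_var: float = 9.0 / 4.0
    gamma1_log_mean: float = 0.25
    gamma1_log_var: float = 9.0 / 4.0
    relevant_gamma0: float = 5.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n % 2:
            raise ValueError("n must be even: the binary confounder is balanced")
        if self.s > self.p:
            raise ValueError("s cannot exceed p")
        if len(self.beta_values) != self.s:
            raise ValueError("beta_values must have length s")
        if self.scenario not in (0.0, 0.6, 1.0):
            raise ValueError("scenario must be one of 0, 0.6, 1.0")
        if self.phi < 0:
            raise ValueError("dispersion phi must be >= 0")
        if self.gamma1_sign not in ("random", "all_plus", "all_minus"):
            raise ValueError("gamma1_sign must be 'random', 'all_plus' or 'all_minus'")
        m = self.n_affected
        need = {1.0: self.s, 0.6: 3, 0.0: 0}[self.scenario]
        if m < need:
            raise ValueError("affected block too small for the requested scenario")
        if self.scenario < 1.0 and self.p - m < self.s - int(round(self.scenario * self.s)):
            raise ValueError("unaffected block too small for the requested scenario")

    @property
    def n_affected(self) -> int:
        return int(round(self.prop_affected * self.p))

    def relevant_index(self) -> np.ndarray:
        """Positions of the s relevant features under the scenario.

        100% confounded: the first s features (inside the affected block);
        60%: the first three affected plus the first two unaffected;
        0%: the first s unaffected features.
        """
        m = self.n_affected
        if self.scenario == 1.0:
            return np.arange(self.s)
        if self.scenario == 0.6:
            return np.concatenate([np.arange(3), m + np.arange(self.s - 3)])
        return m + np.arange(self.s)

    def beta(self) -> np.ndarray:
        """Full-length stratum-0 coefficient vector."""
        beta = np.zeros(self.p)
        beta[self.relevant_index()] = np.asarray(self.beta_values, dtype=float)
        return beta

    def confounder(self) -> np.ndarray:
        """L_i = 1 for the first n/2 samples, 0 for the rest."""
        return np.concatenate([np.ones(self.n // 2, dtype=int),
                               np.zeros(self.n // 2, dtype=int)])


@dataclass
class SimMetrics:
    """Aggregated benchmark metrics for one (setting, model) pair."""

    tpr: float                      # mean TPR of the q < 0.05 inference rule
    fpr: float
    tpr_selection: float            # mean TPR of the beta_hat != 0 selection rule
    fpr_selection: float
    fdp: dict                       # alpha -> mean FDP over replications with discoveries
    auc: float
    n_reps: int
    n_failed: int = 0
    records: list = field(default_factory=list)


def _negative_binomial(rng: np.random.Generator, mean: np.ndarray, phi: float,
                       size) -> np.ndarray:
    """Gamma-Poisson draw with Var = mu + phi*mu^2 (Poisson when phi = 0)."""
    mean = np.broadcast_to(np.asarray(mean, dtype=float), size)
    if phi == 0:
        return rng.poisson(mean)
    lam = rng.gamma(shape=1.0 / phi, scale=mean * phi)
    return rng.poisson(lam)


def simulate_features(config: SimulationConfig, rng: Optional[np.random.Generator] = None):
    """Draw the count matrix; returns ``(counts, truth)``.

    ``truth`` holds the confounder labels, relevant/affected indices, the
    per-feature baseline means gamma_0j and fold changes gamma_1j, and the
    coefficient vector.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n, p = config.n, config.p
    L = config.confounder()
    relevant = config.relevant_index()
    affected = np.arange(config.n_affected)

    gamma0 = rng.lognormal(config.gamma0_log_mean, np.sqrt(config.gamma0_log_var), p)
    gamma0[relevant] = config.relevant_gamma0
    gamma1 = np.ones(p)
    if affected.size:
        if config.gamma1_sign == "random":
            signs = rng.choice([-1.0, 1.0], size=affected.size)
        elif config.gamma1_sign == "all_plus":
            signs = np.ones(affected.size)
        else:
            signs = -np.ones(affected.size)
        gamma1[affected] = rng.lognormal(signs * config.gamma1_log_mean,
                                         np.sqrt(config.gamma1_log_var))

    mean = np.where(L[:, None] == 1, gamma0 * gamma1, gamma0)
    counts = _negative_binomial(rng, mean, config.phi, (n, p))
    truth = {
        "L": L,
        "relevant": relevant,
        "affected": affected,
        "gamma0": gamma0,
        "gamma1": gamma1,
        "beta": config.beta(),
    }
    return counts, truth


def simulate_response(counts: np.ndarray, config: SimulationConfig,
                      rng: Optional[np.random.Generator] = None,
                      L: Optional[np.ndarray] = None) -> np.ndarray:
    """Draw the outcome given simulated counts.

    Features enter the mean after within-stratum centering/scaling; a
    relevant feature that is constant within a stratum (essentially never
    at these abundances) is excluded from that stratum's mean with a
    warning.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if L is None:
        L = config.confounder()
    counts = np.asarray(counts, dtype=float)
    beta = config.beta()
    mu = np.full(config.n, config.beta0, dtype=float)
    for lev, mult, shift in ((0, 1.0, 0.0), (1, config.delta, config.beta_l)):
        idx = np.where(L == lev)[0]
        block = counts[idx]
        sd = block.std(axis=0, ddof=1)
        degenerate = (sd == 0) & (beta != 0)
        if degenerate.any():
            warnings.warn(
                f"relevant feature(s) {np.where(degenerate)[0].tolist()} constant in "
                f"stratum {lev}; excluded from the outcome mean there", stacklevel=2)
        ok = sd > 0
        A = (block[:, ok] - block[:, ok].mean(axis=0)) / sd[ok]
        mu[idx] += shift + A @ (mult * beta[ok])
    return mu + rng.normal(0.0, np.sqrt(config.sigma2), config.n)


def simulate_dataset(config: SimulationConfig, seed: Optional[int] = None):
    """One complete synthetic study; returns ``(StratifiedDataset, truth)``."""
    rng = np.random.default_rng(config.seed if seed is None else seed)
    counts, truth = simulate_features(config, rng)
    y = simulate_response(counts, config, rng, truth["L"])
    n, p = config.n, config.p
    data = StratifiedDataset(
        counts=counts,
        sample_ids=[f"S{i + 1:04d}" for i in range(n)],
        feature_ids=[f"F{j + 1:04d}" for j in range(p)],
        outcome=y,
        confounder=np.array(["1" if l == 1 else "0" for l in truth["L"]]),
    )
    return data, truth


def tpr_fpr(selected: np.ndarray, truth_mask: np.ndarray):
    """True/false positive rates of a selection set against the truth."""
    selected = np.asarray(selected, dtype=bool)
    truth_mask = np.asarray(truth_mask, dtype=bool)
    pos = truth_mask.sum()
    neg = (~truth_mask).sum()
    tpr = (selected & truth_mask).sum() / pos if pos else np.nan
    fpr = (selected & ~truth_mask).sum() / neg if neg else np.nan
    return tpr, fpr


def fdp_at(q_values: np.ndarray, truth_mask: np.ndarray, alpha: float) -> float:
    """False discovery proportion at threshold alpha; NaN with no discoveries."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    q = np.asarray(q_values, dtype=float)
    disc = ~np.isnan(q) & (q < alpha)
    n_disc = disc.sum()
    if n_disc == 0:
        return np.nan
    return float((disc & ~np.asarray(truth_mask, dtype=bool)).sum() / n_disc)


def pvalue_auc(p_values: np.ndarray, truth_mask: np.ndarray) -> float:
    """ROC AUC using p-values as classifier scores (smaller = more positive).

    Features without a p-value (screened out everywhere) enter at p = 1;
    ties are handled by mid-ranking.
    """
    p = np.asarray(p_values, dtype=float).copy()
    p[np.isnan(p)] = 1.0
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if truth_mask.all() or (~truth_mask).all():
        return np.nan
    return float(roc_auc_score(truth_mask.astype(int), -p))


def all_settings(n_values=(50, 100), p_values=(50, 2000), phi_values=(1e-1, 1e-6),
                 delta_values=(1.0, -0.9), scenarios=(1.0, 0.6, 0.0),
                 **common) -> list[SimulationConfig]:
    """Enumerate the full factorial of study settings (48 by default)."""
    return [SimulationConfig(n=n, p=p, phi=phi, delta=delta, scenario=sc, **common)
            for p, n, phi, delta, sc in product(p_values, n_values, phi_values,
                                                delta_values, scenarios)]


def run_replications(config: SimulationConfig, model_names: Sequence[str] = ("conditional_std",),
                     n_reps: int = 100, alpha_grid: Iterable[float] = DEFAULT_ALPHA_GRID,
                     seed: int = 0, fdr: float = 0.05, penalty: str = "lasso",
                     screen: str = "isis", max_failure_rate: float = 0.10,
                     **model_kwargs) -> dict:
    """Fit each model on replicated datasets and aggregate the benchmark metrics.

    Replication seeds derive deterministically from ``seed``.  Individual
    replication failures are recorded; the run errors only if more than
    ``max_failure_rate`` of replications fail for some model.
    Returns ``{model_name: SimMetrics}``.
    """
    from .model import fit_model  # local import to avoid a cycle

    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    alpha_grid = list(alpha_grid)
    child_seeds = [int(s.generate_state(1)[0] & 0x7FFFFFFF)
                   for s in np.random.SeedSequence(seed).spawn(n_reps)]
    records: dict = {m: [] for m in model_names}
    failures: dict = {m: 0 for m in model_names}
    for rep, rep_seed in enumerate(child_seeds):
        data, truth = simulate_dataset(config, seed=rep_seed)
        truth_mask = np.zeros(config.p, dtype=bool)
        truth_mask[truth["relevant"]] = True
        for name in model_names:
            try:
                res = fit_model(data, model=name, penalty=penalty, screen=screen,
                                alpha=fdr, seed=rep_seed, **model_kwargs)
            except Exception as exc:  # noqa: BLE001 - recorded, not fatal
                failures[name] += 1
                records[name].append({"rep": rep, "error": repr(exc)})
                continue
            sel_inf = res.population.selected
            sel_var = res.population.selection_estimate != 0
            t_i, f_i = tpr_fpr(sel_inf, truth_mask)
            t_s, f_s = tpr_fpr(sel_var, truth_mask)
            rec = {
                "rep": rep,
                "tpr": t_i, "fpr": f_i,
                "tpr_selection": t_s, "fpr_selection": f_s,
                "auc": pvalue_auc(res.population.p_value, truth_mask),
                "fdp": {a: fdp_at(res.population.q_value, truth_mask, a)
                        for a in alpha_grid},
            }
            records[name].append(rec)
    out = {}
    for name in model_names:
        if failures[name] > max_failure_rate * n_reps:
            raise RuntimeError(
                f"{failures[name]}/{n_reps} replications failed for model {name!r}")
        good = [r for r in records[name] if "error" not in r]
        def _mean(key):
            vals = np.array([r[key] for r in good], dtype=float)
            return float(np.nanmean(vals)) if np.any(~np.isnan(vals)) else np.nan
        fdp_means = {}
        for a in alpha_grid:
            vals = np.array([r["fdp"][a] for r in good], dtype=float)
            fdp_means[a] = float(np.nanmean(vals)) if np.any(~np.isnan(vals)) else np.nan
        out[name] = SimMetrics(
            tpr=_mean("tpr"), fpr=_mean("fpr"),
            tpr_selection=_mean("tpr_selection"), fpr_selection=_mean("fpr_selection"),
            fdp=fdp_means, auc=_mean("auc"),
            n_reps=n_reps, n_failed=failures[name], records=records[name],
        )
    return out


def metrics_frame(metrics: dict, config: SimulationConfig):
    """Flatten ``run_replications`` output to a tidy DataFrame (one row per model)."""
    import pandas as pd

    rows = []
    cfg = {k: v for k, v in asdict(config).items()
           if k in ("n", "p", "phi", "delta", "scenario")}
    for name, m in metrics.items():
        row = {"model": name, **cfg,
               "tpr": m.tpr, "fpr": m.fpr,
               "tpr_selection": m.tpr_selection, "fpr_selection": m.fpr_selection,
               "auc": m.auc, "n_reps": m.n_reps, "n_failed": m.n_failed}
        for a, v in m.fdp.items():
            row[f"fdp_{a:g}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
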