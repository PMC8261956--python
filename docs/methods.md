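# Methods

## The estimand and the model

`microstd` estimates the population-level effect of each microbiome
feature (OTU, ASV, or taxon) on a continuous outcome when a categorical
confounder `L` with finitely many, well-represented levels affects both
the features and the outcome.  The target is defined through a marginal
structural model on potential outcomes: the expected outcome under a
(possibly counterfactual) microbiome profile `a` is linear,
`E[Y^a] = beta_0 + sum_j beta_j a_j`.  Within each confounder stratum `l`
the observed data follow the stratum-specific linear model
`E[Y | A = a, L = l] = beta_0^l + sum_j beta_j^l a_j`, allowing effect
modification (`beta^l` differing across strata).  The population effect
is recovered by standardization to the confounder distribution of the
target population,

```
beta_j = sum_l beta_j^l Pr(L = l),
```

with `Pr(L = l)` either the empirical prevalence `n_l / n` or
user-supplied target-population weights.  Interpreting `beta` causally
requires positivity, conditional exchangeability (no unmeasured
confounding), and consistency; none of these are computable from the
data, and the package documents rather than verifies them.  Without
them the same estimates remain valid as associational effects.

Working within strata has a second, purely statistical payoff: a
confounder that shifts many feature means at once induces strong
*marginal* correlation among features and between irrelevant features
and the outcome, which is exactly the regime where marginal screening
and pooled penalized regression mis-select.  Conditioning removes that
shared component.

## The per-stratum estimator

Within each stratum (independently):

1. **Centering/scaling.**  Features are centered and scaled to sample
   variance one (denominator `n - 1`) within the stratum, so
   coefficients are per one within-stratum SD.  Features constant in a
   stratum are collinear with the intercept and are excluded from that
   stratum's model (they contribute effect 0 and SE 0 to the
   standardization sums) while remaining in the population feature list.
2. **Screening.**  Iterative sure independence screening with budget
   `d_l = floor(n_l / log n_l)`: an initial marginal screen to
   `ceil(2 d_l / 3)` features, then up to 4 further cycles that fit a
   BIC-tuned penalized regression on the recruited set, delete the
   features it zeroes, and recruit the features most correlated with the
   current residuals (up to the budget), stopping when the retained set
   stabilizes or reaches `d_l`.  Ties in |correlation| break to the
   lower feature index, which makes the ranking deterministic and
   permutation-equivariant.
3. **Penalized selection.**  LASSO (default) or SCAD (`a = 3.7`,
   solved by iterated local linear approximation) on the retained set,
   minimizing `(1/2n) RSS + sum_j p_lambda(beta_j)` by coordinate
   descent on the precomputed Gram matrix (convergence when the largest
   coefficient change is below 1e-8).  `lambda` is tuned by
   `BIC = n log(RSS/n) + df log n` over 100 log-spaced values from
   `lambda_max` down to `1e-3 lambda_max`, warm-started, with ties
   resolved to the sparser (larger-`lambda`) fit;
   `df = |active| + #unpenalized + 1`.
4. **Debiased inference.**  The desparsified-lasso correction
   `b = beta_hat + Theta X'(y - X beta_hat)/n` is applied to the
   BIC-tuned lasso fit on the screened columns.  `Theta` comes from
   nodewise lasso regressions with per-column `lambda` chosen by 10-fold
   cross-validation on a fold split fixed by the run seed.  Standard
   errors are `se_j = sigma_hat sqrt([Theta Sigma_hat Theta']_jj / n)`
   under homoscedastic noise.

**Noise scale.**  `sigma_hat` is, by default, the scaled-lasso estimate
on the screened design (universal penalty
`lambda_0 = sqrt(2 log m / n)`, alternating the lasso fit with
`sigma^2 = RSS/n` until convergence).  This choice is deliberate and is
the main numerically sensitive decision in the package: a residual-SD
estimate taken from the BIC-tuned fit itself collapses whenever the
iterative screening has recruited noise features (they were recruited
*because* they correlate with the residuals, so the fit absorbs real
noise variance), which silently inflates every z-statistic.  The scaled
lasso is self-tuning and immune to that, at the price of a conservative
(upward) bias when a few coefficients are very large, since their
shrinkage bias enters the RSS.  Two alternatives are available through
`sigma_method`: `"scaled_lasso_refit"` (OLS on the scaled-lasso active
set; removes the large-coefficient bias but re-exposes the recruited
noise, trading FDR control for power) and `"lasso_df"` (residual SD of
the initial fit with `df = n - |active| - 1`).  The default favors
honest error control.

## Population combination and multiplicity

Standardized estimates and standard errors combine across strata as

```
b_j  = sum_l b_j^l Pr(L = l)
se_j = sqrt( sum_l [ se_j^l Pr(L = l) ]^2 )
```

(the variance form follows from independence of the strata).  A feature
screened out in stratum `l` contributes `(0, 0)` there.  Two-sided
normal p-values `p_j = 2[1 - Phi(|b_j|/se_j)]` are computed for features
retained in at least one stratum; the phrase "not screened out in all
strata" is ambiguous between that reading and the stricter
"retained in every stratum", so the strict variant is available via
`require_all_strata=True`.  Benjamini–Hochberg adjustment always runs
over **all p features**, with screened-out features entering at
`p = 1`: multiplicity is charged for every feature examined.  With few
tested features among thousands this is severe by design — a single
`p = 0.001` among `p_total = 2000` untested companions is not a
discovery.

## Pooled comparison designs

Six pooled-data competitors share the machinery: the confounder
indicator can be screened and penalized like a feature (`select_l`),
forced in unpenalized (`require_l`, whose screening utilities are
correlations with the residual of the outcome on the confounder), or
omitted (`ignore_l`); each variant either shares feature coefficients
across strata (pooled-scaled features) or allows effect modification
(`*_effmod`: within-stratum-scaled features interacted with stratum
indicators, `2p` penalized columns for a binary confounder, population
effects recovered by the standardization average).  Pooled designs
screen with budget `d = floor(n / log n)`.  With a single confounder
level all seven models collapse to the same estimator; this degenerate
case is exercised in the tests.

## The synthetic-data generator

The generator emulates a balanced two-arm amplicon study (first `n/2`
samples have `L = 1`).  Counts are negative binomial via a gamma–Poisson
mixture with `Var = mu + phi mu^2` (`phi = 0.1`, or `1e-6` for the
Poisson-like regime).  Baseline means `gamma_0j` are 5 for the `s = 5`
relevant features (abundant enough to be selectable) and
log-normal(1/2, 9/4) otherwise; the first 30% of features are
confounder-affected through a multiplicative fold change
`gamma_1j ~ log-normal(+-1/4, 9/4)`, the sign an independent fair coin
per feature by default (configurable to all-up or all-down).  The
outcome is Gaussian with variance `sigma^2 = 1/16` around a sparse
linear model on the *within-stratum standardized* features with nonzero
effects `(3, -3, 3, -3, 3)`, a direct confounder shift `beta_ell = 1`
(configurable; only its existence, not its value, matters to the
estimand since the confounder is binary and balanced), and an effect
modification multiplier `delta` (`1` = none; `-0.9` = strong, making
population effects `0.05 beta_j` — large conditionally, small
marginally).  Three scenarios place all, three, or none of the relevant
features inside the affected block.  The factorial over
`p in {50, 2000}`, `n in {50, 100}`, two dispersions, two `delta`, and
three scenarios yields 48 settings.

What the generator does *not* emulate: library-size variation (every
count is an absolute draw), zero inflation beyond what the negative
binomial produces, compositional closure, and feature–feature ecological
interactions.  Passing benchmarks therefore demonstrate correct behavior
under categorical confounding with independent count noise, not
robustness to compositionality or depth artifacts — real studies should
be rarefied or otherwise normalized upstream (the package provides
multivariate-hypergeometric rarefaction and a minimum-prevalence filter,
default: features observed in fewer than 4 samples are removed).

## Evaluation metrics

Per replication: TPR and FPR of a selection rule against the simulated
truth (for the penalized paths, `beta_hat_j != 0` after standardization;
for the debiased path, the FDR-controlled decision `q_j < 0.05`),
`FDP(alpha)` over `alpha = 0.01, ..., 0.10` (a replication with no
discoveries contributes a missing value, excluded from the mean;
a zero-convention would shrink mean FDP toward 0 and is deliberately not
the default), and AUC using p-values as ranking scores (untested
features at `p = 1`, ties mid-ranked).

## Numerical choices and degenerate inputs

- Rarefaction uses exact multivariate-hypergeometric draws; a library
  below the requested depth is an error naming the samples.
- Missing outcome or confounder values are errors, never dropped:
  silent dropping would change `n_l` and hence the weights.
- A stratum with fewer than 5 samples aborts with advice to pool.
- Screened sets of size 1 use the exact 1x1 relaxed inverse; size 0
  yields no inference for that stratum.
- Exactly collinear columns in the nodewise design are an error.
- All randomness (rarefaction, CV folds, replication seeds) derives
  from one master seed; per-stratum seeds are spawned deterministically,
  so concurrent or sequential stratum processing gives identical output.

## Problem sizes in the shipped benchmarks

The packaged acceptance checks reproduce the low-dimensional benchmark
(p = 50, n = 100, Poisson-like, strong effect modification, all relevant
features confounded) over 100 replications, and the null-coverage study
(n = 100, ambient p = 150, screened set of 21 fixed independently of the
response) over 200 replications.  These sizes match the study design the
generator encodes; the high-dimensional settings (p = 2000) run through
the same code paths and are exercised at small scale in the unit tests.

## Known limitations

- FDR control after screening is not exact in principle: features
  recruited by residual correlation are selected on the same noise that
  the test evaluates.  With the default conservative noise scale the
  realized FDP stays below nominal in the benchmark settings, at some
  cost in power; with `scaled_lasso_refit` the power is near perfect but
  mean FDP can exceed nominal (~0.1 at nominal 0.05 in the strong
  effect-modification benchmark).  This trade-off is intrinsic, not a
  tuning artifact.
- BIC-tuned penalized *selection* (as opposed to the FDR-controlled
  test) retains noise features whose sample |z| exceeds ~sqrt(log n);
  at n = 100 this is a nontrivial false positive rate however the
  solver is implemented.
- Multi-level (non-binary) confounders are supported via one indicator
  per non-reference level in the pooled designs; the benchmark
  generator only exercises the binary case.
- BIOM-format input is not implemented; count tables are tab-delimited
  text.
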