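import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from microstd import (
    ConditionalStandardization,
    StratumWeights,
    bh_adjust,
    estimate_stratum_weights,
    population_pvalues,
    standardize_debiased,
    standardize_effects,
)
from microstd.debias import DebiasedFit


def make_db(features, estimates, se):
    m = len(features)
    return DebiasedFit(estimates=np.asarray(estimates, dtype=float),
                       se=np.asarray(se, dtype=float), sigma_hat=1.0,
                       theta=np.eye(m), lambda_nodewise=np.full(m, np.nan),
                       features=np.asarray(features))


class TestStratumWeights:
    def test_empirical_proportions(self):
        labels = np.array(["high"] * 17 + ["low"] * 17)
        w = estimate_stratum_weights(labels)
        assert w["high"] == pytest.approx(0.5)
        assert w["low"] == pytest.approx(0.5)

    def test_user_weights_returned_verbatim(self):
        labels = np.array(["a", "a", "b", "b", "b"])
        user = StratumWeights({"a": 0.3, "b": 0.7})
        assert estimate_stratum_weights(labels, user) is user

    def test_user_weights_with_unknown_level_rejected(self):
        labels = np.array(["a", "a", "b"])
        with pytest.raises(Exception):
            estimate_stratum_weights(labels, StratumWeights({"a": 0.5, "c": 0.5}))

    def test_renormalized_weights_change_nothing(self):
        est = {"a": np.array([2.0, 0.0]), "b": np.array([4.0, 1.0])}
        w1 = StratumWeights({"a": 0.25, "b": 0.75})
        doubled = {k: 2 * v for k, v in w1.weights.items()}
        w2 = StratumWeights({k: v / sum(doubled.values()) for k, v in doubled.items()})
        np.testing.assert_allclose(standardize_effects(est, w1),
                                   standardize_effects(est, w2))


class TestStandardizeEffects:
    @pytest.mark.parametrize("high,low,expected", [
        (6.36, 0.00, 3.18),
        (0.00, 9.37, 4.685),
        (7.45, 0.00, 3.725),
        (3.06, 0.00, 1.53),
    ])
    def test_equal_weight_average(self, high, low, expected):
        w = StratumWeights({"high": 0.5, "low": 0.5})
        out = standardize_effects({"high": np.array([high]), "low": np.array([low])}, w)
        assert out[0] == pytest.approx(expected, abs=1e-12)

    def test_identical_estimates_are_a_fixed_point(self):
        v = np.array([1.0, -2.0, 0.0])
        w = StratumWeights({"a": 0.2, "b": 0.8})
        np.testing.assert_allclose(standardize_effects({"a": v, "b": v}, w), v)

    def test_result_is_convex_combination(self, rng):
        a, b = rng.normal(size=6), rng.normal(size=6)
        w = StratumWeights({"a": 0.35, "b": 0.65})
        out = standardize_effects({"a": a, "b": b}, w)
        assert np.all(out >= np.minimum(a, b) - 1e-12)
        assert np.all(out <= np.maximum(a, b) + 1e-12)

    def test_level_mismatch_is_error(self):
        w = StratumWeights({"a": 0.5, "b": 0.5})
        with pytest.raises(Exception):
            standardize_effects({"a": np.zeros(2)}, w)


class TestStandardizeDebiased:
    def test_equal_weights_equal_se_combine_as_s_over_sqrt2(self):
        w = StratumWeights({"a": 0.5, "b": 0.5})
        fits = {"a": make_db([0], [1.0], [2.0]), "b": make_db([0], [3.0], [2.0])}
        b, se, tested = standardize_debiased(fits, w, n_features=1)
        assert b[0] == pytest.approx(2.0)
        assert se[0] == pytest.approx(2.0 / np.sqrt(2))

    def test_degenerate_weights_return_single_stratum(self):
        w = StratumWeights({"a": 1.0, "b": 0.0})
        fits = {"a": make_db([0], [1.5], [0.4]), "b": make_db([0], [9.9], [9.9])}
        b, se, tested = standardize_debiased(fits, w, n_features=1)
        assert b[0] == pytest.approx(1.5)
        assert se[0] == pytest.approx(0.4)

    def test_uneven_weights_arithmetic(self):
        w = StratumWeights({"a": 0.3, "b": 0.7})
        fits = {"a": make_db([0], [0.0], [2.0]), "b": make_db([0], [0.0], [1.0])}
        _, se, _ = standardize_debiased(fits, w, n_features=1)
        assert se[0] == pytest.approx(np.sqrt(0.6**2 + 0.7**2))

    def test_combined_se_bounded_by_max_stratum_se(self, rng):
        w = StratumWeights({"a": 0.4, "b": 0.6})
        s = rng.uniform(0.1, 3.0, size=4)
        fits = {"a": make_db(range(4), np.zeros(4), s),
                "b": make_db(range(4), np.zeros(4), s[::-1].copy())}
        _, se, _ = standardize_debiased(fits, w, n_features=4)
        assert np.all(se <= np.maximum(s, s[::-1]) + 1e-12)

    def test_feature_screened_out_in_one_stratum_contributes_zero(self):
        w = StratumWeights({"a": 0.5, "b": 0.5})
        fits = {"a": make_db([0, 1], [2.0, 4.0], [1.0, 1.0]),
                "b": make_db([0], [6.0], [1.0])}
        b, se, tested = standardize_debiased(fits, w, n_features=2)
        assert b.tolist() == [4.0, 2.0]
        assert se[1] == pytest.approx(0.5)
        assert tested.tolist() == [True, True]

    def test_strict_mode_requires_every_stratum(self):
        w = StratumWeights({"a": 0.5, "b": 0.5})
        fits = {"a": make_db([0, 1], [2.0, 4.0], [1.0, 1.0]),
                "b": make_db([0], [6.0], [1.0])}
        _, _, tested = standardize_debiased(fits, w, n_features=2, require_all_strata=True)
        assert tested.tolist() == [True, False]


class TestPvalues:
    def test_zero_estimate_gives_p_one(self):
        p = population_pvalues(np.array([0.0]), np.array([1.0]))
        assert p[0] == pytest.approx(1.0)

    @pytest.mark.parametrize("z,expected", [(1.959964, 0.05), (3.090232, 0.002)])
    def test_two_sided_normal_quantiles(self, z, expected):
        p = population_pvalues(np.array([z]), np.array([1.0]))
        assert p[0] == pytest.approx(expected, abs=5e-5)

    def test_untested_features_get_nan(self):
        p = population_pvalues(np.array([1.0, 1.0]), np.array([1.0, 0.0]),
                               tested=np.array([True, False]))
        assert np.isnan(p[1]) and np.isfinite(p[0])

    def test_negative_se_is_error(self):
        with pytest.raises(ValueError):
            population_pvalues(np.array([1.0]), np.array([-0.1]))


def bh_oracle(pvals, m, alpha):
    """Definition-based step-up: q_(i) = min_{k>=i} p_(k)*m/k, capped at 1."""
    order = np.argsort(pvals, kind="stable")
    q = np.empty(len(pvals))
    sorted_p = pvals[order]
    for i in range(len(pvals)):
        q[order[i]] = min(min(sorted_p[k] * m / (k + 1) for k in range(i, len(pvals))), 1.0)
    return q


class TestBhAdjust:
    def test_equal_pvalues_unchanged(self):
        p = np.full(4, 0.05)
        q, sel = bh_adjust(p)
        np.testing.assert_allclose(q, 0.05)

    def test_hand_computed_step_up(self):
        q, _ = bh_adjust(np.array([0.01, 0.02, 0.04]))
        np.testing.assert_allclose(q, [0.03, 0.03, 0.04])

    def test_full_p_correction_is_severe(self):
        # one tested p = 0.001 among p_total = 2000: the 1999 untested
        # hypotheses enter at p = 1, so q = min(2.0, 1) = 1 via the tail
        q, sel = bh_adjust(np.array([0.001]), p_total=2000)
        assert q[0] == pytest.approx(1.0)
        assert not sel[0]

    def test_untested_nan_features_get_nan_q(self):
        q, sel = bh_adjust(np.array([0.001, np.nan, 0.5]))
        assert np.isnan(q[1]) and not sel[1]
        assert np.isfinite(q[0]) and np.isfinite(q[2])

    def test_out_of_range_pvalue_is_error(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([1.5]))

    def test_q_at_least_p_and_monotone(self, rng):
        p = rng.uniform(size=30)
        q, _ = bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    @settings(max_examples=60, deadline=None)
    @given(st.integers(min_value=0, max_value=2**31 - 1),
           st.integers(min_value=1, max_value=50),
           st.integers(min_value=0, max_value=30))
    def test_matches_definition_oracle(self, seed, n_tested, n_extra):
        g = np.random.default_rng(seed)
        p = g.uniform(size=n_tested)
        m = n_tested + n_extra
        q, _ = bh_adjust(p, p_total=m)
        full = np.concatenate([p, np.ones(n_extra)])
        expect = bh_oracle(full, m, 0.05)[:n_tested]
        np.testing.assert_allclose(q, expect, atol=1e-12)


class TestSingleStratumCollapse:
    def test_pipeline_equals_unstratified_analysis(self, rng):
        """One confounder level: standardization must be a no-op."""
        from microstd.preprocess import center_scale
        from microstd.screening import isis_select
        from microstd.penalized import bic_select
        from microstd.debias import debias, nodewise_lasso
        from microstd.model import _derive_seed
        from microstd import StratifiedDataset

        n, p = 40, 12
        counts = rng.poisson(20, size=(n, p))
        X = counts.astype(float)
        A = (X - X.mean(0)) / X.std(0, ddof=1)
        y = 2.0 * A[:, 0] - 2.0 * A[:, 5] + rng.normal(0, 0.3, n)
        data = StratifiedDataset(counts=counts, sample_ids=[f"s{i}" for i in range(n)],
                                 feature_ids=[f"f{j}" for j in range(p)],
                                 outcome=y, confounder=np.array(["only"] * n))
        res = ConditionalStandardization(data, budget=6).fit(seed=9)

        # manual unstratified pipeline with the same derived seed
        sc = center_scale(X)
        Xs = sc.values
        sres = isis_select(Xs, y, penalty="lasso", d=6, max_iter=5)
        fit = bic_select(Xs[:, sres.retained], y, penalty="lasso")
        theta, _ = nodewise_lasso(Xs[:, sres.retained], seed=_derive_seed(9, 0))
        db = debias(Xs[:, sres.retained], y, fit, theta)

        np.testing.assert_allclose(
            res.population.estimate[sres.retained], db.estimates, atol=1e-10)
        np.testing.assert_allclose(
            res.population.se[sres.retained], db.se, atol=1e-10)
        beta = np.zeros(p)
        beta[sres.retained] = fit.coef
        np.testing.assert_allclose(res.population.selection_estimate, beta, atol=1e-10)
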