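"""Proportion CIs, sample size, random-intercept ICC, Cohen's kappa."""

from __future__ import annotations

import math

import numpy as np
import pytest
from numpy.polynomial.hermite import hermgauss
from scipy.special import expit

import hhflow as h
from hhflow.stats import (
    LATENT_LOGISTIC_VARIANCE,
    _agq_loglik,
    _cluster_stats,
)

from .oracles import oracle_clopper_pearson


class TestProportionCI:
    @pytest.mark.parametrize(
        "k,n,percent", [(192, 781, 24.6), (492, 781, 63.0), (75, 781, 9.6)]
    )
    def test_headline_percentages(self, k, n, percent):
        est = h.proportion_ci(k, n)
        assert round(est.percent, 1) == percent

    def test_zero_successes_boundary(self):
        est = h.proportion_ci(0, 50, method="clopper_pearson")
        assert est.percent == 0.0
        assert est.ci_low == 0.0
        assert est.ci_high > 0

    @pytest.mark.parametrize("k,n", [(30, 100), (0, 10), (10, 10), (1, 781), (60, 192)])
    def test_clopper_pearson_matches_tail_inversion(self, k, n):
        est = h.proportion_ci(k, n, method="clopper_pearson")
        lo, hi = oracle_clopper_pearson(k, n)
        assert est.ci_low / 100 == pytest.approx(lo, abs=1e-6)
        assert est.ci_high / 100 == pytest.approx(hi, abs=1e-6)

    def test_wilson_differs_but_brackets_p_hat(self):
        cp = h.proportion_ci(30, 100, method="clopper_pearson")
        wi = h.proportion_ci(30, 100, method="wilson")
        for est in (cp, wi):
            assert est.ci_low <= 100 * est.p_hat <= est.ci_high
        assert (cp.ci_low, cp.ci_high) != (wi.ci_low, wi.ci_high)

    def test_interval_width_shrinks_with_n(self):
        widths = []
        for n in (10, 40, 160, 640):
            est = h.proportion_ci(n // 4, n)
            widths.append(est.ci_high - est.ci_low)
        assert widths == sorted(widths, reverse=True)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            h.proportion_ci(5, 0)
        with pytest.raises(ValueError):
            h.proportion_ci(11, 10)


class TestSampleSize:
    def test_survey_design_effect_two(self):
        assert h.sample_size_proportion(0.10, 0.03, 0.05, 2).n_required == 768

    def test_simple_random_sample(self):
        assert h.sample_size_proportion(0.10, 0.03, 0.05, 1).n_required == 384

    def test_extreme_precision_sanity(self):
        assert h.sample_size_proportion(0.5, 0.5, 0.05, 1).n_required == 3

    def test_monotone_in_deff_and_precision(self):
        n1 = h.sample_size_proportion(0.2, 0.05, 0.05, 1).n_required
        n2 = h.sample_size_proportion(0.2, 0.05, 0.05, 1.5).n_required
        n3 = h.sample_size_proportion(0.2, 0.05, 0.05, 2).n_required
        assert n1 <= n2 <= n3
        m1 = h.sample_size_proportion(0.2, 0.10, 0.05, 1).n_required
        m2 = h.sample_size_proportion(0.2, 0.05, 0.05, 1).n_required
        m3 = h.sample_size_proportion(0.2, 0.02, 0.05, 1).n_required
        assert m1 <= m2 <= m3

    def test_domain_errors(self):
        for bad in [(0, 0.03, 0.05, 2), (0.1, 0, 0.05, 2), (0.1, 0.03, 0, 2),
                    (0.1, 0.03, 0.05, 0.5)]:
            with pytest.raises(ValueError):
                h.sample_size_proportion(*bad)


class TestRandomInterceptLogistic:
    def test_identical_outcomes_hit_boundary(self):
        groups = {"a": [0, 0, 0], "b": [0, 0], "c": [0, 0, 0, 0]}
        with pytest.warns(UserWarning, match="identical"):
            fit = h.fit_random_intercept_logistic(groups)
        assert fit.sigma_u2 == 0.0
        assert fit.beta0 == -10.0
        assert h.icc_from_fit(fit.sigma_u2) == 0.0

    def test_homogeneous_rates_give_near_zero_icc(self):
        rng = np.random.default_rng(0)
        groups = {
            f"a{i}": (rng.random(50) < 0.3).astype(int).tolist() for i in range(60)
        }
        fit = h.fit_random_intercept_logistic(groups)
        assert h.icc_from_fit(fit.sigma_u2) < 0.02

    def test_quadrature_matches_monte_carlo_integration(self):
        """AGQ log-likelihood vs 10^6-draw Monte-Carlo integration of the
        same integrand on a 5-attendant toy set."""
        groups = {"a": [1, 0, 1], "b": [0, 0], "c": [1, 1, 1, 0], "d": [0],
                  "e": [1, 0]}
        stats = _cluster_stats(groups)
        nodes, weights = hermgauss(21)
        beta0, sigma = -0.3, 0.8
        ll = _agq_loglik(beta0, sigma, stats, nodes, weights)
        rng = np.random.default_rng(0)
        u = rng.normal(0.0, sigma, 10**6)
        p = expit(beta0 + u)
        mc = sum(
            c * math.log(np.mean(p**k * (1 - p) ** (n - k)))
            for k, n, c in stats
        )
        assert ll == pytest.approx(mc, abs=1e-3)

    def test_doubling_quadrature_order_is_stable(self):
        rng = np.random.default_rng(1)
        groups = {
            f"a{i}": (rng.random(10) < expit(-1 + rng.normal(0, 1))).astype(int).tolist()
            for i in range(40)
        }
        f21 = h.fit_random_intercept_logistic(groups, quadrature_order=21)
        f42 = h.fit_random_intercept_logistic(groups, quadrature_order=42)
        assert abs(f21.loglik - f42.loglik) < 1e-6

    def test_parameter_recovery(self):
        """Simulated 200 attendants x 20 outcomes at sigma_u2=1: mean
        recovered ICC over 20 seeds within 0.05 of 1/(1 + pi^2/3)."""
        iccs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            groups = {
                f"a{i}": (
                    rng.random(20) < expit(-1.0 + rng.normal(0.0, 1.0))
                ).astype(int).tolist()
                for i in range(200)
            }
            fit = h.fit_random_intercept_logistic(groups)
            iccs.append(h.icc_from_fit(fit.sigma_u2))
        target = 1.0 / (1.0 + LATENT_LOGISTIC_VARIANCE)
        assert abs(np.mean(iccs) - target) < 0.05

    def test_bias_decreases_with_more_outcomes_per_attendant(self):
        target = 1.0 / (1.0 + LATENT_LOGISTIC_VARIANCE)

        def mean_bias(n_per: int) -> float:
            iccs = []
            for seed in range(20):
                rng = np.random.default_rng(1000 + seed)
                groups = {
                    f"a{i}": (
                        rng.random(n_per) < expit(-1.0 + rng.normal(0.0, 1.0))
                    ).astype(int).tolist()
                    for i in range(200)
                }
                fit = h.fit_random_intercept_logistic(groups)
                iccs.append(h.icc_from_fit(fit.sigma_u2))
            return abs(float(np.mean(iccs)) - target)

        assert mean_bias(40) <= mean_bias(10) + 1e-3

    def test_needs_two_attendants(self):
        with pytest.raises(ValueError):
            h.fit_random_intercept_logistic({"a": [0, 1]})


class TestIcc:
    def test_analytic_half(self):
        assert h.icc_from_fit(LATENT_LOGISTIC_VARIANCE) == pytest.approx(0.5)

    def test_zero_variance(self):
        assert h.icc_from_fit(0.0) == 0.0

    def test_between_plus_within_is_one(self):
        for s2 in (0.0, 0.3, 1.7):
            icc = h.icc_from_fit(s2)
            assert icc + (1 - icc) == pytest.approx(1.0)
            assert 0 <= icc < 1

    def test_bootstrap_requires_b_and_seed(self):
        groups = {"a": [0, 1], "b": [1, 1]}
        with pytest.raises(ValueError, match="B >= 100"):
            h.bootstrap_ci(groups, B=10, seed=1)
        with pytest.raises(ValueError, match="seed"):
            h.bootstrap_ci(groups, B=100, seed=None)

    def test_bootstrap_reproducible_and_brackets_estimate(self):
        rng = np.random.default_rng(4)
        groups = {
            f"a{i}": (rng.random(12) < expit(-0.5 + rng.normal(0, 0.9))).astype(int).tolist()
            for i in range(30)
        }
        lo1, hi1 = h.bootstrap_ci(groups, B=100, seed=7)
        lo2, hi2 = h.bootstrap_ci(groups, B=100, seed=7)
        assert (lo1, hi1) == (lo2, hi2)
        assert 0 <= lo1 <= hi1 <= 1

    def test_filter_min_opportunities(self):
        groups = {"a": [0] * 4, "b": [1] * 5, "c": [0, 1] * 5}
        assert set(h.filter_min_opportunities(groups, 5)) == {"b", "c"}
        assert h.filter_min_opportunities(groups, 1) == {
            k: list(v) for k, v in groups.items()
        }
        with pytest.raises(ValueError):
            h.filter_min_opportunities(groups, 0)

    def test_fixture_retains_65_attendants(self, fixture_classified):
        groups = h.behavior_outcome_groups(fixture_classified, "b1")
        assert len(h.filter_min_opportunities(groups, 5)) == 65
        groups3 = h.behavior_outcome_groups(fixture_classified, "b3")
        assert len(h.filter_min_opportunities(groups3, 5)) == 65


class TestKappa:
    def test_perfect_agreement(self):
        assert h.cohen_kappa([[25, 0], [0, 25]]).kappa == pytest.approx(1.0)

    def test_worked_example(self):
        res = h.cohen_kappa([[20, 5], [5, 20]])
        assert (res.po, res.pe) == (0.8, 0.5)
        assert res.kappa == pytest.approx(0.6)

    def test_independence_gives_zero(self):
        assert h.cohen_kappa([[25, 25], [25, 25]]).kappa == pytest.approx(0.0)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(2)
        for _ in range(50):
            t = rng.integers(0, 30, size=(2, 2))
            if t.sum() == 0:
                continue
            k1 = h.cohen_kappa(t).kappa
            k2 = h.cohen_kappa(t[::-1, ::-1]).kappa  # swap category labels
            if k1 is None or k2 is None:
                assert k1 == k2
            else:
                assert k1 == pytest.approx(k2)

    def test_degenerate_marginals_undefined(self):
        assert h.cohen_kappa([[10, 0], [0, 0]]).kappa is None

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import cohens_kappa

        rng = np.random.default_rng(9)
        for _ in range(20):
            t = rng.integers(1, 30, size=(2, 2))
            ours = h.cohen_kappa(t).kappa
            ref = cohens_kappa(t, return_results=False)
            assert ours == pytest.approx(ref)
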