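"""Closed-form equality Bayes factors, cross-checked against quadrature."""

import numpy as np
import pytest
from scipy import integrate
from scipy.special import betaln
from scipy.stats import beta as beta_dist

from ordbf.conjugate import (
    CountData,
    PriorSpec,
    log_binom_bf_equality,
    log_binom_bf_equality_point,
    log_equality_group_bf,
    log_mult_bf_equality,
    posterior_summary,
)


def mult(x, a):
    return CountData.from_counts(x), PriorSpec("multinomial", a)


def binom(x, n, a, b):
    return CountData.from_counts(x, n=n), PriorSpec("binomial", a, b)


class TestMultinomialEquality:
    def test_two_category_closed_form(self):
        # B(1,1)/B(2,2) * (1/2)^2 = 6/4
        data, prior = mult([1, 1], [1, 1])
        assert log_mult_bf_equality(data, prior, [0.5, 0.5]) == pytest.approx(
            np.log(1.5), abs=1e-12)

    def test_matches_numerical_integration(self):
        # marginal likelihood ratio of H0 (point) vs He (Beta(2,3) composition)
        x, a, p0 = np.array([3, 2]), np.array([2.0, 3.0]), np.array([0.4, 0.6])
        data, prior = mult(x, a)
        ml_e, _ = integrate.quad(
            lambda t: t ** x[0] * (1 - t) ** x[1]
            * t ** (a[0] - 1) * (1 - t) ** (a[1] - 1) / np.exp(betaln(*a)),
            0, 1)
        ml_0 = p0[0] ** x[0] * p0[1] ** x[1]
        assert log_mult_bf_equality(data, prior, p0) == pytest.approx(
            np.log(ml_0 / ml_e), abs=1e-10)

    def test_empty_data_gives_unit_bayes_factor(self):
        data, prior = mult([0, 0, 0], [2.0, 1.0, 0.5])
        assert log_mult_bf_equality(data, prior, [0.2, 0.3, 0.5]) == 0.0

    def test_zero_predicted_proportion_with_counts_is_minus_inf(self):
        data, prior = mult([1, 1], [1, 1])
        assert log_mult_bf_equality(data, prior, [1.0, 0.0]) == -np.inf

    def test_no_overflow_for_extreme_counts(self):
        k = 5
        data, prior = mult(np.full(k, 10**6), np.ones(k))
        val = log_mult_bf_equality(data, prior, np.full(k, 1 / k))
        assert np.isfinite(val)


class TestBinomialEquality:
    def test_two_category_closed_form(self):
        # B(3,3)/B(2,2)^2 = (1/30)/(1/36) = 1.2
        data, prior = binom([1, 1], [2, 2], [1, 1], [1, 1])
        assert log_binom_bf_equality(data, prior) == pytest.approx(
            np.log(1.2), abs=1e-12)

    def test_single_category_collapse_is_identity(self):
        data, prior = binom([3], [10], [2], [4])
        assert log_binom_bf_equality(data, prior) == pytest.approx(0.0, abs=1e-12)

    def test_permutation_invariance(self):
        x, n = [3, 7, 1], [12, 9, 5]
        a, b = [1.0, 2.0, 0.5], [2.0, 1.0, 1.5]
        ref = log_binom_bf_equality(*binom(x, n, a, b))
        perm = [2, 0, 1]
        val = log_binom_bf_equality(*binom(
            np.array(x)[perm], np.array(n)[perm],
            np.array(a)[perm], np.array(b)[perm]))
        assert val == pytest.approx(ref, abs=1e-12)

    def test_matches_numerical_integration(self):
        x, n = np.array([2, 5]), np.array([6, 8])
        data, prior = binom(x, n, [1, 1], [1, 1])

        def lik(t, xk, nk):
            return t ** xk * (1 - t) ** (nk - xk)

        ml_e = np.prod([
            integrate.quad(lambda t: lik(t, xk, nk), 0, 1)[0]
            for xk, nk in zip(x, n)
        ])
        ml_0, _ = integrate.quad(lambda t: lik(t, x.sum(), n.sum()), 0, 1)
        assert log_binom_bf_equality(data, prior) == pytest.approx(
            np.log(ml_0 / ml_e), abs=1e-9)

    def test_nonpositive_collapsed_prior_raises(self):
        data, prior = binom([1, 1, 1], [2, 2, 2], [0.5, 0.5, 0.5], [1, 1, 1])
        with pytest.raises(ValueError):
            log_binom_bf_equality(data, prior)


class TestBinomialPointNull:
    @pytest.mark.parametrize("x, n, theta0, expected", [
        ([1], [2], 0.5, np.log(1.5)),   # (1/B(2,2)) * 0.25
        ([0], [1], 0.5, 0.0),           # (B(1,1)/B(1,2)) * 0.5
    ])
    def test_closed_forms(self, x, n, theta0, expected):
        data, prior = binom(x, n, np.ones(len(x)), np.ones(len(x)))
        assert log_binom_bf_equality_point(data, prior, theta0) == pytest.approx(
            expected, abs=1e-12)

    def test_quadrature_oracle(self):
        x, n = np.array([3, 1]), np.array([5, 4])
        data, prior = binom(x, n, [2, 1], [1, 2])
        theta0 = 0.35
        ml_0 = theta0 ** x.sum() * (1 - theta0) ** (n.sum() - x.sum())
        ml_e = np.prod([
            integrate.quad(
                lambda t: t ** (xk + ak - 1) * (1 - t) ** (nk - xk + bk - 1), 0, 1
            )[0] / np.exp(betaln(ak, bk))
            for xk, nk, ak, bk in zip(x, n, prior.a, prior.b)
        ])
        assert log_binom_bf_equality_point(data, prior, theta0) == pytest.approx(
            np.log(ml_0 / ml_e), abs=1e-9)

    def test_maximized_at_pooled_mle(self):
        x, n = np.array([4, 6]), np.array([10, 10])
        data, prior = binom(x, n, [1, 1], [1, 1])
        mle = x.sum() / n.sum()
        at_mle = log_binom_bf_equality_point(data, prior, mle)
        for eps in (-0.01, 0.01):
            assert log_binom_bf_equality_point(data, prior, mle + eps) < at_mle

    def test_implausible_point_null_is_strongly_rejected(self):
        data, prior = binom([0], [200], np.ones(1), np.ones(1))
        assert log_binom_bf_equality_point(data, prior, 0.999) < -100

    def test_theta0_outside_unit_interval_raises(self):
        data, prior = binom([1], [2], [1], [1])
        with pytest.raises(ValueError):
            log_binom_bf_equality_point(data, prior, 1.0)


class TestEqualityGroupBF:
    def test_full_span_group_equals_uniform_point_null(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            k = rng.integers(2, 7)
            x = rng.integers(0, 40, k)
            a = rng.uniform(0.5, 4.0, k)
            data, prior = mult(x, a)
            full = log_equality_group_bf(data, prior, range(k))
            point = log_mult_bf_equality(data, prior, np.full(k, 1 / k))
            assert full == pytest.approx(point, abs=1e-10)

    def test_binomial_two_category_group_matches_equality_bf(self):
        data, prior = binom([3, 5], [9, 11], [1, 2], [2, 1])
        assert log_equality_group_bf(data, prior, (0, 1)) == pytest.approx(
            log_binom_bf_equality(data, prior), abs=1e-12)

    def test_zero_counts_give_unit_bf(self):
        data, prior = mult([0, 0, 0, 5], [1, 1, 1, 1])
        assert log_equality_group_bf(data, prior, (0, 1, 2)) == 0.0

    def test_degenerate_group_raises(self):
        data, prior = mult([1, 2], [1, 1])
        with pytest.raises(ValueError):
            log_equality_group_bf(data, prior, (0,))


class TestPosteriorSummary:
    def test_binomial_median_matches_beta_quantiles(self):
        data, prior = binom([39], [80], [1], [1])
        s = posterior_summary(data, prior)
        assert s["median"].iloc[0] == pytest.approx(
            beta_dist.ppf(0.5, 40, 42), abs=1e-12)
        assert s["lower"].iloc[0] == pytest.approx(
            beta_dist.ppf(0.025, 40, 42), abs=1e-12)

    def test_symmetric_posterior_has_median_half(self):
        data, prior = binom([5], [10], [2], [2])
        assert posterior_summary(data, prior)["median"].iloc[0] == pytest.approx(0.5)

    def test_benford_coverage_on_fiscal_digits(self, greek_counts):
        # only three of the nine expected proportions fall inside the 95% CIs
        from ordbf.fixtures import benford_proportions
        data, prior = mult(greek_counts, np.ones(9))
        s = posterior_summary(data, prior, level=0.95)
        p = benford_proportions(9)
        inside = (s["lower"].to_numpy() < p) & (p < s["upper"].to_numpy())
        assert inside.sum() == 3

    def test_invalid_level_raises(self):
        data, prior = mult([1, 2], [1, 1])
        with pytest.raises(ValueError):
            posterior_summary(data, prior, level=1.2)
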