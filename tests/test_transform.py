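"""Stick-breaking/probit map: bijectivity, bounds and density normalization."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy import integrate

from ordbf.sampling import restriction_satisfied, sample_constrained
from ordbf.transform import (
    log_target_density_real,
    n_real_dims,
    to_probability,
    to_real,
)

from conftest import make_problem

ROUND_TRIP_PROBLEMS = [
    ("1 < 2 < 3", 3, "multinomial", None),
    ("1 , 2 < 3 , 4 < 5", 5, "multinomial", None),
    ("1 > 2 = 3 = 4 = 5 = 6 = 7 > 8 , 9", 9, "multinomial", None),
    ("1 = 2 < 3 , 4 = 5", 5, "multinomial", None),
    ("1,2,3,4 < 5,6,7,8", 8, "binomial", np.ones(8, int)),
    ("1 < 2 , 3 < 4", 4, "binomial", np.ones(4, int)),
]


class TestBijection:
    @pytest.mark.parametrize("hyp, k, fam, n", ROUND_TRIP_PROBLEMS)
    def test_round_trip_reproduces_constrained_draws(self, hyp, k, fam, n):
        prob = make_problem(hyp, k, family=fam, n=n)[3].section_problems()[0]
        s = sample_constrained(prob, "prior", n_draws=10_000, n_burn=100, seed=3)
        back = to_probability(to_real(s).xi, prob)
        assert np.abs(back.draws - s.draws).max() < 1e-8
        assert restriction_satisfied(prob, back.draws).all()

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(hnp.arrays(np.float64, (3,), elements=st.floats(-4, 4)))
    def test_any_real_vector_maps_into_the_region(self, xi):
        prob = make_problem("1 < 2 , 3 < 4", 4)[3]
        out = to_probability(xi.reshape(1, 3), prob)
        assert restriction_satisfied(prob, out.draws).all()
        assert np.allclose(out.draws.sum(), 1.0)

    def test_extreme_positive_inputs_collapse_to_the_equal_corner(self):
        # as xi -> +inf every element approaches the feasibility corner where
        # all per-category means coincide; ordering then only holds weakly at
        # float resolution
        prob = make_problem("1 < 2 , 3 < 4", 4)[3]
        out = to_probability(np.full((1, 3), 30.0), prob)
        assert np.allclose(out.draws, 0.25, atol=1e-6)
        t = out.draws[0]
        assert t[0] <= min(t[1], t[2]) + 1e-9 and max(t[1], t[2]) <= t[3] + 1e-9

    def test_extreme_negative_inputs_stay_ordered(self):
        prob = make_problem("1 < 2 < 3", 3, family="binomial",
                            n=np.ones(3, int))[3]
        out = to_probability(np.full((1, 3), -30.0), prob)
        t = out.draws[0]
        assert t[0] < t[1] < t[2]
        assert t[0] < 1e-10

    def test_boundary_draw_is_rejected_with_index(self):
        prob = make_problem("1 < 2", 2, family="binomial", n=np.ones(2, int))[3]
        from ordbf.sampling import ConstrainedSamples
        bad = ConstrainedSamples(
            draws=np.array([[0.3, 0.3]]), target="prior", problem=prob,
            seed=None, n_burn=0, n_chains=1)
        with pytest.raises(ValueError, match="boundary"):
            to_real(bad)


class TestBounds:
    def test_midpoint_construction_for_binomial_chain(self):
        # xi = 0 places each theta at the midpoint of (previous, 1)
        prob = make_problem("1 < 2 < 3", 3, family="binomial",
                            n=np.ones(3, int))[3]
        out = to_probability(np.zeros((1, 3)), prob)
        assert np.allclose(out.draws, [[0.5, 0.75, 0.875]])

    def test_single_free_binomial_theta_half_maps_to_zero(self):
        prob = make_problem("1", 1, family="binomial", n=np.ones(1, int))[3]
        from ordbf.sampling import ConstrainedSamples
        s = ConstrainedSamples(np.array([[0.5]]), "prior", prob, None, 0, 1)
        assert to_real(s).xi[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_smallest_of_three_ascending_elements_has_upper_bound_third(self):
        prob = make_problem("1 < 2 < 3", 3)[3]
        s = sample_constrained(prob, "prior", n_draws=200, n_burn=50, seed=4)
        td = to_real(s)
        assert np.allclose(td.upper[:, 0], 1 / 3)
        # second element: remaining stick over the two remaining parts
        assert np.allclose(td.upper[:, 1], (1 - s.draws[:, 0]) / 2)


class TestTargetDensity:
    def test_unconstrained_uniform_reduces_to_normal_jacobian(self):
        prob = make_problem("1", 1, family="binomial", n=np.ones(1, int))[3]
        val = log_target_density_real(np.zeros((1, 1)), prob, "prior")
        assert val[0] == pytest.approx(np.log(1 / np.sqrt(2 * np.pi)), abs=1e-12)

    @pytest.mark.parametrize("hyp, k, fam, n, mass", [
        ("1 < 2", 2, "binomial", np.ones(2, int), 0.5),
        ("1 < 2 < 3", 3, "multinomial", None, 1 / 6),
        ("1 , 2 < 3", 3, "multinomial", None, 1 / 3),
    ])
    def test_quadrature_normalization(self, hyp, k, fam, n, mass):
        # exp(log target - log mass) must integrate to one over R^d
        prob = make_problem(hyp, k, family=fam, n=n)[3]
        assert n_real_dims(prob) == 2

        def f(y, x):
            return np.exp(
                log_target_density_real(np.array([[x, y]]), prob, "prior")
            )[0] / mass

        val, err = integrate.dblquad(f, -8, 8, -8, 8, epsabs=1e-9)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_free_group_density_symmetric_under_member_swap(self):
        prob = make_problem("1 , 2 < 3", 3, family="binomial",
                            n=np.ones(3, int))[3]
        xi = np.array([[0.3, -0.8, 1.1]])
        swapped = xi[:, [1, 0, 2]]
        a = log_target_density_real(xi, prob, "prior")
        b = log_target_density_real(swapped, prob, "prior")
        assert a[0] == pytest.approx(b[0], abs=1e-10)

    def test_posterior_density_uses_conjugate_update(self):
        prob = make_problem("1 < 2", 2, family="binomial",
                            x=[2, 1], n=[10, 7])[3]

        def f(y, x):
            return np.exp(
                log_target_density_real(np.array([[x, y]]), prob, "posterior")
            )[0]

        val, _ = integrate.dblquad(f, -8, 8, -8, 8, epsabs=1e-9)
        # normalizing constant = constrained posterior mass, 0.42534 from a
        # frozen 2e6-draw rejection run
        assert val == pytest.approx(0.42534, abs=2e-3)
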