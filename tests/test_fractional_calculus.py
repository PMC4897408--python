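"""Kernel algebra: lattice series, fractional integral/derivative, zero test."""

import math
import random

import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from nhpm import (
    FracSeries,
    alpha,
    caputo_deriv,
    h,
    is_zero,
    rl_integral,
    rl_integral_power,
    t,
    x,
    y,
)
from nhpm.errors import (
    AlphaMismatchError,
    InvalidOrderError,
    LatticeViolationError,
)
from nhpm.fractional_calculus import random_series


def series(terms, a=alpha, trunc=6):
    return FracSeries(terms, a, trunc)


class TestRLIntegral:
    def test_constant_maps_to_t_alpha_over_gamma(self):
        s = series({0: 5 * x})
        out = rl_integral(s)
        assert out.coeff(1) == sp.expand(5 * x / sp.gamma(alpha + 1))
        assert out.coeff(0) == 0

    def test_order_zero_is_identity(self):
        s = series({0: x, 2: y})
        assert rl_integral(s, 0) == s

    def test_half_order_semigroup_on_t(self):
        # J^(1/2) J^(1/2) t = J^1 t = t**2/2, off-lattice power rule
        half = sp.Rational(1, 2)
        inner = rl_integral_power(1, half)
        coeff = inner / t ** sp.Rational(3, 2)
        result = sp.simplify(coeff * rl_integral_power(sp.Rational(3, 2), half))
        assert sp.simplify(result - t**2 / 2) == 0

    def test_lattice_shift_for_numeric_alpha(self):
        s = FracSeries({0: x}, sp.Rational(1, 2), 4)
        out = s.rl_integral(1)  # 1 = 2 * alpha, shift by two lattice steps
        assert out.indices == (2,)
        assert sp.simplify(out.coeff(2) - x / sp.gamma(2)) == 0

    def test_negative_order_rejected(self):
        with pytest.raises(InvalidOrderError):
            series({0: x}).rl_integral(-1)
        with pytest.raises(InvalidOrderError):
            rl_integral_power(1, -sp.Rational(1, 2))

    def test_off_lattice_order_rejected(self):
        with pytest.raises(LatticeViolationError):
            series({0: x}).rl_integral(sp.Rational(1, 3))

    def test_terms_beyond_truncation_dropped(self):
        s = series({5: x, 6: y})
        out = rl_integral(s)
        assert out.indices == (6,)

    @pytest.mark.parametrize("trial", range(10))
    def test_semigroup_random_rational_orders(self, trial):
        rng = random.Random(100 + trial)
        mu = sp.Rational(rng.randint(1, 8), rng.randint(1, 4))
        beta = sp.Rational(rng.randint(1, 8), rng.randint(1, 4))
        g = sp.Rational(rng.randint(0, 6), rng.randint(1, 3))
        inner = rl_integral_power(g, mu)
        coeff = inner / t ** (g + mu)
        lhs = sp.simplify(coeff * rl_integral_power(g + mu, beta))
        rhs = sp.simplify(rl_integral_power(g, mu + beta))
        assert sp.simplify(lhs - rhs) == 0


class TestCaputo:
    def test_constant_annihilated(self):
        assert caputo_deriv(series({0: x * y})).is_empty()

    def test_t_alpha_over_gamma_derives_to_one(self):
        s = series({1: 1 / sp.gamma(alpha + 1)})
        assert sp.simplify(caputo_deriv(s).coeff(0) - 1) == 0

    @pytest.mark.parametrize("t_val", [0.5, 1.0])
    def test_against_quadrature_oracle_at_half_order(self, t_val):
        # Caputo D^a f = 1/Gamma(1-a) * int_0^t (t-tau)^(-a) f'(tau) dtau
        # for f = t**a / Gamma(a+1) with a = 1/2 the result is 1.
        a = 0.5
        fprime = lambda tau: a * tau ** (a - 1) / math.gamma(a + 1)
        val, _ = quad(
            lambda tau: (t_val - tau) ** (-a) * fprime(tau), 0, t_val,
            points=[0, t_val], limit=200,
        )
        val /= math.gamma(1 - a)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_inverts_rl_integral_on_random_series(self):
        rng = random.Random(7)
        for _ in range(5):
            s = random_series(rng, alpha, 6, 4)
            back = caputo_deriv(rl_integral(s))
            assert back.equals(s.truncate(5))

    def test_alpha_mismatch_rejected(self):
        with pytest.raises(AlphaMismatchError):
            series({1: x}).caputo(sp.Rational(1, 2))


class TestRingLaws:
    def test_additive_identity_and_inverse(self):
        s = series({0: x, 2: y**2})
        zero = FracSeries.zero(alpha, 6)
        assert (s + zero) == s
        assert (s + s.scale(-1)).is_empty()

    def test_binomial_square(self):
        one_plus = series({0: 1, 1: 1})
        sq = one_plus * one_plus
        assert sq.coeff(0) == 1 and sq.coeff(1) == 2 and sq.coeff(2) == 1

    def test_radical_product_on_constant_term(self):
        s = series({0: sp.sqrt(x * y)})
        assert (s * s).coeff(0) == x * y

    def test_multiplicative_identity(self):
        s = series({0: x, 3: x * y})
        assert (s * FracSeries.constant(1, alpha, 6)) == s

    @given(st.integers(0, 2**30))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_commutativity_and_associativity(self, seed):
        rng = random.Random(seed)
        s1, s2, s3 = (random_series(rng, alpha, 4, 3) for _ in range(3))
        assert (s1 + s2) == (s2 + s1)
        assert (s1 * s2) == (s2 * s1)
        assert ((s1 + s2) + s3) == (s1 + (s2 + s3))
        assert ((s1 * s2) * s3).equals(s1 * (s2 * s3))
        assert (s1 * (s2 + s3)).equals(s1 * s2 + s1 * s3)

    def test_alpha_mismatch_rejected(self):
        with pytest.raises(AlphaMismatchError):
            series({0: x}) + FracSeries({0: x}, sp.Rational(1, 2), 6)

    def test_linearity_of_operators(self):
        rng = random.Random(11)
        s1 = random_series(rng, alpha, 5, 3)
        s2 = random_series(rng, alpha, 5, 3)
        left = rl_integral(s1.scale(3 * x) + s2)
        right = rl_integral(s1).scale(3 * x) + rl_integral(s2)
        assert left.equals(right)


class TestSpatialDiff:
    def test_second_derivative_of_bilinear_vanishes(self):
        s = series({0: x * y})
        assert s.diff(x, 2).is_empty()

    def test_radical_second_derivative(self):
        s = series({0: sp.sqrt(x * y)})
        expected = -sp.sqrt(x) * y ** sp.Rational(-3, 2) / 4
        assert sp.simplify(s.diff(y, 2).coeff(0) - expected) == 0

    def test_mixed_partials_commute(self):
        rng = random.Random(3)
        s = random_series(rng, alpha, 4, 4)
        assert s.diff(x).diff(y) == s.diff(y).diff(x)

    def test_commutes_with_addition(self):
        rng = random.Random(4)
        s1 = random_series(rng, alpha, 4, 3)
        s2 = random_series(rng, alpha, 4, 3)
        assert ((s1 + s2).diff(x)).equals(s1.diff(x) + s2.diff(x))


class TestIsZero:
    def test_syntactic_zero(self):
        assert is_zero(x - x)

    def test_radical_cancellation_from_population_model(self):
        # the bracket that closes the t**(3 alpha) term of the first example
        a0 = h * sp.sqrt(x * y)
        expr = 2 * sp.diff(a0, y) ** 2 + 2 * a0 * sp.diff(a0, y, 2)
        assert is_zero(expr)

    def test_distinct_symbols_not_zero(self):
        assert not is_zero(x - y)

    def test_numeric_constant(self):
        assert is_zero(sp.Integer(0))
        assert not is_zero(sp.Rational(1, 10**6))


class TestNormalizationAndSerialization:
    def test_normalization_drops_zero_terms_and_is_idempotent(self):
        s = series({0: x - x, 1: y, 5: 0})
        assert s.indices == (1,)
        again = FracSeries(dict(s._terms), s.alpha, s.trunc)
        assert again == s

    def test_roundtrip_symbolic_alpha(self):
        s = series({0: sp.sqrt(x * y), 2: h * x / 3})
        assert FracSeries.from_json(s.to_json()) == s

    def test_roundtrip_numeric_alpha(self):
        s = FracSeries({0: x, 1: x * y}, sp.Rational(1, 2), 4)
        back = FracSeries.from_json(s.to_json())
        assert back == s and back.alpha == sp.Rational(1, 2)
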