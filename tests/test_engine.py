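"""Engine: ansatz, zeroth iterate, order-by-order solve, residuals."""

import pytest
import sympy as sp
from sympy import exp, gamma, sqrt

from nhpm import (
    FracSeries,
    ModelSpec,
    alpha,
    build_U0,
    build_u0_ansatz,
    example1,
    example3,
    h,
    residual,
    solve_coefficients,
    u1_integrand,
    x,
    y,
)
from nhpm.engine import NHPMSolution
from nhpm.errors import UnsupportedModelError


def decay_model(init=sp.Integer(1), a=alpha):
    return ModelSpec(
        name="decay",
        components=("u",),
        spatial_vars=(x, y),
        params={},
        initial_conditions={"u": init},
        rhs=lambda U: {"u": U["u"].scale(-1)},
        alpha=a,
    )


class TestAnsatz:
    def test_single_term(self):
        a0 = sp.Symbol("a0")
        s = build_u0_ansatz([a0], 1, alpha)
        assert s.indices == (0,) and s.coeff(0) == a0

    def test_three_terms_have_distinct_placeholders(self):
        syms = sp.symbols("a0:3")
        s = build_u0_ansatz(syms, 3, alpha)
        assert s.indices == (0, 1, 2)
        assert len({s.coeff(k) for k in range(3)}) == 3

    def test_rejects_zero_order(self):
        with pytest.raises(ValueError):
            build_u0_ansatz([], 0, alpha)


class TestBuildU0:
    def test_population_first_weight(self):
        u0 = FracSeries({0: h * sqrt(x * y)}, alpha, 2)
        U0 = build_U0(u0, sqrt(x * y))
        assert U0.coeff(0) == sqrt(x * y)
        assert sp.simplify(U0.coeff(1) - h * sqrt(x * y) / gamma(alpha + 1)) == 0

    def test_population_second_weight(self):
        u0 = FracSeries({1: h**2 * sqrt(x * y)}, alpha, 2)
        U0 = build_U0(u0, sqrt(x * y))
        expected = h**2 * sqrt(x * y) * gamma(alpha + 1) / gamma(2 * alpha + 1)
        assert sp.simplify(U0.coeff(2) - expected) == 0

    def test_zero_ansatz_returns_initial_condition(self):
        U0 = build_U0(FracSeries.zero(alpha, 3), x * y)
        assert U0.indices == (0,) and U0.coeff(0) == x * y

    def test_as_printed_weights_are_integer_order(self):
        u0 = FracSeries({1: h}, alpha, 2)
        U0 = build_U0(u0, 0, mode="as_printed")
        assert U0.coeff(2) == sp.Rational(1, 2) * h


class TestU1Integrand:
    def test_population_model_index0(self):
        a0 = sp.Symbol("a0")
        model = example1()
        u0 = FracSeries({0: a0}, alpha, 0)
        U0 = {"u": build_U0(u0, sqrt(x * y)).truncate(0)}
        integrand = u1_integrand(model, U0, u0, "u")
        assert sp.simplify(integrand.coeff(0) - (h * sqrt(x * y) - a0)) == 0

    def test_decay_model_with_empty_ansatz(self):
        model = decay_model()
        u0 = FracSeries.zero(alpha, 0)
        U0 = {"u": build_U0(u0, sp.Integer(1)).truncate(0)}
        integrand = u1_integrand(model, U0, u0, "u")
        assert integrand.coeff(0) == -1

    def test_triple_system_u_component_index0(self):
        a0 = sp.Symbol("a0")
        model = example3()
        U0 = {}
        for comp, init in model.initial_conditions.items():
            U0[comp] = build_U0(FracSeries.zero(alpha, 0), init).truncate(0)
        u0 = FracSeries({0: a0}, alpha, 0)
        integrand = u1_integrand(model, U0, u0, "u")
        assert sp.simplify(integrand.coeff(0) - (-exp(x + y) - a0)) == 0


class TestSolve:
    def test_strict_second_coefficient_population(self, ex1_strict):
        expected = h**2 * sqrt(x * y) / gamma(alpha + 1)
        assert sp.simplify(ex1_strict.coeffs["u"][1] - expected) == 0

    def test_printed_table_population(self, ex1_printed):
        for n, c in enumerate(ex1_printed.coeffs["u"]):
            expected = h ** (n + 1) * sqrt(x * y) / sp.factorial(n)
            assert sp.simplify(c - expected) == 0

    def test_triple_system_symmetry_v_w(self, ex3_strict):
        # swapping x <-> y maps the v-series onto the w-series termwise
        swap = {x: y, y: x}
        for bn, cn in zip(ex3_strict.coeffs["v"], ex3_strict.coeffs["w"]):
            assert sp.simplify(bn.subs(swap, simultaneous=True) - cn) == 0

    def test_modes_agree_when_alpha_is_one(self):
        model = example1(alpha=sp.Integer(1))
        strict = solve_coefficients(model, 4, mode="strict")
        printed = solve_coefficients(model, 4, mode="as_printed")
        for a_s, a_p in zip(strict.coeffs["u"], printed.coeffs["u"]):
            assert sp.simplify(a_s - a_p) == 0

    def test_rejects_invalid_order_and_mode(self):
        with pytest.raises(ValueError):
            solve_coefficients(example1(), 0)
        with pytest.raises(ValueError):
            solve_coefficients(example1(), 2, mode="loose")

    def test_nonlinear_in_newest_unknown_rejected(self):
        # a right-hand side applying D^alpha to the unknown feeds the newest
        # coefficient back quadratically at order zero
        model = ModelSpec(
            name="pathological",
            components=("u",),
            spatial_vars=(x, y),
            params={},
            initial_conditions={"u": sp.Integer(1)},
            rhs=lambda U: {"u": U["u"].caputo() * U["u"].caputo()},
            alpha=alpha,
        )
        with pytest.raises(UnsupportedModelError):
            solve_coefficients(model, 2)

    def test_determinism_identical_json(self):
        a = solve_coefficients(example1(), 3, mode="as_printed").to_json()
        b = solve_coefficients(example1(), 3, mode="as_printed").to_json()
        assert a == b

    def test_diagnostics_record_every_order(self, ex1_printed):
        orders = [d["order"] for d in ex1_printed.diagnostics]
        assert orders == list(range(5))

    def test_solution_roundtrip(self, ex1_printed):
        back = NHPMSolution.from_json(ex1_printed.to_json())
        assert back.mode == ex1_printed.mode and back.N == ex1_printed.N
        for n in range(5):
            assert sp.simplify(back.coeffs["u"][n] - ex1_printed.coeffs["u"][n]) == 0
        assert back.series["u"] == ex1_printed.series["u"]


class TestResidual:
    def test_zero_model_residual_vanishes_identically(self):
        model = ModelSpec(
            name="null",
            components=("u",),
            spatial_vars=(x, y),
            params={},
            initial_conditions={"u": x * y},
            rhs=lambda U: {"u": FracSeries.zero(U["u"].alpha, U["u"].trunc)},
            alpha=alpha,
        )
        sol = solve_coefficients(model, 3)
        rep = residual(model, sol)
        assert rep.leading_index["u"] is None
        assert rep.residuals["u"].is_empty()

    def test_strict_population_leading_index_at_truncation(self, ex1_strict):
        rep = residual(example1(), ex1_strict)
        assert rep.leading_index["u"] is None or rep.leading_index["u"] >= 5

    def test_as_printed_leading_index_is_one_for_symbolic_alpha(self, ex1_printed):
        rep = residual(example1(), ex1_printed)
        assert rep.leading_index["u"] == 1

    def test_as_printed_exact_at_alpha_one(self, ex1_alpha1_printed):
        model = example1(alpha=sp.Integer(1))
        rep = residual(model, ex1_alpha1_printed, M=6)
        assert rep.leading_index["u"] is None or rep.leading_index["u"] >= 6
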