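"""Built-in models, their reference solutions, and random linear fixtures.

The registry carries the two study systems:

* the degenerate-diffusion biological population model
  ``D_t^alpha u = (u^2)_xx + (u^2)_yy + h u^a (1 - r u^b)`` for a population
  density u(x, y, t) with Verhulst-type supply (a = b = 1), and
* an antisymmetrically coupled system of three exponential components
  ``D_t^alpha u = -v_x w_y + v_y w_x - u`` (and cyclic variants with
  flipped signs).

Initial data are taken with the radical readings sqrt(x*y) and
exp(sqrt(h*r/8)*(x+y)): the first makes the degenerate diffusion
(u^2)_xx + (u^2)_yy vanish identically for u = sqrt(x*y)*v(t), the second
satisfies the cancellation 8*theta**2 = h*r that removes the nonlinear
terms from the supply balance.  Both identities are asserted by tests in
this repository rather than assumed.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Callable

import sympy as sp
from sympy import Rational, exp, factorial, gamma, sqrt

from ._symbols import alpha as ALPHA
from ._symbols import h, r, x, y
from .engine import ModelSpec
from .errors import UnsupportedModelError
from .fractional_calculus import FracSeries

__all__ = [
    "biological_population_model",
    "three_component_model",
    "example1",
    "example2",
    "example3",
    "ReferenceSolution",
    "reference_solution",
    "printed_coefficient",
    "random_linear_fixture",
    "LinearFixtureOracle",
    "MODEL_REGISTRY",
    "get_model",
]


def biological_population_model(
    h_val=h,
    r_val=0,
    a: int = 1,
    b: int = 1,
    init: sp.Expr | None = None,
    alpha=ALPHA,
    name: str = "biopop",
) -> ModelSpec:
    """Degenerate-diffusion population model with supply h*u^a*(1 - r*u^b).

    The reaction exponents a, b must be nonnegative integers: non-integer
    powers of a series with non-constant leading term leave the lattice
    series class and are rejected rather than approximated.
    """
    if int(a) != a or a < 0 or int(b) != b or b < 0:
        raise UnsupportedModelError(
            f"reaction exponents must be nonnegative integers, got a={a}, b={b}"
        )
    a, b = int(a), int(b)
    h_val = sp.sympify(h_val)
    r_val = sp.sympify(r_val)
    if init is None:
        init = sqrt(x * y)
    init = sp.sympify(init)

    def rhs(U):
        u = U["u"]
        u2 = u * u
        diffusion = u2.diff(x, 2) + u2.diff(y, 2)
        supply = u.pow(a).scale(h_val)
        if r_val != 0:
            supply = supply - u.pow(a + b).scale(h_val * r_val)
        return {"u": diffusion + supply}

    return ModelSpec(
        name=name,
        components=("u",),
        spatial_vars=(x, y),
        params={"h": h_val, "r": r_val, "a": sp.Integer(a), "b": sp.Integer(b)},
        initial_conditions={"u": init},
        rhs=rhs,
        alpha=alpha,
    )


def three_component_model(
    init_u: sp.Expr = exp(x + y),
    init_v: sp.Expr = exp(x - y),
    init_w: sp.Expr = exp(-x + y),
    alpha=ALPHA,
    name: str = "triple",
) -> ModelSpec:
    """Three coupled components with antisymmetric Jacobian-type coupling."""

    def rhs(U):
        u, v, w = U["u"], U["v"], U["w"]
        ru = (v.diff(y) * w.diff(x)) - (v.diff(x) * w.diff(y)) - u
        rv = v - (w.diff(x) * u.diff(y)) - (w.diff(y) * u.diff(x))
        rw = w - (u.diff(x) * v.diff(y)) - (u.diff(y) * v.diff(x))
        return {"u": ru, "v": rv, "w": rw}

    return ModelSpec(
        name=name,
        components=("u", "v", "w"),
        spatial_vars=(x, y),
        params={},
        initial_conditions={"u": init_u, "v": init_v, "w": init_w},
        rhs=rhs,
        alpha=alpha,
    )


def example1(alpha=ALPHA) -> ModelSpec:
    """Population model with a = 1, r = 0 and initial density sqrt(x*y)."""
    return biological_population_model(
        h_val=h, r_val=0, a=1, b=1, init=sqrt(x * y), alpha=alpha, name="biopop-ex1"
    )


def example2(alpha=ALPHA) -> ModelSpec:
    """Verhulst population model (a = b = 1), initial exp(sqrt(h*r/8)*(x+y))."""
    init = exp(sqrt(h * r / 8) * (x + y))
    return biological_population_model(
        h_val=h, r_val=r, a=1, b=1, init=init, alpha=alpha, name="biopop-ex2"
    )


def example3(alpha=ALPHA) -> ModelSpec:
    """The exponential three-component system."""
    return three_component_model(alpha=alpha, name="triple-ex3")


@dataclass(frozen=True)
class ReferenceSolution:
    """Closed-form series term and exact alpha = 1 solution for an example."""

    example_id: str
    component: str
    #: coefficient of t**(n*alpha), n >= 0, as a function of n
    closed_series_term: Callable[[int], sp.Expr]
    #: closed-form function of (x, y, t) solving the alpha = 1 problem
    exact_alpha1: sp.Expr


def _gamma_term(prefactor: sp.Expr, rate: sp.Expr, sign: int = 1):
    """General term prefactor * (sign)^n * Gamma((n-1)a+1) rate^n / ((n-1)! Gamma(na+1))."""

    def term(n: int) -> sp.Expr:
        if n == 0:
            return prefactor
        return (
            prefactor
            * sp.Integer(sign) ** n
            * gamma((n - 1) * ALPHA + 1)
            * rate**n
            / (factorial(n - 1) * gamma(n * ALPHA + 1))
        )

    return term


_T = sp.Symbol("t", nonnegative=True)

_REFERENCES: dict[str, ReferenceSolution] = {
    "1": ReferenceSolution(
        "1", "u", _gamma_term(sqrt(x * y), h), sqrt(x * y) * exp(h * _T)
    ),
    "2": ReferenceSolution(
        "2",
        "u",
        _gamma_term(exp(sqrt(h * r / 8) * (x + y)), h),
        exp(sqrt(h * r / 8) * (x + y) + h * _T),
    ),
    "3u": ReferenceSolution(
        "3u", "u", _gamma_term(exp(x + y), sp.Integer(1), sign=-1), exp(x + y - _T)
    ),
    "3v": ReferenceSolution(
        "3v", "v", _gamma_term(exp(x - y), sp.Integer(1)), exp(x - y + _T)
    ),
    "3w": ReferenceSolution(
        "3w", "w", _gamma_term(exp(-x + y), sp.Integer(1)), exp(-x + y + _T)
    ),
}


def printed_coefficient(example_id: str, n: int) -> sp.Expr:
    """n-th entry of the reported coefficient table for an example component.

    These are the closed forms of the tables the as_printed recursion
    reproduces: h**(n+1)*sqrt(x*y)/n! for the first population model,
    h**(n+1)*exp(sqrt(h*r/8)*(x+y))/n! for the Verhulst model, and the
    alternating/plain exponential families for the three-component system.
    """
    n = int(n)
    tables = {
        "1": h ** (n + 1) * sqrt(x * y) / factorial(n),
        "2": h ** (n + 1) * exp(sqrt(h * r / 8) * (x + y)) / factorial(n),
        "3u": sp.Integer(-1) ** (n + 1) * exp(x + y) / factorial(n),
        "3v": exp(x - y) / factorial(n),
        "3w": exp(-x + y) / factorial(n),
    }
    try:
        return tables[str(example_id)]
    except KeyError:
        raise KeyError(
            f"unknown example id {example_id!r}; choose from {sorted(tables)}"
        ) from None


def reference_solution(example_id: str) -> ReferenceSolution:
    """Reference series/closed form for one of {'1', '2', '3u', '3v', '3w'}."""
    try:
        return _REFERENCES[str(example_id)]
    except KeyError:
        raise KeyError(
            f"unknown example id {example_id!r}; choose from {sorted(_REFERENCES)}"
        ) from None


#: initial-condition family for random linear fixtures
_FIXTURE_INITS: tuple[sp.Expr, ...] = (
    x * y,
    x + y + 1,
    x**2 * y,
    sqrt(x * y),
    exp(x + y),
    exp(x - y),
)


@dataclass(frozen=True)
class LinearFixtureOracle:
    """Independent scalar recurrence for the model D^alpha u = lam*u + mu.

    The strict-mode coefficient sequence satisfies c_0 = lam*g + mu and
    c_{k+1} = lam * c_k * Gamma(k*alpha+1)/Gamma((k+1)*alpha+1); this
    closed recurrence is computed without touching the engine and serves
    as its oracle.
    """

    lam: sp.Expr
    mu: sp.Expr
    init: sp.Expr

    def coeffs(self, N: int, alpha=ALPHA) -> list[sp.Expr]:
        c = [sp.simplify(self.lam * self.init + self.mu)]
        for k in range(N - 1):
            w = gamma(k * alpha + 1) / gamma((k + 1) * alpha + 1)
            c.append(sp.simplify(self.lam * c[-1] * w))
        return c

    def exact_value(self, x_val: float, y_val: float, t_val: float, alpha: float) -> float:
        """Closed-form value via the Mittag-Leffler kernel (lam != 0), or the
        single-term formula for lam = 0."""
        from .evaluation import mittag_leffler
        import math

        g = float(self.init.subs({x: x_val, y: y_val}))
        lam = float(self.lam)
        mu = float(self.mu)
        if lam == 0.0:
            return g + mu * t_val**alpha / math.gamma(alpha + 1)
        z = lam * t_val**alpha
        return g + (lam * g + mu) / lam * (mittag_leffler(z, alpha) - 1.0)


def random_linear_fixture(seed: int, alpha=ALPHA) -> tuple[ModelSpec, LinearFixtureOracle]:
    """Seeded random linear model D^alpha u = lam*u + mu with its oracle.

    lam is a nonzero rational drawn from {+-1/2, +-1} and mu from
    {0, +-1/2, +-1}; rates of order one keep the truncated series well
    inside its reliable local-in-time regime on t <= 1/2.  The initial
    condition is drawn from a small polynomial/radical/exponential family.
    """
    rng = random.Random(seed)
    lam = Rational(rng.choice([-2, -1, 1, 2]), 2)
    mu = Rational(rng.choice([-2, -1, 0, 1, 2]), 2)
    init = rng.choice(_FIXTURE_INITS)

    def rhs(U):
        u = U["u"]
        out = u.scale(lam)
        if mu != 0:
            out = out + FracSeries.constant(mu, u.alpha, u.trunc)
        return {"u": out}

    model = ModelSpec(
        name=f"linear-fixture-{seed}",
        components=("u",),
        spatial_vars=(x, y),
        params={"lam": lam, "mu": mu},
        initial_conditions={"u": init},
        rhs=rhs,
        alpha=alpha,
    )
    return model, LinearFixtureOracle(lam=lam, mu=mu, init=init)


MODEL_REGISTRY: dict[str, Callable[..., ModelSpec]] = {
    "biopop-ex1": example1,
    "biopop-ex2": example2,
    "triple-ex3": example3,
}


def get_model(name: str, alpha=ALPHA, seed: int | None = None) -> ModelSpec:
    """Look up a registered model by CLI name (``linear-fixture`` needs a seed)."""
    if name == "linear-fixture":
        model, _ = random_linear_fixture(1234 if seed is None else seed, alpha=alpha)
        return model
    try:
        return MODEL_REGISTRY[name](alpha=alpha)
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; choose from "
            f"{sorted(MODEL_REGISTRY) + ['linear-fixture']}"
        ) from None
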