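"""Symbolic kernel: generalized power series in t**alpha and the
Riemann-Liouville integral / Caputo derivative acting on them.

Every series handled here lives on the *alpha-lattice*: its t-exponents are
integer multiples of a single fractional order ``alpha`` in (0, 1].  A
:class:`FracSeries` stores the lattice index ``k`` (meaning ``t**(k*alpha)``)
rather than a floating exponent, so the Riemann-Liouville integral of order
``alpha`` is an exact index shift with a Gamma-ratio weight and the Caputo
derivative is its exact inverse on non-constant terms.

Coefficients are sympy expressions over the declared spatial variables and
model parameters ("spatial expressions").  Gamma ratios are kept symbolic;
numeric conversion is deferred to :mod:`nhpm.evaluation`.
"""

from __future__ import annotations

import json
import logging
import random
from typing import Iterable, Mapping, NamedTuple

import sympy as sp
from sympy import gamma

from . import _symbols
from .errors import (
    AlphaMismatchError,
    InconsistencyError,
    InvalidOrderError,
    LatticeViolationError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SeriesTerm",
    "FracSeries",
    "rl_integral",
    "rl_integral_power",
    "caputo_deriv",
    "series_add",
    "series_mul",
    "spatial_diff",
    "is_zero",
]

#: defaults for the numeric zero-probe fallback
PROBE_SEED = 1234
PROBE_POINTS = 5
PROBE_ATOL = 1e-9
#: probes clearly above this are accepted as evidence of non-zero-ness
PROBE_CLEAR = 1e-6


def is_zero(
    expr: sp.Expr,
    *,
    atol: float = PROBE_ATOL,
    seed: int = PROBE_SEED,
    n_points: int = PROBE_POINTS,
) -> bool:
    """Decide whether a spatial expression is identically zero.

    Canonical simplification is tried first; if it does not produce a
    structural zero the expression is probed at ``n_points`` pseudo-random
    points with every free symbol drawn uniformly from (0.5, 2) (fixed
    ``seed``).  A probe clearly different from zero settles the question;
    probes that are all tiny while the simplifier claims non-zero leave the
    expression *indeterminate*: it is treated as non-zero and a warning is
    logged.  Conversely a simplifier zero contradicted by a clearly non-zero
    probe raises :class:`InconsistencyError` rather than guessing.
    """
    expr = sp.sympify(expr)
    expanded = sp.expand(expr)
    simplified = expanded if expanded == 0 else sp.simplify(expanded)
    free = sorted(expr.free_symbols, key=lambda s: s.name)
    if not free:
        return simplified == 0 or abs(complex(expr.evalf())) <= atol

    rng = random.Random(seed)
    probes = []
    for _ in range(n_points):
        subs = {s: sp.Float(rng.uniform(0.5, 2.0)) for s in free}
        val = complex(expr.evalf(subs=subs, chop=False))
        probes.append(abs(val))

    if simplified == 0:
        if max(probes) > PROBE_CLEAR:
            raise InconsistencyError(
                f"simplifier reduced {expr} to zero but a probe gave {max(probes):g}"
            )
        return True
    if max(probes) > atol:
        return False
    logger.warning(
        "is_zero indeterminate for %s: simplifier non-zero, probes all <= %g; "
        "treating as non-zero",
        expr,
        atol,
    )
    return False


def _fast_zero(expr: sp.Expr) -> bool:
    """Cheap structural zero test used during normalization."""
    return sp.expand(expr) == 0


class SeriesTerm(NamedTuple):
    """One summand ``coeff * t**(index*alpha)`` of a :class:`FracSeries`."""

    index: int
    coeff: sp.Expr


class FracSeries:
    """Truncated generalized power series ``sum_k c_k(x) * t**(k*alpha)``.

    Parameters
    ----------
    terms
        Mapping ``index -> coefficient`` (sympy expressions).  Indices must
        be nonnegative; terms beyond ``trunc`` are discarded and structurally
        zero coefficients are dropped (normalization is idempotent).
    alpha
        The fractional order: a positive symbol or a number in (0, 1] (the
        value 1 recovers ordinary Taylor series).
    trunc
        Highest lattice index retained.
    """

    __slots__ = ("_terms", "alpha", "trunc")

    def __init__(self, terms: Mapping[int, sp.Expr], alpha, trunc: int):
        alpha = sp.sympify(alpha)
        if alpha.is_number and not (0 < alpha <= 1):
            raise InvalidOrderError(f"alpha must lie in (0, 1], got {alpha}")
        if trunc < 0:
            raise ValueError("trunc must be nonnegative")
        clean: dict[int, sp.Expr] = {}
        for k, c in terms.items():
            k = int(k)
            if k < 0:
                raise ValueError(f"negative lattice index {k}")
            if k > trunc:
                continue
            c = sp.sympify(c)
            if not _fast_zero(c):
                clean[k] = sp.expand(c)
        self._terms = dict(sorted(clean.items()))
        self.alpha = alpha
        self.trunc = int(trunc)

    # -- basic accessors -------------------------------------------------
    @property
    def terms(self) -> tuple[SeriesTerm, ...]:
        return tuple(SeriesTerm(k, c) for k, c in self._terms.items())

    def coeff(self, index: int) -> sp.Expr:
        return self._terms.get(index, sp.Integer(0))

    @property
    def indices(self) -> tuple[int, ...]:
        return tuple(self._terms)

    def is_empty(self) -> bool:
        return not self._terms

    @classmethod
    def zero(cls, alpha, trunc: int) -> "FracSeries":
        return cls({}, alpha, trunc)

    @classmethod
    def constant(cls, coeff, alpha, trunc: int) -> "FracSeries":
        return cls({0: coeff}, alpha, trunc)

    # -- ring structure --------------------------------------------------
    def _check_compat(self, other: "FracSeries") -> None:
        if sp.simplify(self.alpha - other.alpha) != 0:
            raise AlphaMismatchError(
                f"cannot combine series with alpha={self.alpha} and alpha={other.alpha}"
            )

    def __add__(self, other: "FracSeries") -> "FracSeries":
        if not isinstance(other, FracSeries):
            return NotImplemented
        self._check_compat(other)
        trunc = min(self.trunc, other.trunc)
        out: dict[int, sp.Expr] = dict(self._terms)
        for k, c in other._terms.items():
            out[k] = out.get(k, sp.Integer(0)) + c
        return FracSeries(out, self.alpha, trunc)

    def __sub__(self, other: "FracSeries") -> "FracSeries":
        return self + other.scale(-1)

    def __mul__(self, other: "FracSeries") -> "FracSeries":
        if not isinstance(other, FracSeries):
            return NotImplemented
        self._check_compat(other)
        trunc = min(self.trunc, other.trunc)
        out: dict[int, sp.Expr] = {}
        for i, ci in self._terms.items():
            for j, cj in other._terms.items():
                if i + j <= trunc:
                    out[i + j] = out.get(i + j, sp.Integer(0)) + ci * cj
        return FracSeries(out, self.alpha, trunc)

    def scale(self, factor) -> "FracSeries":
        """Multiply every coefficient by a spatial expression or scalar."""
        factor = sp.sympify(factor)
        return FracSeries(
            {k: factor * c for k, c in self._terms.items()}, self.alpha, self.trunc
        )

    def pow(self, n: int) -> "FracSeries":
        """Integer power by repeated Cauchy products (n >= 0)."""
        if n < 0 or int(n) != n:
            raise ValueError("series power requires a nonnegative integer exponent")
        out = FracSeries.constant(1, self.alpha, self.trunc)
        for _ in range(int(n)):
            out = out * self
        return out

    def truncate(self, trunc: int) -> "FracSeries":
        return FracSeries(self._terms, self.alpha, trunc)

    # -- calculus --------------------------------------------------------
    def diff(self, var: sp.Symbol, order: int = 1) -> "FracSeries":
        if order < 1 or int(order) != order:
            raise ValueError("differentiation order must be a positive integer")
        return FracSeries(
            {k: sp.diff(c, var, int(order)) for k, c in self._terms.items()},
            self.alpha,
            self.trunc,
        )

    def rl_integral(self, mu=None) -> "FracSeries":
        """Riemann-Liouville fractional integral of order ``mu``.

        On a power, J^mu maps ``t**g`` to ``Gamma(g+1)/Gamma(mu+g+1) *
        t**(mu+g)``.  ``mu`` must be zero (identity), the series' own alpha,
        or — when it is a number commensurate with a numeric alpha — an
        integer multiple of alpha, so that the result stays on the lattice;
        anything else raises :class:`LatticeViolationError`.  Terms pushed
        beyond the truncation order are discarded.
        """
        alpha = self.alpha
        if mu is None:
            mu = alpha
        mu = sp.sympify(mu)
        if mu.is_number and mu < 0:
            raise InvalidOrderError(f"integral order must be >= 0, got {mu}")
        if mu == 0:
            return self
        shift = sp.simplify(mu / alpha)
        if not (shift.is_integer and shift.is_positive):
            raise LatticeViolationError(
                f"J^{mu} leaves the {alpha}-lattice (shift {shift} not a positive integer)"
            )
        m = int(shift)
        out = {}
        for k, c in self._terms.items():
            if k + m <= self.trunc:
                w = gamma(k * alpha + 1) / gamma(k * alpha + mu + 1)
                out[k + m] = c * w
        return FracSeries(out, alpha, self.trunc)

    def caputo(self, alpha=None) -> "FracSeries":
        """Caputo fractional derivative of order alpha (the series' own).

        Constant-in-t terms are annihilated; ``c * t**(k*alpha)`` with k >= 1
        maps to ``c * Gamma(k*alpha+1)/Gamma((k-1)*alpha+1) * t**((k-1)*alpha)``,
        the exact left inverse of :meth:`rl_integral`.
        """
        if alpha is not None and sp.simplify(sp.sympify(alpha) - self.alpha) != 0:
            raise AlphaMismatchError(
                f"Caputo order {alpha} differs from series alpha {self.alpha}"
            )
        a = self.alpha
        out = {}
        for k, c in self._terms.items():
            if k == 0:
                continue
            w = gamma(k * a + 1) / gamma((k - 1) * a + 1)
            out[k - 1] = c * w
        return FracSeries(out, a, self.trunc)

    # -- equality / display ----------------------------------------------
    def as_expr(self, t: sp.Symbol = _symbols.t) -> sp.Expr:
        """The series as a sympy expression in ``t``."""
        return sp.Add(*(c * t ** (k * self.alpha) for k, c in self._terms.items()))

    def equals(self, other: "FracSeries") -> bool:
        """Symbolic termwise equality (up to the common truncation order)."""
        self._check_compat(other)
        trunc = min(self.trunc, other.trunc)
        for k in range(trunc + 1):
            if not is_zero(self.coeff(k) - other.coeff(k)):
                return False
        return True

    def __eq__(self, other) -> bool:
        if not isinstance(other, FracSeries):
            return NotImplemented
        return (
            self.alpha == other.alpha
            and self.trunc == other.trunc
            and self._terms == other._terms
        )

    def __hash__(self):
        return hash((self.alpha, self.trunc, tuple(self._terms.items())))

    def __repr__(self) -> str:
        body = " + ".join(
            f"({sp.sstr(c)})*t^{{{k}a}}" for k, c in self._terms.items()
        ) or "0"
        return f"FracSeries[alpha={self.alpha}, trunc={self.trunc}]: {body}"

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        if not self.alpha.is_number:
            alpha = "symbolic"
        elif self.alpha.is_Integer:
            alpha = int(self.alpha)
        elif self.alpha.is_Rational:
            alpha = sp.sstr(self.alpha)  # e.g. "1/2", kept exact
        else:
            alpha = float(self.alpha)
        return {
            "alpha": alpha,
            "trunc": self.trunc,
            "terms": [
                {"index": k, "coeff": sp.sstr(c)} for k, c in self._terms.items()
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "FracSeries":
        alpha = data["alpha"]
        if alpha == "symbolic":
            alpha = _symbols.alpha
        elif isinstance(alpha, str):
            alpha = _symbols.parse_expr(alpha)
        elif isinstance(alpha, int):
            alpha = sp.Integer(alpha)
        else:
            alpha = sp.Float(alpha)
        terms = {
            int(item["index"]): _symbols.parse_expr(item["coeff"])
            for item in data["terms"]
        }
        return cls(terms, alpha, int(data["trunc"]))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "FracSeries":
        return cls.from_dict(json.loads(text))


# -- functional wrappers (the module-level operation surface) --------------

def rl_integral(s: FracSeries, mu=None) -> FracSeries:
    """Riemann-Liouville integral J^mu of a lattice series (see method)."""
    return s.rl_integral(mu)


def caputo_deriv(s: FracSeries, alpha=None) -> FracSeries:
    """Caputo derivative D^alpha of a lattice series (see method)."""
    return s.caputo(alpha)


def series_add(a: FracSeries, b: FracSeries) -> FracSeries:
    return a + b


def series_mul(a: FracSeries, b: FracSeries) -> FracSeries:
    return a * b


def spatial_diff(s: FracSeries, var: sp.Symbol, order: int = 1) -> FracSeries:
    return s.diff(var, order)


def rl_integral_power(exponent, mu, var: sp.Symbol = _symbols.t) -> sp.Expr:
    """J^mu applied to the bare power ``var**exponent`` (exponent > -1).

    This is the Gamma-ratio power rule off the lattice, used for identities
    like the semigroup law J^mu J^beta = J^(mu+beta) on monomials.
    """
    mu = sp.sympify(mu)
    exponent = sp.sympify(exponent)
    if mu.is_number and mu < 0:
        raise InvalidOrderError(f"integral order must be >= 0, got {mu}")
    if exponent.is_number and exponent <= -1:
        raise InvalidOrderError(f"power rule requires exponent > -1, got {exponent}")
    if mu == 0:
        return var**exponent
    return gamma(exponent + 1) / gamma(mu + exponent + 1) * var ** (mu + exponent)


def random_series(
    rng: random.Random,
    alpha,
    trunc: int,
    n_terms: int,
    variables: Iterable[sp.Symbol] = (_symbols.x, _symbols.y),
) -> FracSeries:
    """Small random series with polynomial coefficients, for property tests."""
    variables = tuple(variables)
    terms: dict[int, sp.Expr] = {}
    for _ in range(n_terms):
        k = rng.randint(0, trunc)
        c = sp.Integer(rng.randint(-3, 3))
        for v in variables:
            c *= v ** rng.randint(0, 2)
        terms[k] = terms.get(k, sp.Integer(0)) + c
    return FracSeries(terms, alpha, trunc)
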