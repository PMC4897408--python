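"""Two-iterate homotopy perturbation engine for time-fractional systems.

The method writes each unknown as ``U = U0 + p*U1`` in a formal embedding
parameter ``p`` and chooses the initial-approximation series
``u0 = sum_n a_n(x) * t**(n*alpha)`` so that the first-order correction
``U1 = J^alpha( RHS(U0) - u0 )`` vanishes identically.  Matching the p^0
coefficient gives ``U0 = U(x, 0) + J^alpha(u0)``; vanishing U1 order by
order yields a triangular sequence of *linear* equations for the a_n — at
lattice index k the right-hand side only involves coefficients a_0..a_{k-1}
through the J^alpha shift, so each new unknown enters affinely (this is
asserted at runtime, and its failure marks a model outside the method's
demonstrated scope).

Two solver modes are provided.  ``strict`` propagates the exact Gamma-ratio
weights Gamma(k*alpha+1)/Gamma((k+1)*alpha+1) of J^alpha through the
recursion; the resulting series satisfies the equation to the truncation
order for symbolic alpha (Mittag-Leffler-type sums for linear problems).
``as_printed`` runs the identical recursion with those propagation weights
evaluated at alpha = 1 — the coefficient recursion of the integer-order
problem — and then assembles the final series with the alpha-dependent
weights.  The two modes coincide at alpha = 1; for alpha < 1 the as_printed
series is an alpha-deformation of the classical solution whose residual
generally starts at lattice index 1 (see :func:`residual`).
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import sympy as sp
from sympy import gamma

from . import _symbols
from .errors import SolveFailureError, UnsupportedModelError
from .fractional_calculus import FracSeries, is_zero

logger = logging.getLogger(__name__)

__all__ = [
    "ModelSpec",
    "NHPMSolution",
    "ResidualReport",
    "build_u0_ansatz",
    "build_U0",
    "u1_integrand",
    "solve_coefficients",
    "assemble_solution",
    "residual",
]

MODES = ("strict", "as_printed")


@dataclass(frozen=True)
class ModelSpec:
    """A system of time-fractional evolution equations D^alpha u_i = RHS_i(u).

    ``rhs`` receives the current approximations as a mapping ``name ->
    FracSeries`` and must return one lattice series per component, built
    from series addition, Cauchy products, scalar weighting and spatial
    differentiation only (this guarantees closure on the alpha-lattice).
    """

    name: str
    components: tuple[str, ...]
    spatial_vars: tuple[sp.Symbol, ...]
    params: dict[str, sp.Expr]
    initial_conditions: dict[str, sp.Expr]
    rhs: Callable[[Mapping[str, FracSeries]], dict[str, FracSeries]]
    alpha: sp.Expr = _symbols.alpha

    def __post_init__(self):
        if not self.components:
            raise UnsupportedModelError("model needs at least one component")
        missing = set(self.components) - set(self.initial_conditions)
        if missing:
            raise UnsupportedModelError(f"missing initial conditions for {missing}")
        object.__setattr__(self, "alpha", sp.sympify(self.alpha))

    def with_alpha(self, alpha) -> "ModelSpec":
        """The same model with the fractional order replaced (e.g. by 1)."""
        return ModelSpec(
            name=self.name,
            components=self.components,
            spatial_vars=self.spatial_vars,
            params=self.params,
            initial_conditions=self.initial_conditions,
            rhs=self.rhs,
            alpha=alpha,
        )


@dataclass
class NHPMSolution:
    """Solved coefficient families and the assembled series per component."""

    model_name: str
    mode: str
    N: int
    alpha: sp.Expr
    coeffs: dict[str, list[sp.Expr]]
    series: dict[str, FracSeries]
    diagnostics: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        alpha = self.series[next(iter(self.series))].to_dict()["alpha"]
        return {
            "model": self.model_name,
            "mode": self.mode,
            "N": self.N,
            "alpha": alpha,
            "components": {
                c: {
                    "coeffs": [sp.sstr(v) for v in self.coeffs[c]],
                    "series": self.series[c].to_dict(),
                }
                for c in self.coeffs
            },
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    @classmethod
    def from_dict(cls, data: dict) -> "NHPMSolution":
        comps = data["components"]
        coeffs = {
            c: [_symbols.parse_expr(v) for v in comps[c]["coeffs"]] for c in comps
        }
        series = {c: FracSeries.from_dict(comps[c]["series"]) for c in comps}
        alpha = series[next(iter(series))].alpha
        return cls(
            model_name=data["model"],
            mode=data["mode"],
            N=int(data["N"]),
            alpha=alpha,
            coeffs=coeffs,
            series=series,
        )

    @classmethod
    def from_json(cls, text: str) -> "NHPMSolution":
        return cls.from_dict(json.loads(text))


@dataclass
class ResidualReport:
    """D^alpha U0 - RHS(U0) per component, truncated at order M."""

    residuals: dict[str, FracSeries]
    leading_index: dict[str, int | None]

    def min_leading_index(self) -> int | None:
        finite = [v for v in self.leading_index.values() if v is not None]
        if len(finite) < len(self.leading_index):
            return None if not finite else min(finite)
        return min(finite)


def _weight(k: int, alpha, mode: str) -> sp.Expr:
    """Index-shift weight of J^alpha used while *propagating* coefficients."""
    if mode == "as_printed":
        return sp.Rational(1, k + 1)  # Gamma(k+1)/Gamma(k+2)
    return gamma(k * alpha + 1) / gamma((k + 1) * alpha + 1)


def build_u0_ansatz(coeff_symbols: Sequence[sp.Expr], N: int, alpha) -> FracSeries:
    """Initial-approximation ansatz sum_{n<N} a_n * t**(n*alpha)."""
    if N < 1:
        raise ValueError("ansatz order N must be >= 1")
    if len(coeff_symbols) < N:
        raise ValueError(f"need {N} coefficient symbols, got {len(coeff_symbols)}")
    return FracSeries({n: coeff_symbols[n] for n in range(N)}, alpha, max(N - 1, 0))


def build_U0(u0: FracSeries, init: sp.Expr, alpha=None, mode: str = "strict") -> FracSeries:
    """Zeroth homotopy iterate U0 = U(x, 0) + J^alpha(u0).

    The index-0 coefficient is the initial condition; index k+1 carries
    ``a_k`` times the J^alpha shift weight (exact in strict mode, evaluated
    at alpha = 1 in as_printed mode).
    """
    a = u0.alpha if alpha is None else sp.sympify(alpha)
    terms = {0: sp.sympify(init)}
    trunc = u0.trunc + 1
    for k, c in zip(u0.indices, (term.coeff for term in u0.terms)):
        if k + 1 <= trunc:
            terms[k + 1] = terms.get(k + 1, sp.Integer(0)) + c * _weight(k, a, mode)
    return FracSeries(terms, a, trunc)


def u1_integrand(
    model: ModelSpec,
    U0_all: Mapping[str, FracSeries],
    u0: FracSeries,
    component: str,
) -> FracSeries:
    """The bracket RHS(U0) - u0 whose J^alpha is the first-order term U1."""
    rhs = model.rhs(U0_all)
    return rhs[component] - u0


def _affine_solve(eq: sp.Expr, unknown: sp.Symbol, order: int, component: str) -> sp.Expr:
    """Solve an equation asserted to be affine in ``unknown``."""
    eq = sp.expand(eq)
    slope = sp.diff(eq, unknown)
    if unknown in slope.free_symbols:
        raise UnsupportedModelError(
            f"coefficient equation at order {order} ({component}) is nonlinear "
            f"in the newest unknown; the model is outside the method's scope"
        )
    if slope == 0:
        raise SolveFailureError(
            f"coefficient equation at order {order} ({component}) does not "
            f"determine the new coefficient",
            order=order,
        )
    return sp.simplify(sp.cancel(-eq.subs(unknown, 0) / slope))


def solve_coefficients(model: ModelSpec, N: int, mode: str = "strict") -> NHPMSolution:
    """Vanish U1 order by order and return the solved series (order N).

    At step k the zeroth iterate is rebuilt with all previously solved
    coefficients substituted *before* the right-hand side's spatial
    derivatives act — the coefficients are functions of the spatial
    variables, so substitution cannot be deferred past differentiation.
    The t**(k*alpha) coefficient of RHS(U0) - u0 is then equated to zero
    and solved for a_k.
    """
    if N < 1:
        raise ValueError("solution order N must be >= 1")
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    alpha = model.alpha
    solved: dict[str, list[sp.Expr]] = {c: [] for c in model.components}
    diagnostics: list[dict] = []

    for k in range(N):
        # Zeroth iterate from the coefficients solved so far.  Substitution
        # must precede the rhs builder's spatial derivatives, so solved
        # values are baked in; the still-unknown a_k rides along as a
        # placeholder at index k+1 (where J^alpha puts it) — the t**(k*alpha)
        # rhs coefficient can only reach it through operators that shift
        # indices down, which the affinity assertion below polices.
        placeholders = {c: sp.Dummy(f"a_{c}_{k}") for c in model.components}
        U0_all = {}
        for c in model.components:
            u0_partial = FracSeries(
                {**dict(enumerate(solved[c])), k: placeholders[c]}, alpha, k
            )
            U0_all[c] = build_U0(u0_partial, model.initial_conditions[c], alpha, mode)
        rhs = model.rhs(U0_all)
        for c in model.components:
            t0 = time.perf_counter()
            a_k = placeholders[c]
            eq = rhs[c].coeff(k) - a_k
            value = _affine_solve(eq, a_k, k, c)
            foreign = value.free_symbols & set(placeholders.values())
            if foreign:
                raise SolveFailureError(
                    f"coefficient equation at order {k} ({c}) couples same-order "
                    f"unknowns of other components",
                    order=k,
                )
            solved[c].append(value)
            diagnostics.append(
                {
                    "component": c,
                    "order": k,
                    "equation": sp.sstr(eq),
                    "solution": sp.sstr(value),
                    "seconds": round(time.perf_counter() - t0, 4),
                }
            )
            logger.info("order %d, component %s: a_%d = %s", k, c, k, value)

    series = assemble_solution(model, solved, N)
    return NHPMSolution(
        model_name=model.name,
        mode=mode,
        N=N,
        alpha=alpha,
        coeffs=solved,
        series=series,
        diagnostics=diagnostics,
    )


def assemble_solution(
    model: ModelSpec, coeffs: Mapping[str, Sequence[sp.Expr]], N: int
) -> dict[str, FracSeries]:
    """Assemble u = U(x,0) + J^alpha(sum_k a_k t**(k*alpha)) per component.

    Assembly always applies the exact alpha-dependent Gamma-ratio weights,
    whichever mode produced the coefficients: this is what turns the
    as_printed integer-order recursion into the fractional series the
    method reports.
    """
    alpha = model.alpha
    out = {}
    for c in model.components:
        u0 = FracSeries(dict(enumerate(coeffs[c])), alpha, N)
        out[c] = build_U0(u0, model.initial_conditions[c], alpha, mode="strict").truncate(N)
    return out


def residual(model: ModelSpec, sol: NHPMSolution, M: int | None = None) -> ResidualReport:
    """Residual series D^alpha U0 - RHS(U0) truncated at lattice index M.

    For strict-mode solutions the leading nonvanishing index is >= N by
    construction (the recursion matches orders exactly).  For as_printed
    solutions with symbolic alpha < 1 the leading index is typically 1 —
    the Gamma-bookkeeping difference between the two modes — while at
    alpha = 1 the modes coincide and the leading index is again >= N.
    """
    if M is None:
        M = sol.N
    residuals: dict[str, FracSeries] = {}
    leading: dict[str, int | None] = {}
    U0_all = {c: s.truncate(M) for c, s in sol.series.items()}
    rhs = model.rhs(U0_all)
    for c in model.components:
        res = U0_all[c].caputo() - rhs[c].truncate(M)
        residuals[c] = res
        idx = None
        for k in range(M + 1):
            coeff = res.coeff(k)
            if coeff != 0 and not is_zero(coeff):
                idx = k
                break
        leading[c] = idx
    return ResidualReport(residuals=residuals, leading_index=leading)
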