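"""Numeric evaluation of assembled series and closed-form reference sums.

The Gamma-ratio terms of the series span many orders of magnitude, so the
scalar sums here work in log-Gamma arithmetic with sign tracking and
accumulate in ascending order with Kahan compensation.  Truncated series
are local-in-time approximations: the default horizon is t in [0, 1], and
callers are warned when the last retained term is no longer small against
the partial sum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import sympy as sp

from . import _symbols
from .engine import NHPMSolution
from .errors import ConvergenceError, DomainError

__all__ = [
    "EvalGrid",
    "gamma_series_sum",
    "mittag_leffler",
    "evaluate_solution",
    "error_report",
]


@dataclass(frozen=True)
class EvalGrid:
    """Evaluation points (x, y, t) with x, y > 0, t >= 0, and alpha values."""

    points: tuple[tuple[float, float, float], ...]
    alpha_values: tuple[float, ...] = (1.0,)

    def __post_init__(self):
        pts = tuple((float(a), float(b), float(c)) for a, b, c in self.points)
        for xv, yv, tv in pts:
            if xv <= 0 or yv <= 0:
                raise DomainError(f"spatial point ({xv}, {yv}) outside x, y > 0")
            if tv < 0:
                raise DomainError(f"negative time {tv}")
        alphas = tuple(float(a) for a in self.alpha_values)
        for a in alphas:
            if not 0 < a <= 1:
                raise DomainError(f"alpha {a} outside (0, 1]")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "alpha_values", alphas)

    @classmethod
    def product(
        cls,
        xs: Iterable[float],
        ys: Iterable[float],
        ts: Iterable[float],
        alphas: Iterable[float] = (1.0,),
    ) -> "EvalGrid":
        pts = tuple((xv, yv, tv) for xv in xs for yv in ys for tv in ts)
        return cls(points=pts, alpha_values=tuple(alphas))


class _Kahan:
    """Compensated accumulator."""

    __slots__ = ("s", "c")

    def __init__(self):
        self.s = 0.0
        self.c = 0.0

    def add(self, v: float) -> None:
        t = v - self.c
        u = self.s + t
        self.c = (u - self.s) - t
        self.s = u


def gamma_series_sum(z: float, alpha: float, n_terms: int) -> float:
    """Partial sum 1 + sum_{n=1}^{n_terms} Gamma((n-1)a+1) z^n / ((n-1)! Gamma(na+1)).

    This is the scalar kernel of the assembled solution series (the spatial
    prefactor is applied by the caller); at alpha = 1 the general term
    collapses to z^n/n! and the sum is the exponential partial sum.  Terms
    are formed in log-Gamma arithmetic and added in ascending n.
    """
    if not 0 < alpha <= 1:
        raise DomainError(f"alpha {alpha} outside (0, 1]")
    if n_terms < 1:
        raise ValueError("n_terms must be >= 1")
    acc = _Kahan()
    acc.add(1.0)
    if z == 0.0:
        return acc.s
    sign_z = -1.0 if z < 0 else 1.0
    log_abs_z = math.log(abs(z))
    for n in range(1, n_terms + 1):
        log_term = (
            math.lgamma((n - 1) * alpha + 1.0)
            - math.lgamma(n)
            - math.lgamma(n * alpha + 1.0)
            + n * log_abs_z
        )
        acc.add(sign_z**n * math.exp(log_term))
    return acc.s


def mittag_leffler(
    z: float, alpha: float, tol: float = 1e-15, max_terms: int = 500
) -> float:
    """One-parameter Mittag-Leffler function E_alpha(z) = sum z^n / Gamma(na+1).

    Partial summation with a term-magnitude stopping rule (two consecutive
    terms below ``tol`` relative to the accumulated sum); reduces to e^z at
    alpha = 1.  Raises :class:`ConvergenceError` when the rule is not met
    within ``max_terms`` terms.
    """
    if not 0 < alpha <= 1:
        raise DomainError(f"alpha {alpha} outside (0, 1]")
    acc = _Kahan()
    acc.add(1.0)
    if z == 0.0:
        return acc.s
    sign_z = -1.0 if z < 0 else 1.0
    log_abs_z = math.log(abs(z))
    small_streak = 0
    for n in range(1, max_terms + 1):
        term = sign_z**n * math.exp(n * log_abs_z - math.lgamma(n * alpha + 1.0))
        acc.add(term)
        if abs(term) <= tol * max(1.0, abs(acc.s)):
            small_streak += 1
            if small_streak >= 2:
                return acc.s
        else:
            small_streak = 0
    raise ConvergenceError(
        f"E_{alpha}({z}) did not converge to tol {tol} in {max_terms} terms",
        terms_used=max_terms,
    )


def _subs_map(alpha_val: float, params: Mapping | None) -> dict:
    """Substitution map resolving parameter names against the canonical
    (assumption-carrying) symbol registry."""
    subs = {_symbols.alpha: sp.Float(alpha_val)}
    if params:
        for k, v in params.items():
            key = _symbols.parse_expr(k) if isinstance(k, str) else sp.sympify(k)
            subs[key] = sp.sympify(v)
    return subs


def _series_callable(series, alpha_val: float, params: Mapping | None):
    """Numeric (x, y, t) callable for one component series at numeric alpha."""
    expr = series.as_expr().subs(_subs_map(alpha_val, params))
    leftover = expr.free_symbols - {_symbols.x, _symbols.y, _symbols.t}
    if leftover:
        raise DomainError(
            f"series still contains symbols {sorted(map(str, leftover))}; "
            f"supply numeric parameter values"
        )
    f = sp.lambdify((_symbols.x, _symbols.y, _symbols.t), expr, modules="numpy")
    return f


def _last_term_callable(series, alpha_val: float, params: Mapping | None):
    if series.is_empty():
        return None
    k_last = series.indices[-1]
    expr = (series.coeff(k_last) * _symbols.t ** (k_last * series.alpha)).subs(
        _subs_map(alpha_val, params)
    )
    if expr.free_symbols - {_symbols.x, _symbols.y, _symbols.t}:
        return None
    return sp.lambdify((_symbols.x, _symbols.y, _symbols.t), expr, modules="numpy")


def evaluate_solution(
    sol: NHPMSolution,
    grid: EvalGrid,
    params: Mapping | None = None,
    warn_truncation: bool = True,
) -> pd.DataFrame:
    """Evaluate every component series on the grid.

    Returns a tidy frame with columns (component, x, y, t, alpha, value).
    When ``warn_truncation`` is set, a warning is emitted if at some point
    the last retained series term exceeds 1% of the partial sum — the
    truncated series should not be trusted there.
    """
    rows = []
    flagged = 0
    for alpha_val in grid.alpha_values:
        for comp, series in sol.series.items():
            f = _series_callable(series, alpha_val, params)
            g_last = _last_term_callable(series, alpha_val, params) if warn_truncation else None
            for xv, yv, tv in grid.points:
                val = float(f(xv, yv, tv))
                rows.append(
                    {
                        "component": comp,
                        "x": xv,
                        "y": yv,
                        "t": tv,
                        "alpha": alpha_val,
                        "value": val,
                    }
                )
                if g_last is not None and tv > 0:
                    last = abs(float(g_last(xv, yv, tv)))
                    if last > 0.01 * max(abs(val), 1e-300):
                        flagged += 1
    if flagged:
        warnings.warn(
            f"{flagged} grid evaluations have a last retained term above 1% of "
            f"the partial sum; the truncated series is unreliable there",
            stacklevel=2,
        )
    return pd.DataFrame(rows, columns=["component", "x", "y", "t", "alpha", "value"])


def error_report(
    sol: NHPMSolution,
    reference: Mapping[str, sp.Expr],
    grid: EvalGrid,
    params: Mapping | None = None,
) -> pd.DataFrame:
    """Absolute and relative errors of the series against a reference.

    ``reference`` maps component names to closed-form expressions in
    (x, y, t) — and possibly alpha — e.g. the exact alpha = 1 solutions.
    """
    table = evaluate_solution(sol, grid, params=params, warn_truncation=False)
    ref_vals = []
    for alpha_val in grid.alpha_values:
        for comp in sol.series:
            expr = sp.sympify(reference[comp]).subs(_subs_map(alpha_val, params))
            fref = sp.lambdify((_symbols.x, _symbols.y, _symbols.t), expr, modules="numpy")
            for xv, yv, tv in grid.points:
                ref_vals.append(float(fref(xv, yv, tv)))
    table = table.assign(reference=ref_vals)
    table["abs_err"] = (table["value"] - table["reference"]).abs()
    denom = table["reference"].abs().clip(lower=np.finfo(float).tiny)
    table["rel_err"] = table["abs_err"] / denom
    return table
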