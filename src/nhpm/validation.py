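"""Self-contained validation checks tying the solver to its references.

Each check compares engine output against data that is independent of the
recursion it validates: closed-form coefficient tables, general series
terms, exact alpha = 1 solutions, the Gamma-ratio power rule, and the
scalar recurrence oracle for random linear fixtures.  The CLI ``validate``
subcommand and the repository's acceptance machinery both run these.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass

import sympy as sp
from sympy import Rational, factorial, gamma, sqrt

from ._symbols import alpha as ALPHA
from ._symbols import h, r, t, x, y
from .engine import residual, solve_coefficients
from .evaluation import EvalGrid, evaluate_solution, gamma_series_sum, mittag_leffler
from .fractional_calculus import is_zero, rl_integral_power, random_series
from .models import (
    example1,
    example2,
    example3,
    printed_coefficient,
    random_linear_fixture,
    reference_solution,
)

__all__ = [
    "CheckResult",
    "check_printed_tables",
    "check_closed_form_series",
    "check_alpha1_exactness",
    "check_residual_orders",
    "check_kernel_laws",
    "check_fixture_recovery",
    "check_evaluator",
    "check_radical_readings",
    "run_all",
]

_EXAMPLES = {
    "1": (example1, {"u": "1"}),
    "2": (example2, {"u": "2"}),
    "3": (example3, {"u": "3u", "v": "3v", "w": "3w"}),
}


@dataclass
class CheckResult:
    name: str
    passed: bool
    detail: str = ""


def _sym_eq(a: sp.Expr, b: sp.Expr) -> bool:
    return is_zero(sp.expand(a - b))


def check_printed_tables(N: int = 5) -> CheckResult:
    """as_printed coefficients match the reported closed-form tables (n < N)."""
    failures = []
    for ex_id, (builder, comp_map) in _EXAMPLES.items():
        sol = solve_coefficients(builder(), N, mode="as_printed")
        for comp, table_id in comp_map.items():
            for n in range(N):
                expected = printed_coefficient(table_id, n)
                if not _sym_eq(sol.coeffs[comp][n], expected):
                    failures.append(f"example {ex_id}/{comp} a_{n}")
    return CheckResult(
        "printed coefficient tables",
        not failures,
        "; ".join(failures) or f"all tables match for n < {N}",
    )


def check_closed_form_series(n_max: int = 8) -> CheckResult:
    """Assembled as_printed series equal the closed general terms, n <= n_max."""
    failures = []
    for ex_id, (builder, comp_map) in _EXAMPLES.items():
        sol = solve_coefficients(builder(), n_max, mode="as_printed")
        for comp, ref_id in comp_map.items():
            ref = reference_solution(ref_id)
            for n in range(n_max + 1):
                if not _sym_eq(sol.series[comp].coeff(n), ref.closed_series_term(n)):
                    failures.append(f"example {ex_id}/{comp} term {n}")
    return CheckResult(
        "closed-form series terms",
        not failures,
        "; ".join(failures) or f"all series terms match for n <= {n_max}",
    )


def check_alpha1_exactness(N: int = 8) -> CheckResult:
    """At alpha = 1 both modes give the degree-N Taylor polynomial of the
    exact solution, and the two coefficient families coincide termwise."""
    failures = []
    for ex_id, (builder, comp_map) in _EXAMPLES.items():
        model = builder(alpha=sp.Integer(1))
        sols = {m: solve_coefficients(model, N, mode=m) for m in ("strict", "as_printed")}
        for comp, ref_id in comp_map.items():
            exact = reference_solution(ref_id).exact_alpha1
            taylor = sp.series(exact, t, 0, N + 1).removeO()
            for mode, sol in sols.items():
                if not _sym_eq(sol.series[comp].as_expr(), sp.expand(taylor)):
                    failures.append(f"example {ex_id}/{comp} {mode} Taylor")
            for n in range(N):
                if not _sym_eq(
                    sols["strict"].coeffs[comp][n], sols["as_printed"].coeffs[comp][n]
                ):
                    failures.append(f"example {ex_id}/{comp} mode mismatch a_{n}")
    return CheckResult(
        "alpha=1 exactness",
        not failures,
        "; ".join(failures) or f"degree-{N} Taylor polynomials reproduced",
    )


def check_residual_orders(N: int = 6) -> CheckResult:
    """Strict residuals vanish below index N (symbolic alpha); as_printed
    residuals lead at index 1 symbolically and below-N-free at alpha = 1."""
    failures = []
    for ex_id, (builder, _) in _EXAMPLES.items():
        model = builder()
        strict = solve_coefficients(model, N, mode="strict")
        rep = residual(model, strict, M=N)
        for comp, idx in rep.leading_index.items():
            if idx is not None and idx < N:
                failures.append(f"example {ex_id}/{comp} strict leading {idx} < {N}")
        printed = solve_coefficients(model, N, mode="as_printed")
        rep_p = residual(model, printed, M=N)
        for comp, idx in rep_p.leading_index.items():
            if idx != 1:
                failures.append(f"example {ex_id}/{comp} as_printed leading {idx} != 1")
        model1 = builder(alpha=sp.Integer(1))
        printed1 = solve_coefficients(model1, N, mode="as_printed")
        rep1 = residual(model1, printed1, M=N)
        for comp, idx in rep1.leading_index.items():
            if idx is not None and idx < N:
                failures.append(f"example {ex_id}/{comp} alpha=1 leading {idx} < {N}")
    return CheckResult(
        "residual orders",
        not failures,
        "; ".join(failures) or f"strict residuals vanish below index {N}",
    )


def check_kernel_laws(n_checks: int = 200, seed: int = 1234) -> CheckResult:
    """Randomized semigroup, linearity, and inversion laws of the kernel."""
    rng = random.Random(seed)
    failed = 0
    per_law = max(n_checks // 4, 1)
    # semigroup J^mu J^beta = J^(mu+beta) on monomials t**g, exact
    for _ in range(per_law):
        mu = Rational(rng.randint(1, 8), rng.randint(1, 4))
        beta = Rational(rng.randint(1, 8), rng.randint(1, 4))
        g = Rational(rng.randint(0, 6), rng.randint(1, 3))
        inner = rl_integral_power(g, mu)
        # apply J^beta to the resulting monomial coeff * t**(g+mu)
        coeff = inner / t ** (g + mu)
        lhs2 = sp.simplify(coeff * rl_integral_power(g + mu, beta))
        rhs = sp.simplify(rl_integral_power(g, mu + beta))
        if sp.simplify(lhs2 - rhs) != 0:
            failed += 1
    # linearity of J^alpha and D^alpha over spatial-coefficient sums
    for _ in range(per_law):
        s1 = random_series(rng, ALPHA, 6, 3)
        s2 = random_series(rng, ALPHA, 6, 3)
        c = sp.Integer(rng.randint(-3, 3))
        left = (s1.scale(c) + s2).rl_integral()
        right = s1.rl_integral().scale(c) + s2.rl_integral()
        if not left.equals(right):
            failed += 1
        left_d = (s1.scale(c) + s2).caputo()
        right_d = s1.caputo().scale(c) + s2.caputo()
        if not left_d.equals(right_d):
            failed += 1
    # inversion D^alpha (J^alpha s) = s up to truncation
    for _ in range(per_law):
        s = random_series(rng, ALPHA, 6, 4)
        back = s.rl_integral().caputo()
        if not back.equals(s.truncate(s.trunc - 1)):
            failed += 1
    total = per_law * 4
    return CheckResult(
        "kernel laws",
        failed == 0,
        f"{total - failed}/{total} randomized checks passed",
    )


def check_fixture_recovery(
    n_seeds: int = 20, N: int = 8, tol: float = 1e-10, seed0: int = 0
) -> CheckResult:
    """Strict coefficients equal the scalar-recurrence oracle for seeded
    linear fixtures, and numeric values match the Mittag-Leffler closed
    form on t <= 0.5."""
    failures = []
    max_err = 0.0
    grid_alphas = (0.7, 0.85, 1.0)
    pts = [(1.0, 1.0, tv) for tv in (0.1, 0.3, 0.5)] + [(0.8, 1.3, 0.4)]
    for i in range(n_seeds):
        seed = seed0 + i
        model, oracle = random_linear_fixture(seed)
        sol = solve_coefficients(model, N, mode="strict")
        expected = oracle.coeffs(N)
        for n in range(N):
            if not _sym_eq(sol.coeffs["u"][n], expected[n]):
                failures.append(f"seed {seed} a_{n}")
                break
        # numeric check at N=15 for a tight truncation error
        sol15 = solve_coefficients(model, 15, mode="strict")
        for a_val in grid_alphas:
            table = evaluate_solution(
                sol15, EvalGrid(points=tuple(pts), alpha_values=(a_val,)),
                warn_truncation=False,
            )
            for _, row in table.iterrows():
                ref = oracle.exact_value(row.x, row.y, row.t, a_val)
                err = abs(row.value - ref)
                max_err = max(max_err, err)
                if err > tol:
                    failures.append(f"seed {seed} numeric err {err:.2e} at alpha={a_val}")
    return CheckResult(
        "fixture recovery",
        not failures,
        "; ".join(failures[:5]) or f"{n_seeds} fixtures recovered, max numeric error {max_err:.2e}",
    )


def check_evaluator(n_terms: int = 30, tol: float = 1e-12) -> CheckResult:
    """gamma_series_sum at alpha = 1 is the exponential partial sum, and the
    Gamma identity Gamma(n)/((n-1)! Gamma(n+1)) = 1/n! holds symbolically."""
    failures = []
    max_err = 0.0
    for z10 in range(-50, 51, 5):
        z = z10 / 10.0
        err = abs(gamma_series_sum(z, 1.0, n_terms) - math.exp(z))
        max_err = max(max_err, err)
        if err > tol:
            failures.append(f"z={z} err {err:.2e}")
    for n in range(1, 31):
        ratio = gamma(n) / (factorial(n - 1) * gamma(n + 1))
        if sp.simplify(ratio - Rational(1, math.factorial(n))) != 0:
            failures.append(f"Gamma identity n={n}")
    return CheckResult(
        "evaluator correctness",
        not failures,
        "; ".join(failures[:5]) or f"max |sum - exp| = {max_err:.2e} over z in [-5, 5]",
    )


def check_radical_readings() -> CheckResult:
    """The radical readings of the initial data are forced by cancellation:
    (u^2)_xx + (u^2)_yy vanishes identically for u = sqrt(x*y)*v(t), and the
    alpha = 1 residual of the Verhulst exact form vanishes iff the initial
    exponent theta satisfies 8*theta**2 = h*r."""
    failures = []
    v = sp.Function("v")
    u = sqrt(x * y) * v(t)
    diffusion = sp.diff(u**2, x, 2) + sp.diff(u**2, y, 2)
    if sp.simplify(diffusion) != 0:
        failures.append("degenerate diffusion does not vanish for sqrt(x*y)*v(t)")
    theta = sp.Symbol("theta", positive=True)
    u2 = sp.exp(theta * (x + y) + h * t)
    res = sp.diff(u2, t) - (
        sp.diff(u2**2, x, 2) + sp.diff(u2**2, y, 2) + h * u2 * (1 - r * u2)
    )
    res_pinned = res.subs(theta, sqrt(h * r / 8))
    if sp.simplify(res_pinned) != 0:
        failures.append("residual does not vanish at theta = sqrt(h*r/8)")
    # residual must NOT vanish for generic theta (e.g. theta with 8theta^2 != hr)
    res_generic = sp.simplify(res.subs({theta: sp.Integer(1), h: sp.Integer(1), r: sp.Integer(1)}))
    if res_generic == 0:
        failures.append("residual vanishes for a generic exponent; reading not pinned")
    return CheckResult(
        "radical readings",
        not failures,
        "; ".join(failures) or "8*theta**2 = h*r cancellation pins the readings",
    )


def run_all(fast: bool = False) -> list[CheckResult]:
    """Run every check; ``fast`` shrinks sizes for interactive use."""
    if fast:
        return [
            check_printed_tables(N=3),
            check_closed_form_series(n_max=4),
            check_alpha1_exactness(N=4),
            check_residual_orders(N=3),
            check_kernel_laws(n_checks=40),
            check_fixture_recovery(n_seeds=3, N=5),
            check_evaluator(),
            check_radical_readings(),
        ]
    return [
        check_printed_tables(),
        check_closed_form_series(),
        check_alpha1_exactness(),
        check_residual_orders(),
        check_kernel_laws(),
        check_fixture_recovery(),
        check_evaluator(),
        check_radical_readings(),
    ]
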