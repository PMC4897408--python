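# Methods

## Problem class and operators

The solver targets systems of time-fractional evolution equations
`D_t^α u_i = L_i(u) + N_i(u) + f_i` on the positive orthant `x, y > 0`
with classical initial data `u_i(x, y, 0)` and `0 < α ≤ 1`.  `D_t^α` is
the Caputo derivative, i.e. a Riemann–Liouville integral of an
integer-order derivative; its key property here is that it admits
ordinary initial conditions and annihilates constants.  All series live
on the *α-lattice*: exponents of `t` are integer multiples of α.  The
kernel stores the lattice index `k` (meaning `t^{kα}`) instead of a
floating exponent, so on a lattice series

* `J^α` is an exact index shift `k → k+1` with weight
  `Γ(kα+1)/Γ((k+1)α+1)`,
* `D^α` is the exact inverse shift, with index-0 terms mapped to zero,

and both identities hold symbolically without Γ-simplification
heuristics.  Arbitrary positive orders are supported on bare powers
through the Γ-ratio power rule (`rl_integral_power`); on lattice series
an order is accepted only if it is an integer multiple of α, otherwise a
lattice-violation error is raised.  Fractional orders α > 1,
Riemann–Liouville-type derivatives and exponents off the lattice are out
of scope.

## The two-iterate homotopy recursion

Writing `U = U₀ + p U₁` and `u₀ = Σ_{n<N} a_n(x, y) t^{nα}`, matching
powers of the embedding parameter gives

* `p⁰`: `U₀ = u(x, 0) + J^α(u₀)`
* `p¹`: `U₁ = J^α(L(U₀) + N(U₀) + f − u₀)`

and the method chooses the `a_n` so that `U₁ ≡ 0`.  The `t^{kα}`
coefficient of the integrand couples `a_k` (from `−u₀`) to the rhs
coefficient at index k, which only involves `a_0 … a_{k−1}` because the
rhs is built from additions, Cauchy products, scalar weights and spatial
derivatives — operators that never shift lattice indices down.  The
system is therefore triangular with each equation *affine* in its newest
unknown; the engine asserts this at runtime and rejects models where it
fails (e.g. right-hand sides applying `D^α` to the unknown, which do
shift indices down and can couple `a_k` nonlinearly).

Two implementation points matter for correctness:

1. **Substitution precedes differentiation.**  The solved `a_j(x, y)`
   are spatial functions, so they must be substituted into `U₀` *before*
   the rhs applies `∂/∂x`, `∂/∂y`.  The engine rebuilds `U₀` from solved
   coefficients at every order; carrying opaque placeholder symbols
   through the derivatives would silently treat them as constants and
   corrupt every order beyond the first.
2. **Only the newest unknown rides along** as a placeholder at index
   k+1 (where `J^α` puts it), so the affinity assertion can see it when
   a pathological rhs reaches down to it.

Reaction exponents in the population supply term `h u^a(1 − r u^b)` are
restricted to nonnegative integers: non-integer powers of a series with
non-constant leading term leave the representable class, and the model
constructor rejects them loudly rather than approximating.

## Solver modes

`strict` (default) propagates the exact weights
`Γ(kα+1)/Γ((k+1)α+1)` of `J^α` through the recursion.  The resulting
series matches orders exactly: its residual `D^α U₀ − RHS(U₀)` has no
nonvanishing coefficient below the truncation order for symbolic α, and
linear problems sum to Mittag-Leffler-type series.

`as_printed` runs the identical recursion with the propagation weights
evaluated at α = 1 (`1/(k+1)`, the integer-order recursion) and applies
the α-dependent weights only in the final assembly.  This is the
classical presentation of the method and reproduces the familiar
coefficient tables (`a_n = h^{n+1}√(xy)/n!` etc.) and closed general
terms verbatim.  For α < 1 its residual generally starts at lattice
index 1 — the Γ-bookkeeping difference between the recursions — while at
α = 1 both modes coincide.  The residual diagnostic reports this fact
without adjudicating which series is "the" fractional solution; both
modes are first-class outputs.

The homotopy map `H(U; p)` and the parameter `p` are never materialized
as data: `p` is formal bookkeeping, and the engine implements the
`p⁰`/`p¹` equations directly.

## Built-in models and the radical readings

The initial data of the two population examples are taken as `√(xy)` and
`exp(√(hr/8)(x+y))`.  These radical readings are *forced* by internal
consistency, and the package pins them with symbolic tests rather than
assuming them:

* `(u²)_xx + (u²)_yy ≡ 0` for any separable profile `u = √(xy) v(t)` —
  the degenerate diffusion is invisible exactly for this spatial shape,
  which is what makes the pure-growth example solvable in closed form
  (`√(xy) e^{ht}` at α = 1);
* with initial exponent θ, the α = 1 residual of `e^{θ(x+y)+ht}` in the
  Verhulst model vanishes **iff** `8θ² = hr`, which selects
  `θ = √(hr/8)`.

The spatial variables are declared positive (`x, y > 0`), which is both
the natural habitat of `√(xy)` and `(xy)^{3/2}` and what lets the
simplifier close the radical cancellations.  The growth/competition
parameters `h, r` are likewise declared positive so that `√(hr/8)` is
real.  The three-component system is taken in its clean antisymmetric
form `D^α u = −v_x w_y + v_y w_x − u` (cyclically, with sign flips on
the linear terms); at its exponential initial data the gradient
couplings cancel pairwise and the system collapses to three decoupled
linear equations — which is why its strict solution is a pure
Mittag-Leffler deformation of `(e^{x+y−t}, e^{x−y+t}, e^{−x+y+t})`.

## Zero testing

Deciding whether a spatial coefficient vanishes drives both
normalization and residual grading.  `is_zero` first tries canonical
simplification; if inconclusive it probes the expression at 5
pseudo-random points with every free symbol drawn uniformly from
(0.5, 2) (fixed seed 1234, absolute tolerance 1e-9).  A clearly nonzero
probe settles the matter; probes that are all tiny against a
nonzero-looking simplification leave the expression *indeterminate* —
treated as nonzero with a logged warning.  A simplifier zero
contradicted by a clearly nonzero probe raises an inconsistency error
rather than guessing.  Fast structural expansion (not the full probe
machinery) is used inside series normalization, which keeps it cheap and
idempotent.

## Synthetic fixtures

`random_linear_fixture(seed)` draws a linear model `D^α u = λu + μ` with
λ a nonzero rational in {±1/2, ±1}, μ in {0, ±1/2, ±1}, and an initial
condition from a small polynomial/radical/exponential family.  Its
strict coefficient sequence satisfies the scalar recurrence
`c₀ = λg + μ`, `c_{k+1} = λ c_k Γ(kα+1)/Γ((k+1)α+1)`, which the fixture
computes independently of the engine; the closed-form value
`g + (λg+μ)/λ (E_α(λt^α) − 1)` provides the numeric cross-check.  Rates
of order one are representative of the study systems (all three examples
have unit linear rates up to the symbolic h) and keep the truncated
series well inside its reliable regime on `t ≤ 1/2`, where the N = 15
truncation error sits below 1e-10.  What the fixtures do **not**
exercise is nonlinearity — that is covered by the three example models
themselves, whose nonlinear couplings are nontrivial at every order of
the recursion.

## Numerics

`gamma_series_sum` and `mittag_leffler` form each term via `lgamma` with
explicit sign tracking and accumulate in ascending order with Kahan
compensation; `mittag_leffler` stops after two consecutive terms below
the relative tolerance (default 1e-15) and reports non-convergence with
the number of terms used.  Grid evaluation substitutes a numeric α and
parameter values into the assembled series, validates that points lie in
the declared domain (x, y > 0, t ≥ 0, α ∈ (0, 1]), and emits a tidy
table.  A warning is raised when the last retained term exceeds 1% of
the partial sum at some point — the truncation heuristic behind the
default `t ∈ [0, 1]` horizon.

## Problem sizes and defaults

The default truncation order is N = 10 (the ansatz length used in the
logistic example's own statement); validation solves to N = 8 for series
comparisons, N = 6 for residual grading and N = 15 for the numeric
fixture cross-check, sizes at which every check is exact or
tight while the whole suite stays interactive.  Determinism: identical
model, order and mode produce byte-identical serialized solutions, and
all randomness (zero-probe points, fixtures, kernel-law draws) flows
from explicit seeds.

## Known limitations

* Only the `t^{nα}` basis is implemented; general basis functions
  `p_n(t)` and higher homotopy orders (U₂, …) are out of scope — the
  method is defined by its two iterates.
* The as_printed/strict discrepancy for α < 1 is reported, not
  resolved: no convergence theory is provided, and residual order is the
  only optimality notion used.
* Symbolic solving cost grows with nonlinearity depth and order; the
  per-order solve log (equation, solution, time) at INFO verbosity is
  the intended observability hook.
* Numeric evaluation trusts the truncated series only locally in time;
  no series acceleration is attempted.
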