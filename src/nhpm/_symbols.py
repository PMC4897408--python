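"""Canonical symbol registry.

All spatial variables and model parameters live on the positive orthant:
``x, y > 0`` is a declared assumption (the biological population model
involves sqrt(x*y) and (x*y)**(3/2) terms that are meaningless at the
origin), and the growth/competition parameters ``h, r`` are taken positive
so that sqrt(h*r/8) is real.  Expressions parsed from text are resolved
against this registry so that assumptions survive serialization.
"""

from __future__ import annotations

import sympy as sp

x, y = sp.symbols("x y", positive=True)
t = sp.Symbol("t", nonnegative=True)
alpha = sp.Symbol("alpha", positive=True)
h, r = sp.symbols("h r", positive=True)

#: symbols visible to the expression parser
LOCALS = {"x": x, "y": y, "t": t, "alpha": alpha, "h": h, "r": r}


def parse_expr(text: str) -> sp.Expr:
    """Parse a plain-text math expression against the canonical symbols."""
    return sp.sympify(text, locals=dict(LOCALS))
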