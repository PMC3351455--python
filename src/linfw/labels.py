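"""Edge-label algebra.

Edge labels are sympy expressions over two kinds of positive symbols:

* **rate constants** -- plain names (``k1``, ``a``, ``kon``), units 1/time
  or 1/(concentration * time);
* **concentrations** -- bracketed names (``[S]``, ``[E]``), units
  concentration, referring to *slow* species outside the graph.

A label as a whole has units 1/time and must evaluate to a strictly
positive number for any positive assignment of its symbols.  The bracketed
naming convention makes the role of every symbol queryable without a side
registry: a symbol is a concentration iff its name is ``[...]``.
"""

from __future__ import annotations

import re
from typing import Iterable

import sympy

__all__ = [
    "rate",
    "conc",
    "is_conc",
    "species_name",
    "concentration_symbols",
    "parse_label",
    "validate_label",
    "LabelError",
]

_CONC_RE = re.compile(r"\[([A-Za-z_]\w*)\]")
_CONC_PLACEHOLDER = "_CONC_{}_"
_PLACEHOLDER_RE = re.compile(r"_CONC_([A-Za-z_]\w*)_")


class LabelError(ValueError):
    """Raised for malformed or non-positive edge labels."""


def rate(name: str) -> sympy.Symbol:
    """A positive rate-constant symbol."""
    if _CONC_RE.fullmatch(name):
        raise LabelError(f"rate-constant name may not be bracketed: {name!r}")
    return sympy.Symbol(name, positive=True)


def conc(name: str) -> sympy.Symbol:
    """A positive concentration symbol, printed as ``[name]``."""
    if name.startswith("["):
        name = name.strip("[]")
    return sympy.Symbol(f"[{name}]", positive=True)


def is_conc(sym: sympy.Symbol) -> bool:
    name = sym.name
    return name.startswith("[") and name.endswith("]")


def species_name(sym: sympy.Symbol) -> str:
    """Chemical-species name behind a concentration symbol."""
    if not is_conc(sym):
        raise LabelError(f"{sym} is not a concentration symbol")
    return sym.name[1:-1]


def concentration_symbols(expr: sympy.Expr) -> set[sympy.Symbol]:
    """The concentration symbols occurring in a label."""
    return {s for s in sympy.sympify(expr).free_symbols if is_conc(s)}


def parse_label(text: str) -> sympy.Expr:
    """Parse an expression string with ``+ - * / ( )`` and bracketed
    concentrations, e.g. ``"k1*[S] + k4*[P]"``."""
    encoded = _CONC_RE.sub(lambda m: _CONC_PLACEHOLDER.format(m.group(1)), text)
    if "[" in encoded or "]" in encoded:
        raise LabelError(f"malformed label {text!r}: stray bracket")
    names = set(re.findall(r"[A-Za-z_]\w*", encoded))
    local = {}
    for nm in names:
        m = _PLACEHOLDER_RE.fullmatch(nm)
        local[nm] = conc(m.group(1)) if m else rate(nm)
    try:
        expr = sympy.sympify(encoded, locals=local, rational=True)
    except (sympy.SympifyError, SyntaxError, TypeError) as exc:
        raise LabelError(f"malformed label {text!r}: {exc}") from None
    return expr


def format_label(expr: sympy.Expr) -> str:
    """Deterministic string form of a label (sympy's canonical printing)."""
    return sympy.sstr(sympy.sympify(expr), order="lex")


def validate_label(expr: sympy.Expr, *, rng=None, samples: int = 10) -> sympy.Expr:
    """Check that a label is a valid edge weight.

    Positivity is sampled: the label is evaluated at ``samples`` random
    positive points (log-uniform over [1e-3, 1e3]); any non-positive or
    undefined value raises.  Identically-zero labels are rejected -- a
    zero label means "no edge".
    """
    import numpy as np

    expr = sympy.sympify(expr)
    if expr.is_zero:
        raise LabelError("zero label: use no edge instead")
    syms = sorted(expr.free_symbols, key=lambda s: s.name)
    if not syms:
        val = float(expr)
        if not val > 0:
            raise LabelError(f"non-positive constant label {val}")
        return expr
    if rng is None:
        rng = np.random.default_rng(0)
    fn = sympy.lambdify(syms, expr, "numpy")
    for _ in range(samples):
        pt = 10.0 ** rng.uniform(-3, 3, size=len(syms))
        try:
            val = float(fn(*pt))
        except (ZeroDivisionError, FloatingPointError, OverflowError) as exc:
            raise LabelError(f"label {expr} undefined at positive point: {exc}")
        if not np.isfinite(val) or val <= 0:
            raise LabelError(
                f"label {expr} evaluates to {val} at a positive point; "
                "labels must be strictly positive"
            )
    return expr
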