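"""Expression handling shared by the validator, compiler, and file readers.

Rate expressions and edge weights are stored on the model records as plain
strings and only parsed when needed.  Parsing goes through sympy with a
deliberately small namespace: every declared species and parameter name maps
to a plain :class:`sympy.Symbol` (so single-letter names like ``I``, ``S`` or
``E`` never collide with sympy's built-in constants), unknown names become
free symbols the validator can flag, and only a handful of elementary
functions are available.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping

import sympy
from sympy.parsing.sympy_parser import parse_expr

#: Reserved symbol for explicit time dependence in rate expressions.
TIME_SYMBOL = "t"

#: ASCII spellings accepted for the Greek letters the field habitually uses.
GREEK_ALIASES: dict[str, str] = {
    "alpha": "α", "beta": "β", "gamma": "γ", "delta": "δ", "epsilon": "ε",
    "theta": "θ", "kappa": "κ", "lambda": "λ", "mu": "μ", "nu": "ν",
    "rho": "ρ", "sigma": "σ", "tau": "τ", "phi": "φ", "chi": "χ",
    "psi": "ψ", "omega": "ω",
    "Gamma": "Γ", "Delta": "Δ", "Theta": "Θ", "Lambda": "Λ", "Sigma": "Σ",
    "Phi": "Φ", "Psi": "Ψ", "Omega": "Ω",
}

_IDENTIFIER_RE = re.compile(r"^[^\W\d]\w*$", re.UNICODE)
_NAME_TOKEN_RE = re.compile(r"[^\W\d]\w*", re.UNICODE)

# Functions permitted inside rate/weight expressions.
_ALLOWED_FUNCTIONS = {
    "exp": sympy.exp, "log": sympy.log, "sqrt": sympy.sqrt,
    "sin": sympy.sin, "cos": sympy.cos, "tan": sympy.tan,
    "Abs": sympy.Abs, "Min": sympy.Min, "Max": sympy.Max,
    "pi": sympy.pi,
    # number constructors needed by parse_expr's token transformations
    "Integer": sympy.Integer, "Float": sympy.Float, "Rational": sympy.Rational,
    "Symbol": sympy.Symbol,
}


def is_identifier(name: str) -> bool:
    """True if *name* is usable as a species/interaction/parameter name."""
    return bool(name) and bool(_IDENTIFIER_RE.match(name)) and name not in _ALLOWED_FUNCTIONS


def normalize_name(name: str) -> str:
    """Replace an ASCII Greek-letter spelling with the Greek character."""
    return GREEK_ALIASES.get(name, name)


def normalize_expression_text(text: str) -> str:
    """Normalize every identifier token in an expression string.

    Applied when reading model files so that ``kappa*N`` and ``κ*N`` denote
    the same expression.  Function names are left untouched.
    """
    def sub(match: re.Match) -> str:
        tok = match.group(0)
        return tok if tok in _ALLOWED_FUNCTIONS else normalize_name(tok)

    return _NAME_TOKEN_RE.sub(sub, text)


def parse_expression(text: str, declared: Iterable[str] = ()) -> sympy.Expr:
    """Parse an expression string into a sympy expression.

    Every name in *declared* (plus the time symbol) is bound to a plain
    symbol; any other name also becomes a free symbol, which callers may
    inspect via ``free_symbols`` to detect undeclared references.

    Raises ValueError if the text is not a well-formed expression.
    """
    local = {name: sympy.Symbol(name) for name in declared}
    local.setdefault(TIME_SYMBOL, sympy.Symbol(TIME_SYMBOL))
    try:
        expr = parse_expr(str(text), local_dict=local,
                          global_dict=dict(_ALLOWED_FUNCTIONS), evaluate=True)
    except Exception as exc:  # sympy raises SyntaxError/TokenError/TypeError...
        raise ValueError(f"cannot parse expression {text!r}: {exc}") from None
    if not isinstance(expr, sympy.Expr):
        raise ValueError(f"not a scalar expression: {text!r}")
    return expr


def undeclared_symbols(expr: sympy.Expr, declared: Iterable[str]) -> set[str]:
    """Names appearing free in *expr* that are neither declared nor time."""
    allowed = set(declared) | {TIME_SYMBOL}
    return {s.name for s in expr.free_symbols if s.name not in allowed}


def format_expression(expr: sympy.Expr | str) -> str:
    """Serialize an expression back to the storage grammar."""
    if isinstance(expr, str):
        return expr
    return sympy.sstr(expr)


def bindings_with_aliases(bindings: Mapping[str, float]) -> dict[str, float]:
    """Normalize ASCII Greek spellings in a parameter-binding mapping."""
    return {normalize_name(k): float(v) for k, v in bindings.items()}
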