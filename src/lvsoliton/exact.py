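"""Exact scalar arithmetic helpers.

All model and solution coefficients in this package are exact sympy numbers
(rationals, or algebraic numbers where a construction branch demands them).
Floating point is confined to numerical evaluation and integration.
"""

from __future__ import annotations

from fractions import Fraction
from typing import Union

import sympy as sp

#: Anything accepted as an exact scalar input.
ExactLike = Union[int, str, Fraction, sp.Expr]


def to_exact(value: ExactLike) -> sp.Expr:
    """Coerce ``value`` to an exact sympy number.

    Accepts ints, :class:`fractions.Fraction`, exact sympy expressions and
    strings of the form ``"p/q"`` (or ``"p"``).  Floats are rejected: a float
    cannot be trusted to represent the intended rational.
    """
    if isinstance(value, bool):
        raise TypeError("booleans are not exact scalars")
    if isinstance(value, float):
        raise TypeError(
            f"refusing float {value!r}: pass an exact rational such as '1/2'"
        )
    if isinstance(value, int):
        return sp.Integer(value)
    if isinstance(value, Fraction):
        return sp.Rational(value.numerator, value.denominator)
    if isinstance(value, str):
        text = value.strip()
        try:
            if "/" in text:
                num, den = text.split("/")
                return sp.Rational(int(num), int(den))
            return sp.Integer(int(text))
        except (ValueError, ZeroDivisionError) as exc:
            raise ValueError(f"not an exact rational string: {value!r}") from exc
    if isinstance(value, sp.Expr):
        if value.has(sp.Float):
            raise TypeError(f"refusing inexact expression {value!r}")
        return value
    raise TypeError(f"cannot interpret {value!r} as an exact scalar")


def format_exact(value: sp.Expr) -> str:
    """Serialize an exact rational as a bit-exact ``"p/q"`` string."""
    value = sp.nsimplify(value, rational=False) if value.has(sp.Float) else value
    if value.is_Integer:
        return str(value)
    if value.is_Rational:
        return f"{value.p}/{value.q}"
    # Non-rational exact numbers round-trip through sympy's srepr-safe str.
    return sp.srepr(value)


def parse_exact(text: str) -> sp.Expr:
    """Inverse of :func:`format_exact`."""
    if text.startswith(("Integer", "Rational", "Mul", "Add", "Pow", "CRootOf")):
        expr = sp.parse_expr(text)
        return to_exact(expr)
    return to_exact(text)


def is_real_exact(value: sp.Expr) -> bool:
    """True when sympy can certify the exact value is real."""
    return bool(value.is_real)
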