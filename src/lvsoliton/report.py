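"""Condition reports: named residuals with pass/fail status.

Every existence condition in the package is evaluated as an exact residual;
a report passes iff all residuals are exactly zero and no guard (a quantity
that must be nonzero for a formula to apply) is violated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import sympy as sp

from .exact import format_exact


@dataclass(frozen=True)
class CheckEntry:
    name: str
    residual: sp.Expr
    passed: bool

    def to_dict(self) -> dict:
        residual = self.residual
        if isinstance(residual, sp.Expr) and residual.is_number and not residual.has(sp.Float):
            text = format_exact(residual)
        else:
            text = str(residual)
        return {"name": self.name, "residual": text, "pass": self.passed}


@dataclass(frozen=True)
class ConditionReport:
    entries: Sequence[CheckEntry] = ()
    guards_violated: Sequence[str] = field(default_factory=tuple)

    @property
    def passed(self) -> bool:
        return not self.guards_violated and all(e.passed for e in self.entries)

    def residual(self, name: str) -> sp.Expr:
        for entry in self.entries:
            if entry.name == name:
                return entry.residual
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "pass": self.passed,
            "checks": [e.to_dict() for e in sorted(self.entries, key=lambda e: e.name)],
            "guards_violated": sorted(self.guards_violated),
        }


def exact_check(name: str, residual: sp.Expr) -> CheckEntry:
    """Build a check entry whose pass condition is residual == 0 exactly.

    Residuals are polynomials (in t_hat or similar) or scalars with exact
    coefficients.  Zero is decided by expansion, with reduction in the
    algebraic extension field when radical coefficients survive expansion;
    heavyweight general simplification is deliberately avoided.
    """
    residual = sp.sympify(residual)
    value, passed = _reduce_residual(residual)
    return CheckEntry(name=name, residual=value, passed=passed)


def _reduce_residual(expr: sp.Expr):
    expr = sp.expand(sp.cancel(expr)) if not expr.is_number else expr
    if expr == 0:
        return sp.Integer(0), True
    symbols = sorted(expr.free_symbols, key=str)
    try:
        if symbols:
            poly = sp.Poly(expr, *symbols, extension=True)
            if poly.is_zero:
                return sp.Integer(0), True
            return poly.as_expr(), False
        reduced = sp.radsimp(expr)
        if reduced == 0 or reduced.is_zero:
            return sp.Integer(0), True
        return reduced, False
    except Exception:  # algebraic reduction failed; report as-is, not passed
        return expr, False
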