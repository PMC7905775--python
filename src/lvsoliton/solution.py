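"""Solitary-solution representation as ratios of monic polynomials.

An order-``n`` solitary solution component has the closed form

    x(t) = sigma * X(t_hat) / T(t_hat),      t_hat = exp(eta * (t - t0)),

where ``X`` and ``T`` are monic degree-``n`` polynomials sharing the
denominator ``T`` across all four components of a solution set.  The
component is stored coefficient-first: the denominator coefficients ``ae_k``
and the per-component numerator/denominator coefficient ratios ``r_k`` (the
``p_k`` ratios for the x-components, ``h_k`` for the y-components), so that
the numerator coefficient of ``t_hat**k`` is ``r_k * ae_k``.  Roots are
derived views: all existence conditions act on coefficients, and roots may
be complex while the coefficients stay real.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import sympy as sp

from .exact import ExactLike, format_exact, parse_exact, to_exact

__all__ = [
    "SolitaryComponent",
    "SolitarySolutionSet",
    "transform_time",
    "assemble_component",
    "evaluate_solution",
    "roots_from_coeffs",
    "PoleError",
]

_that = sp.Symbol("that", positive=True)


class PoleError(ZeroDivisionError):
    """Raised when a solution is evaluated at a pole of its denominator."""

    def __init__(self, t):
        super().__init__(f"denominator T(t_hat) vanishes at t = {t}")
        self.t = t


def transform_time(t, eta: ExactLike, t0: ExactLike):
    """The substitution ``t_hat = exp(eta * (t - t0))``.

    Exact sympy input yields an exact expression; float input yields a float.
    Strictly positive, and monotone increasing in ``t`` for ``eta > 0``.
    """
    eta = to_exact(eta)
    t0 = to_exact(t0)
    if isinstance(t, (int,)) or isinstance(t, sp.Expr):
        return sp.exp(eta * (sp.sympify(t) - t0))
    return math.exp(float(eta) * (t - float(t0)))


@dataclass(frozen=True)
class SolitaryComponent:
    """One component ``sigma * N(t_hat) / T(t_hat)`` of a solitary solution.

    ``ratios[k]`` multiplies ``aes[k]`` to give the numerator coefficient of
    ``t_hat**k``; both polynomials are monic of degree ``order``.
    """

    sigma: sp.Expr
    ratios: tuple
    aes: tuple

    def __post_init__(self):
        object.__setattr__(self, "sigma", to_exact(self.sigma))
        object.__setattr__(self, "ratios", tuple(to_exact(r) for r in self.ratios))
        object.__setattr__(self, "aes", tuple(to_exact(a) for a in self.aes))
        if len(self.ratios) != len(self.aes):
            raise ValueError("ratios and aes must have equal length n")
        if not self.aes:
            raise ValueError("order n = 0 is not a solitary solution")

    @property
    def order(self) -> int:
        return len(self.aes)

    def numerator_coeffs(self) -> tuple:
        """Ascending coefficients of the monic numerator (degree n last)."""
        return tuple(r * a for r, a in zip(self.ratios, self.aes)) + (sp.Integer(1),)

    def denominator_coeffs(self) -> tuple:
        return self.aes + (sp.Integer(1),)

    def numerator_poly(self, symbol: sp.Symbol = _that) -> sp.Poly:
        return sp.Poly(list(reversed(self.numerator_coeffs())), symbol)

    def denominator_poly(self, symbol: sp.Symbol = _that) -> sp.Poly:
        return sp.Poly(list(reversed(self.denominator_coeffs())), symbol)

    def expression(self, symbol: sp.Symbol = _that) -> sp.Expr:
        return self.sigma * self.numerator_poly(symbol).as_expr() / self.denominator_poly(symbol).as_expr()

    def evaluate_that(self, that: float) -> float:
        num = np.polyval([float(c) for c in reversed(self.numerator_coeffs())], that)
        den = np.polyval([float(c) for c in reversed(self.denominator_coeffs())], that)
        if den == 0.0:
            raise ZeroDivisionError("pole of T(t_hat)")
        return float(self.sigma) * num / den


def assemble_component(sigma: ExactLike, ratios: Sequence[ExactLike], aes: Sequence[ExactLike],
                       allow_degenerate: bool = False) -> SolitaryComponent:
    """Build a component from amplitude, coefficient ratios and shared ae's.

    Rejects the all-zero ``aes`` choice (it collapses numerator and
    denominator to ``t_hat**n`` and the component to the constant ``sigma``)
    unless ``allow_degenerate`` is set.
    """
    component = SolitaryComponent(sigma=to_exact(sigma),
                                  ratios=tuple(to_exact(r) for r in ratios),
                                  aes=tuple(to_exact(a) for a in aes))
    if not allow_degenerate and all(a == 0 for a in component.aes):
        raise ValueError("all ae_k are zero: component degenerates to the constant sigma")
    return component


@dataclass(frozen=True)
class SolitarySolutionSet:
    """Four solitary components (x1, y1, x2, y2) with one shared denominator.

    ``eta`` (a rate, units 1/time) and the time shift ``t0`` fix the
    substitution ``t_hat = exp(eta (t - t0))`` common to all components.
    """

    n: int
    eta: sp.Expr
    t0: sp.Expr
    x1: SolitaryComponent
    y1: SolitaryComponent
    x2: SolitaryComponent
    y2: SolitaryComponent

    def __post_init__(self):
        object.__setattr__(self, "eta", to_exact(self.eta))
        object.__setattr__(self, "t0", to_exact(self.t0))
        if self.eta == 0:
            raise ValueError("eta must be nonzero")
        comps = self.components()
        if any(c.order != self.n for c in comps.values()):
            raise ValueError("all components must have order n")
        aes = comps["x1"].aes
        if any(c.aes != aes for c in comps.values()):
            raise ValueError("components must share one denominator (identical aes)")

    def components(self) -> dict:
        return {"x1": self.x1, "y1": self.y1, "x2": self.x2, "y2": self.y2}

    @property
    def aes(self) -> tuple:
        return self.x1.aes

    @property
    def sigmas(self) -> dict:
        return {name: c.sigma for name, c in self.components().items()}

    def denominator_poly(self, symbol: sp.Symbol = _that) -> sp.Poly:
        return self.x1.denominator_poly(symbol)

    def real_positive_poles(self) -> list:
        """Real positive roots of T(t_hat), mapped back to t."""
        eta, t0 = float(self.eta), float(self.t0)
        poles = []
        for root in sp.Poly(self.denominator_poly(), _that).nroots():
            if abs(sp.im(root)) < 1e-12 and sp.re(root) > 0:
                poles.append(math.log(float(sp.re(root))) / eta + t0)
        return sorted(poles)

    def to_dict(self) -> dict:
        comps = self.components()
        return {
            "n": self.n,
            "eta": format_exact(self.eta),
            "t0": format_exact(self.t0),
            "sigma": {k: format_exact(c.sigma) for k, c in comps.items()},
            "aes": [format_exact(a) for a in self.aes],
            "ratios": {k: [format_exact(r) for r in c.ratios] for k, c in comps.items()},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "SolitarySolutionSet":
        aes = [parse_exact(a) for a in data["aes"]]
        comps = {
            name: SolitaryComponent(
                sigma=parse_exact(data["sigma"][name]),
                ratios=tuple(parse_exact(r) for r in data["ratios"][name]),
                aes=tuple(aes),
            )
            for name in ("x1", "y1", "x2", "y2")
        }
        return cls(n=int(data["n"]), eta=parse_exact(data["eta"]),
                   t0=parse_exact(data["t0"]), **comps)


def evaluate_solution(sol: SolitarySolutionSet, t: float) -> tuple:
    """Evaluate all four components at real time ``t``.

    Raises :class:`PoleError` when ``t`` hits a zero of the shared
    denominator.  As ``t -> +inf`` (eta > 0) each component tends to its
    amplitude sigma; as ``t -> -inf`` it tends to ``sigma * ratios[0]``
    when ``aes[0] != 0``.
    """
    that = transform_time(float(t), sol.eta, sol.t0)
    den = np.polyval([float(c) for c in reversed(sol.x1.denominator_coeffs())], that)
    if den == 0.0 or not np.isfinite(den):
        raise PoleError(t)
    values = []
    for name in ("x1", "y1", "x2", "y2"):
        comp = sol.components()[name]
        num = np.polyval([float(c) for c in reversed(comp.numerator_coeffs())], that)
        values.append(float(comp.sigma) * num / den)
    return tuple(values)


def roots_from_coeffs(component: SolitaryComponent) -> tuple:
    """Numerator and denominator root multisets (exact where possible).

    The product over ``(theta - root)`` reproduces the stored monic
    coefficients; for rational-rooted polynomials the round trip is exact.
    """
    def _roots(poly: sp.Poly) -> list:
        found = sp.roots(poly, _that)
        n_found = sum(found.values())
        if n_found == poly.degree():
            out = []
            for root, mult in found.items():
                out.extend([root] * mult)
            return sorted(out, key=lambda r: (sp.re(r), sp.im(r)))
        return sorted(poly.nroots(), key=lambda r: (sp.re(r), sp.im(r)))

    return _roots(component.numerator_poly()), _roots(component.denominator_poly())
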