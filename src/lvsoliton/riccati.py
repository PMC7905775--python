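"""Base-case solvers: single Riccati kinks and the multiplicatively
coupled Riccati pair.

The scalar Riccati equation x' = c0 + c1 x + c2 x**2 with two distinct real
equilibria admits the kink solitary solution

    x(t) = sigma * (exp(eta t) - s x0) / (exp(eta t) - s t0),

a monotone transition between the equilibria, with eta**2 = c1**2 - 4 c0 c2.
Two Riccati equations coupled through multiplicative terms x*y admit
dark/bright (order-2) solitary solutions only under exact polynomial
conditions on the coefficients; this module evaluates those conditions and
validates user-supplied solutions.  The full constructive recipe for the
pair's dark/bright solutions from arbitrary admissible coefficients is out
of scope here: the pair machinery checks, it does not build.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import sympy as sp

from .exact import ExactLike, to_exact
from .report import CheckEntry, ConditionReport, exact_check

__all__ = [
    "RiccatiEquation",
    "KinkSolution",
    "CoupledPairSystem",
    "riccati_eta",
    "kink_coeffs",
    "kink_from_coeffs",
    "pair_existence_check",
    "pair_eta",
    "pair_root_constraints",
    "inverse_relation_check",
]


@dataclass(frozen=True)
class RiccatiEquation:
    """x' = c0 + c1 x + c2 x**2 with exact coefficients, c2 != 0."""

    c0: sp.Expr
    c1: sp.Expr
    c2: sp.Expr

    def __post_init__(self):
        for name in ("c0", "c1", "c2"):
            object.__setattr__(self, name, to_exact(getattr(self, name)))
        if self.c2 == 0:
            raise ValueError("c2 must be nonzero for a Riccati equation")

    def rhs(self, x: sp.Expr) -> sp.Expr:
        return self.c0 + self.c1 * x + self.c2 * x**2

    def equilibria(self) -> tuple:
        """Roots of the right-hand side (the t -> +-inf kink limits)."""
        x = sp.Symbol("x")
        return tuple(sp.roots(sp.Poly(self.rhs(x), x), x, multiple=True))


@dataclass(frozen=True)
class KinkSolution:
    """Kink parameters: x = sigma (t_hat - s x0) / (t_hat - s t0).

    ``x0_root`` and ``t0_root`` are the numerator/denominator root scales
    (distinct), ``s`` the free constant fixed by an initial condition.  The
    derived coefficient ae0 = s * t0_root is the constant denominator term.
    """

    sigma: sp.Expr
    x0_root: sp.Expr
    t0_root: sp.Expr
    s: sp.Expr
    eta: sp.Expr

    def __post_init__(self):
        for name in ("sigma", "x0_root", "t0_root", "s", "eta"):
            object.__setattr__(self, name, to_exact(getattr(self, name)))
        if self.x0_root == self.t0_root:
            raise ValueError("x0_root and t0_root must be distinct")

    @property
    def ae0(self) -> sp.Expr:
        return self.s * self.t0_root

    def expression(self, t: sp.Symbol) -> sp.Expr:
        that = sp.exp(self.eta * t)
        return self.sigma * (that - self.s * self.x0_root) / (that - self.s * self.t0_root)

    def limits(self) -> tuple:
        """(t -> -inf, t -> +inf) limits for eta > 0: (sigma x0/t0, sigma)."""
        if self.s == 0:
            return (self.sigma, self.sigma)
        return (self.sigma * self.x0_root / self.t0_root, self.sigma)

    def pole_time(self) -> Optional[sp.Expr]:
        """Time of the finite pole, or None when s*t0_root <= 0."""
        st0 = self.s * self.t0_root
        if st0.is_positive:
            return sp.log(st0) / self.eta
        return None


def riccati_eta(eq: RiccatiEquation) -> tuple:
    """Principal eta with eta**2 = c1**2 - 4 c0 c2.

    Returns ``(eta, is_real)``; a negative discriminant flags a complex eta
    (no real kink) rather than raising.
    """
    disc = eq.c1**2 - 4 * eq.c0 * eq.c2
    eta = sp.sqrt(disc)
    return eta, bool(disc.is_nonnegative)


def kink_coeffs(sol: KinkSolution) -> RiccatiEquation:
    """Riccati coefficients generated by kink parameters.

    The returned coefficients satisfy c1**2 - 4 c0 c2 = eta**2 identically.
    """
    if sol.sigma == 0:
        raise ValueError("sigma = 0: degenerate amplitude, c2 undefined")
    x0, t0, sigma, eta = sol.x0_root, sol.t0_root, sol.sigma, sol.eta
    c0 = sigma * x0 * eta / (x0 - t0)
    c1 = (t0 + x0) * eta / (t0 - x0)
    c2 = t0 * eta / (sigma * (x0 - t0))
    return RiccatiEquation(c0=c0, c1=c1, c2=c2)


def kink_from_coeffs(eq: RiccatiEquation, x_init: ExactLike, t_init=0) -> KinkSolution:
    """Kink solution of ``eq`` passing through ``(t_init, x_init)``.

    Requires a positive discriminant (two distinct real equilibria).  The
    two equilibria are the t -> +-inf limits; for eta > 0 the limit reached
    as t -> +infinity is the dynamically stable one, which fixes sigma.
    An initial value at an equilibrium returns the constant solution
    (s = 0); an initial value outside the equilibrium interval produces a
    valid solution with a finite-time pole (see ``pole_time``).
    """
    eta, real = riccati_eta(eq)
    if not real or eta == 0:
        raise ValueError("complex or zero eta: no kink solitary solution")
    x_init = to_exact(x_init)
    # Stable root as t -> +inf (RHS slope -eta there), unstable root is the
    # t -> -inf limit sigma * x0/t0.
    sigma = (-eq.c1 - eta) / (2 * eq.c2)
    other = (-eq.c1 + eta) / (2 * eq.c2)
    t0_root = sp.Integer(1)
    x0_root = sp.simplify(other / sigma)
    if x0_root == t0_root:  # pragma: no cover - excluded by eta != 0
        raise ValueError("degenerate equilibria")
    if x_init == sigma:
        s = sp.Integer(0)
    else:
        t_init = sp.sympify(t_init) if not isinstance(t_init, sp.Expr) else t_init
        that0 = sp.exp(eta * t_init)
        s = sp.simplify(that0 * (x_init - sigma) / (x_init * t0_root - sigma * x0_root))
    return KinkSolution(sigma=sigma, x0_root=x0_root, t0_root=t0_root, s=s, eta=eta)


@dataclass(frozen=True)
class CoupledPairSystem:
    """x' = a0 + a1 x + a2 x^2 + a3 x y;  y' = b0 + b1 y + b2 y^2 + b3 x y."""

    a0: sp.Expr
    a1: sp.Expr
    a2: sp.Expr
    a3: sp.Expr
    b0: sp.Expr
    b1: sp.Expr
    b2: sp.Expr
    b3: sp.Expr

    def __post_init__(self):
        for name in ("a0", "a1", "a2", "a3", "b0", "b1", "b2", "b3"):
            object.__setattr__(self, name, to_exact(getattr(self, name)))


def pair_existence_check(sys: CoupledPairSystem) -> ConditionReport:
    """Exact dark/bright existence conditions for the coupled pair.

    Checks the two coupling symmetries a3 = b2, a2 = b3 and the degree-3
    coefficient identity; passes iff all three residuals vanish exactly.
    """
    cubic = (9 * sys.a0 * sys.a1 * sys.a2 + 9 * sys.b0 * sys.b1 * sys.b2
             - 18 * sys.a0 * sys.a2 * sys.b1 - 18 * sys.b0 * sys.b2 * sys.a1
             + 3 * sys.a1 * sys.b1**2 + 3 * sys.b1 * sys.a1**2
             - 2 * sys.a1**3 - 2 * sys.b1**3)
    return ConditionReport(entries=(
        exact_check("a3_minus_b2", sys.a3 - sys.b2),
        exact_check("a2_minus_b3", sys.a2 - sys.b3),
        exact_check("cubic_identity", cubic),
    ))


def pair_eta(sys: CoupledPairSystem) -> sp.Expr:
    """Exact rate parameter of the pair's dark/bright solutions."""
    return sp.cancel((sys.a1**2 - sys.a1 * sys.b1 + sys.b1**2) / 3
                        - sys.a0 * sys.a2 - sys.b0 * sys.b2)


def pair_root_constraints(xbar: Sequence[ExactLike], ybar: Sequence[ExactLike],
                          tbar: Sequence[ExactLike]) -> ConditionReport:
    """Root cross-ratio conditions tying dark/bright roots to shared poles.

    For each of x and y the products of root-minus-pole differences must
    equal minus the ratio of the two roots.
    """
    x1, x2 = (to_exact(v) for v in xbar)
    y1, y2 = (to_exact(v) for v in ybar)
    t1, t2 = (to_exact(v) for v in tbar)
    guards = []
    for name, value in (("xbar2", x2), ("ybar2", y2)):
        if value == 0:
            guards.append(f"{name} must be nonzero")
    for name, value in (("xbar2", x2), ("ybar2", y2)):
        if value in (t1, t2):
            guards.append(f"{name} coincides with a pole root")
    if guards:
        return ConditionReport(entries=(), guards_violated=tuple(guards))
    entries = []
    for name, r1, r2 in (("x_root_ratio", x1, x2), ("y_root_ratio", y1, y2)):
        lhs = (r1 - t1) * (r1 - t2) / ((r2 - t1) * (r2 - t2))
        entries.append(exact_check(name, sp.cancel(lhs + r1 / r2)))
    return ConditionReport(entries=tuple(entries))


def inverse_relation_check(x_expr: sp.Expr, y_expr: sp.Expr,
                           symbol: Optional[sp.Symbol] = None):
    """Test whether x*y is a constant Omega (the pair-uncoupling relation).

    Symbolic inputs are rational functions of one symbol; returns the exact
    Omega when the product is constant, else None.
    """
    product = sp.cancel(sp.together(x_expr * y_expr))
    free = product.free_symbols if symbol is None else {symbol} & product.free_symbols
    if not free:
        return product
    simplified = sp.simplify(product)
    if not (simplified.free_symbols if symbol is None else {symbol} & simplified.free_symbols):
        return simplified
    return None
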