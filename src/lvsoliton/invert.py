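"""Inverse direction: recover solitary-solution parameters from a given
meta-model system.

The t -> +infinity limits of an order-n solitary solution are the
amplitudes sigma, and the leading-order existence conditions say exactly
that the amplitude vector is an equilibrium of the system.  Once an
equilibrium branch is fixed, every auxiliary parameter (A, L, N, K) is an
explicit rational function of the rate eta alone, and the remaining
coupling conditions reduce to univariate polynomial equations in eta.  The
solver therefore: (1) enumerates admissible equilibria (or takes them from
a user gauge), (2) intersects the exact eta roots of the coupling
conditions, and (3) keeps the branches that reproduce the input system
bit-exactly through the forward assembly map.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import sympy as sp

from .construct import (AuxiliaryParams, MetaModelSystem, assemble_system,
                        default_zero_aes, required_zero_aes)
from .exact import ExactLike, to_exact
from .report import ConditionReport, exact_check
from .solution import SolitaryComponent, SolitarySolutionSet

__all__ = [
    "RecoveredBranch",
    "check_coeff_constraints",
    "recover_parameters",
    "recover_solution",
]

_L = (1, 2)


@dataclass(frozen=True)
class RecoveredBranch:
    """One admissible (auxiliaries, amplitudes, eta) assignment."""

    aux: AuxiliaryParams
    sigmas: dict
    eta: sp.Expr

    def to_dict(self) -> dict:
        from .exact import format_exact
        return {
            "eta": format_exact(self.eta),
            "sigma": {k: format_exact(v) for k, v in self.sigmas.items()},
            "aux": self.aux.to_dict(),
        }


def check_coeff_constraints(sys: MetaModelSystem) -> ConditionReport:
    """Coefficient symmetries required for order n >= 2 solutions.

    The unique L = N triple forces a2l = mu_l and b2l = lambda_l; a
    decoupled system (some gamma_l = 0) is flagged and should be analysed
    as two independent Riccati pairs instead.
    """
    entries = []
    guards = []
    for l in _L:
        i = l - 1
        entries.append(exact_check(f"a2_minus_mu_l{l}", sys.a2[i] - sys.mu[i]))
        entries.append(exact_check(f"b2_minus_lambda_l{l}", sys.b2[i] - sys.lam[i]))
        if sys.gam[i] == 0:
            guards.append(f"decoupled: gamma_{l} = 0 (analyse as Riccati pairs)")
    return ConditionReport(entries=tuple(entries), guards_violated=tuple(guards))


def _equilibrium_equations(sys: MetaModelSystem, s1, s2, n: int):
    """Leading-order conditions: (s1, s2) is an equilibrium of the system.

    For n = 1 the L and N triples are independent, so both the (mu, b2)
    and the (a2, lambda) forms of the x-equation condition apply.
    """
    eqs = []
    for l, r in ((1, 2), (2, 1)):
        i = l - 1
        eqs.append(sys.a0[i] + sys.a1[i] * s1[l] + sys.a2[i] * s1[l] ** 2
                   + sys.lam[i] * s1[l] * s2[l])
        if n >= 2:
            # Equivalent to the line above under a2 = mu, b2 = lambda; kept
            # as the L-side form actually used by the conditions.
            eqs.append(sys.a0[i] + sys.a1[i] * s1[l] + sys.mu[i] * s1[l] ** 2
                       + sys.b2[i] * s1[l] * s2[l])
        eqs.append(sys.b0[i] + sys.b1[i] * s2[l] + sys.b2[i] * s2[l] ** 2
                   + sys.mu[i] * s1[l] * s2[l] + sys.gam[i] * (s2[r] - s2[l]))
    return eqs


def _sigma_branches(sys: MetaModelSystem, n: int, gauge: Mapping[str, ExactLike]):
    """Admissible amplitude vectors: nonzero real equilibria."""
    symbols = {}
    s1, s2 = {}, {}
    for l in _L:
        for comp, store in ((f"x{l}", s1), (f"y{l}", s2)):
            if comp in gauge:
                store[l] = to_exact(gauge[comp])
            else:
                symbol = sp.Symbol(f"sigma_{comp}")
                symbols[comp] = symbol
                store[l] = symbol
    eqs = [sp.expand(e) for e in _equilibrium_equations(sys, s1, s2, n)]
    if not symbols:
        if all(sp.cancel(e) == 0 for e in eqs):
            return [{f"x{l}": s1[l] for l in _L} | {f"y{l}": s2[l] for l in _L}]
        return []
    if set(symbols) == {"x1", "y1", "x2", "y2"}:
        raw = _equilibria_full(sys, n)
    else:
        try:
            raw = sp.solve(eqs, list(symbols.values()), dict=True)
        except NotImplementedError:
            raw = []
        raw = [{comp: candidate.get(symbol)
                for comp, symbol in symbols.items()}
               for candidate in raw if len(candidate) == len(symbols)]
    branches = []
    for candidate in raw:
        values = {}
        ok = True
        for comp in ("x1", "y1", "x2", "y2"):
            if comp in symbols:
                value = candidate.get(comp)
            else:
                value = (s1 if comp.startswith("x") else s2)[int(comp[1])]
            if value is None:
                ok = False
                break
            value = sp.cancel(value)
            if value == 0 or value.is_real is not True or value.free_symbols:
                ok = False
                break
            values[comp] = value
        if ok and all(sp.cancel(e.subs([(symbols[c], values[c]) for c in symbols])) == 0
                      for e in eqs):
            branches.append(values)
    unique = []
    for values in branches:
        if values not in unique:
            unique.append(values)
    unique.sort(key=lambda b: tuple(str(b[k]) for k in ("x1", "y1", "x2", "y2")))
    return unique


def _equilibria_full(sys: MetaModelSystem, n: int) -> list:
    """Enumerate equilibria by elimination.

    Each x-equation condition is linear in sigma_2l, so sigma_2l is
    substituted out; the two y-equation conditions leave two polynomials in
    (sigma_11, sigma_12), reduced by a resultant.  Roots of irreducible
    resultant factors of degree > 2 are not enumerated (they lie in high
    algebraic extensions); pin them through the gauge if needed.
    """
    u1, u2 = sp.symbols("sig_x1 sig_x2")
    u = {1: u1, 2: u2}
    s2 = {}
    for l in _L:
        i = l - 1
        if sys.lam[i] == 0:
            return []
        s2[l] = -(sys.a0[i] + sys.a1[i] * u[l] + sys.a2[i] * u[l] ** 2) / (sys.lam[i] * u[l])
    polys = []
    for l, r in ((1, 2), (2, 1)):
        i = l - 1
        expr = (sys.b0[i] + sys.b1[i] * s2[l] + sys.b2[i] * s2[l] ** 2
                + sys.mu[i] * u[l] * s2[l] + sys.gam[i] * (s2[r] - s2[l]))
        polys.append(sp.Poly(sp.numer(sp.together(expr)), u1, u2))
    resultant = sp.Poly(sp.resultant(polys[0], polys[1], u2), u1)
    if resultant.is_zero:
        return []
    candidates_x1 = _roots_upto_quadratic(resultant)
    out = []
    for x1 in candidates_x1:
        if x1 == 0:
            continue
        p1 = sp.Poly(sp.cancel(polys[0].as_expr().subs(u1, x1)), u2)
        p2 = sp.Poly(sp.cancel(polys[1].as_expr().subs(u1, x1)), u2)
        common = sp.gcd(p1, p2)
        if common.degree() < 1:
            continue
        for x2 in _roots_upto_quadratic(common):
            if x2 == 0:
                continue
            values = {"x1": x1, "x2": x2}
            skip = False
            for l in _L:
                y = sp.cancel(s2[l].subs({u1: x1, u2: x2}))
                if y == 0 or y.is_real is not True:
                    skip = True
                    break
                values[f"y{l}"] = y
            if not skip:
                out.append(values)
    return out


def _roots_upto_quadratic(poly: sp.Poly) -> list:
    """Exact real roots from the factors of degree <= 2 of ``poly``."""
    roots = []
    _, factors = sp.factor_list(poly)
    for factor, _mult in factors:
        factor = sp.Poly(factor, *poly.gens)
        if factor.degree() > 2:
            continue
        for root in sp.roots(factor, poly.gens[0], multiple=True):
            if root.is_real:
                roots.append(root)
    return roots


def _aux_of_eta(sys: MetaModelSystem, sigmas: Mapping[str, sp.Expr], n: int,
                eta: sp.Expr) -> dict:
    """All auxiliaries as expressions in (a possibly symbolic) eta."""
    s1 = {l: sigmas[f"x{l}"] for l in _L}
    s2 = {l: sigmas[f"y{l}"] for l in _L}
    out = {}
    for l, r in ((1, 2), (2, 1)):
        i = l - 1
        A2 = -eta * s1[l] / sys.a0[i]
        A1 = -1 - n * A2
        N1 = (sys.a1[i] + sys.a0[i] / s1[l] - n * eta) / eta
        if n >= 2:
            L1 = N1
        else:
            # Order 1: beta is fixed by the leading L-equation instead.
            L1 = -n - (sys.mu[i] * s1[l] + sys.b2[i] * s2[l]) / eta
        out[l] = {
            "A1": A1, "A2": A2,
            "L1": L1, "L2": sys.mu[i] * s1[l] / eta, "L3": sys.b2[i] * s2[l] / eta,
            "N1": N1, "N2": sys.a2[i] * s1[l] / eta, "N3": sys.lam[i] * s2[l] / eta,
            "K1": (sys.b1[i] - sys.gam[i] - eta * L1) * s2[l] / (sys.gam[i] * s2[r]),
            "K2": sys.b0[i] / (sys.gam[i] * s2[r]),
            "K3": -eta * s2[l] / (sys.gam[i] * s2[r]),
        }
    return out


def _eta_conditions(sys: MetaModelSystem, aux, n: int, active: Sequence[int]):
    """Coupling conditions as rational expressions in symbolic eta.

    h_kl is defined by the L-side linear conditions; the K-side conditions
    at every active index k then pin eta.
    """
    h = {}
    p = {}
    conditions = []
    for l in _L:
        a = aux[l]
        for k in active:
            p[(k, l)] = 1 / (1 + (n - k) * a["A2"])
            if n >= 2:
                h[(k, l)] = -(k + a["L1"] + a["L2"] * p[(k, l)]) / a["L3"]
            else:
                h[(k, l)] = -(a["N1"] + a["N2"] * p[(k, l)]) / a["N3"]
    for l, r in ((1, 2), (2, 1)):
        a = aux[l]
        for k in active:
            conditions.append(h[(k, r)] + a["K1"] * h[(k, l)] + a["K2"]
                              + a["K3"] * k * h[(k, l)])
        if n == 1:
            # The L-form of the k = 0 condition must agree with the N-form
            # used to define h_0l.
            conditions.append(a["L1"] + a["L2"] * p[(0, l)] + a["L3"] * h[(0, l)])
    return conditions


def recover_parameters(sys: MetaModelSystem, n: int,
                       gauge: Optional[Mapping[str, ExactLike]] = None,
                       zero_aes: Optional[Iterable[int]] = None) -> list:
    """All real (aux, sigma, eta) branches admitting an order-n solution.

    ``gauge`` may pin any of the amplitudes (keys ``x1``, ``y1``, ``x2``,
    ``y2``) and/or ``eta`` to select among branches.  An empty list means
    the system admits no order-n solitary solution under the given gauge
    and zero pattern.  Every returned branch reproduces ``sys`` exactly
    through the forward assembly map.
    """
    gauge = dict(gauge or {})
    if n < 1:
        raise ValueError("order n must be >= 1")
    if any(a == 0 for a in sys.a0):
        raise ValueError("a0l = 0: the A-parametrisation requires a0l nonzero")
    if sys.decoupled:
        return []
    if n >= 2 and not check_coeff_constraints(sys).passed:
        return []
    zero = set(default_zero_aes(n) if zero_aes is None else zero_aes)
    if len(zero) < required_zero_aes(n):
        return []
    active = [k for k in range(n) if k not in zero]
    eta_sym = sp.Symbol("eta_recover")
    branches = []
    for sigmas in _sigma_branches(sys, n, gauge):
        aux_expr = _aux_of_eta(sys, sigmas, n, eta_sym)
        conditions = _eta_conditions(sys, aux_expr, n, active)
        numerators = [sp.numer(sp.together(sp.cancel(c))) for c in conditions]
        if "eta" in gauge:
            eta_candidates = [to_exact(gauge["eta"])]
        else:
            pivot = next((num for num in numerators
                          if num.has(eta_sym)), None)
            if pivot is None:
                # eta not pinned by any condition: only constant conditions.
                if all(sp.cancel(num) == 0 for num in numerators):
                    continue  # underdetermined family; nothing exact to report
                continue
            try:
                eta_candidates = sp.solve(pivot, eta_sym)
            except NotImplementedError:
                continue
        for eta in eta_candidates:
            eta = sp.cancel(eta)
            if eta == 0 or eta.is_real is not True:
                continue
            if not all(sp.cancel(c.subs(eta_sym, eta)) == 0 for c in conditions):
                continue
            values = {l: {key: sp.cancel(expr.subs(eta_sym, eta))
                          for key, expr in aux_expr[l].items()} for l in _L}
            if any(v.has(sp.zoo, sp.nan) for row in values.values() for v in row.values()):
                continue
            aux = AuxiliaryParams(
                **{key: (values[1][key], values[2][key])
                   for key in ("A1", "A2", "L1", "L2", "L3",
                               "N1", "N2", "N3", "K1", "K2", "K3")})
            rebuilt = assemble_system(aux, sigmas, eta)
            if _systems_equal(rebuilt, sys):
                branches.append(RecoveredBranch(aux=aux, sigmas=dict(sigmas), eta=eta))
    branches.sort(key=lambda b: (str(b.eta),) + tuple(
        str(b.sigmas[k]) for k in ("x1", "y1", "x2", "y2")))
    return branches


def _systems_equal(a: MetaModelSystem, b: MetaModelSystem) -> bool:
    for name in ("a0", "a1", "a2", "lam", "b0", "b1", "b2", "mu", "gam"):
        for i in (0, 1):
            if sp.cancel(getattr(a, name)[i] - getattr(b, name)[i]) != 0:
                return False
    return True


def recover_solution(sys: MetaModelSystem, n: int, branch: RecoveredBranch,
                     aes: Sequence[ExactLike], t0: ExactLike = 0) -> SolitarySolutionSet:
    """Solitary solution of ``sys`` for a recovered branch and chosen ae's.

    The ae's at zeroed indices (per the order dichotomy) must vanish; an
    ae_0 = 0 choice is valid but divides a common factor t_hat out of all
    numerators and the denominator, reducing the effective order — a
    warning is emitted.  The result is residual-verified against ``sys``;
    a violated condition raises with its name.
    """
    from .verify import ode_residual  # local import to avoid a cycle

    aes = tuple(to_exact(a) for a in aes)
    if len(aes) != n:
        raise ValueError("aes must have length n")
    zero_needed = required_zero_aes(n)
    if sum(1 for a in aes[2:] if a == 0) < zero_needed:
        raise ValueError(f"order {n} requires {zero_needed} zero ae's at indices >= 2")
    aux, eta = branch.aux, branch.eta
    p, h = {}, {}
    for l in _L:
        i = l - 1
        for k in range(n):
            if aes[k] == 0:
                p[(k, l)] = sp.Integer(0)
                h[(k, l)] = sp.Integer(0)
                continue
            p[(k, l)] = sp.cancel(1 / (1 + (n - k) * aux.A2[i]))
            if n >= 2:
                h[(k, l)] = sp.cancel(
                    -(k + aux.L1[i] + aux.L2[i] * p[(k, l)]) / aux.L3[i])
            else:
                h[(k, l)] = sp.cancel(
                    -(aux.N1[i] + aux.N2[i] * p[(k, l)]) / aux.N3[i])
    if aes[0] == 0:
        warnings.warn("ae_0 = 0: common factor t_hat reduces the effective order",
                      stacklevel=2)
    components = {}
    for l in _L:
        components[f"x{l}"] = SolitaryComponent(
            sigma=branch.sigmas[f"x{l}"],
            ratios=tuple(p[(k, l)] for k in range(n)), aes=aes)
        components[f"y{l}"] = SolitaryComponent(
            sigma=branch.sigmas[f"y{l}"],
            ratios=tuple(h[(k, l)] for k in range(n)), aes=aes)
    sol = SolitarySolutionSet(n=n, eta=eta, t0=to_exact(t0), **components)
    report = ode_residual(sys, sol)
    if not report.passed:
        failed = [e.name for e in report.entries if not e.passed]
        raise ValueError(f"recovered solution violates conditions: {', '.join(failed)}")
    return sol
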