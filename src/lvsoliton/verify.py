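"""Symbolic and numeric oracles for (system, solution) pairs, and a seeded
generator of random valid instances.

Two independent exact checks are provided.  ``residual_identities`` expands
the eight polynomial identities (two necessary and two sufficient per
subsystem) that characterise solitary solutions of the meta-model;
``ode_residual`` substitutes the closed-form solution into the four ODEs
directly and reduces the residual rational functions to canonical form.
The two oracles agree by construction of the theory; the test suite
exercises that equivalence on random fixtures.  Numerical integration is a
redundancy check only — exact algebra is the acceptance authority.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import sympy as sp
from scipy.integrate import solve_ivp

from .construct import (AuxiliaryParams, MetaModelSystem, assemble_full,
                        assemble_system, default_zero_aes,
                        solve_free_constraints)
from .report import ConditionReport, exact_check
from .solution import SolitarySolutionSet, evaluate_solution

__all__ = [
    "VerificationResult",
    "residual_identities",
    "ode_residual",
    "integrate_and_compare",
    "generate_fixture",
    "FixtureRanges",
]

_u = sp.Symbol("that", positive=True)


@dataclass(frozen=True)
class VerificationResult:
    identity_report: ConditionReport
    ode_report: ConditionReport
    numeric_max_residual: Optional[float]
    pole_locations: tuple

    @property
    def passed(self) -> bool:
        return self.identity_report.passed and self.ode_report.passed

    def to_dict(self) -> dict:
        return {
            "pass": self.passed,
            "identities": self.identity_report.to_dict(),
            "ode_residuals": self.ode_report.to_dict(),
            "numeric_max_residual": self.numeric_max_residual,
            "pole_locations": list(self.pole_locations),
        }


def _polys(sol: SolitarySolutionSet):
    comps = sol.components()
    X = {l: comps[f"x{l}"].numerator_poly(_u).as_expr() for l in (1, 2)}
    Y = {l: comps[f"y{l}"].numerator_poly(_u).as_expr() for l in (1, 2)}
    T = sol.denominator_poly(_u).as_expr()
    return X, Y, T


def residual_identities(aux: AuxiliaryParams, sol: SolitarySolutionSet,
                        sys: Optional[MetaModelSystem] = None) -> ConditionReport:
    """Expand the eight existence identities to canonical polynomial form.

    Passes iff every identity is the zero polynomial in t_hat.  The system
    coefficients are assembled from ``aux`` when not supplied.
    """
    if sys is None:
        sys = assemble_system(aux, sol.sigmas, sol.eta)
    eta = sol.eta
    s1 = {1: sol.x1.sigma, 2: sol.x2.sigma}
    s2 = {1: sol.y1.sigma, 2: sol.y2.sigma}
    X, Y, T = _polys(sol)
    dX = {l: sp.diff(X[l], _u) for l in (1, 2)}
    dY = {l: sp.diff(Y[l], _u) for l in (1, 2)}
    dT = sp.diff(T, _u)
    alpha = aux.alpha(eta)
    beta = aux.beta(eta)
    entries = []
    for l, r in ((1, 2), (2, 1)):
        i = l - 1
        c_l = sys.b1[i] - sys.gam[i]
        checks = {
            f"necessary_x_l{l}":
                sys.a0[i] * T + alpha[i] * s1[l] * X[l] - eta * _u * s1[l] * dX[l],
            f"necessary_y_l{l}":
                eta * _u * dT + beta[i] * T + sys.mu[i] * s1[l] * X[l]
                + sys.b2[i] * s2[l] * Y[l],
            f"sufficient_x_l{l}":
                eta * _u * dT + (sys.a1[i] - alpha[i]) * T + sys.a2[i] * s1[l] * X[l]
                + sys.lam[i] * s2[l] * Y[l],
            f"sufficient_y_l{l}":
                sys.gam[i] * s2[r] * Y[r] + (c_l - beta[i]) * s2[l] * Y[l]
                + sys.b0[i] * T - eta * s2[l] * _u * dY[l],
        }
        for name, expr in checks.items():
            residual = sp.expand(expr)
            entries.append(exact_check(name, residual))
    return ConditionReport(entries=tuple(entries))


def ode_residual(sys: MetaModelSystem, sol: SolitarySolutionSet) -> ConditionReport:
    """Substitute the closed form into the four ODEs and reduce exactly.

    Working in the t_hat domain, x' = eta t_hat sigma (X'T - XT')/T^2; each
    equation residual is multiplied by T^2 and expanded; the pair satisfies
    the system iff all four residual polynomials are identically zero.
    """
    eta = sol.eta
    s1 = {1: sol.x1.sigma, 2: sol.x2.sigma}
    s2 = {1: sol.y1.sigma, 2: sol.y2.sigma}
    X, Y, T = _polys(sol)
    dX = {l: sp.diff(X[l], _u) for l in (1, 2)}
    dY = {l: sp.diff(Y[l], _u) for l in (1, 2)}
    dT = sp.diff(T, _u)
    entries = []
    for l, r in ((1, 2), (2, 1)):
        i = l - 1
        res_x = (eta * _u * s1[l] * (dX[l] * T - X[l] * dT)
                 - sys.a0[i] * T**2 - sys.a1[i] * s1[l] * X[l] * T
                 - sys.a2[i] * s1[l] ** 2 * X[l] ** 2
                 - sys.lam[i] * s1[l] * s2[l] * X[l] * Y[l])
        res_y = (eta * _u * s2[l] * (dY[l] * T - Y[l] * dT)
                 - sys.b0[i] * T**2 - sys.b1[i] * s2[l] * Y[l] * T
                 - sys.b2[i] * s2[l] ** 2 * Y[l] ** 2
                 - sys.mu[i] * s1[l] * s2[l] * X[l] * Y[l]
                 - sys.gam[i] * (s2[r] * Y[r] - s2[l] * Y[l]) * T)
        entries.append(exact_check(f"ode_x{l}", sp.expand(res_x)))
        entries.append(exact_check(f"ode_y{l}", sp.expand(res_y)))
    return ConditionReport(entries=tuple(entries))


def integrate_and_compare(sys: MetaModelSystem, sol: SolitarySolutionSet,
                          t_span: Tuple[float, float], rtol: float = 1e-10,
                          n_points: int = 201) -> float:
    """Max scale-normalized deviation between integration and closed form.

    The integration starts from the closed-form state at ``t_span[0]``;
    the deviation of each component is normalized by max(1, its amplitude)
    because solitary solutions trace separatrix-like trajectories along
    which absolute integration error grows with the component scale.
    A real pole of the shared denominator inside the span is an error.
    """
    t_start, t_end = float(t_span[0]), float(t_span[1])
    for pole in sol.real_positive_poles():
        if t_start <= pole <= t_end:
            raise ValueError(f"pole of the solution at t = {pole} inside t_span")
    coeffs = {name: tuple(float(c) for c in getattr(sys, name))
              for name in ("a0", "a1", "a2", "lam", "b0", "b1", "b2", "mu", "gam")}

    def rhs(_t, state):
        x = (state[0], state[2])
        y = (state[1], state[3])
        out = []
        for i, r in ((0, 1), (1, 0)):
            out.append(coeffs["a0"][i] + coeffs["a1"][i] * x[i]
                       + coeffs["a2"][i] * x[i] ** 2 + coeffs["lam"][i] * x[i] * y[i])
            out.append(coeffs["b0"][i] + coeffs["b1"][i] * y[i]
                       + coeffs["b2"][i] * y[i] ** 2 + coeffs["mu"][i] * x[i] * y[i]
                       + coeffs["gam"][i] * (y[r] - y[i]))
        return out

    grid = np.linspace(t_start, t_end, n_points)
    y0 = evaluate_solution(sol, t_start)
    result = solve_ivp(rhs, (t_start, t_end), y0, t_eval=grid, rtol=rtol,
                       atol=1e-12, method="DOP853")
    if not result.success:
        raise RuntimeError(f"integration failed: {result.message}")
    closed = np.array([evaluate_solution(sol, t) for t in grid])
    scale = np.maximum(1.0, np.max(np.abs(closed), axis=0))
    return float(np.max(np.abs(result.y.T - closed) / scale))


def verify_pair(sys: MetaModelSystem, sol: SolitarySolutionSet,
                aux: Optional[AuxiliaryParams] = None,
                numeric_span: Optional[Tuple[float, float]] = None,
                rtol: float = 1e-10) -> VerificationResult:
    """Full verification: exact identities plus optional numeric cross-check."""
    ode_report = ode_residual(sys, sol)
    if aux is not None:
        identity_report = residual_identities(aux, sol, sys)
    else:
        identity_report = ode_report
    numeric = None
    if numeric_span is not None:
        numeric = integrate_and_compare(sys, sol, numeric_span, rtol=rtol)
    return VerificationResult(
        identity_report=identity_report, ode_report=ode_report,
        numeric_max_residual=numeric,
        pole_locations=tuple(sol.real_positive_poles()),
    )


@dataclass(frozen=True)
class FixtureRanges:
    """Magnitude bounds for the random rational draws of the generator."""

    magnitude: int = 20
    max_retries: int = 40


def _rational(rng: random.Random, ranges: FixtureRanges, nonzero: bool = True,
              exclude: Sequence = ()) -> sp.Rational:
    mag = ranges.magnitude
    for _ in range(1000):
        value = sp.Rational(rng.randint(-mag, mag), rng.randint(1, mag))
        if nonzero and value == 0:
            continue
        if value in exclude:
            continue
        return value
    raise RuntimeError("rational draw failed")  # pragma: no cover


def generate_fixture(n: int, seed: int, ranges: Optional[FixtureRanges] = None):
    """Deterministic random valid (aux, solution, system) triple of order n.

    Free choices are drawn as small rationals and the remaining existence
    conditions are solved exactly; draws violating a guard or leaving no
    admissible real branch are retried (bounded).  For n > 3 the default
    n - 3 denominator coefficients ae_2 .. ae_{n-2} are zeroed.
    """
    ranges = ranges or FixtureRanges()
    rng = random.Random(f"lvsoliton-fixture:{n}:{seed}")
    zero = set(default_zero_aes(n))
    last_error = None
    for _attempt in range(ranges.max_retries):
        try:
            free = _draw_free(n, rng, ranges)
            if n >= 2:
                branches = solve_free_constraints(n, free, zero_aes=zero)
                rational = [b for b in branches
                            if all(v.is_rational for v in b.values())]
                if not rational:
                    raise ValueError("no rational branch for this draw")
                free = {name: value for name, value in rational[0].items()}
            aes = []
            for k in range(n):
                if k in zero:
                    aes.append(sp.Integer(0))
                else:
                    aes.append(_rational(rng, ranges))
            sigmas = {name: _rational(rng, ranges) for name in ("x1", "y1", "x2", "y2")}
            eta = abs(_rational(rng, ranges))
            t0 = _rational(rng, ranges, nonzero=False)
            aux, sol, sys = assemble_full(n, free, aes, sigmas, eta, t0,
                                          zero_aes=zero, branch=0)
            if not residual_identities(aux, sol, sys).passed:
                raise ValueError("residual identities failed")
            return aux, sol, sys
        except (ValueError, ZeroDivisionError) as exc:
            last_error = exc
            continue
    raise RuntimeError(
        f"fixture generation exhausted {ranges.max_retries} retries "
        f"(n={n}, seed={seed}): {last_error}")


def _draw_free(n: int, rng: random.Random, ranges: FixtureRanges) -> dict:
    free = {}
    for l in (1, 2):
        free[f"A1{l}"] = _rational(rng, ranges, exclude=(sp.Integer(-1), sp.Integer(0)))
    if n == 1:
        for l in (1, 2):
            free[f"h0{l}"] = _rational(rng, ranges, exclude=(sp.Integer(1),))
            free[f"K3{l}"] = _rational(rng, ranges)
            free[f"L3{l}"] = _rational(rng, ranges)
            free[f"N3{l}"] = _rational(rng, ranges)
    elif n == 2:
        for l in (1, 2):
            free[f"h0{l}"] = _rational(rng, ranges, exclude=(sp.Integer(1),))
            free[f"h1{l}"] = _rational(rng, ranges)
    elif n == 3:
        free["h12"] = _rational(rng, ranges, nonzero=False)
        free["h22"] = _rational(rng, ranges, nonzero=False)
    else:
        active = [k for k in range(n) if k not in set(default_zero_aes(n))]
        for k in active[1:]:
            free[f"h{k}2"] = _rational(rng, ranges, nonzero=False)
    return free
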