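"""Forward construction: from free solution-side choices to a complete
(auxiliary parameters, solitary solution, coupled system) triple.

The meta-model couples two Riccati pairs (multiplicative coupling lambda_l,
mu_l inside each pair, diffusive coupling gamma_l between the pairs):

    x_l' = a0l + a1l x_l + a2l x_l^2 + lambda_l x_l y_l
    y_l' = b0l + b1l y_l + b2l y_l^2 + mu_l x_l y_l + gamma_l (y_r - y_l)

An order-n solitary solution exists iff a finite family of exact algebraic
conditions on the solution-side parameters holds.  Those conditions involve
the auxiliary quantities A, L, N, K linking solution coefficients to system
coefficients; for n <= 3 they can be solved with all denominator
coefficients ae_k free, while for n > 3 exactly (n - 3) of the ae_k must
vanish, which drops the corresponding conditions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Sequence, Tuple

import sympy as sp

from .exact import ExactLike, format_exact, parse_exact, to_exact
from .report import ConditionReport, exact_check
from .solution import SolitaryComponent, SolitarySolutionSet

__all__ = [
    "AuxiliaryParams",
    "MetaModelSystem",
    "solve_A",
    "solve_LN_order1",
    "solve_LN_unique",
    "h_from_L",
    "solve_K",
    "constraint_residuals",
    "solve_free_constraints",
    "required_zero_aes",
    "assemble_system",
    "assemble_full",
]

_L = (1, 2)  # subsystem labels


def _pair(values, name: str) -> tuple:
    values = tuple(to_exact(v) for v in values)
    if len(values) != 2:
        raise ValueError(f"{name} must have one value per subsystem l = 1, 2")
    return values


@dataclass(frozen=True)
class AuxiliaryParams:
    """Auxiliary quantities linking system and solution coefficients.

    Each field is a pair indexed by subsystem l in {1, 2}.  For n >= 2 the
    L and N triples coincide; alpha_l and beta_l are the residual constants
    of the necessary conditions and satisfy alpha_l = -eta A1l / A2l,
    beta_l = eta L1l.
    """

    A1: tuple
    A2: tuple
    L1: tuple
    L2: tuple
    L3: tuple
    N1: tuple
    N2: tuple
    N3: tuple
    K1: tuple
    K2: tuple
    K3: tuple

    def __post_init__(self):
        for name in ("A1", "A2", "L1", "L2", "L3", "N1", "N2", "N3", "K1", "K2", "K3"):
            object.__setattr__(self, name, _pair(getattr(self, name), name))
        for l in (0, 1):
            if self.A2[l] == 0:
                raise ValueError("A2l must be nonzero")

    def alpha(self, eta: sp.Expr) -> tuple:
        return tuple(-eta * self.A1[i] / self.A2[i] for i in (0, 1))

    def beta(self, eta: sp.Expr) -> tuple:
        return tuple(eta * self.L1[i] for i in (0, 1))

    def to_dict(self) -> dict:
        out = {}
        for name in ("A1", "A2", "L1", "L2", "L3", "N1", "N2", "N3", "K1", "K2", "K3"):
            for l in _L:
                out[f"{name}_{l}"] = format_exact(getattr(self, name)[l - 1])
        return out

    @classmethod
    def from_dict(cls, data: Mapping[str, str]) -> "AuxiliaryParams":
        kwargs = {
            name: tuple(parse_exact(data[f"{name}_{l}"]) for l in _L)
            for name in ("A1", "A2", "L1", "L2", "L3", "N1", "N2", "N3", "K1", "K2", "K3")
        }
        return cls(**kwargs)


@dataclass(frozen=True)
class MetaModelSystem:
    """The 18 exact coefficients of the coupled 4-ODE meta-model.

    Fields are pairs indexed by subsystem l.  gamma_l = 0 decouples the
    meta-model into two independent Riccati pairs and is rejected here.
    """

    a0: tuple
    a1: tuple
    a2: tuple
    lam: tuple
    b0: tuple
    b1: tuple
    b2: tuple
    mu: tuple
    gam: tuple

    def __post_init__(self):
        for name in ("a0", "a1", "a2", "lam", "b0", "b1", "b2", "mu", "gam"):
            object.__setattr__(self, name, _pair(getattr(self, name), name))

    @property
    def decoupled(self) -> bool:
        return any(g == 0 for g in self.gam)

    def rhs(self, x: Sequence[sp.Expr], y: Sequence[sp.Expr]) -> tuple:
        """Right-hand sides (x1', y1', x2', y2') at symbolic state values."""
        out = []
        for i, r in ((0, 1), (1, 0)):
            out.append(self.a0[i] + self.a1[i] * x[i] + self.a2[i] * x[i] ** 2
                       + self.lam[i] * x[i] * y[i])
            out.append(self.b0[i] + self.b1[i] * y[i] + self.b2[i] * y[i] ** 2
                       + self.mu[i] * x[i] * y[i] + self.gam[i] * (y[r] - y[i]))
        return (out[0], out[1], out[2], out[3])

    def to_dict(self) -> dict:
        out = {}
        for name in ("a0", "a1", "a2", "lam", "b0", "b1", "b2", "mu", "gam"):
            for l in _L:
                out[f"{name}{l}"] = format_exact(getattr(self, name)[l - 1])
        return out

    @classmethod
    def from_dict(cls, data: Mapping[str, str]) -> "MetaModelSystem":
        kwargs = {
            name: tuple(parse_exact(data[f"{name}{l}"]) for l in _L)
            for name in ("a0", "a1", "a2", "lam", "b0", "b1", "b2", "mu", "gam")
        }
        return cls(**kwargs)


def required_zero_aes(n: int) -> int:
    """Number of denominator coefficients that must vanish at order n."""
    if n < 1:
        raise ValueError("order n must be >= 1")
    return max(0, n - 3)


def default_zero_aes(n: int) -> tuple:
    """Default zeroed indices ae_2 .. ae_{n-2}.

    Zeroing ae_0 would make t_hat a common factor of every numerator and
    the denominator, silently reducing the effective order, so indices 0
    and 1 are never zeroed by default.
    """
    return tuple(range(2, 2 + required_zero_aes(n)))


def solve_A(n: int, A1: Sequence[ExactLike]) -> Tuple[tuple, Dict[Tuple[int, int], sp.Expr]]:
    """A2l and the numerator ratio table p_kl from the free choices A1l.

    A2l = -(1 + A1l)/n and p_kl = 1/(1 + (n-k) A2l) for k = 0..n-1.
    A1l = -1 is rejected (it forces A2l = 0, contradicting
    A2l = -eta sigma_1l / a0l with nonzero eta and sigma).
    """
    A1 = _pair(A1, "A1")
    A2 = []
    p: Dict[Tuple[int, int], sp.Expr] = {}
    for idx, l in enumerate(_L):
        if A1[idx] == -1:
            raise ValueError(f"A1{l} = -1 forces A2{l} = 0 (inadmissible)")
        a2 = -(1 + A1[idx]) / sp.Integer(n)
        A2.append(a2)
        for k in range(n):
            den = 1 + (n - k) * a2
            if den == 0:
                raise ValueError(f"p-denominator 1 + ({n}-{k}) A2{l} vanishes at k = {k}")
            p[(k, l)] = sp.cancel(1 / den)
    return tuple(A2), p


def solve_LN_order1(p0: ExactLike, h0: ExactLike, free: ExactLike) -> tuple:
    """(L1, L2) for order n = 1 given the free third entry L3 (same form
    for the N triple).  Requires p0 != 1."""
    p0, h0, L3 = to_exact(p0), to_exact(h0), to_exact(free)
    if p0 == 1:
        raise ValueError("p0 = 1: order-1 L/N system is degenerate")
    L1 = ((1 + L3) * p0 - L3 * h0) / (1 - p0)
    L2 = (-(1 + L3) + L3 * h0) / (1 - p0)
    return sp.cancel(L1), sp.cancel(L2)


def _ln_guard(p0, p1, h0, h1) -> sp.Expr:
    return (1 - p1) * h0 + (h1 - 1) * p0 + (p1 - h1)


def solve_LN_unique(n: int, p0: ExactLike, p1: ExactLike,
                    h0: ExactLike, h1: ExactLike) -> tuple:
    """The unique (L1, L2, L3) triple for order n >= 2.

    The shared denominator (the guard) must be nonzero; it vanishes exactly
    when (p0, p1) = (h0, h1) up to the degenerate ratio configurations.
    """
    if n < 2:
        raise ValueError("unique L/N triple requires n >= 2")
    p0, p1, h0, h1 = (to_exact(v) for v in (p0, p1, h0, h1))
    D = _ln_guard(p0, p1, h0, h1)
    if D == 0:
        raise ValueError("degenerate ratio configuration: L/N denominator vanishes")
    L1 = ((p1 * n - 1) * h0 - p0 * (n * h1 - 1)) / D
    L2 = ((1 - n) * h0 - 1 + n * h1) / D
    L3 = ((n - 1) * p0 + 1 - n * p1) / D
    return sp.cancel(L1), sp.cancel(L2), sp.cancel(L3)


def h_from_L(k: int, L: Sequence[ExactLike], p_k: ExactLike) -> sp.Expr:
    """Solve the k-th linear condition k + L1 + L2 p_k + L3 h_k = 0 for h_k."""
    L1, L2, L3 = (to_exact(v) for v in L)
    if L3 == 0:
        raise ValueError("L3 = 0: condition cannot be solved for h_k")
    return sp.cancel(-(k + L1 + L2 * to_exact(p_k)) / L3)


def solve_K(n: int, h0_self: ExactLike, h0_other: ExactLike,
            K3: ExactLike) -> tuple:
    """(K1, K2) from the leading and k = 0 equations of the K system."""
    h0l, h0r, K3 = to_exact(h0_self), to_exact(h0_other), to_exact(K3)
    if h0l == 1:
        raise ValueError("h0 = 1: K system is degenerate")
    K1 = (h0r - n * K3 - 1) / (1 - h0l)
    K2 = ((n * K3 + 1) * h0l - h0r) / (1 - h0l)
    return sp.cancel(K1), sp.cancel(K2)


def _other(l: int) -> int:
    return 2 if l == 1 else 1


def constraint_residuals(n: int, A1: Sequence[ExactLike], K3: Sequence[ExactLike],
                         h: Mapping[Tuple[int, int], ExactLike],
                         zero_aes: Iterable[int] = ()) -> ConditionReport:
    """Exact residuals of every remaining existence condition at order n.

    ``h`` maps (k, l) to the ratio h_kl for every non-zeroed index k.
    Conditions at zeroed ae indices hold identically and are skipped.
    """
    zero = set(zero_aes)
    active = [k for k in range(n) if k not in zero]
    A1 = _pair(A1, "A1")
    K3 = _pair(K3, "K3")
    h = {key: to_exact(v) for key, v in h.items()}
    _, p = solve_A(n, A1)
    entries = []
    guards = []
    for l in _L:
        if n >= 2:
            try:
                L = solve_LN_unique(n, p[(0, l)], p[(1, l)], h[(0, l)], h[(1, l)])
            except ValueError as exc:
                guards.append(f"l={l}: {exc}")
                continue
            for k in active:
                if k < 2:
                    continue
                entries.append(exact_check(
                    f"L_condition_k{k}_l{l}",
                    k + L[0] + L[1] * p[(k, l)] + L[2] * h[(k, l)],
                ))
        r = _other(l)
        try:
            K1, K2 = solve_K(n, h[(0, l)], h[(0, r)], K3[l - 1])
        except ValueError as exc:
            guards.append(f"l={l}: {exc}")
            continue
        for k in active:
            if k < 1:
                continue
            entries.append(exact_check(
                f"K_condition_k{k}_l{l}",
                h[(k, r)] + K1 * h[(k, l)] + K2 + K3[l - 1] * k * h[(k, l)],
            ))
    return ConditionReport(entries=tuple(entries), guards_violated=tuple(guards))


def _base_unknowns(n: int) -> list:
    names = []
    for l in _L:
        names.append(f"A1{l}")
    for l in _L:
        names.append(f"h0{l}")
        if n >= 2:
            names.append(f"h1{l}")
    for l in _L:
        names.append(f"K3{l}")
    return names


def solve_free_constraints(n: int, fixed: Mapping[str, ExactLike],
                           zero_aes: Optional[Iterable[int]] = None,
                           real_only: bool = True) -> list:
    """Solve the order-n existence conditions for the non-fixed unknowns.

    ``fixed`` maps parameter names (``A1l``, ``hkl``, ``K3l``) to exact
    values.  Returns a list of solution branches, each a complete mapping of
    all base parameters; an infeasible system yields an empty list.  All
    algebraic branches are computed; ``real_only`` filters to branches whose
    values sympy certifies real.  Zeroed ae indices must lie in {2..n-1}:
    the closed-form L/N triple needs h0 and h1.
    """
    if n < 1:
        raise ValueError("order n must be >= 1")
    zero = set(default_zero_aes(n) if zero_aes is None else zero_aes)
    if len(zero) < required_zero_aes(n):
        # Fewer zeroed coefficients than the order dichotomy demands: the
        # condition system is still formed and solved; it is expected to
        # come back empty for n > 3.
        pass
    if zero - set(range(2, n)):
        raise ValueError("zeroed ae indices must lie in {2, .., n-1}")
    active = [k for k in range(n) if k not in zero]
    fixed = {name: to_exact(v) for name, v in fixed.items()}

    values: Dict[str, sp.Expr] = {}
    unknowns = []
    for name in _base_unknowns(n):
        if name in fixed:
            values[name] = fixed[name]
        else:
            symbol = sp.Symbol(name)
            values[name] = symbol
            unknowns.append(symbol)

    A2 = {l: -(1 + values[f"A1{l}"]) / n for l in _L}
    p = {(k, l): 1 / (1 + (n - k) * A2[l]) for k in active for l in _L}
    h: Dict[Tuple[int, int], sp.Expr] = {}
    equations = []
    L: Dict[int, tuple] = {}
    if n >= 2:
        for l in _L:
            h[(0, l)] = values[f"h0{l}"]
            h[(1, l)] = values[f"h1{l}"]
            p0, p1, h0, h1 = p[(0, l)], p[(1, l)], h[(0, l)], h[(1, l)]
            D = _ln_guard(p0, p1, h0, h1)
            L[l] = (((p1 * n - 1) * h0 - p0 * (n * h1 - 1)) / D,
                    ((1 - n) * h0 - 1 + n * h1) / D,
                    ((n - 1) * p0 + 1 - n * p1) / D)
            for k in active:
                if k < 2:
                    continue
                name = f"h{k}{l}"
                if name in fixed:
                    h[(k, l)] = fixed[name]
                    equations.append(k + L[l][0] + L[l][1] * p[(k, l)] + L[l][2] * h[(k, l)])
                else:
                    h[(k, l)] = -(k + L[l][0] + L[l][1] * p[(k, l)]) / L[l][2]
    else:
        for l in _L:
            h[(0, l)] = values[f"h0{l}"]
    for l in _L:
        r = _other(l)
        K3 = values[f"K3{l}"]
        K1 = (h[(0, r)] - n * K3 - 1) / (1 - h[(0, l)])
        K2 = ((n * K3 + 1) * h[(0, l)] - h[(0, r)]) / (1 - h[(0, l)])
        for k in active:
            if k < 1:
                continue
            equations.append(h[(k, r)] + K1 * h[(k, l)] + K2 + K3 * k * h[(k, l)])

    if unknowns and len(equations) < len(unknowns):
        raise ValueError(
            f"underdetermined: {len(unknowns)} unknowns but only "
            f"{len(equations)} conditions; fix more free choices"
        )
    raw = _solve_condition_system(equations, unknowns)
    branches = []
    for sol in raw:
        subs = dict(sol)
        branch_values = {name: sp.cancel(expr.subs(subs))
                         if getattr(expr, "free_symbols", None) else to_exact(expr)
                         for name, expr in values.items()}
        if not _branch_admissible(n, branch_values, active, real_only):
            continue
        full = dict(branch_values)
        degenerate = False
        for k in active:
            for l in _L:
                expr = sp.sympify(h[(k, l)])
                value = sp.cancel(expr.subs(subs)) if expr.free_symbols else to_exact(expr)
                if value.has(sp.zoo, sp.nan, sp.oo):
                    degenerate = True
                full[f"h{k}{l}"] = value
        if degenerate:
            continue
        branches.append(full)
    branches.sort(key=lambda b: tuple(str(b[name]) for name in sorted(b)))
    return branches


def _solve_condition_system(equations, unknowns) -> list:
    """Solve the rational condition equations for ``unknowns`` exactly.

    The condition system is close to triangular: most equations are linear
    in one of the remaining unknowns once earlier ones are substituted.
    Those pivots are eliminated first; only the small residual polynomial
    core (generically two unknowns) goes to ``sympy.solve``.  Every
    candidate is re-checked against the full original equation set, which
    also discards spurious branches introduced by clearing denominators.
    """
    original = [sp.together(eq) for eq in equations]
    if not unknowns:
        return [{}] if all(sp.cancel(eq) == 0 for eq in original) else []
    pending = [sp.numer(eq) for eq in original]
    remaining = list(unknowns)
    chain = []  # (symbol, expr-in-later-unknowns), elimination order
    progress = True
    while progress and len(remaining) > 2:
        progress = False
        for i, eq in enumerate(pending):
            pivot = None
            for u in remaining:
                try:
                    poly = sp.Poly(eq, u)
                except sp.PolynomialError:
                    continue
                if poly.degree() == 1:
                    c1, c0 = poly.all_coeffs()
                    pivot = (u, sp.cancel(-c0 / c1))
                    break
            if pivot is None:
                continue
            u, expr = pivot
            chain.append((u, expr))
            remaining.remove(u)
            rest = []
            for j, other in enumerate(pending):
                if j == i:
                    continue
                rest.append(sp.numer(sp.together(sp.cancel(other.subs(u, expr)))))
            pending = rest
            progress = True
            break
    if remaining:
        try:
            core = sp.solve([sp.expand(eq) for eq in pending], remaining, dict=True)
        except NotImplementedError:
            core = []
    else:
        core = [{}] if all(sp.cancel(eq) == 0 for eq in pending) else []
    solutions = []
    for candidate in core:
        if len(candidate) != len(remaining):
            continue  # parametric family: degenerate, guard-violating
        assignment = dict(candidate)
        bad = False
        for u, expr in reversed(chain):
            value = sp.cancel(expr.subs(assignment))
            if value.has(sp.zoo, sp.nan) or value.free_symbols:
                bad = True
                break
            assignment[u] = value
        if bad:
            continue
        # Final check against the uncleared equations.
        if all(sp.cancel(eq.subs(assignment)) == 0 for eq in original):
            solutions.append({u: sp.cancel(assignment[u]) for u in unknowns})
    return solutions


def _branch_admissible(n, branch, active, real_only) -> bool:
    for l in _L:
        A1 = branch[f"A1{l}"]
        if A1 == -1:
            return False
        A2 = -(1 + A1) / n
        if any(1 + (n - k) * A2 == 0 for k in active):
            return False
        if branch[f"h0{l}"] == 1:
            return False
        if branch[f"K3{l}"] == 0:
            return False
        if n >= 2:
            p0 = 1 / (1 + n * A2)
            p1 = 1 / (1 + (n - 1) * A2)
            D = _ln_guard(p0, p1, branch[f"h0{l}"], branch[f"h1{l}"])
            if D == 0:
                return False
            L3 = ((n - 1) * p0 + 1 - n * p1) / D
            if L3 == 0:
                return False
    if real_only:
        for name, value in branch.items():
            if value.is_real is not True:
                return False
    return True


def assemble_system(aux: AuxiliaryParams, sigmas: Mapping[str, ExactLike],
                    eta: ExactLike) -> MetaModelSystem:
    """Meta-model coefficients generated by auxiliaries, amplitudes and eta.

    All coefficients scale linearly with eta.  The y-equation linear
    coefficient is derived from the defining auxiliary relations:
    b1l = eta (L1l - K1l/K3l - sigma_2l / (K3l sigma_2r)).
    """
    eta = to_exact(eta)
    if eta == 0:
        raise ValueError("eta must be nonzero")
    s1 = (to_exact(sigmas["x1"]), to_exact(sigmas["x2"]))
    s2 = (to_exact(sigmas["y1"]), to_exact(sigmas["y2"]))
    if any(s == 0 for s in s1 + s2):
        raise ValueError("all sigma amplitudes must be nonzero")
    if any(k == 0 for k in aux.K3):
        raise ValueError("K3l must be nonzero")
    coeffs: Dict[str, list] = {name: [] for name in
                               ("a0", "a1", "a2", "lam", "b0", "b1", "b2", "mu", "gam")}
    for i, r in ((0, 1), (1, 0)):
        coeffs["a0"].append(sp.cancel(-eta * s1[i] / aux.A2[i]))
        coeffs["a1"].append(sp.cancel(eta * (aux.N1[i] - aux.A1[i] / aux.A2[i])))
        coeffs["a2"].append(sp.cancel(aux.N2[i] * eta / s1[i]))
        coeffs["lam"].append(sp.cancel(aux.N3[i] * eta / s2[i]))
        coeffs["b0"].append(sp.cancel(-eta * s2[i] * aux.K2[i] / aux.K3[i]))
        coeffs["b1"].append(sp.cancel(
            eta * (aux.L1[i] - aux.K1[i] / aux.K3[i] - s2[i] / (aux.K3[i] * s2[r]))))
        coeffs["b2"].append(sp.cancel(aux.L3[i] * eta / s2[i]))
        coeffs["mu"].append(sp.cancel(aux.L2[i] * eta / s1[i]))
        coeffs["gam"].append(sp.cancel(-eta * s2[i] / (aux.K3[i] * s2[r])))
    return MetaModelSystem(**{name: tuple(vals) for name, vals in coeffs.items()})


def _aux_from_branch(n: int, branch: Mapping[str, sp.Expr],
                     order1_free: Optional[Mapping[str, ExactLike]] = None) -> AuxiliaryParams:
    """Auxiliary parameters from a resolved constraint branch.

    For n = 1 the L and N triples are not unique; their free third entries
    L3l and N3l must be supplied through ``order1_free``.
    """
    A1 = (branch["A11"], branch["A12"])
    A2, p = solve_A(n, A1)
    K3 = (branch["K31"], branch["K32"])
    L_rows, N_rows = [], []
    for l in _L:
        if n >= 2:
            triple = solve_LN_unique(n, p[(0, l)], p[(1, l)],
                                     branch[f"h0{l}"], branch[f"h1{l}"])
            L_rows.append(triple)
            N_rows.append(triple)
        else:
            free = order1_free or {}
            if f"L3{l}" not in free or f"N3{l}" not in free:
                raise ValueError("order 1 requires free choices L3l and N3l")
            L3 = to_exact(free[f"L3{l}"])
            N3 = to_exact(free[f"N3{l}"])
            L1, L2 = solve_LN_order1(p[(0, l)], branch[f"h0{l}"], L3)
            N1, N2 = solve_LN_order1(p[(0, l)], branch[f"h0{l}"], N3)
            L_rows.append((L1, L2, L3))
            N_rows.append((N1, N2, N3))
    K1_row, K2_row = [], []
    for l in _L:
        K1, K2 = solve_K(n, branch[f"h0{l}"], branch[f"h0{_other(l)}"], K3[l - 1])
        K1_row.append(K1)
        K2_row.append(K2)
    return AuxiliaryParams(
        A1=A1, A2=A2,
        L1=tuple(t[0] for t in L_rows), L2=tuple(t[1] for t in L_rows),
        L3=tuple(t[2] for t in L_rows),
        N1=tuple(t[0] for t in N_rows), N2=tuple(t[1] for t in N_rows),
        N3=tuple(t[2] for t in N_rows),
        K1=tuple(K1_row), K2=tuple(K2_row), K3=K3,
    )


def assemble_full(n: int, free: Mapping[str, ExactLike], aes: Sequence[ExactLike],
                  sigmas: Mapping[str, ExactLike], eta: ExactLike, t0: ExactLike,
                  zero_aes: Optional[Iterable[int]] = None, branch: Optional[int] = None,
                  real_only: bool = True):
    """Complete an order-n construction from free choices.

    Solves the existence conditions for the parameters not given in
    ``free``, then assembles the auxiliary parameters, the solitary
    solution (with denominator coefficients ``aes``) and the generated
    meta-model system.  ``aes`` entries at zeroed indices must be zero.
    Returns the triple for the selected branch (``branch`` indexes the
    deterministic branch ordering; with a single admissible branch it may
    be omitted).
    """
    aes = tuple(to_exact(a) for a in aes)
    if len(aes) != n:
        raise ValueError("aes must have length n")
    zero = set(default_zero_aes(n) if zero_aes is None else zero_aes)
    if {k for k, a in enumerate(aes) if a == 0 and k >= 2} != zero and zero:
        zero_from_aes = {k for k, a in enumerate(aes) if a == 0}
        if not zero <= zero_from_aes:
            raise ValueError("aes must vanish at every zeroed index")
    order1_free = {name: free[name] for name in ("L31", "L32", "N31", "N32")
                   if name in free} if n == 1 else None
    constraint_free = {name: value for name, value in free.items()
                       if name not in ("L31", "L32", "N31", "N32")}
    branches = solve_free_constraints(n, constraint_free, zero_aes=zero,
                                      real_only=real_only)
    if not branches:
        raise ValueError("no admissible branch: the condition system is infeasible")
    if branch is None:
        if len(branches) > 1:
            raise ValueError(
                f"{len(branches)} branches found; select one with branch=<index>")
        branch = 0
    chosen = branches[branch]
    aux = _aux_from_branch(n, chosen, order1_free)
    _, p = solve_A(n, aux.A1)
    h = {}
    for l in _L:
        for k in range(n):
            if k in zero:
                h[(k, l)] = sp.Integer(0)
            elif f"h{k}{l}" in chosen:
                h[(k, l)] = chosen[f"h{k}{l}"]
            else:
                L = (aux.L1[l - 1], aux.L2[l - 1], aux.L3[l - 1])
                h[(k, l)] = h_from_L(k, L, p[(k, l)])
    p_full = {(k, l): (sp.Integer(0) if k in zero else p[(k, l)])
              for k in range(n) for l in _L}
    components = {}
    for l in _L:
        components[f"x{l}"] = SolitaryComponent(
            sigma=to_exact(sigmas[f"x{l}"]),
            ratios=tuple(p_full[(k, l)] for k in range(n)), aes=aes)
        components[f"y{l}"] = SolitaryComponent(
            sigma=to_exact(sigmas[f"y{l}"]),
            ratios=tuple(h[(k, l)] for k in range(n)), aes=aes)
    sol = SolitarySolutionSet(n=n, eta=to_exact(eta), t0=to_exact(t0), **components)
    system = assemble_system(aux, sigmas, eta)
    return aux, sol, system
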