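"""Riccati base cases: kink solutions and the coupled-pair conditions."""

import pytest
import sympy as sp
from hypothesis import given, settings
from hypothesis import strategies as st
from sympy import Rational as Q

from lvsoliton import (CoupledPairSystem, KinkSolution, RiccatiEquation,
                       inverse_relation_check, kink_coeffs, kink_from_coeffs,
                       pair_eta, pair_existence_check, pair_root_constraints,
                       riccati_eta)

rationals = st.fractions(min_value=-8, max_value=8, max_denominator=6)


@pytest.fixture(scope="module")
def worked_kink_equation():
    """x' = -1 + 5x - 4x^2, the reference single-equation example."""
    return RiccatiEquation(c0=-1, c1=5, c2=-4)


@pytest.fixture(scope="module")
def worked_pair():
    """The reference multiplicatively coupled pair admitting dark/bright
    solutions."""
    return CoupledPairSystem(
        a0=Q(136, 11), a1=Q(-828, 319), a2=Q(29, 187), a3=Q(-550, 1479),
        b0=Q(-51, 29), b1=Q(345, 319), b2=Q(-550, 1479), b3=Q(29, 187))


class TestRiccatiEta:
    def test_worked_example(self, worked_kink_equation):
        eta, real = riccati_eta(worked_kink_equation)
        assert real and eta == 3

    def test_unit_discriminant(self):
        eta, real = riccati_eta(RiccatiEquation(c0=0, c1=1, c2=Q(7, 3)))
        assert real and eta == 1

    def test_complex_flagged_not_raised(self):
        eta, real = riccati_eta(RiccatiEquation(c0=1, c1=0, c2=1))
        assert not real
        assert sp.simplify(eta**2 + 4) == 0

    def test_c2_zero_rejected(self):
        with pytest.raises(ValueError):
            RiccatiEquation(c0=1, c1=1, c2=0)


class TestKinkCoeffs:
    def test_direct_substitution(self):
        sol = KinkSolution(sigma=1, x0_root=1, t0_root=2, s=1, eta=1)
        eq = kink_coeffs(sol)
        assert (eq.c0, eq.c1, eq.c2) == (-1, 3, -2)
        assert eq.c1**2 - 4 * eq.c0 * eq.c2 == 1

    def test_symmetric_roots_kill_c1(self):
        sol = KinkSolution(sigma=2, x0_root=3, t0_root=-3, s=1, eta=5)
        assert kink_coeffs(sol).c1 == 0

    def test_zero_sigma_rejected(self):
        sol = KinkSolution(sigma=0, x0_root=1, t0_root=2, s=1, eta=1)
        with pytest.raises(ValueError, match="sigma"):
            kink_coeffs(sol)

    def test_equal_roots_rejected(self):
        with pytest.raises(ValueError):
            KinkSolution(sigma=1, x0_root=2, t0_root=2, s=1, eta=1)

    def test_discriminant_identity_symbolic(self):
        """c1^2 - 4 c0 c2 = eta^2 holds identically in the parameters."""
        sigma, x0, t0, eta = sp.symbols("sigma x0 t0 eta", nonzero=True)
        c0 = sigma * x0 * eta / (x0 - t0)
        c1 = (t0 + x0) * eta / (t0 - x0)
        c2 = t0 * eta / (sigma * (x0 - t0))
        assert sp.simplify(c1**2 - 4 * c0 * c2 - eta**2) == 0


class TestKinkFromCoeffs:
    def test_worked_example_limits_and_monotonicity(self, worked_kink_equation):
        sol = kink_from_coeffs(worked_kink_equation, Q(1, 3))
        assert sol.limits() == (Q(1, 4), 1)
        assert sol.pole_time() is None
        t = sp.Symbol("t")
        x = sol.expression(t)
        # passes through the initial condition and rises monotonically
        assert sp.simplify(x.subs(t, 0) - Q(1, 3)) == 0
        samples = [x.subs(t, v).evalf() for v in (-2, -1, 0, 1, 2)]
        assert all(a < b for a, b in zip(samples, samples[1:]))

    def test_symbolic_residual_zero(self, worked_kink_equation):
        t = sp.Symbol("t")
        sol = kink_from_coeffs(worked_kink_equation, Q(1, 3))
        x = sol.expression(t)
        residual = sp.diff(x, t) - worked_kink_equation.rhs(x)
        assert sp.simplify(residual) == 0

    def test_equilibrium_initial_condition_gives_constant(self, worked_kink_equation):
        sol = kink_from_coeffs(worked_kink_equation, 1)
        assert sol.s == 0
        assert sol.limits() == (1, 1)

    def test_exterior_initial_condition_has_pole(self, worked_kink_equation):
        sol = kink_from_coeffs(worked_kink_equation, 2)
        pole = sol.pole_time()
        assert pole is not None
        assert sp.simplify(pole - sp.log(Q(4, 7)) / 3) == 0

    def test_complex_eta_rejected(self):
        with pytest.raises(ValueError, match="kink"):
            kink_from_coeffs(RiccatiEquation(c0=1, c1=0, c2=1), 0)

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(sigma=rationals.filter(lambda f: f != 0),
           x0=rationals, eta=rationals.filter(lambda f: f > 0))
    def test_roundtrip_on_equation_coefficients(self, sigma, x0, eta):
        """kink_coeffs then kink_from_coeffs reproduces the equation."""
        if Q(x0) == -1:  # t0_root would be 0, killing c2
            return
        sol = KinkSolution(sigma=Q(sigma), x0_root=Q(x0), t0_root=Q(x0) + 1,
                           s=1, eta=Q(eta))
        eq = kink_coeffs(sol)
        equilibria = set(eq.equilibria())
        x_init = sol.sigma * Q(7, 8)
        if x_init in equilibria:
            return
        back = kink_from_coeffs(eq, x_init)
        rebuilt = kink_coeffs(back)
        assert (rebuilt.c0, rebuilt.c1, rebuilt.c2) == (eq.c0, eq.c1, eq.c2)


class TestCoupledPair:
    def test_reference_pair_satisfies_conditions(self, worked_pair):
        report = pair_existence_check(worked_pair)
        assert report.passed
        assert report.residual("cubic_identity") == 0

    def test_asymmetric_coupling_fails(self, worked_pair):
        broken = CoupledPairSystem(
            a0=worked_pair.a0, a1=worked_pair.a1, a2=worked_pair.a2,
            a3=worked_pair.a3 + 1, b0=worked_pair.b0, b1=worked_pair.b1,
            b2=worked_pair.b2, b3=worked_pair.b3)
        report = pair_existence_check(broken)
        assert not report.passed
        assert report.residual("a3_minus_b2") == 1

    def test_equal_subsystems_cubic_residual(self):
        """With a = b coefficients the cubic collapses to 2a1^3 - 18a0a2a1:
        zero iff a1 = 0 or a1^2 = 9 a0 a2."""
        a0, a1, a2 = sp.symbols("a0 a1 a2")
        sys_sym = CoupledPairSystem(a0=a0, a1=a1, a2=a2, a3=a2,
                                    b0=a0, b1=a1, b2=a2, b3=a2)
        cubic = (9 * a0 * a1 * a2 + 9 * a0 * a1 * a2 - 18 * a0 * a2 * a1
                 - 18 * a0 * a2 * a1 + 3 * a1 * a1**2 + 3 * a1 * a1**2
                 - 2 * a1**3 - 2 * a1**3)
        assert sp.expand(cubic - (2 * a1**3 - 18 * a0 * a1 * a2)) == 0
        zero_a1 = CoupledPairSystem(a0=3, a1=0, a2=5, a3=5, b0=3, b1=0, b2=5, b3=5)
        assert pair_existence_check(zero_a1).residual("cubic_identity") == 0

    def test_pair_eta_reference_value(self, worked_pair):
        assert pair_eta(worked_pair) == 1

    @pytest.mark.parametrize("c, expected", [(3, 3), (Q(1, 2), Q(1, 12))])
    def test_pair_eta_collapse(self, c, expected):
        sys_ = CoupledPairSystem(a0=0, a1=c, a2=1, a3=1, b0=0, b1=c, b2=1, b3=1)
        assert pair_eta(sys_) == Q(c) ** 2 / 3 == expected

    def test_pair_eta_all_zero(self):
        sys_ = CoupledPairSystem(a0=0, a1=0, a2=1, a3=0, b0=0, b1=0, b2=1, b3=0)
        assert pair_eta(sys_) == 0


class TestPairRootConstraints:
    def test_symmetric_configuration_passes(self):
        # x roots (c, -c) with poles (t1, -t1): cross-ratio equals -x1/x2 = 1.
        report = pair_root_constraints(
            xbar=(3, -3), ybar=(5, -5), tbar=(Q(7, 2), Q(-7, 2)))
        assert report.passed

    def test_zero_root_with_zero_pole_root(self):
        # With xbar1 = 0 the right side is 0; the left side is then
        # tbar1*tbar2 / ((x2-t1)(x2-t2)), zero exactly when a pole root is 0.
        report = pair_root_constraints(xbar=(0, 2), ybar=(0, 3), tbar=(0, 7))
        assert report.passed
        report = pair_root_constraints(xbar=(0, 2), ybar=(0, 3), tbar=(5, 7))
        assert not report.passed

    def test_generic_rationals_fail(self):
        report = pair_root_constraints(xbar=(1, 2), ybar=(3, 4), tbar=(5, 6))
        assert not report.passed
        assert report.residual("x_root_ratio") != 0

    def test_zero_denominator_guarded(self):
        report = pair_root_constraints(xbar=(1, 0), ybar=(3, 4), tbar=(5, 6))
        assert report.guards_violated


class TestInverseRelation:
    def test_exact_cancellation(self):
        that = sp.Symbol("that", positive=True)
        x = 3 * (that - 2) / (that - 5)
        y = Q(7, 3) * (that - 5) / (that - 2)
        assert inverse_relation_check(x, y) == 7

    def test_constants(self):
        assert inverse_relation_check(sp.Integer(4), Q(3, 2)) == 6

    def test_nonconstant_product_fails(self, example2_triple):
        _, sol, _ = example2_triple
        that = sp.Symbol("that", positive=True)
        x1 = sol.x1.expression(that)
        y1 = sol.y1.expression(that)
        assert inverse_relation_check(x1, y1, symbol=that) is None
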