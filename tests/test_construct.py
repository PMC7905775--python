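"""Forward construction: ratio tables, auxiliary triples, condition
solving and full assembly, pinned against the reference order-3 example."""

import random

import pytest
import sympy as sp
from sympy import Rational as Q

from lvsoliton import (assemble_full, assemble_system, constraint_residuals,
                       default_zero_aes, h_from_L, required_zero_aes, solve_A,
                       solve_K, solve_LN_order1, solve_LN_unique,
                       solve_free_constraints)
from lvsoliton.construct import AuxiliaryParams

#: Reference auxiliary values of the order-3 inverse example.
L_TRIPLE_1 = (Q(-28, 9), Q(-68, 5), Q(617, 45))
L_TRIPLE_2 = (Q(-226, 63), Q(136, 315), Q(7, 45))


class TestSolveA:
    def test_reference_p_table_l1(self):
        A2, p = solve_A(3, (Q(4, 5), Q(2, 5)))
        assert A2 == (Q(-3, 5), Q(-7, 15))
        assert (p[(0, 1)], p[(1, 1)], p[(2, 1)]) == (Q(-5, 4), -5, Q(5, 2))

    def test_reference_p_table_l2(self):
        _, p = solve_A(3, (Q(4, 5), Q(2, 5)))
        assert (p[(0, 2)], p[(1, 2)], p[(2, 2)]) == (Q(-5, 2), 15, Q(15, 8))

    def test_minus_one_rejected(self):
        with pytest.raises(ValueError, match="A1"):
            solve_A(3, (-1, Q(1, 2)))

    def test_vanishing_p_denominator(self):
        # n=1, A1=0 gives A2=-1 and p0 denominator 1 + 1*(-1) = 0.
        with pytest.raises(ValueError, match="vanishes"):
            solve_A(1, (0, Q(1, 2)))


class TestSolveLNOrder1:
    @pytest.mark.parametrize("seed", range(5))
    def test_back_substitution(self, seed):
        rng = random.Random(seed)
        rq = lambda: Q(rng.randint(-9, 9), rng.randint(1, 9))
        p0 = rq()
        while p0 == 1:
            p0 = rq()
        h0, L3 = rq(), rq()
        L1, L2 = solve_LN_order1(p0, h0, L3)
        assert 1 + L1 + L2 + L3 == 0
        assert L1 + L2 * p0 + L3 * h0 == 0

    def test_l3_zero_collapse(self):
        p0 = Q(1, 3)
        L1, L2 = solve_LN_order1(p0, Q(9), 0)
        assert (L1, L2) == (p0 / (1 - p0), -1 / (1 - p0))
        assert 1 + L1 + L2 == 0

    def test_p0_one_rejected(self):
        with pytest.raises(ValueError):
            solve_LN_order1(1, 2, 3)


class TestSolveLNUnique:
    def test_reference_l1_triple(self):
        triple = solve_LN_unique(3, Q(-5, 4), -5,
                                 Q(-34171, 31979), Q(-170881, 31979))
        assert triple == (Q(-9929, 4410), -8, Q(31979, 4410))

    def test_reference_l2_value(self):
        triple = solve_LN_unique(3, Q(-5, 2), 15,
                                 Q(-10021, 7619), Q(139919, 7619))
        assert triple[1] == -2
        assert triple == (Q(-12029, 4410), -2, Q(7619, 4410))

    @pytest.mark.parametrize("seed", range(5))
    def test_satisfies_generating_equations(self, seed):
        rng = random.Random(100 + seed)
        rq = lambda: Q(rng.randint(-9, 9), rng.randint(1, 9))
        n, p0, p1, h0, h1 = 3, rq(), rq(), rq(), rq()
        try:
            L1, L2, L3 = solve_LN_unique(n, p0, p1, h0, h1)
        except ValueError:
            return
        assert n + L1 + L2 + L3 == 0
        assert 0 + L1 + L2 * p0 + L3 * h0 == 0
        assert 1 + L1 + L2 * p1 + L3 * h1 == 0

    def test_degenerate_guard(self):
        with pytest.raises(ValueError, match="degenerate"):
            solve_LN_unique(3, Q(1, 2), Q(1, 3), Q(1, 2), Q(1, 3))


class TestHFromL:
    @pytest.mark.parametrize("k, p_k, expected", [
        (0, Q(-5, 2), 30),
        (1, 15, -25),
        (2, Q(15, 8), 5),
    ])
    def test_reference_h_table_l2(self, k, p_k, expected):
        assert h_from_L(k, L_TRIPLE_2, p_k) == expected

    def test_l3_zero_rejected(self):
        with pytest.raises(ValueError):
            h_from_L(0, (1, 1, 0), 1)


class TestSolveK:
    def test_reference_k_pair(self):
        K1, K2 = solve_K(3, Q(-625, 617), 30, Q(10489, 81))
        assert (K1, K2) == (Q(-130187, 729), Q(-153745, 729))

    @pytest.mark.parametrize("seed", range(5))
    def test_satisfies_generating_equations(self, seed):
        rng = random.Random(7 + seed)
        rq = lambda: Q(rng.randint(-9, 9), rng.randint(1, 9))
        n, h0, h0r, K3 = 2, rq(), rq(), rq()
        if h0 == 1:
            return
        K1, K2 = solve_K(n, h0, h0r, K3)
        assert 1 + K1 + K2 + n * K3 == 0
        assert h0r + K1 * h0 + K2 == 0

    def test_h0_one_rejected(self):
        with pytest.raises(ValueError):
            solve_K(3, 1, 2, 3)


class TestConstraintResiduals:
    H_EX1 = {(0, 1): Q(-34171, 31979), (1, 1): Q(-170881, 31979),
             (2, 1): Q(89309, 31979), (0, 2): Q(-10021, 7619),
             (1, 2): Q(139919, 7619), (2, 2): Q(39493, 15238)}
    K3_EX1 = (Q(-7834855, 274284), Q(-685710, 223853))

    H_EX2 = {(0, 1): Q(-625, 617), (1, 1): Q(-2965, 617), (2, 1): Q(1580, 617),
             (0, 2): 30, (1, 2): -25, (2, 2): 5}
    K3_EX2 = (Q(10489, 81), Q(-153, 617))

    def test_example1_values_all_zero(self):
        report = constraint_residuals(3, (Q(4, 5), Q(2, 5)), self.K3_EX1, self.H_EX1)
        assert report.passed
        assert len(report.entries) == 6

    def test_example2_values_all_zero(self):
        report = constraint_residuals(3, (Q(4, 5), Q(2, 5)), self.K3_EX2, self.H_EX2)
        assert report.passed

    def test_single_perturbation_detected(self):
        h = dict(self.H_EX1)
        h[(1, 1)] += 1
        report = constraint_residuals(3, (Q(4, 5), Q(2, 5)), self.K3_EX1, h)
        assert not report.passed
        assert sum(1 for e in report.entries if not e.passed) >= 1


class TestRequiredZeroAes:
    @pytest.mark.parametrize("n, expected", [(1, 0), (2, 0), (3, 0), (4, 1), (5, 2)])
    def test_dichotomy_count(self, n, expected):
        assert required_zero_aes(n) == expected

    def test_default_indices_avoid_0_and_1(self):
        assert default_zero_aes(5) == (2, 3)
        assert default_zero_aes(3) == ()


class TestSolveFreeConstraints:
    def test_reference_order3_branch(self, example1_free):
        branches = solve_free_constraints(3, example1_free)
        assert len(branches) == 1
        b = branches[0]
        assert b["K31"] == Q(-7834855, 274284)
        assert b["K32"] == Q(-685710, 223853)
        assert b["h01"] == Q(-34171, 31979)
        assert b["h02"] == Q(-10021, 7619)
        assert b["h11"] == Q(-170881, 31979)
        assert b["h21"] == Q(89309, 31979)

    def test_order2_random_choices_solvable(self):
        rng = random.Random(42)
        rq = lambda: Q(rng.randint(-9, 9), rng.randint(1, 9))
        for _ in range(5):
            fixed = {"A11": rq(), "A12": rq(),
                     "h01": rq(), "h11": rq(), "h02": rq(), "h12": rq()}
            if fixed["A11"] in (-1, 0) or fixed["A12"] in (-1, 0):
                continue
            try:
                branches = solve_free_constraints(2, fixed)
            except ValueError:
                continue
            for b in branches:
                report = constraint_residuals(
                    2, (b["A11"], b["A12"]), (b["K31"], b["K32"]),
                    {(k, l): b[f"h{k}{l}"] for k in (0, 1) for l in (1, 2)})
                assert report.passed

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError, match="underdetermined"):
            solve_free_constraints(3, {"A11": Q(4, 5)})

    def test_zero_aes_outside_range_rejected(self):
        with pytest.raises(ValueError, match="zeroed"):
            solve_free_constraints(4, {}, zero_aes=(0,))


class TestAssembleSystem:
    @pytest.fixture(scope="class")
    def example2_aux(self):
        return AuxiliaryParams(
            A1=(Q(4, 5), Q(2, 5)), A2=(Q(-3, 5), Q(-7, 15)),
            L1=(Q(-28, 9), Q(-226, 63)), L2=(Q(-68, 5), Q(136, 315)),
            L3=(Q(617, 45), Q(7, 45)),
            N1=(Q(-28, 9), Q(-226, 63)), N2=(Q(-68, 5), Q(136, 315)),
            N3=(Q(617, 45), Q(7, 45)),
            K1=(Q(-130187, 729), Q(27, 617)), K2=(Q(-153745, 729), Q(-185, 617)),
            K3=(Q(10489, 81), Q(-153, 617)))

    SIGMAS = {"x1": 1, "y1": 3, "x2": 2, "y2": 4}

    def test_reference_subsystem1(self, example2_aux, example2_system):
        built = assemble_system(example2_aux, self.SIGMAS, 1)
        for name in ("a0", "a1", "a2", "lam", "b0", "b1", "b2", "mu", "gam"):
            assert getattr(built, name)[0] == getattr(example2_system, name)[0], name

    def test_reference_subsystem2(self, example2_aux, example2_system):
        built = assemble_system(example2_aux, self.SIGMAS, 1)
        for name in ("a0", "a1", "a2", "lam", "b0", "b1", "b2", "mu", "gam"):
            assert getattr(built, name)[1] == getattr(example2_system, name)[1], name

    def test_eta_linearity(self, example2_aux):
        one = assemble_system(example2_aux, self.SIGMAS, 1)
        two = assemble_system(example2_aux, self.SIGMAS, 2)
        for name in ("a0", "a1", "a2", "lam", "b0", "b1", "b2", "mu", "gam"):
            assert tuple(2 * c for c in getattr(one, name)) == getattr(two, name)

    def test_zero_sigma_rejected(self, example2_aux):
        with pytest.raises(ValueError, match="sigma"):
            assemble_system(example2_aux, {"x1": 0, "y1": 3, "x2": 2, "y2": 4}, 1)


class TestAssembleFull:
    def test_example2_closed_forms(self, example2_triple, example2_system):
        aux, sol, system = example2_triple
        # monic numerator of the reference y2 closed form
        assert sol.y2.numerator_coeffs() == (30, -125, 75, 1)
        assert sol.x1.numerator_coeffs() == (Q(-5, 4), -25, Q(75, 2), 1)
        assert sol.y1.ratios == (Q(-625, 617), Q(-2965, 617), Q(1580, 617))
        assert system.to_dict() == example2_system.to_dict()

    def test_example1_solution_polynomials(self, example1_triple_eta4):
        aux, sol, system = example1_triple_eta4
        assert sol.x1.numerator_coeffs() == (-10, -70, Q(35, 2), 1)
        assert sol.x2.numerator_coeffs() == (-20, 210, Q(105, 8), 1)
        assert sol.y1.ratios == (Q(-34171, 31979), Q(-170881, 31979), Q(89309, 31979))
        assert sol.denominator_poly().all_coeffs() == [1, 7, 14, 8]

    def test_ae_invariance_of_system(self, example2_triple):
        """Different ae choices generate new solutions to the same system."""
        _, _, system = example2_triple
        free = {"A11": Q(4, 5), "A12": Q(2, 5), "h12": Q(-25), "h22": Q(5)}
        sigmas = {"x1": 1, "y1": 3, "x2": 2, "y2": 4}
        _, sol_b, system_b = assemble_full(3, free, aes=(2, 1, 7), sigmas=sigmas,
                                           eta=1, t0=0)
        assert system_b.to_dict() == system.to_dict()
        assert sol_b.aes != (1, 5, 15)

    def test_infeasible_raises(self):
        # order 4 without a zeroed ae and overdetermining fixed choices
        free = {"A11": Q(1, 2), "A12": Q(1, 3), "h12": Q(2, 7), "h32": Q(3, 5)}
        with pytest.raises(ValueError, match="no admissible branch"):
            assemble_full(4, free, aes=(1, 2, 3, 4),
                          sigmas={"x1": 1, "y1": 1, "x2": 1, "y2": 1},
                          eta=1, t0=0, zero_aes=())
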