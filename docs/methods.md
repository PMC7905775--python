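# Methods

## Model and solution family

The package operates on the four-equation meta-model of two diffusively
coupled Lotka–Volterra (Riccati) pairs,

    x_l' = a_0l + a_1l x_l + a_2l x_l^2 + lambda_l x_l y_l
    y_l' = b_0l + b_1l y_l + b_2l y_l^2 + mu_l x_l y_l + gamma_l (y_r - y_l)

for l, r in {1, 2}, l != r, with all 18 coefficients exact rationals.
`gamma_l = 0` decouples the meta-model into two independent pairs and is
rejected by the inverse solver (the pair case is handled by the
`riccati` module).  Solitary solutions of order n are

    x_l = sigma_1l X_l(t_hat)/T(t_hat),  y_l = sigma_2l Y_l(t_hat)/T(t_hat),
    t_hat = exp(eta (t - t0)),

with `X_l`, `Y_l`, `T` monic of degree n and `T` shared by all four
components.  Components are stored coefficient-first: the shared
denominator coefficients `ae_k` and per-component ratios `p_kl` (x) and
`h_kl` (y) such that the numerator coefficient of `t_hat^k` is
`ratio_k * ae_k`.  Roots are derived views; all existence conditions act
on coefficients, which stay real even when roots are complex.

Assumptions inherited from the theory: `eta != 0`, all four amplitudes
`sigma` nonzero, `a_0l != 0` (the A-parametrisation divides by it), and
for n >= 2 the coefficient symmetries `a_2l = mu_l`, `b_2l = lambda_l`
(forced by the uniqueness of the L = N triple).

## Existence conditions and the verification oracles

Substituting the ansatz and clearing denominators yields, per subsystem,
two "necessary" and two "sufficient" polynomial identities in `t_hat`
(eight in total), with residual constants `alpha_l`, `beta_l`.  The central
equivalence of the theory is that a (system, solution) pair satisfies the
ODEs iff all eight identities are the zero polynomial.  Two independent exact oracles
implement this:

* `residual_identities` expands the eight identities directly;
* `ode_residual` differentiates the closed form in the `t_hat` domain,
  multiplies by `T^2`, and expands the four residual polynomials.

Both reduce to canonical polynomial form; pass means *identically zero*,
not small.  When a construction branch carries algebraic (radical)
coefficients, zero-testing reduces coefficients in the algebraic extension
field (`sympy.Poly(..., extension=True)`); heavyweight generic
simplification is deliberately avoided.  Numerical integration
(`integrate_and_compare`, DOP853 at rtol 1e-10, atol 1e-12) is a
redundancy check only: solitary solutions trace separatrix-like
trajectories, so forward-integration error grows exponentially and is
reported scale-normalized (per-component deviation divided by
max(1, amplitude)); the exact algebra is the acceptance authority.

## Forward construction

In vector form the conditions split into an A-system (fixing
`A_2l = -(1 + A_1l)/n` and the ratio table `p_kl = 1/(1 + (n-k) A_2l)`),
an L- and an identical N-system (for n >= 2 a unique closed-form triple in
`p_0l, p_1l, h_0l, h_1l`; for n = 1 a one-parameter family with free
`L_3l`, `N_3l`), and a K-system (closed forms for `K_1l, K_2l` given
`h_0l, h_0r, K_3l`).  What remains after the closed forms is the coupling
condition set: the L-side conditions at k >= 2 and the K-side conditions
at k >= 1, over the base unknowns `A_1l, h_0l, h_1l, K_3l` (free choices
fix some of them).

`solve_free_constraints` solves that set exactly.  Plain `sympy.solve` on
the raw system is intractable beyond order 3 (a Groebner blow-up), so the
solver first runs a linear-triangularization pass — the condition system
is generically linear in one unknown at a time once earlier pivots are
substituted — leaving a two-variable polynomial core for `sympy.solve`.
Every candidate branch is re-verified against the original (uncleared)
equations, which also discards spurious branches introduced by clearing
denominators, and guard-violating branches (`A_1l = -1`, `h_0l = 1`,
vanishing ratio denominators, `K_3l = 0`, zero L/N-denominator) are
filtered.  All surviving algebraic branches are returned in a
deterministic order; "real mode" (default) keeps only branches whose
values sympy certifies real.  At order 3 with the default free set
`{A11, A12, h12, h22}` the admissible branch is generically unique and
rational.

System coefficients follow from the auxiliaries by the assembly map
(linear in `eta`).  The y-equation linear coefficient is derived from the
defining auxiliary relations,

    b_1l = eta (L_1l - K_1l/K_3l - sigma_2l / (K_3l sigma_2r)),

which reproduces the reference construction exactly; an alternative
closed form that flips the sign on `L_1l` does not, and is
regression-tested as a documented discrepancy.

### Order dichotomy and zeroed coefficients

For n > 3 the condition set is solvable only when n - 3 of the `ae_k`
vanish; a zeroed index drops its conditions (they hold identically) and
its `h` ratio.  Default zeroed indices are `ae_2 .. ae_{n-2}`: indices 0
and 1 are never zeroed by default because the closed-form L/N triple needs
`h_0l, h_1l`, and because `ae_0 = 0` makes `t_hat` a common factor of all
numerators and the denominator, silently reducing the effective order
(an explicit `ae_0 = 0` request emits a warning).  Zero sets may be
overridden within `{2, .., n-1}`.

The infeasibility side of the dichotomy is checked empirically (it does
not follow from naive equation counting): randomized free-choice sets of
the same shape as the feasible zeroed case return no real branch when no
`ae` is zeroed.  The fully square no-zero system (only the two `A_1l`
fixed) is beyond exact elimination in reasonable time and is not part of
the checked conditions.

## Inverse recovery

Given a system and target order, the leading-order conditions say exactly
that the amplitude vector `(sigma_11, sigma_21, sigma_12, sigma_22)` is an
equilibrium of the ODE system — the amplitudes are determined (up to a
finite branch set), not gauge freedom.  Once an equilibrium is fixed,
every auxiliary parameter is an explicit rational function of `eta` alone,
and the remaining coupling conditions are univariate rational equations in
`eta`: the solver takes the exact roots of the first nontrivial numerator
and keeps those on which every condition vanishes.  Each surviving branch
is pushed through the forward assembly map and kept only if it reproduces
the input system bit-exactly.  For n = 1 the L and N triples decouple
(`beta_l` comes from the leading L-equation) and the `h_0l` agreement
between the two triples joins the condition set.

Equilibria are enumerated by elimination: `sigma_2l` is linear in each
x-equation condition and is substituted out; the two y-equation conditions
leave two polynomials in `(sigma_11, sigma_12)`, reduced by a resultant.
Roots of irreducible resultant factors of degree > 2 are not enumerated
(they live in high algebraic extensions and make downstream exact algebra
impractical); a user gauge can pin any subset of the amplitudes and `eta`
to select such branches explicitly.  This is the one known completeness
limitation of ungauged recovery.

Because the `ae_k` and `t0` never enter the system coefficients, recovery
is independent of them; they are free solution-side choices applied by
`recover_solution`, which residual-verifies its output.

## Random instance generator

`generate_fixture(n, seed)` draws free choices as small rationals
(numerators and denominators bounded by a configured magnitude, default
20, the generator's study condition) and solves the remaining conditions
exactly, re-drawing on guard violations or when no all-rational branch
exists (bounded retries; rational branches keep the exact residual checks
fast, and at orders 2-3 the admissible branch is generically rational
anyway).  Amplitudes and `ae_k` are nonzero draws, `eta > 0`.  A single
integer seed drives all draws; identical seeds give identical instances.

What the generator emulates: valid (system, solution) pairs across the
admissible parameter space, including the zeroed-`ae` pattern for n > 3.
What it does not: systems with irrational coefficients, decoupled systems,
the degenerate guard manifolds, or any claim about real biological
parameter ranges — passing tests certify the algebra, not the biology.

## Numerical and design choices

* Exact scalars are sympy numbers; floats are rejected at every input
  boundary (configs require `"p/q"` strings) so serialization round-trips
  bit-exactly.
* `sympy.nsimplify` is never used on exact values (it routes through
  float identification); canonicalisation is `sympy.cancel`.
* Branch ordering (everywhere a branch list is returned) is by the string
  sort of the exact values — deterministic across runs.
* Kink inversion (order-1 single Riccati equation): the two equilibria
  are the t -> +-inf limits; for `eta > 0` the limit at +infinity is the
  dynamically stable root `(-c1 - eta)/(2 c2)`, which fixes `sigma`; the
  free constant `s` then follows from the initial condition.  Initial
  values outside the equilibrium interval give a valid solution with a
  finite-time pole, whose location is reported.
* The acceptance script's targets are the order-3 worked-construction
  ratios and auxiliaries; they are exact rational computations, so the
  script runs in seconds.  Property-level claims live in the test suite
  at the problem sizes stated there (100 seeded instances per order for
  the oracle equivalence, 201 round trips, 6 randomized infeasibility
  draws plus 4 constructed feasible cases at order 4) — sizes chosen to
  exercise the claims densely while keeping exact algebra the dominant
  cost.

## Known limitations

* Ungauged inverse recovery does not enumerate equilibrium branches whose
  minimal polynomial factor has degree > 2 (gauge them explicitly).
* The constructive recipe for dark/bright solutions of the
  multiplicatively coupled pair from arbitrary admissible coefficients is
  out of scope; the pair module checks the existence conditions and the
  inverse-relation uncoupling, and validates supplied solutions.
* Extremum counts of higher-order components are exposed through exact
  root counting of the derivative numerator, but no optimisation over
  free choices to shape extrema is provided.
* `solve_free_constraints` loses solution branches that lie on the
  vanishing locus of a linear-elimination pivot coefficient; such branches
  violate the guard set in all cases observed, but no completeness proof
  is attempted.
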