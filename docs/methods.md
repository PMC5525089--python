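# Methods

This note records the models implemented, the conventions and defaults
chosen where the underlying theory leaves them open, and what the test
fixtures do and do not establish.

## Model

All algebras are finite-dimensional structure-constant algebras: a basis
`a_1..a_n`, a tensor `γ_ijk` over an exact scalar field, and the bilinear
product `(xy)_k = Σ_ij x_i y_j γ_ijk`.  The underlying space is an
ordinary vector space; all of the "left almost" (noncommutative)
structure lives in the multiplication.  The baric weight `ω(x) = Σ_i x_i`
is a homomorphism onto the scalars exactly when every tensor row sums
to 1, which every gametic-family constructor enforces.

Genetic reading: basis elements are gametes (or zygote types), `γ_ijk`
are relative gene frequencies, weight-1 elements are populations, and
multiplication is random mating.  Squaring a population is one
generation of random mating of the population with itself; that is why
idempotents are equilibria.  The theory itself does not fix a dynamical
system — adopting the squaring map `x ↦ x²` is this package's (standard)
choice, and `evolve` implements exactly that and nothing more.

### Exact scalars

Four domains, each with a unique canonical form so equality is a
representation comparison:

* `ℚ` as `fractions.Fraction` (always reduced, positive denominator);
* `ℚ(√d)` as pairs of reduced fractions `p + q√d`; ordering for `d > 0`
  is decided exactly by sign analysis of `p² − d q²`, never by floats;
* `GF(p^k)` as coefficient vectors reduced modulo the (validated
  irreducible) modulus; irreducibility is checked by exhaustive trial
  division by monic polynomials of degree ≤ k/2, which is entirely
  adequate at the degrees used (k ≤ 4) and avoids any factorization
  dependency; inverses are found by search — the fields used are tiny;
* `ℚ(symbols)`, rational functions canonicalized by `sympy.cancel`,
  used to verify parameter-dependent facts (the Gonshor basis products)
  once for all parameter values.  This domain is unordered, so range
  validations (frequencies in [0, 1]) do not apply to it.

`float(...)` on scalars exists only for display and for a sanity oracle
in the tests (exact quadratic arithmetic vs. floating evaluation to
1e−12); no decision in the package depends on a float.

Constructors that need the scalar 1/2 (Mendelian, mutation) reject
fields of characteristic 2 explicitly rather than silently producing
garbage; the GF(2²) constructions (the star algebra) never divide by 2.

### Conventions

* Indices are 1-based in every user-facing label, witness, and error
  message; storage is 0-based.
* Powers are principal (left-normed): `x^1 = x`, `x^{m+1} = x^m x`.
  This is the only convention the power-law identities use.
* Zygote basis order is lexicographic `(i, j)` with `i ≤ j`.
* Change of basis takes a matrix whose **rows** are the new basis
  vectors in old coordinates; an element with new coordinates `c` has
  old coordinates `cM`, and tensors transform so that the round trip
  through `M`, `M⁻¹` is exactly the identity.

## Identity checking

Identities are product trees over variables with power annotations,
organised in chains (a three-way equality is checked pairwise).

* **Multilinear** identities (each variable exactly once per side, no
  powers) are proved by evaluating all `n^arity` basis tuples; by
  multilinearity this determines both sides on all elements.  Requesting
  basis mode for a non-multilinear identity is an error, with the reason
  stated: validity on the basis does not extend when a variable repeats.
* Over finite fields, any identity is proved by exhausting element
  tuples when the tuple count stays under ~3·10⁵ (e.g. all of
  `GF(4)²`-coefficient pairs for dimension-2 fixtures).
* Otherwise identities are checked on seeded exact random **weight-1**
  elements: coordinates are random bounded-denominator fractions (both
  components for `ℚ(√5)`), the last coordinate completing the sum to 1.
  The weight-1 restriction is the genetically meaningful one, and it is
  also what makes the flexibility/Jordan facts about the star algebra
  true: `X⋆X = X` holds there only when the coefficients sum to 1.
  Sampled verdicts are reported as `holds-on-sample`, never `holds`.

Failure reports always carry the witness assignment (in basis labels
when possible) and both evaluated sides; `recheck_counterexample()`
re-evaluates it, and the tests assert every reported witness
revalidates.

The derived-identity suite (`x²y = yx²`, power associativity and its
relatives, `(ab)(cd) = (db)(ca) = (dc)(ba)`, the generalized Jordan
family `(x^m y)x^n = x^m(y x^n)`) is a set of consequences derived for
**LA alternative** algebras.  The classifier therefore gates it: unless
the left invertive law and both alternative laws hold, these identities
are reported `not-applicable` rather than pass/fail.  The star algebras
fail the alternative laws, so for them the suite is gated off; the
positive fixture for the suite is a commutative associative (diagonal)
algebra over GF(2²), where every identity is verified exhaustively.  No
richer LA-alternative example is known to this package, and it does not
invent one.  Power-parametrized laws are instantiated up to a `depth`
bound on exponents, default 3 — enough to exercise the `m ≥ 2` / `n ≥ 2`
edge conditions without blowing up term sizes.  The generalized Jordan
family is instantiated for `m ≥ 1, n ≥ 2`.

`find_left_identity` solves the exact linear system `e·a_j = a_j` (n²
equations); if the solved system is underdetermined the particular
solution with free variables zero is verified before being returned.

## Constructors and completions

Two places required a decision the source theory leaves implicit:

* **R² completion.**  The mutation algebra is specified by its `D²` and
  `DR` rows, together with the assertion that `b = D − R` satisfies
  `b² = 0`.  Writing `R² = uD + vR` and expanding
  `b² = D² − 2DR + R²` gives `u = s`, `v = 1 − s` as the *unique*
  commutative completion with `b² = 0`; it is also the mirror of the
  `D²` row under swapping the roles of `D, R` and `r, s`.  The package
  uses `R² = sD + (1−s)R`, and the symbolic test verifies the Gonshor
  products coefficient-for-coefficient in `(r, s)`.
* **Duplication coefficients.**  The zygotic product is specified only
  as "commutative duplication".  The package uses the classical rule:
  mating `e_ij × e_pq` draws one gamete from each parental offspring
  distribution `a_i a_j` and `a_p a_q` independently and pairs them, so

      γ_{ij,pq,(k,s)} = γ_ijk γ_pqs + γ_ijs γ_pqk   (k < s),
                        γ_ijk γ_pqk                 (k = s).

  Row-stochasticity is inherited (`(Σγ_ij·)(Σγ_pq·) = 1`), and the
  2-allele Mendelian case reproduces the 1:2:1 heterozygote-cross ratio
  and the Hardy–Weinberg idempotent surface, both asserted in tests.

The LA-gametic variant differs from the classical gametic constraints
only by dropping the symmetry `γ_ijk = γ_jik`; exactly that printed
difference is implemented, nothing more.  The star algebra supports both
scalar homes for `α` (the golden roots in `ℚ(√5)`, and `t` or `t²` in
GF(2²)); the package privileges neither and tests both.

### Synthetic fixtures

`random_gametic(n, seed, la_variant, denominator_bound)` draws each
product distribution as a uniform random composition of
`denominator_bound` (default 12) into `n` parts, giving exact fractions
with a common denominator, rows summing to 1, entries in [0, 1].
Without `la_variant` only `i ≤ j` rows are drawn and mirrored.  This
emulates *valid* relative-frequency tables of arbitrary inheritance
systems; it does not emulate any biological linkage/selection structure,
so tests on these fixtures establish algebraic correctness (bilinearity,
weight homomorphism, validation, duplication) — not genetic realism.
Determinism: one `random.Random(seed)` per call; the same seed gives
byte-identical JSON artifacts.

## Equilibria and dynamics

`find_idempotents` solves `x∘x = x` exactly:

* finite fields: exhaustive enumeration of all coefficient vectors
  (optionally restricted to weight 1) — a proof;
* otherwise symbolically via sympy for dimension ≤ 3.  The weight
  constraint is eliminated first (substituting
  `x_n = 1 − x_1 − … − x_{n−1}`): positive-dimensional solution
  varieties — the whole simplex for the Mendelian algebra, the
  Hardy–Weinberg curve for the zygotic algebra — defeat the general
  polynomial solver but fall out directly after the substitution.
  Continua are reported as their defining parametrization plus at least
  3 exact sample points; solution branches leaving the scalar field
  (e.g. radical parameter values) are skipped, not approximated.  Every
  returned point is re-verified by substitution into the exact product;
  the residual `x∘x − x` is asserted to be exactly zero.

`evolve` iterates `x ↦ x²` exactly.  On ordered fields a convergence
flag is set when successive iterates differ by less than `tol`
(default 10⁻⁹, max-norm, compared exactly after rationalizing the
tolerance); the flag never alters the iterates.  For the mutation
algebra the weight-0 coordinate obeys the affine recurrence
`β_{m+1} = (1−r−s)β_m − r`, so denominators grow geometrically — not
doubly exponentially — and a few hundred exact generations are cheap.
The convergence tests cap trajectories at 600 generations, comfortably
beyond the worst contraction ratio `7/8` that the eighth-denominator
rate grid used there can produce.

`distance_to_set` is the max-norm distance to the nearest returned
point; when a continuum's description reduces to a single affine
constraint `a·y = c`, the exact distance `|a·x − c| / Σ|a_i|` is used
instead.  For general curved continua (Hardy–Weinberg) the sample-point
distance is an upper bound, and is documented as such.

## Problem sizes

The test suite proves the left invertive law basis-exhaustively for the
star algebras at `n = 2..6` over both scalar domains, exhausts GF(2²)
and GF(3²) for the field axioms, exhausts all element tuples of the
dimension-2 GF(4) fixtures, and samples 100–200 exact weight-1 elements
for the non-multilinear star-algebra identities.  These sizes make every
exhaustive claim a genuine proof at desk scale while keeping the whole
suite fast.

## Limitations

* Non-multilinear verdicts over infinite fields are sample-based
  (`holds-on-sample`); the package proves them only over small finite
  fields.  It verifies instances, not theorems.
* Symbolic idempotent search stops at dimension 3; larger algebras need
  a finite field or externally supplied candidate points.
* No stability/eigenvalue analysis of equilibria, no selection models,
  no train/Bernstein/copular constructions.
* The identity catalog is fixed (the LA/flexible/alternative/Jordan
  family); Bol/Moufang-type laws are out of scope.
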