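# laalg — exact left almost algebras of genetic inheritance

`laalg` is a library and CLI for building and analysing the nonassociative
algebras that model genetic inheritance, with **exact arithmetic
throughout**: no floating point ever touches a structure constant, an
identity verdict, or an equilibrium.

It is aimed at people working in algebraic genetics / algebraic biology who
want machine-checked instances of structural claims about these algebras —
which identities hold, where the population equilibria sit — rather than
numerical simulation.

## The algebras

A *gametic algebra* puts the `n` alleles of a locus on a basis
`a_1, …, a_n` and encodes random mating in the bilinear product

```
a_i a_j = Σ_k γ_ijk a_k ,     Σ_k γ_ijk = 1 ,   0 ≤ γ_ijk ≤ 1 ,
```

where `γ_ijk` are relative gene frequencies.  The coefficient sum is the
baric *weight* homomorphism; weight-1 elements are populations.  The
package covers:

* **Mendelian gametic algebra** `a_i a_j = ½(a_i + a_j)` and its *zygotic*
  algebra obtained by commutative duplication onto genotype pairs `e_ij`;
* **Gonshor's mutation algebra** on `(D, R)` with mutation rates `r`
  (D→R) and `s` (R→D): `D² = (1−r)D + rR`,
  `DR = ½(1−r+s)D + ½(1−s+r)R`, and in the basis `a = D, b = D − R`:
  `a² = a − rb`, `ab = ½(1−r−s)b`, `b² = 0`;
* the **left almost (LA) star algebra** `M_n` with
  `a_i ⋆ a_j = α a_i + α² a_j` for any exact scalar with `α + α² = 1` —
  the golden roots `(−1 ± √5)/2` in `ℚ(√5)`, or the generator `t` of
  `GF(2²) = ℤ₂[t]/(t² + t + 1)`.  `M_n` is noncommutative and
  nonassociative yet satisfies the *left invertive law* `(ab)c = (cb)a`,
  and on weight-1 elements (where `x² = x`) it is flexible and generalized
  Jordan;
* arbitrary and seeded-random gametic tensors, including the
  noncommutative LA-gametic variant that drops `γ_ijk = γ_jik`.

The identity checker *proves* multilinear identities on a finite-
dimensional algebra by exhausting basis tuples, proves arbitrary
identities over small finite fields by exhausting elements, and otherwise
samples exact random weight-1 elements (seeded).  Every failure comes with
a witness that re-evaluates to unequal elements.  Idempotents `x² = x` —
the fixed points of the random-mating map, i.e. the population
equilibria — are found symbolically (dimension ≤ 3) or exhaustively
(finite fields), and verified by substitution.

## Worked example

```python
from fractions import Fraction
import laalg as la

M4 = la.star_algebra(4)                      # alpha = (-1+sqrt5)/2
print("LA law:", la.check_identity(M4, "left_invertive").verdict)
print("commutative:", la.check_identity(M4, "commutative").verdict)
print("flexible on 100 weight-1 samples:",
      la.check_identity(M4, "flexible", mode="weight1-sample",
                        sample_size=100, seed=1).verdict)

Mu = la.mutation_algebra(Fraction(1, 4), Fraction(1, 2))
eq = la.find_idempotents(Mu, weight1=True)
print("mutation equilibrium:", eq.points[0])
traj = la.evolve(Mu, Mu.basis_element(1), 30)
print("from pure D, converged:", traj.converged,
      "after", traj.generations, "generations")

Z, idx = la.zygotic_duplicate(la.mendelian_gametic(2))
e12 = Z.basis_element(idx.position(1, 2))
print("Aa x Aa offspring:", e12 * e12)
```

prints

```
LA law: holds
commutative: fails
flexible on 100 weight-1 samples: holds-on-sample
mutation equilibrium: (2/3)*D + (1/3)*R
from pure D, converged: True after 15 generations
Aa x Aa offspring: (1/4)*e11 + (1/2)*e12 + (1/4)*e22
```

`holds` for the left invertive law is a proof (the identity is multilinear
and all `4³` basis triples were checked); `fails` comes with a concrete
counterexample.  The mutation equilibrium `(2/3)D + (1/3)R` is the exact
point `(s/(r+s), r/(r+s))`, and repeated random mating from a pure-`D`
population converges to it geometrically with ratio `|1 − r − s| = 1/4`.
The `¼ : ½ : ¼` zygote distribution is the Mendelian 1:2:1 ratio of a
heterozygote cross, and the weight-1 idempotents of the zygotic algebra
are exactly the Hardy–Weinberg states `(p², 2pq, q²)`.

The same operations are available from the shell:

```
laalg make star --n 3 --field qsqrt5 --out m3.json
laalg check --in m3.json --identity left_invertive --mode basis
laalg make mutation --r 1/4 --s 1/2 --out mu.json
laalg idempotents --in mu.json --weight1
laalg evolve --in mu.json --x0 "1,0" --gens 30 --out trajectory.csv
```

Algebras cross the CLI boundary in a JSON exchange format with scalars as
exact strings (`"3/4"`, `{"a": "-1/2", "b": "1/2"}`, coefficient lists);
see `laalg/io.py` for the schema.

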