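"""Named constructors for the genetic algebras, plus a seeded fixture generator.

Covered models:

* ``mendelian_gametic``: n alleles with a_i a_j = (1/2)(a_i + a_j) — simple
  Mendelian inheritance, the basic baric algebra of population genetics.
* ``gametic_from_tensor``: a general gametic algebra from arbitrary relative
  gene frequencies gamma_ijk (row sums 1, entries in [0,1]); with
  ``la_variant=True`` the commutativity constraint gamma_ijk = gamma_jik is
  dropped, giving the noncommutative ("left almost") gametic generalization.
* ``random_gametic``: seeded random valid gametic tensors (synthetic fixtures).
* ``zygotic_duplicate``: commutative duplication of a gametic algebra onto
  the zygote basis e_ij (i <= j), the Etherington construction.
* ``mutation_algebra`` / ``gonshor_basis``: Gonshor's two-allele mutation
  algebra with rates r (D -> R) and s (R -> D), and its (a, b) = (D, D - R)
  basis in which a^2 = a - r b, ab = (1/2)(1 - r - s) b, b^2 = 0.
* ``star_algebra``: the left almost algebra M_n with a_i * a_j =
  alpha a_i + alpha^2 a_j for any scalar with alpha + alpha^2 = 1 — the
  golden roots (-1 +- sqrt 5)/2 over Q(sqrt 5), or t in GF(2^2).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction
from typing import Optional, Sequence, Tuple

from .algebra import Algebra, AlgebraError, StructureTensor, change_of_basis
from .fields import Field, FieldElement, FieldError, QQ, QuadraticField, golden_alpha

__all__ = [
    "MutationParams",
    "DuplicationIndex",
    "mendelian_gametic",
    "gametic_from_tensor",
    "random_gametic",
    "zygotic_duplicate",
    "mutation_algebra",
    "gonshor_basis",
    "star_algebra",
    "ConstructorError",
]


class ConstructorError(ValueError):
    pass


def _require_char_not_2(field: Field, what: str):
    if field.characteristic == 2:
        raise ConstructorError(
            f"{what} needs the scalar 1/2, which does not exist in "
            f"characteristic 2; choose a field of characteristic != 2"
        )


# ---------------------------------------------------------------------------
# Gametic algebras
# ---------------------------------------------------------------------------


def mendelian_gametic(n: int = 2, field: Optional[Field] = None) -> Algebra:
    """The n-allele Mendelian gametic algebra: a_i a_j = (1/2)(a_i + a_j).

    Row-stochastic and gametic-symmetric; every weight-1 element is
    idempotent (x^2 = x when the allele frequencies sum to 1), so the whole
    population simplex is an equilibrium set under random mating.
    """
    if n < 2:
        raise ConstructorError(f"need at least 2 alleles, got n={n}")
    field = field or QQ
    _require_char_not_2(field, "the Mendelian gametic algebra")
    half = field.coerce(field.div(field.one_raw, field.from_int(2)))
    zero = field.zero_raw
    entries = [
        [
            [
                field.add(half if k == i else zero, half if k == j else zero)
                for k in range(n)
            ]
            for j in range(n)
        ]
        for i in range(n)
    ]
    return Algebra(
        field,
        [f"a{i}" for i in range(1, n + 1)],
        StructureTensor(field, entries),
        {"constructor": "mendelian_gametic", "n": n},
    )


def gametic_from_tensor(
    gamma, field: Optional[Field] = None, la_variant: bool = False
) -> Algebra:
    """Validate and build a gametic algebra from structure constants.

    Constraints: every row sum sum_k gamma_ijk = 1; on ordered fields every
    entry lies in [0, 1] (they are relative gene frequencies); and unless
    ``la_variant`` is set, the symmetry gamma_ijk = gamma_jik.  The LA
    variant keeps the frequency constraints but permits noncommutative
    multiplication tables.
    """
    field = field or QQ
    tensor = gamma if isinstance(gamma, StructureTensor) else StructureTensor(field, gamma)
    if tensor.field != field:
        raise ConstructorError("tensor scalars do not belong to the given field")
    n = tensor.n
    one = field.one_raw
    problems = []
    for i in range(1, n + 1):
        for j in range(1, n + 1):
            rs = tensor.row_sum(i, j)
            if rs.raw != one:
                problems.append(
                    f"row (i={i}, j={j}) sums to {field.format(rs.raw)}, not 1"
                )
    if field.is_ordered:
        for i in range(1, n + 1):
            for j in range(1, n + 1):
                for k in range(1, n + 1):
                    v = tensor.gamma(i, j, k)
                    if v < 0 or v > 1:
                        problems.append(
                            f"gamma({i},{j},{k}) = {field.format(v.raw)} "
                            "outside [0, 1]"
                        )
    if not la_variant:
        for i in range(1, n + 1):
            for j in range(i + 1, n + 1):
                for k in range(1, n + 1):
                    if tensor.gamma(i, j, k) != tensor.gamma(j, i, k):
                        problems.append(
                            f"symmetry gamma({i},{j},{k}) = gamma({j},{i},{k}) "
                            f"violated: {field.format(tensor.gamma(i, j, k).raw)}"
                            f" != {field.format(tensor.gamma(j, i, k).raw)} "
                            "(use la_variant=True for the noncommutative form)"
                        )
    if problems:
        raise ConstructorError(
            "invalid gametic structure constants:\n  " + "\n  ".join(problems)
        )
    return Algebra(
        field,
        [f"a{i}" for i in range(1, n + 1)],
        tensor,
        {"constructor": "gametic_from_tensor", "la_variant": la_variant},
    )


def random_gametic(
    n: int,
    field: Optional[Field] = None,
    seed: int = 0,
    la_variant: bool = False,
    denominator_bound: int = 12,
) -> Algebra:
    """A seeded random valid gametic algebra (the synthetic fixture source).

    Each product distribution gamma_ij. is drawn as a uniform random
    composition of ``denominator_bound`` into n nonnegative parts, so every
    entry is an exact fraction with denominator ``denominator_bound``, lies
    in [0, 1], and each row sums to 1.  Without ``la_variant`` only the
    i <= j rows are drawn and mirrored (commutative); with it all rows are
    drawn independently, which breaks the symmetry with high probability.
    """
    if field is not None and field != QQ:
        raise ConstructorError("random gametic tensors are generated over Q")
    field = QQ
    if n < 2:
        raise ConstructorError(f"need at least 2 alleles, got n={n}")
    d = int(denominator_bound)
    if d < 1:
        raise ConstructorError("denominator_bound must be >= 1")
    rng = random.Random(seed)

    def draw_row():
        # stars-and-bars: cut [0, d] at n-1 points -> composition of d
        cuts = sorted(rng.randint(0, d) for _ in range(n - 1))
        parts = []
        prev = 0
        for c in cuts:
            parts.append(c - prev)
            prev = c
        parts.append(d - prev)
        return [Fraction(p, d) for p in parts]

    entries = [[None] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            if la_variant or i <= j:
                entries[i][j] = draw_row()
    if not la_variant:
        for i in range(n):
            for j in range(i):
                entries[i][j] = entries[j][i]
    alg = gametic_from_tensor(
        StructureTensor(field, entries), field, la_variant=la_variant
    )
    alg.provenance.update(
        {
            "constructor": "random_gametic",
            "seed": seed,
            "la_variant": la_variant,
            "denominator_bound": d,
            "n": n,
        }
    )
    return alg


# ---------------------------------------------------------------------------
# Zygotic duplication
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DuplicationIndex:
    """Maps zygote basis positions to gamete index pairs (i, j), i <= j,
    in lexicographic order; 1-based like all public indices."""

    pairs: Tuple[Tuple[int, int], ...]

    def label(self, pos: int) -> str:
        i, j = self.pairs[pos - 1]
        return f"e{i}{j}" if j <= 9 else f"e{i}_{j}"

    def position(self, i: int, j: int) -> int:
        """1-based position of the pair (min(i,j), max(i,j))."""
        key = (min(i, j), max(i, j))
        return self.pairs.index(key) + 1


def zygotic_duplicate(G: Algebra) -> Tuple[Algebra, DuplicationIndex]:
    """Commutative duplication: the zygotic algebra of a gametic algebra.

    Zygotes e_ij (i <= j) are unordered gamete pairs.  Mating e_ij x e_pq
    draws one gamete from each parental distribution a_i a_j and a_p a_q
    and pairs them, so the offspring frequency of zygote e_ks is the
    symmetrized product

        gamma_ijk gamma_pqs + gamma_ijs gamma_pqk   (k < s)
        gamma_ijk gamma_pqk                         (k = s).

    Row-stochasticity is inherited: the duplicated row sums are products of
    unit row sums.
    """
    if not G.tensor.is_row_stochastic():
        raise ConstructorError(
            "zygotic duplication requires a row-stochastic gametic algebra"
        )
    f = G.field
    n = G.n
    pairs = tuple((i, j) for i in range(1, n + 1) for j in range(i, n + 1))
    index = DuplicationIndex(pairs)
    N = len(pairs)
    g = G.tensor.gamma

    def dup_coeff(ij, pq, ks):
        (i, j), (p, q), (k, s) = ij, pq, ks
        if k == s:
            return (g(i, j, k) * g(p, q, k)).raw
        return (g(i, j, k) * g(p, q, s) + g(i, j, s) * g(p, q, k)).raw

    entries = [
        [[dup_coeff(pairs[a], pairs[b], pairs[c]) for c in range(N)]
         for b in range(N)]
        for a in range(N)
    ]
    labels = [index.label(pos) for pos in range(1, N + 1)]
    Z = Algebra(
        f,
        labels,
        StructureTensor(f, entries),
        {
            "constructor": "zygotic_duplicate",
            "gametic": G.provenance.get("constructor", "unknown"),
            "n_gametes": n,
        },
    )
    return Z, index


# ---------------------------------------------------------------------------
# Mutation algebra (Gonshor)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MutationParams:
    """Mutation rates: r is the D -> R rate, s the R -> D rate."""

    r: Fraction
    s: Fraction


def mutation_algebra(
    r, s, field: Optional[Field] = None
) -> Algebra:
    """Gonshor's 2-dimensional mutation algebra on the basis (D, R).

        D^2 = (1 - r) D + r R
        DR  = RD = (1/2)(1 - r + s) D + (1/2)(1 - s + r) R
        R^2 = s D + (1 - s) R

    The R^2 row mirrors the D^2 row with the reverse rate s; it is the
    unique commutative completion under which b = D - R satisfies b^2 = 0
    (see the methods note).  On ordered fields the rates must lie in [0, 1].
    """
    field = field or QQ
    _require_char_not_2(field, "the mutation algebra")
    r_el = FieldElement(field, field.coerce(r))
    s_el = FieldElement(field, field.coerce(s))
    if field.is_ordered:
        for name, v in (("r", r_el), ("s", s_el)):
            if v < 0 or v > 1:
                raise ConstructorError(
                    f"mutation rate {name} = {field.format(v.raw)} outside [0, 1]"
                )
    one = field.one
    half = one / 2
    dd = [one - r_el, r_el]
    dr = [half * (one - r_el + s_el), half * (one - s_el + r_el)]
    rr = [s_el, one - s_el]
    entries = [[dd, dr], [dr, rr]]
    return Algebra(
        field,
        ["D", "R"],
        StructureTensor(field, [[[c.raw for c in row] for row in plane]
                                for plane in entries]),
        {
            "constructor": "mutation_algebra",
            "r": field.format(r_el.raw),
            "s": field.format(s_el.raw),
        },
    )


def gonshor_basis(Mu: Algebra) -> Algebra:
    """Change the mutation algebra to the basis a = D, b = D - R.

    In this basis the products collapse to a^2 = a - r b,
    ab = ba = (1/2)(1 - r - s) b, b^2 = 0: the weight functional is carried
    entirely by a, and b spans the weight-0 direction along which mutation
    pressure acts.
    """
    if Mu.provenance.get("constructor") != "mutation_algebra":
        raise ConstructorError("gonshor_basis expects a mutation_algebra output")
    f = Mu.field
    one, zero = f.one_raw, f.zero_raw
    M = [[one, zero], [one, f.neg(one)]]  # a = D, b = D - R
    out = change_of_basis(Mu, M, ["a", "b"])
    out.provenance.update(
        {
            "constructor": "gonshor_basis",
            "r": Mu.provenance.get("r"),
            "s": Mu.provenance.get("s"),
        }
    )
    return out


# ---------------------------------------------------------------------------
# Star (left almost) algebra M_n
# ---------------------------------------------------------------------------


def star_algebra(n: int, field: Optional[Field] = None, alpha=None) -> Algebra:
    """The left almost algebra M_n: a_i * a_j = alpha a_i + alpha^2 a_j.

    Requires alpha + alpha^2 = 1 exactly, which forces every basis element
    (indeed every weight-1 element) to be idempotent.  Valid choices: the
    golden roots (-1 +- sqrt 5)/2 in Q(sqrt 5) (the default), or the
    generator t (and t^2) in GF(2^2) where t^2 + t + 1 = 0.

    Noncommutative and nonassociative for n >= 2, yet it satisfies the left
    invertive law (ab)c = (cb)a basis-exhaustively — the defining LA
    property.
    """
    if n < 1:
        raise ConstructorError(f"dimension must be >= 1, got n={n}")
    if alpha is None:
        alpha = golden_alpha(+1)
    if isinstance(alpha, FieldElement):
        if field is None:
            field = alpha.field
        elif field != alpha.field:
            raise ConstructorError("alpha does not belong to the given field")
        a_raw = alpha.raw
    else:
        if field is None:
            raise ConstructorError("a bare alpha value needs an explicit field")
        a_raw = field.coerce(alpha)
    a = FieldElement(field, a_raw)
    if a + a * a != field.one:
        raise ConstructorError(
            f"alpha = {field.format(a_raw)} violates the defining constraint "
            "alpha + alpha^2 = 1"
        )
    a2 = (a * a).raw
    zero = field.zero_raw
    entries = [
        [
            [
                field.add(a_raw if k == i else zero, a2 if k == j else zero)
                for k in range(n)
            ]
            for j in range(n)
        ]
        for i in range(n)
    ]
    return Algebra(
        field,
        [f"a{i}" for i in range(1, n + 1)],
        StructureTensor(field, entries),
        {
            "constructor": "star_algebra",
            "n": n,
            "alpha": field.format(a_raw),
            "field": field.spec_json(),
        },
    )
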