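"""Population equilibria (idempotents) and random-mating dynamics.

A weight-1 element of a baric genetic algebra is a population; squaring it
is one round of random mating (the offspring distribution of a population
mated with itself).  Fixed points of the squaring map — idempotents
x^2 = x — are therefore the population equilibria: the whole simplex for
the Mendelian gametic algebra (one round of random mating changes
nothing), the Hardy-Weinberg surface (p^2, 2pq, q^2) for the zygotic
algebra, and the single point (s/(r+s), r/(r+s)) on (D, R) for the
mutation algebra with rates r + s > 0.

Idempotents are found exactly: symbolically (sympy) for dimension <= 3 on
infinite fields, exhaustively over all vectors on finite fields.  The
trajectory iterator keeps every iterate exact; the convergence tolerance
only sets a flag.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field as dc_field
from fractions import Fraction
from typing import List, Optional

import sympy

from .algebra import Algebra, AlgebraElement, multiply
from .fields import FieldElement, FieldError

__all__ = [
    "EquilibriumSet",
    "Trajectory",
    "find_idempotents",
    "evolve",
    "distance_to_set",
    "DynamicsError",
]


class DynamicsError(ValueError):
    pass


@dataclass
class EquilibriumSet:
    """Idempotents of an algebra, exact.

    ``kind`` is ``isolated`` (finitely many points, all listed),
    ``continuum`` (positive-dimensional solution variety: the defining
    polynomial constraints are reported along with exact sample points), or
    ``none-found``.
    """

    kind: str
    points: List[AlgebraElement]
    constraints: List[str] = dc_field(default_factory=list)
    free_parameters: int = 0
    weight1: bool = True

    def to_json(self) -> dict:
        out = {
            "kind": self.kind,
            "weight1": self.weight1,
            "points": [
                [p.algebra.field.format(c) for c in p.coeffs] for p in self.points
            ],
        }
        if self.constraints:
            out["constraints"] = self.constraints
            out["free_parameters"] = self.free_parameters
        return out


@dataclass
class Trajectory:
    """Iterates of the random-mating (squaring) map, all exact."""

    points: List[AlgebraElement]
    converged: bool
    limit: Optional[AlgebraElement] = None

    @property
    def generations(self) -> int:
        return len(self.points) - 1


def _verify_idempotent(A: Algebra, x: AlgebraElement) -> bool:
    return multiply(A, x, x) == x


# ---------------------------------------------------------------------------
# Idempotent finding
# ---------------------------------------------------------------------------


def _find_idempotents_exhaustive(A: Algebra, weight1: bool) -> EquilibriumSet:
    f = A.field
    one = f.one_raw
    points = []
    for combo in itertools.product(f.elements_raw(), repeat=A.n):
        x = AlgebraElement(A, combo)
        if weight1 and x.weight().raw != one:
            continue
        if _verify_idempotent(A, x):
            points.append(x)
    kind = "isolated" if points else "none-found"
    return EquilibriumSet(kind=kind, points=points, weight1=weight1)


_PARAM_VALUES = [sympy.Integer(0), sympy.Integer(1), sympy.Rational(1, 2),
                 sympy.Integer(2), sympy.Rational(1, 3), sympy.Rational(-1, 2)]


def _element_from_sympy(A: Algebra, vec) -> Optional[AlgebraElement]:
    try:
        return AlgebraElement(A, [A.field.from_sympy(v) for v in vec])
    except (FieldError, ValueError, TypeError):
        return None  # solution lies outside the scalar field


def _idempotent_equations(A: Algebra, xs):
    """The n polynomial components of x x - x as sympy expressions."""
    f = A.field
    n = A.n
    gamma = A.tensor.entries
    eqs = []
    for k in range(n):
        expr = -xs[k]
        for i in range(n):
            for j in range(n):
                gk = f.to_sympy(gamma[i][j][k])
                if gk != 0:
                    expr += xs[i] * xs[j] * gk
        eqs.append(sympy.expand(expr))
    return eqs


def _collect_solutions(A, xs, sols, exact_points, constraints):
    """Sort solved branches into exact points vs parametrized continua."""
    max_free = 0
    for vec in sols:
        free = set().union(*(v.free_symbols for v in vec)) & set(xs)
        if not free:
            el = _element_from_sympy(A, vec)
            if el is not None and _verify_idempotent(A, el):
                if el not in exact_points:
                    exact_points.append(el)
            continue
        max_free = max(max_free, len(free))
        desc = ", ".join(
            f"{x} = {v}" for x, v in zip(xs, vec) if v != x
        )
        constraints.append(desc if desc else "all coordinates free")
        free_list = sorted(free, key=lambda s: s.name)
        samples_added = 0
        for values in itertools.product(_PARAM_VALUES, repeat=len(free_list)):
            subs = dict(zip(free_list, values))
            cand = [sympy.together(v.subs(subs)) for v in vec]
            el = _element_from_sympy(A, cand)
            if el is not None and _verify_idempotent(A, el):
                if el not in exact_points:
                    exact_points.append(el)
                    samples_added += 1
            if samples_added >= 3:
                break
    return max_free


def _find_idempotents_symbolic(A: Algebra, weight1: bool) -> EquilibriumSet:
    n = A.n
    if n > 3:
        raise DynamicsError(
            f"symbolic idempotent search supports dimension <= 3 (got {n}); "
            "use a finite field (exhaustive search) or pick candidate points "
            "and verify with the algebra product"
        )
    f = A.field
    xs = sympy.symbols(f"x1:{n + 1}")
    eqs = _idempotent_equations(A, xs)

    exact_points: List[AlgebraElement] = []
    constraints: List[str] = []
    max_free = 0

    if weight1:
        # eliminate the weight constraint first: positive-dimensional
        # varieties (the whole simplex, the Hardy-Weinberg surface) defeat
        # the general solver but fall out after the substitution
        sub = {xs[-1]: 1 - sympy.Add(*xs[:-1])}
        reduced = [sympy.expand(e.subs(sub)) for e in eqs]
        reduced = [e for e in reduced if e != 0]
        if not reduced:
            # every weight-1 element is idempotent
            constraints.append(f"{xs[-1]} = {sympy.expand(sub[xs[-1]])}")
            max_free = n - 1
            for i in range(1, n + 1):
                el = A.basis_element(i)
                if _verify_idempotent(A, el) and el not in exact_points:
                    exact_points.append(el)
                if len(exact_points) >= 3:
                    break
        else:
            sols2 = sympy.solve(reduced, list(xs[:-1]), dict=True)
            vecs = []
            for sol in sols2:
                head = [sympy.together(sol.get(x, x)) for x in xs[:-1]]
                tail = sympy.together(sympy.expand(1 - sympy.Add(*head)))
                vecs.append(head + [tail])
            max_free = _collect_solutions(A, xs, vecs, exact_points, constraints)
    else:
        sols = sympy.solve(eqs, list(xs), dict=True)
        vecs = [[sympy.together(sol.get(x, x)) for x in xs] for sol in sols]
        max_free = _collect_solutions(A, xs, vecs, exact_points, constraints)
        zero = A.zero()  # always idempotent; keep it even if the solver balks
        if _verify_idempotent(A, zero) and zero not in exact_points:
            exact_points.append(zero)

    if max_free > 0:
        kind = "continuum"
    elif exact_points:
        kind = "isolated"
    else:
        kind = "none-found"
    return EquilibriumSet(
        kind=kind,
        points=exact_points,
        constraints=constraints,
        free_parameters=max_free,
        weight1=weight1,
    )


def find_idempotents(
    A: Algebra, weight1: bool = True, method: str = "auto"
) -> EquilibriumSet:
    """All solutions of x x = x, exactly (optionally restricted to weight 1).

    ``method='symbolic'`` solves the quadratic system with sympy (dimension
    <= 3); ``method='exhaustive'`` enumerates all coefficient vectors
    (finite fields only); ``'auto'`` picks whichever applies.  Every
    returned point is re-verified by substitution into the exact product.
    """
    if method == "auto":
        method = "exhaustive" if A.field.is_finite else "symbolic"
    if method == "exhaustive":
        if not A.field.is_finite:
            raise DynamicsError("exhaustive idempotent search needs a finite field")
        if A.field.order ** A.n > 5_000_000:
            raise DynamicsError("element space too large for exhaustive search")
        return _find_idempotents_exhaustive(A, weight1)
    if method == "symbolic":
        if A.field.is_finite:
            return _find_idempotents_exhaustive(A, weight1)
        return _find_idempotents_symbolic(A, weight1)
    raise DynamicsError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Random-mating trajectories
# ---------------------------------------------------------------------------


def evolve(
    A: Algebra,
    x0: AlgebraElement,
    generations: int,
    tol: float | Fraction = Fraction(1, 10**9),
) -> Trajectory:
    """Iterate the random-mating map x -> x^2 for a number of generations.

    Iterates are exact.  On ordered fields the convergence flag is set when
    two successive iterates differ by less than ``tol`` in max-norm (an
    exact comparison against the rationalized tolerance); the flag stops
    the iteration early and the last iterate is reported as the limit
    estimate.
    """
    if generations < 1:
        raise DynamicsError("need at least one generation")
    tol_f = Fraction(tol) if not isinstance(tol, Fraction) else tol
    f = A.field
    tol_raw = None
    if f.is_ordered:
        tol_raw = f.coerce(Fraction(tol_f))
    points = [x0]
    converged = False
    x = x0
    for _ in range(generations):
        nxt = multiply(A, x, x)
        points.append(nxt)
        if f.is_ordered:
            diff_max = None
            for a, b in zip(nxt.coeffs, x.coeffs):
                d = abs(FieldElement(f, f.sub(a, b)))
                if diff_max is None or d > diff_max:
                    diff_max = d
            if diff_max is not None and diff_max < FieldElement(f, tol_raw):
                converged = True
                x = nxt
                break
        elif nxt == x:  # exact fixed point on unordered fields
            converged = True
            x = nxt
            break
        x = nxt
    return Trajectory(points=points, converged=converged,
                      limit=points[-1] if converged else None)


# ---------------------------------------------------------------------------
# Distance to an equilibrium set
# ---------------------------------------------------------------------------


def _linear_constraint_distance(x: AlgebraElement, E: EquilibriumSet):
    """Exact max-norm distance to a single linear constraint a.y = c, if the
    continuum's defining equations reduce to one; else None.

    For one affine constraint the max-norm projection shifts every
    coordinate equally: dist = |a.x - c| / sum_i |a_i|.
    """
    A = x.algebra
    n = A.n
    xs = sympy.symbols(f"x1:{n + 1}", real=True)
    # reconstruct the variety: the parametrized descriptions in E.constraints
    # came from solved systems; the weight-1 Mendelian case is the variety
    # sum x_i = 1.  Detect it via the stored parametrization: a single bound
    # coordinate, affine in the free ones.
    if len(E.constraints) != 1 or E.free_parameters != A.n - 1:
        return None
    desc = E.constraints[0]
    if "=" not in desc:
        return None
    lhs_name, rhs_str = desc.split("=", 1)
    try:
        bound = sympy.Symbol(lhs_name.strip(), real=True)
        rhs = sympy.sympify(rhs_str, locals={s.name: s for s in xs})
    except (sympy.SympifyError, TypeError):
        return None
    residual = bound - rhs  # = 0 on the variety
    try:
        poly = sympy.Poly(residual, *xs)
    except sympy.PolynomialError:
        return None  # non-polynomial (radical) parametrization
    if poly.total_degree() > 1:
        return None
    f = A.field
    coeffs = [poly.coeff_monomial(s) for s in xs]
    const = poly.coeff_monomial(1)
    acc = f.coerce(Fraction(int(sympy.nsimplify(const).p),
                            int(sympy.nsimplify(const).q)))
    denom = f.zero_raw
    for c, xi in zip(coeffs, x.coeffs):
        cr = f.coerce(Fraction(int(sympy.Rational(c).p), int(sympy.Rational(c).q)))
        acc = f.add(acc, f.mul(cr, xi))
        denom = f.add(denom, abs(FieldElement(f, cr)).raw)
    if denom == f.zero_raw:
        return None
    return abs(FieldElement(f, acc)) / FieldElement(f, denom)


def distance_to_set(x: AlgebraElement, E: EquilibriumSet) -> FieldElement:
    """Max-norm distance from x to the equilibrium set, exact.

    For isolated sets: the distance to the nearest listed point.  For a
    continuum whose description reduces to a single linear constraint the
    exact distance to the affine variety is used; otherwise the nearest
    listed sample point bounds it from above.
    """
    A = x.algebra
    f = A.field
    if not f.is_ordered:
        raise DynamicsError("distance needs an ordered field (finite fields "
                            "carry no order)")
    best = None
    for p in E.points:
        d = None
        for a, b in zip(x.coeffs, p.coeffs):
            dv = abs(FieldElement(f, f.sub(a, b)))
            d = dv if d is None or dv > d else d
        if best is None or (d is not None and d < best):
            best = d
    if E.kind == "continuum":
        lin = _linear_constraint_distance(x, E)
        if lin is not None and (best is None or lin < best):
            best = lin
    if best is None:
        raise DynamicsError("equilibrium set has no points to measure against")
    return best
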