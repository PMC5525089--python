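"""Identity catalog, checker, and classifier for nonassociative algebras.

The identities of interest are polynomial identities built from binary
products and principal (left-normed) powers: the left invertive law
(ab)c = (cb)a that defines left almost (LA) algebras, flexibility,
the alternative laws, the (generalized) Jordan identities, and the
commutative-like consequences that LA alternative algebras enjoy
(x^2 y = y x^2, power associativity, (ab)^n = a^n b^n, ...).

Checking strategy:

* **multilinear** identities (every variable occurs exactly once on each
  side, no powers) are *proved* on a given finite-dimensional algebra by
  exhaustive evaluation on all basis tuples — by multilinearity both sides
  are determined by their values on the basis;
* non-multilinear identities cannot be settled on the basis alone.  They
  are checked on exact random **weight-1** elements (the genetically
  meaningful ones: the star product makes every weight-1 element
  idempotent, which is exactly what the flexibility/Jordan results use),
  or **exhaustively over all elements** on small algebras over finite
  fields, which again is a proof.

Every failure report carries a witness that re-evaluates to genuinely
unequal elements.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass, field as dc_field
from typing import Optional, Sequence

from .algebra import Algebra, AlgebraElement, multiply, principal_power, solve_linear
from .fields import FieldError

__all__ = [
    "var",
    "mul",
    "pw",
    "IdentityDef",
    "IdentityReport",
    "catalog",
    "check_identity",
    "find_left_identity",
    "left_identity_commutativity_check",
    "classify",
    "CONDITIONAL_SUITE",
    "IdentityError",
]


class IdentityError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Product trees
# ---------------------------------------------------------------------------
# Expressions are nested tuples: ("var", name), ("mul", lhs, rhs),
# ("pow", expr, m) with principal-power semantics.


def var(name: str):
    return ("var", name)


def mul(lhs, rhs):
    return ("mul", lhs, rhs)


def pw(expr, m: int):
    if m < 1:
        raise IdentityError("principal powers need exponent >= 1")
    return ("pow", expr, m)


def eval_expr(A: Algebra, expr, env: dict) -> AlgebraElement:
    op = expr[0]
    if op == "var":
        return env[expr[1]]
    if op == "mul":
        return multiply(A, eval_expr(A, expr[1], env), eval_expr(A, expr[2], env))
    if op == "pow":
        return principal_power(A, eval_expr(A, expr[1], env), expr[2])
    raise IdentityError(f"unknown expression node {op!r}")


def format_expr(expr) -> str:
    op = expr[0]
    if op == "var":
        return expr[1]
    if op == "mul":
        return f"({format_expr(expr[1])}{format_expr(expr[2])})"
    if op == "pow":
        return f"{format_expr(expr[1])}^{expr[2]}"
    return "?"


def _var_counts(expr, counts: dict, linear: list):
    op = expr[0]
    if op == "var":
        counts[expr[1]] = counts.get(expr[1], 0) + 1
    elif op == "mul":
        _var_counts(expr[1], counts, linear)
        _var_counts(expr[2], counts, linear)
    elif op == "pow":
        linear[0] = False
        _var_counts(expr[1], counts, linear)


@dataclass(frozen=True)
class IdentityDef:
    """One identity: a list of chains, each a tuple of >= 2 equal sides.

    A chain like ``(lhs, mid, rhs)`` asserts lhs = mid = rhs and is checked
    pairwise.  Power-parametrized laws (a^m a^n = a^{m+n} for several
    (m, n)) carry one chain per instantiated exponent pair.
    """

    name: str
    variables: tuple
    chains: tuple  # tuple of tuples of expressions
    weight1_only: bool = False
    conditional: bool = False  # only meaningful for LA alternative algebras
    description: str = ""

    @property
    def arity(self) -> int:
        return len(self.variables)

    @property
    def multilinear(self) -> bool:
        for chain in self.chains:
            for side in chain:
                counts: dict = {}
                linear = [True]
                _var_counts(side, counts, linear)
                if not linear[0]:
                    return False
                if any(c != 1 for c in counts.values()):
                    return False
                if set(counts) != set(self.variables):
                    return False
        return True


@dataclass
class IdentityReport:
    """Verdict for one identity on one algebra, with a checkable witness."""

    identity: str
    mode: str  # basis-exhaustive | element-exhaustive | weight1-sample
    verdict: str  # holds | fails | holds-on-sample | not-applicable
    counterexample: Optional[dict] = None
    sample_size: Optional[int] = None
    seed: Optional[int] = None
    detail: str = ""
    _witness_env: dict = dc_field(default=None, repr=False, compare=False)
    _witness_sides: tuple = dc_field(default=None, repr=False, compare=False)
    _algebra: Algebra = dc_field(default=None, repr=False, compare=False)

    def recheck_counterexample(self) -> bool:
        """Re-evaluate the stored witness; True iff the sides really differ."""
        if self.verdict != "fails" or self._witness_env is None:
            raise IdentityError("no counterexample to recheck")
        lhs, rhs = self._witness_sides
        a = eval_expr(self._algebra, lhs, self._witness_env)
        b = eval_expr(self._algebra, rhs, self._witness_env)
        return a != b

    def to_json(self) -> dict:
        out = {
            "identity": self.identity,
            "mode": self.mode,
            "verdict": self.verdict,
        }
        if self.sample_size is not None:
            out["sample_size"] = self.sample_size
        if self.seed is not None:
            out["seed"] = self.seed
        if self.counterexample is not None:
            out["counterexample"] = self.counterexample
        if self.detail:
            out["detail"] = self.detail
        return out


# ---------------------------------------------------------------------------
# Catalog
# ---------------------------------------------------------------------------

_x, _y, _z = var("x"), var("y"), var("z")
_a, _b, _c, _d = var("a"), var("b"), var("c"), var("d")


def _sq(e):
    return pw(e, 2)


def catalog(depth: int = 3) -> dict:
    """The identity catalog; power laws instantiated for exponents <= depth.

    ``depth`` bounds m, n in the parametrized families (a^m a^n = a^{m+n},
    (a^m)^n = a^{mn}, x^n y^m = y^m x^n, ...).
    """
    ids: dict = {}

    def add(name, variables, chains, **kw):
        ids[name] = IdentityDef(name, tuple(variables), tuple(chains), **kw)

    add("commutative", "xy", [(mul(_x, _y), mul(_y, _x))],
        description="xy = yx")
    add("associative", "xyz", [(mul(mul(_x, _y), _z), mul(_x, mul(_y, _z)))],
        description="(xy)z = x(yz)")
    add("left_invertive", "xyz", [(mul(mul(_x, _y), _z), mul(mul(_z, _y), _x))],
        description="(xy)z = (zy)x — the left almost (LA) law")
    add("left_id_consequence", "xyz", [(mul(mul(_x, _y), _z), mul(_y, mul(_x, _z)))],
        description="(xy)z = y(xz) — holds in LA structures with a left identity")
    add("flexible", "xy", [(mul(mul(_x, _y), _x), mul(_x, mul(_y, _x)))],
        description="(xy)x = x(yx)")
    add("generalized_jordan", "xy",
        [(mul(mul(_x, _y), _sq(_x)), mul(_x, mul(_y, _sq(_x))))],
        description="(xy)x^2 = x(yx^2)")
    add("alternative_left", "xy", [(mul(_x, mul(_x, _y)), mul(mul(_x, _x), _y))],
        description="x(xy) = (xx)y")
    add("alternative_right", "xy", [(mul(mul(_y, _x), _x), mul(_y, mul(_x, _x)))],
        description="(yx)x = y(xx)")

    # consequences valid in LA alternative algebras
    add("square_commute", "xy", [(mul(_sq(_x), _y), mul(_y, _sq(_x)))],
        conditional=True, description="x^2 y = y x^2")
    add("lemma9", "xy", [(mul(mul(_sq(_x), _y), _x), mul(_sq(_x), mul(_y, _x)))],
        conditional=True, description="(x^2 y)x = x^2 (yx)")
    add("thm10a", "xyz", [(mul(mul(_sq(_x), _y), _z), mul(_sq(_x), mul(_y, _z)))],
        conditional=True, description="(x^2 y)z = x^2 (yz)")
    add("thm10b", "xyz", [(mul(_sq(_x), mul(_y, _z)), mul(_sq(_x), mul(_z, _y)))],
        conditional=True, description="x^2 (yz) = x^2 (zy)")
    add("prop11", "abcd",
        [(mul(mul(_a, _b), mul(_c, _d)),
          mul(mul(_d, _b), mul(_c, _a)),
          mul(mul(_d, _c), mul(_b, _a)))],
        conditional=True, description="(ab)(cd) = (db)(ca) = (dc)(ba)")

    rng_ = range(1, depth + 1)
    add("power_sum", "a",
        [(mul(pw(_a, m), pw(_a, n)), pw(_a, m + n))
         for m in rng_ for n in rng_],
        conditional=True, description="a^m a^n = a^{m+n}")
    add("power_power", "a",
        [(pw(pw(_a, m), n), pw(_a, m * n)) for m in rng_ for n in rng_],
        conditional=True, description="(a^m)^n = a^{mn}")
    add("product_power", "ab",
        [(pw(mul(_a, _b), n), mul(pw(_a, n), pw(_b, n))) for n in rng_],
        conditional=True, description="(ab)^n = a^n b^n")
    add("power_commute", "xy",
        [(mul(pw(_x, n), pw(_y, m)), mul(pw(_y, m), pw(_x, n)))
         for n in rng_ for m in rng_ if m >= 2],
        conditional=True, description="x^n y^m = y^m x^n, m >= 2")
    add("thm17", "xy",
        [(mul(mul(pw(_x, n), pw(_x, m)), _y), mul(_y, mul(pw(_x, m), pw(_x, n))))
         for n in rng_ for m in rng_ if m >= 2],
        conditional=True, description="(x^n x^m)y = y(x^m x^n), m >= 2")
    add("gen_jordan_mn", "xy",
        [(mul(mul(pw(_x, m), _y), pw(_x, n)), mul(pw(_x, m), mul(_y, pw(_x, n))))
         for m in rng_ for n in rng_ if n >= 2],
        conditional=True, description="(x^m y)x^n = x^m (y x^n), m >= 1, n >= 2")
    return ids


CONDITIONAL_SUITE = tuple(
    name for name, ident in catalog().items() if ident.conditional
)


# ---------------------------------------------------------------------------
# Checker
# ---------------------------------------------------------------------------

_EXHAUSTIVE_LIMIT = 300_000  # max element tuples for element-exhaustive mode


def _chain_pairs(chain):
    for i in range(len(chain) - 1):
        yield chain[i], chain[i + 1]


def _witness_json(A: Algebra, env: dict, lhs, rhs, lv, rv) -> dict:
    f = A.field

    def vec(el):
        return [f.format(c) for c in el.coeffs]

    assignment = {}
    for name, el in env.items():
        # prefer basis-label notation when the value is a basis element
        lab = None
        for i, bl in enumerate(A.basis_labels):
            if el == A.basis_element(i + 1):
                lab = bl
                break
        assignment[name] = lab if lab is not None else vec(el)
    return {
        "assignment": assignment,
        "lhs": format_expr(lhs),
        "rhs": format_expr(rhs),
        "lhs_value": vec(lv),
        "rhs_value": vec(rv),
    }


def _check_on_envs(A, ident, envs, mode, sample_size=None, seed=None):
    for env in envs:
        for chain in ident.chains:
            for lhs, rhs in _chain_pairs(chain):
                lv = eval_expr(A, lhs, env)
                rv = eval_expr(A, rhs, env)
                if lv != rv:
                    return IdentityReport(
                        identity=ident.name,
                        mode=mode,
                        verdict="fails",
                        counterexample=_witness_json(A, env, lhs, rhs, lv, rv),
                        sample_size=sample_size,
                        seed=seed,
                        _witness_env=env,
                        _witness_sides=(lhs, rhs),
                        _algebra=A,
                    )
    verdict = (
        "holds" if mode in ("basis-exhaustive", "element-exhaustive")
        else "holds-on-sample"
    )
    return IdentityReport(
        identity=ident.name, mode=mode, verdict=verdict,
        sample_size=sample_size, seed=seed,
    )


def _random_weight1_element(A: Algebra, rng, denominator_bound=7) -> AlgebraElement:
    f = A.field
    coeffs = [f.random_raw(rng, denominator_bound) for _ in range(A.n - 1)]
    total = f.zero_raw
    for c in coeffs:
        total = f.add(total, c)
    coeffs.append(f.sub(f.one_raw, total))
    return AlgebraElement(A, coeffs)


def _random_element(A: Algebra, rng, denominator_bound=7) -> AlgebraElement:
    f = A.field
    return AlgebraElement(
        A, [f.random_raw(rng, denominator_bound) for _ in range(A.n)]
    )


def check_identity(
    A: Algebra,
    ident: IdentityDef | str,
    mode: str = "auto",
    sample_size: int = 100,
    seed: int = 0,
    weight1: bool | None = None,
    depth: int = 3,
) -> IdentityReport:
    """Check one identity on an algebra.

    Modes: ``basis-exhaustive`` (multilinear identities only — a proof),
    ``element-exhaustive`` (finite fields, small dimension — a proof,
    optionally restricted to weight-1 elements), ``weight1-sample`` /
    ``random-sample`` (seeded exact sampling), or ``auto`` which picks the
    soundest feasible mode.
    """
    if isinstance(ident, str):
        cat = catalog(depth)
        if ident not in cat:
            raise IdentityError(
                f"unknown identity {ident!r}; known: {', '.join(sorted(cat))}"
            )
        ident = cat[ident]
    restrict_w1 = ident.weight1_only if weight1 is None else weight1

    if mode == "auto":
        if ident.multilinear:
            mode = "basis-exhaustive"
        elif A.field.is_finite:
            per_var = A.field.order ** (A.n - 1 if restrict_w1 else A.n)
            if per_var ** ident.arity <= _EXHAUSTIVE_LIMIT:
                mode = "element-exhaustive"
            else:
                mode = "weight1-sample"
        else:
            mode = "weight1-sample"

    if mode == "basis-exhaustive":
        if not ident.multilinear:
            raise IdentityError(
                f"identity {ident.name!r} is not multilinear: a variable repeats "
                "(or a power occurs), so its validity on basis tuples does not "
                "extend to all elements; use element-exhaustive or weight1-sample"
            )
        basis = A.basis()
        envs = (
            dict(zip(ident.variables, combo))
            for combo in itertools.product(basis, repeat=ident.arity)
        )
        return _check_on_envs(A, ident, envs, mode)

    if mode == "element-exhaustive":
        if not A.field.is_finite:
            raise IdentityError("element-exhaustive mode requires a finite field")
        f = A.field
        all_raw = list(itertools.product(f.elements_raw(), repeat=A.n))
        if restrict_w1:
            one = f.one_raw
            pool = []
            for raw in all_raw:
                total = f.zero_raw
                for c in raw:
                    total = f.add(total, c)
                if total == one:
                    pool.append(AlgebraElement(A, raw))
        else:
            pool = [AlgebraElement(A, raw) for raw in all_raw]
        if len(pool) ** ident.arity > _EXHAUSTIVE_LIMIT:
            raise IdentityError(
                f"element-exhaustive check would need {len(pool) ** ident.arity} "
                "tuples; use weight1-sample instead"
            )
        envs = (
            dict(zip(ident.variables, combo))
            for combo in itertools.product(pool, repeat=ident.arity)
        )
        return _check_on_envs(A, ident, envs, mode)

    if mode in ("weight1-sample", "random-sample"):
        rng = random.Random(seed)
        draw = (
            _random_weight1_element
            if (restrict_w1 or mode == "weight1-sample")
            else _random_element
        )
        envs = [
            {name: draw(A, rng) for name in ident.variables}
            for _ in range(sample_size)
        ]
        return _check_on_envs(
            A, ident, envs, "weight1-sample" if draw is _random_weight1_element
            else "random-sample",
            sample_size=sample_size, seed=seed,
        )

    raise IdentityError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# Left identity
# ---------------------------------------------------------------------------


def find_left_identity(A: Algebra) -> Optional[AlgebraElement]:
    """Solve e a_j = a_j for all j; returns the solution or None.

    The system is linear in the coordinates of e: sum_i e_i gamma_ijk =
    delta_jk for all j, k.  In a left almost structure a left identity is
    unique when it exists; if the solved system is underdetermined, the
    particular solution (free variables zero) is returned after
    verification.
    """
    f = A.field
    n = A.n
    rows, rhs = [], []
    ent = A.tensor.entries
    for j in range(n):
        for k in range(n):
            rows.append([ent[i][j][k] for i in range(n)])
            rhs.append(f.one_raw if j == k else f.zero_raw)
    sol = solve_linear(f, rows, rhs)
    if sol is None:
        return None
    e = AlgebraElement(A, sol[0])
    for j in range(1, n + 1):
        aj = A.basis_element(j)
        if multiply(A, e, aj) != aj:
            return None
    return e


def left_identity_commutativity_check(A: Algebra, depth: int = 3) -> Optional[dict]:
    """If A has a left identity and is LA + alternative, commutativity must
    follow; run that implication check and report it.

    Returns None when the hypotheses do not hold (no left identity, or the
    LA/alternative laws fail); otherwise a dict with the commutativity
    report, which an honest implementation can never see fail.
    """
    e = find_left_identity(A)
    if e is None:
        return None
    pre = {
        name: check_identity(A, name, depth=depth)
        for name in ("left_invertive", "alternative_left", "alternative_right")
    }
    if any(r.verdict == "fails" for r in pre.values()):
        return None
    comm = check_identity(A, "commutative", depth=depth)
    return {"left_identity": e, "premises": pre, "commutative": comm}


# ---------------------------------------------------------------------------
# Classifier
# ---------------------------------------------------------------------------


def classify(
    A: Algebra, depth: int = 3, sample_size: int = 100, seed: int = 0
) -> dict:
    """Run the whole catalog with the soundest available mode per identity.

    The conditional suite (consequences the theory derives for LA
    *alternative* algebras) is reported ``not-applicable`` unless the left
    invertive law and both alternative laws hold on A.
    """
    cat = catalog(depth)
    reports: dict = {}
    for name in ("left_invertive", "alternative_left", "alternative_right"):
        reports[name] = check_identity(
            A, cat[name], sample_size=sample_size, seed=seed
        )
    gate_ok = all(
        reports[name].verdict in ("holds", "holds-on-sample")
        for name in ("left_invertive", "alternative_left", "alternative_right")
    )
    for name, ident in cat.items():
        if name in reports:
            continue
        if ident.conditional and not gate_ok:
            reports[name] = IdentityReport(
                identity=name, mode="gated", verdict="not-applicable",
                detail="derived-identity suite applies only to LA alternative "
                       "algebras; the gate identities do not all hold",
            )
            continue
        reports[name] = check_identity(
            A, ident, sample_size=sample_size, seed=seed
        )
    return reports
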