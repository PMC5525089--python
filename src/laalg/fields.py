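"""Exact scalar domains for genetic algebras.

Structure constants of gametic algebras are relative gene frequencies and
must be handled exactly: a Hardy-Weinberg equilibrium or a mutation-algebra
fixed point is an algebraic identity, not a numerical approximation.  This
module provides the four scalar domains the package works over:

* the rationals (Mendelian frequencies like 1/2, 1/4),
* a real quadratic extension Q(sqrt(d)) — needed for the golden ratios
  alpha = (-1 +- sqrt(5))/2 that satisfy alpha + alpha^2 = 1,
* finite fields GF(p^k), in particular GF(2^2) built from t^2 + t + 1,
  where alpha = t satisfies the same constraint,
* a rational-function field over named symbols, so that facts like the
  Gonshor change of basis can be verified symbolically in the mutation
  rates (r, s) rather than at sampled values.

No floating point is used anywhere; ``to_float`` exists only as a display /
sanity-check convenience.  Every domain keeps a unique canonical form per
element, so equality is a plain representation comparison.
"""

from __future__ import annotations

import itertools
from fractions import Fraction
from typing import Iterator, Sequence

import sympy

__all__ = [
    "Field",
    "FieldElement",
    "RationalField",
    "QuadraticField",
    "FiniteField",
    "SymbolicField",
    "make_finite_field",
    "element_order",
    "golden_alpha",
    "QQ",
    "field_from_json",
]


class FieldError(ValueError):
    """Raised for invalid field constructions or operations."""


class Field:
    """Abstract exact scalar domain.

    Concrete subclasses store elements in a canonical internal
    representation (``raw`` values) and expose arithmetic on them; the
    :class:`FieldElement` wrapper provides operator syntax on top.
    """

    kind: str = "abstract"

    # -- arithmetic on raw representations ---------------------------------
    def add(self, a, b):
        raise NotImplementedError

    def mul(self, a, b):
        raise NotImplementedError

    def neg(self, a):
        raise NotImplementedError

    def inv(self, a):
        raise NotImplementedError

    def sub(self, a, b):
        return self.add(a, self.neg(b))

    def div(self, a, b):
        return self.mul(a, self.inv(b))

    # -- constants ----------------------------------------------------------
    @property
    def zero_raw(self):
        return self.from_int(0)

    @property
    def one_raw(self):
        return self.from_int(1)

    def from_int(self, n: int):
        raise NotImplementedError

    # -- structure ----------------------------------------------------------
    @property
    def characteristic(self) -> int:
        return 0

    @property
    def is_ordered(self) -> bool:
        """Whether the domain embeds in R with a decidable exact ordering."""
        return False

    @property
    def is_finite(self) -> bool:
        return False

    def sign(self, a) -> int:
        raise FieldError(f"{self.kind} field has no order")

    def to_float(self, a) -> float:
        raise FieldError(f"{self.kind} scalars have no float image")

    # -- conversions ---------------------------------------------------------
    def coerce(self, x):
        """Coerce ``x`` (int, Fraction, str, raw, or FieldElement) to raw form."""
        raise NotImplementedError

    def __call__(self, x) -> "FieldElement":
        return FieldElement(self, self.coerce(x))

    def element(self, x) -> "FieldElement":
        return self(x)

    @property
    def zero(self) -> "FieldElement":
        return FieldElement(self, self.zero_raw)

    @property
    def one(self) -> "FieldElement":
        return FieldElement(self, self.one_raw)

    def format(self, a) -> str:
        raise NotImplementedError

    def raw_to_json(self, a):
        raise NotImplementedError

    def raw_from_json(self, obj):
        raise NotImplementedError

    def to_sympy(self, a) -> sympy.Expr:
        raise NotImplementedError

    def from_sympy(self, expr: sympy.Expr):
        raise NotImplementedError

    def spec_json(self) -> dict:
        raise NotImplementedError

    # -- sampling (exact) ----------------------------------------------------
    def random_raw(self, rng, denominator_bound: int = 9):
        """A random exact scalar; used by weight-1 samplers.  Seeded rng."""
        raise NotImplementedError

    def __eq__(self, other):
        return type(self) is type(other) and self._key() == other._key()

    def __hash__(self):
        return hash((type(self).__name__, self._key()))

    def _key(self):
        return ()


_NO_COERCION = object()


class FieldElement:
    """A scalar tied to its field; supports ``+ - * /`` and exact equality.

    Binary operations with objects the field cannot coerce (e.g. algebra
    elements) return NotImplemented so the other operand's reflected method
    gets a chance.
    """

    __slots__ = ("field", "raw")

    def __init__(self, field: Field, raw):
        self.field = field
        self.raw = raw

    def _coerce(self, other):
        if isinstance(other, FieldElement):
            if other.field != self.field:
                raise FieldError("scalars belong to different fields")
            return other.raw
        return self.field.coerce(other)

    def _maybe_coerce(self, other):
        try:
            return self._coerce(other)
        except Exception:
            return _NO_COERCION

    def __add__(self, other):
        raw = self._maybe_coerce(other)
        if raw is _NO_COERCION:
            return NotImplemented
        return FieldElement(self.field, self.field.add(self.raw, raw))

    __radd__ = __add__

    def __sub__(self, other):
        raw = self._maybe_coerce(other)
        if raw is _NO_COERCION:
            return NotImplemented
        return FieldElement(self.field, self.field.sub(self.raw, raw))

    def __rsub__(self, other):
        raw = self._maybe_coerce(other)
        if raw is _NO_COERCION:
            return NotImplemented
        return FieldElement(self.field, self.field.sub(raw, self.raw))

    def __mul__(self, other):
        raw = self._maybe_coerce(other)
        if raw is _NO_COERCION:
            return NotImplemented
        return FieldElement(self.field, self.field.mul(self.raw, raw))

    __rmul__ = __mul__

    def __truediv__(self, other):
        return FieldElement(self.field, self.field.div(self.raw, self._coerce(other)))

    def __rtruediv__(self, other):
        return FieldElement(self.field, self.field.div(self._coerce(other), self.raw))

    def __neg__(self):
        return FieldElement(self.field, self.field.neg(self.raw))

    def __pow__(self, m: int):
        if not isinstance(m, int) or m < 0:
            raise FieldError("scalar powers take a nonnegative integer exponent")
        out = self.field.one_raw
        for _ in range(m):
            out = self.field.mul(out, self.raw)
        return FieldElement(self.field, out)

    def __eq__(self, other):
        try:
            return self.raw == self._coerce(other)
        except (FieldError, ValueError, TypeError):
            return NotImplemented

    def __hash__(self):
        return hash((self.field, self.raw))

    def __bool__(self):
        return self.raw != self.field.zero_raw

    @property
    def is_zero(self) -> bool:
        return self.raw == self.field.zero_raw

    def sign(self) -> int:
        return self.field.sign(self.raw)

    def __abs__(self):
        return -self if self.field.sign(self.raw) < 0 else self

    def __lt__(self, other):
        return self.field.sign(self.field.sub(self.raw, self._coerce(other))) < 0

    def __le__(self, other):
        return self.field.sign(self.field.sub(self.raw, self._coerce(other))) <= 0

    def __gt__(self, other):
        return self.field.sign(self.field.sub(self.raw, self._coerce(other))) > 0

    def __ge__(self, other):
        return self.field.sign(self.field.sub(self.raw, self._coerce(other))) >= 0

    def __float__(self):
        return self.field.to_float(self.raw)

    def __repr__(self):
        return self.field.format(self.raw)


# ---------------------------------------------------------------------------
# Rationals
# ---------------------------------------------------------------------------


class RationalField(Field):
    """The field Q; elements are stdlib :class:`fractions.Fraction`."""

    kind = "rational"

    def add(self, a, b):
        return a + b

    def mul(self, a, b):
        return a * b

    def neg(self, a):
        return -a

    def inv(self, a):
        if a == 0:
            raise FieldError("division by zero")
        return 1 / a

    def from_int(self, n):
        return Fraction(n)

    @property
    def is_ordered(self):
        return True

    def sign(self, a):
        return (a > 0) - (a < 0)

    def to_float(self, a):
        return float(a)

    def coerce(self, x):
        if isinstance(x, FieldElement):
            if x.field != self:
                raise FieldError("scalar from a different field")
            return x.raw
        if isinstance(x, Fraction):
            return x
        if isinstance(x, (int, str)):
            return Fraction(x)
        raise FieldError(f"cannot coerce {x!r} to a rational")

    def format(self, a):
        return str(a)

    def raw_to_json(self, a):
        return str(a)

    def raw_from_json(self, obj):
        if not isinstance(obj, str):
            raise FieldError(f"rational scalar must be a string like '3/4', got {obj!r}")
        return Fraction(obj)

    def to_sympy(self, a):
        return sympy.Rational(a.numerator, a.denominator)

    def from_sympy(self, expr):
        expr = sympy.nsimplify(expr, rational=True)
        if not expr.is_Rational:
            raise FieldError(f"{expr} is not rational")
        return Fraction(int(expr.p), int(expr.q))

    def spec_json(self):
        return {"kind": "rational"}

    def random_raw(self, rng, denominator_bound: int = 9):
        den = rng.randint(1, denominator_bound)
        num = rng.randint(-denominator_bound, denominator_bound)
        return Fraction(num, den)


QQ = RationalField()


# ---------------------------------------------------------------------------
# Quadratic extension Q(sqrt(d))
# ---------------------------------------------------------------------------


def _is_square(n: int) -> bool:
    if n < 0:
        return False
    r = sympy.integer_nthroot(n, 2)[0]
    return r * r == n


class QuadraticField(Field):
    """Q(sqrt(d)) for a non-square integer d; elements are pairs (a, b) of
    Fractions meaning a + b*sqrt(d).  Ordered (real-embedded) when d > 0."""

    kind = "quadratic"

    def __init__(self, discriminant: int = 5):
        if not isinstance(discriminant, int) or _is_square(discriminant):
            raise FieldError(
                f"discriminant must be a non-square integer, got {discriminant}"
            )
        self.d = discriminant

    def _key(self):
        return (self.d,)

    def add(self, a, b):
        return (a[0] + b[0], a[1] + b[1])

    def mul(self, a, b):
        return (a[0] * b[0] + self.d * a[1] * b[1], a[0] * b[1] + a[1] * b[0])

    def neg(self, a):
        return (-a[0], -a[1])

    def inv(self, a):
        # (a + b*sqrt(d))^-1 = (a - b*sqrt(d)) / (a^2 - d b^2)
        norm = a[0] * a[0] - self.d * a[1] * a[1]
        if norm == 0:
            if a == (Fraction(0), Fraction(0)):
                raise FieldError("division by zero")
            raise FieldError("zero norm element (d is a square?)")
        return (a[0] / norm, -a[1] / norm)

    def from_int(self, n):
        return (Fraction(n), Fraction(0))

    @property
    def is_ordered(self):
        return self.d > 0

    def sign(self, a):
        if self.d < 0:
            raise FieldError("imaginary quadratic field has no order")
        p, q = a
        if q == 0:
            return (p > 0) - (p < 0)
        if p == 0:
            return 1 if q > 0 else -1
        if p > 0 and q > 0:
            return 1
        if p < 0 and q < 0:
            return -1
        # mixed signs: compare p^2 with d q^2 on the dominant side
        if p > 0:  # q < 0: positive iff p^2 > d q^2
            return 1 if p * p > self.d * q * q else -1
        return -1 if p * p > self.d * q * q else 1  # p < 0, q > 0

    def to_float(self, a):
        return float(a[0]) + float(a[1]) * float(self.d) ** 0.5

    def coerce(self, x):
        if isinstance(x, FieldElement):
            if x.field != self:
                raise FieldError("scalar from a different field")
            return x.raw
        if isinstance(x, tuple) and len(x) == 2:
            return (Fraction(x[0]), Fraction(x[1]))
        if isinstance(x, (int, Fraction, str)):
            return (Fraction(x), Fraction(0))
        raise FieldError(f"cannot coerce {x!r} to {self!r}")

    def sqrt_d(self) -> FieldElement:
        return FieldElement(self, (Fraction(0), Fraction(1)))

    def format(self, a):
        p, q = a
        if q == 0:
            return str(p)
        if p == 0:
            return f"{q}*sqrt{self.d}"
        op = "+" if q > 0 else "-"
        return f"{p}{op}{abs(q)}*sqrt{self.d}"

    def raw_to_json(self, a):
        return {"a": str(a[0]), "b": str(a[1])}

    def raw_from_json(self, obj):
        if not (isinstance(obj, dict) and set(obj) == {"a", "b"}):
            raise FieldError(
                f'quadratic scalar must be {{"a": ..., "b": ...}}, got {obj!r}'
            )
        return (Fraction(obj["a"]), Fraction(obj["b"]))

    def to_sympy(self, a):
        return sympy.Rational(a[0].numerator, a[0].denominator) + sympy.Rational(
            a[1].numerator, a[1].denominator
        ) * sympy.sqrt(self.d)

    def from_sympy(self, expr):
        s = sympy.sqrt(self.d)
        ex = sympy.expand(sympy.radsimp(expr))
        b = ex.coeff(s)
        a = sympy.expand(ex - b * s)
        if not (a.is_Rational and b.is_Rational):
            raise FieldError(f"{expr} does not lie in Q(sqrt{self.d})")
        return (Fraction(int(a.p), int(a.q)), Fraction(int(b.p), int(b.q)))

    def spec_json(self):
        return {"kind": "quadratic", "discriminant": self.d}

    def random_raw(self, rng, denominator_bound: int = 9):
        return (
            QQ.random_raw(rng, denominator_bound),
            QQ.random_raw(rng, denominator_bound),
        )

    def __repr__(self):
        return f"Q(sqrt{self.d})"


def golden_alpha(sign: int = +1) -> FieldElement:
    """The root alpha = (-1 + sign*sqrt(5))/2 of x^2 + x = 1, in Q(sqrt(5)).

    Both roots satisfy alpha + alpha^2 = 1 exactly; this is the defining
    constraint of the star product a_i * a_j = alpha*a_i + alpha^2*a_j, under
    which every basis element (and every weight-1 population) is idempotent.
    """
    if sign not in (+1, -1):
        raise FieldError("sign must be +1 or -1")
    F = QuadraticField(5)
    return FieldElement(F, (Fraction(-1, 2), Fraction(sign, 2)))


# ---------------------------------------------------------------------------
# Finite fields GF(p^k)
# ---------------------------------------------------------------------------


def _poly_degree(coeffs_asc: tuple, p: int) -> int:
    deg = -1
    for i, c in enumerate(coeffs_asc):
        if c % p != 0:
            deg = i
    return deg


def _poly_mod(num: list, den: tuple, p: int) -> tuple:
    """Remainder of num by monic-normalized den, over Z_p.  Ascending coeffs."""
    den_deg = _poly_degree(den, p)
    lead_inv = pow(den[den_deg], p - 2, p) if p > 2 else den[den_deg] % p
    num = [c % p for c in num]
    for i in range(len(num) - 1, den_deg - 1, -1):
        if num[i] == 0:
            continue
        factor = (num[i] * lead_inv) % p
        for j in range(den_deg + 1):
            num[i - den_deg + j] = (num[i - den_deg + j] - factor * den[j]) % p
    return tuple(num[:den_deg])


def _poly_mul(a: Sequence[int], b: Sequence[int], p: int) -> list:
    out = [0] * (len(a) + len(b) - 1)
    for i, ai in enumerate(a):
        if ai == 0:
            continue
        for j, bj in enumerate(b):
            out[i + j] = (out[i + j] + ai * bj) % p
    return out


def _format_poly(coeffs_asc: Sequence[int], var: str = "t") -> str:
    terms = []
    for i, c in enumerate(coeffs_asc):
        if c == 0:
            continue
        if i == 0:
            terms.append(str(c))
        elif i == 1:
            terms.append(var if c == 1 else f"{c}*{var}")
        else:
            terms.append(f"{var}^{i}" if c == 1 else f"{c}*{var}^{i}")
    return " + ".join(terms) if terms else "0"


class FiniteField(Field):
    """GF(p^k) as Z_p[t] modulo an irreducible degree-k polynomial.

    Elements are length-k tuples of ints in [0, p): ascending coefficients
    (c0 + c1*t + ... + c_{k-1}*t^{k-1}).  The modulus is given with the
    leading coefficient first, the way polynomials are written.
    Use :func:`make_finite_field` which validates irreducibility.
    """

    kind = "finite"

    def __init__(self, p: int, k: int, modulus_desc: Sequence[int]):
        self.p = p
        self.k = k
        self.modulus_desc = tuple(c % p for c in modulus_desc)
        self._mod_asc = tuple(reversed(self.modulus_desc))

    def _key(self):
        return (self.p, self.k, self.modulus_desc)

    @property
    def order(self) -> int:
        return self.p**self.k

    @property
    def characteristic(self) -> int:
        return self.p

    @property
    def is_finite(self):
        return True

    def add(self, a, b):
        return tuple((x + y) % self.p for x, y in zip(a, b))

    def neg(self, a):
        return tuple((-x) % self.p for x in a)

    def mul(self, a, b):
        prod = _poly_mul(a, b, self.p)
        rem = _poly_mod(prod, self._mod_asc, self.p)
        return tuple(rem) + (0,) * (self.k - len(rem))

    def inv(self, a):
        if a == self.zero_raw:
            raise FieldError("division by zero")
        # brute force: the field is desk-scale (q <= a few hundred)
        for b in self.elements_raw():
            if self.mul(a, b) == self.one_raw:
                return b
        raise FieldError("no inverse found (modulus not irreducible?)")

    def from_int(self, n):
        return (n % self.p,) + (0,) * (self.k - 1)

    def coerce(self, x):
        if isinstance(x, FieldElement):
            if x.field != self:
                raise FieldError("scalar from a different field")
            return x.raw
        if isinstance(x, int):
            return self.from_int(x)
        if isinstance(x, (tuple, list)):
            if len(x) != self.k:
                raise FieldError(f"coefficient list must have length {self.k}")
            return tuple(int(c) % self.p for c in x)
        raise FieldError(f"cannot coerce {x!r} to GF({self.p}^{self.k})")

    @property
    def t(self) -> FieldElement:
        """The generator t (the residue of the variable), for k >= 2."""
        if self.k < 2:
            raise FieldError("prime field has no extension generator t")
        return FieldElement(self, (0, 1) + (0,) * (self.k - 2))

    def elements_raw(self) -> Iterator[tuple]:
        for combo in itertools.product(range(self.p), repeat=self.k):
            yield combo

    def elements(self) -> Iterator[FieldElement]:
        for raw in self.elements_raw():
            yield FieldElement(self, raw)

    def format(self, a):
        return _format_poly(a)

    def raw_to_json(self, a):
        return list(reversed(a))  # leading coefficient first, like the modulus

    def raw_from_json(self, obj):
        if not (isinstance(obj, list) and len(obj) == self.k):
            raise FieldError(
                f"finite scalar must be a length-{self.k} coefficient list, got {obj!r}"
            )
        return tuple(int(c) % self.p for c in reversed(obj))

    def spec_json(self):
        return {
            "kind": "finite",
            "p": self.p,
            "k": self.k,
            "modulus": list(self.modulus_desc),
        }

    def random_raw(self, rng, denominator_bound: int = 9):
        return tuple(rng.randrange(self.p) for _ in range(self.k))

    def __repr__(self):
        return f"GF({self.p}^{self.k})"


def make_finite_field(p: int, k: int, modulus: Sequence[int]) -> FiniteField:
    """Construct GF(p^k) from a degree-k modulus (leading coefficient first).

    Rejects non-prime p and reducible moduli; a reducible modulus is rejected
    naming an explicit monic factor found by exhaustive trial division.
    """
    if not (isinstance(p, int) and p >= 2 and sympy.isprime(p)):
        raise FieldError(f"characteristic must be prime, got {p}")
    if not (isinstance(k, int) and k >= 1):
        raise FieldError(f"extension degree must be a positive integer, got {k}")
    mod_desc = [c % p for c in modulus]
    asc = tuple(reversed(mod_desc))
    if _poly_degree(asc, p) != k:
        raise FieldError(
            f"modulus {list(modulus)} does not have degree {k} over Z_{p}"
        )
    # exhaustive trial division by monic polynomials of degree 1..k//2
    for d in range(1, k // 2 + 1):
        for tail in itertools.product(range(p), repeat=d):
            cand = list(tail) + [1]  # monic, ascending
            if _poly_mod(list(asc), tuple(cand), p) == tuple([0] * d):
                raise FieldError(
                    f"modulus {_format_poly(asc, 'x')} is reducible over Z_{p}: "
                    f"divisible by {_format_poly(cand, 'x')}"
                )
    return FiniteField(p, k, mod_desc)


def element_order(field: FiniteField, x) -> int:
    """Multiplicative order of a nonzero element: least m >= 1 with x^m = 1.

    Always divides p^k - 1 (the multiplicative group is cyclic); in GF(2^2)
    the generator t has order 3, i.e. t^3 = 1.
    """
    if not isinstance(field, FiniteField):
        raise FieldError("element_order requires a finite field")
    raw = field.coerce(x)
    if raw == field.zero_raw:
        raise FieldError("zero has no multiplicative order")
    acc = raw
    for m in range(1, field.order):
        if acc == field.one_raw:
            return m
        acc = field.mul(acc, raw)
    raise FieldError("order not found; field construction is inconsistent")


# ---------------------------------------------------------------------------
# Rational-function field over named symbols
# ---------------------------------------------------------------------------


class SymbolicField(Field):
    """Q(s1, ..., sm): rational functions in named symbols, via sympy.

    Lets structural facts (e.g. the Gonshor basis products a^2 = a - r*b,
    ab = (1/2)(1-r-s) b, b^2 = 0) be verified once for all parameter values.
    Canonical form is ``sympy.cancel``; the domain is not ordered, so
    range validations (frequencies in [0, 1]) do not apply to it.
    """

    kind = "symbolic"

    def __init__(self, symbols: Sequence[str]):
        self.symbol_names = tuple(str(s) for s in symbols)
        self.symbols = sympy.symbols(self.symbol_names)
        if isinstance(self.symbols, sympy.Symbol):
            self.symbols = (self.symbols,)

    def _key(self):
        return self.symbol_names

    def add(self, a, b):
        return sympy.cancel(a + b)

    def mul(self, a, b):
        return sympy.cancel(a * b)

    def neg(self, a):
        return sympy.cancel(-a)

    def inv(self, a):
        if a == 0:
            raise FieldError("division by zero")
        return sympy.cancel(1 / a)

    def from_int(self, n):
        return sympy.Integer(n)

    def coerce(self, x):
        if isinstance(x, FieldElement):
            if x.field != self:
                raise FieldError("scalar from a different field")
            return x.raw
        if isinstance(x, Fraction):
            return sympy.Rational(x.numerator, x.denominator)
        try:
            expr = sympy.sympify(x, rational=True)
        except sympy.SympifyError as exc:
            raise FieldError(f"cannot coerce {x!r} to {self!r}") from exc
        extra = expr.free_symbols - set(self.symbols)
        if extra:
            raise FieldError(f"unknown symbols {extra} for {self!r}")
        return sympy.cancel(expr)

    def format(self, a):
        return str(a)

    def raw_to_json(self, a):
        return str(a)

    def raw_from_json(self, obj):
        return self.coerce(obj)

    def to_sympy(self, a):
        return a

    def from_sympy(self, expr):
        return self.coerce(expr)

    def spec_json(self):
        return {"kind": "symbolic", "symbols": list(self.symbol_names)}

    def __repr__(self):
        return f"Q({', '.join(self.symbol_names)})"


# ---------------------------------------------------------------------------
# FieldSpec (de)serialization
# ---------------------------------------------------------------------------


def field_from_json(spec: dict) -> Field:
    """Rebuild a field from its JSON spec (validated)."""
    if not isinstance(spec, dict) or "kind" not in spec:
        raise FieldError(f'field spec must be an object with "kind", got {spec!r}')
    kind = spec["kind"]
    if kind == "rational":
        return QQ
    if kind == "quadratic":
        if "discriminant" not in spec:
            raise FieldError('quadratic field spec needs "discriminant"')
        return QuadraticField(spec["discriminant"])
    if kind == "finite":
        for key in ("p", "k", "modulus"):
            if key not in spec:
                raise FieldError(f'finite field spec needs "{key}"')
        return make_finite_field(spec["p"], spec["k"], spec["modulus"])
    if kind == "symbolic":
        return SymbolicField(spec.get("symbols", []))
    raise FieldError(f"unknown field kind {kind!r}")
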