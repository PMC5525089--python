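"""Structure-constant algebras: elements, bilinear products, powers, bases.

An n-dimensional algebra over an exact field is given by its structure
tensor gamma[i][j][k]: the product of basis elements is

    a_i a_j = sum_k gamma_ijk a_k

and extends bilinearly.  In the genetic reading the basis elements are
gametes (or zygote types), the gamma_ijk are relative gene frequencies, and
an element with nonnegative coefficients summing to 1 is a population; the
coefficient sum is the baric weight, a homomorphism onto the scalars
whenever every row of the tensor sums to 1.

Indexing is 1-based in all user-facing labels and messages, matching the
usual subscript convention; storage is 0-based.
"""

from __future__ import annotations

from typing import Callable, Sequence

from .fields import Field, FieldElement, FieldError, QQ

__all__ = [
    "StructureTensor",
    "Algebra",
    "AlgebraElement",
    "multiply",
    "weight",
    "principal_power",
    "change_of_basis",
    "matrix_inverse",
    "apply_matrix",
    "solve_linear",
    "AlgebraError",
]


class AlgebraError(ValueError):
    pass


class StructureTensor:
    """The n x n x n array of structure constants, stored as raw scalars."""

    def __init__(self, field: Field, entries):
        self.field = field
        self.n = len(entries)
        ent = []
        for i, plane in enumerate(entries):
            if len(plane) != self.n:
                raise AlgebraError(f"tensor row {i + 1} has wrong length")
            row_out = []
            for j, row in enumerate(plane):
                if len(row) != self.n:
                    raise AlgebraError(f"tensor entry ({i + 1},{j + 1}) has wrong length")
                row_out.append(tuple(field.coerce(v) for v in row))
            ent.append(tuple(row_out))
        self.entries = tuple(ent)

    def gamma(self, i: int, j: int, k: int) -> FieldElement:
        """gamma_ijk with 1-based indices, as in the written convention."""
        return FieldElement(self.field, self.entries[i - 1][j - 1][k - 1])

    def row_sum(self, i: int, j: int) -> FieldElement:
        """sum_k gamma_ijk (1-based i, j)."""
        f = self.field
        acc = f.zero_raw
        for k in range(self.n):
            acc = f.add(acc, self.entries[i - 1][j - 1][k])
        return FieldElement(f, acc)

    def is_row_stochastic(self) -> bool:
        one = self.field.one_raw
        return all(
            self.row_sum(i, j).raw == one
            for i in range(1, self.n + 1)
            for j in range(1, self.n + 1)
        )

    def is_bounded01(self) -> bool:
        """All entries in [0, 1]; meaningful only on ordered fields."""
        if not self.field.is_ordered:
            raise AlgebraError("entry bounds require an ordered field")
        f = self.field
        for plane in self.entries:
            for row in plane:
                for v in row:
                    if f.sign(v) < 0 or f.sign(f.sub(v, f.one_raw)) > 0:
                        return False
        return True

    def is_gametic_symmetric(self) -> bool:
        """gamma_ijk == gamma_jik: the commutative (classical gametic) case."""
        e = self.entries
        return all(
            e[i][j][k] == e[j][i][k]
            for i in range(self.n)
            for j in range(i + 1, self.n)
            for k in range(self.n)
        )

    def __eq__(self, other):
        return (
            isinstance(other, StructureTensor)
            and self.field == other.field
            and self.entries == other.entries
        )


class Algebra:
    """Basis labels + structure tensor + field; the central container."""

    def __init__(
        self,
        field: Field,
        basis_labels: Sequence[str],
        tensor: StructureTensor,
        provenance: dict | None = None,
    ):
        if len(basis_labels) != tensor.n:
            raise AlgebraError(
                f"{len(basis_labels)} labels for a dimension-{tensor.n} tensor"
            )
        if len(set(basis_labels)) != len(basis_labels):
            raise AlgebraError("basis labels must be unique")
        if tensor.field != field:
            raise AlgebraError("tensor scalars do not belong to the algebra's field")
        self.field = field
        self.basis_labels = tuple(str(b) for b in basis_labels)
        self.tensor = tensor
        self.provenance = dict(provenance or {})

    @property
    def n(self) -> int:
        return self.tensor.n

    def element(self, coeffs) -> "AlgebraElement":
        return AlgebraElement(self, coeffs)

    def basis_element(self, i: int) -> "AlgebraElement":
        """The i-th basis element, 1-based."""
        if not 1 <= i <= self.n:
            raise AlgebraError(f"basis index {i} out of range 1..{self.n}")
        coeffs = [self.field.zero_raw] * self.n
        coeffs[i - 1] = self.field.one_raw
        return AlgebraElement(self, coeffs)

    def basis(self):
        return [self.basis_element(i) for i in range(1, self.n + 1)]

    def zero(self) -> "AlgebraElement":
        return AlgebraElement(self, [self.field.zero_raw] * self.n)

    def __eq__(self, other):
        return (
            isinstance(other, Algebra)
            and self.field == other.field
            and self.basis_labels == other.basis_labels
            and self.tensor == other.tensor
        )

    def __repr__(self):
        name = self.provenance.get("constructor", "algebra")
        return f"<{name}: dim {self.n} over {self.field.kind}>"


class AlgebraElement:
    """A coefficient vector over an algebra's basis.

    ``x * y`` is the algebra product, ``x + y`` the vector sum, ``c * x``
    scalar action.  ``x.weight()`` is the coefficient sum.
    """

    __slots__ = ("algebra", "coeffs")

    def __init__(self, algebra: Algebra, coeffs):
        if len(coeffs) != algebra.n:
            raise AlgebraError(
                f"coefficient vector of length {len(coeffs)} for a "
                f"dimension-{algebra.n} algebra"
            )
        f = algebra.field
        self.algebra = algebra
        self.coeffs = tuple(f.coerce(c) for c in coeffs)

    def coeff(self, i: int) -> FieldElement:
        """1-based coefficient access."""
        return FieldElement(self.algebra.field, self.coeffs[i - 1])

    def _check(self, other: "AlgebraElement"):
        if not isinstance(other, AlgebraElement) or other.algebra.n != self.algebra.n \
                or other.algebra.field != self.algebra.field:
            raise AlgebraError("elements belong to different algebras")

    def __add__(self, other):
        self._check(other)
        f = self.algebra.field
        return AlgebraElement(
            self.algebra, [f.add(a, b) for a, b in zip(self.coeffs, other.coeffs)]
        )

    def __sub__(self, other):
        self._check(other)
        f = self.algebra.field
        return AlgebraElement(
            self.algebra, [f.sub(a, b) for a, b in zip(self.coeffs, other.coeffs)]
        )

    def __neg__(self):
        f = self.algebra.field
        return AlgebraElement(self.algebra, [f.neg(a) for a in self.coeffs])

    def scale(self, c) -> "AlgebraElement":
        f = self.algebra.field
        raw = f.coerce(c)
        return AlgebraElement(self.algebra, [f.mul(raw, a) for a in self.coeffs])

    def __rmul__(self, c):
        if isinstance(c, AlgebraElement):
            return NotImplemented
        return self.scale(c)

    def __mul__(self, other):
        if isinstance(other, AlgebraElement):
            return multiply(self.algebra, self, other)
        return self.scale(other)

    def __pow__(self, m: int):
        return principal_power(self.algebra, self, m)

    def weight(self) -> FieldElement:
        f = self.algebra.field
        acc = f.zero_raw
        for c in self.coeffs:
            acc = f.add(acc, c)
        return FieldElement(f, acc)

    def is_zero(self) -> bool:
        z = self.algebra.field.zero_raw
        return all(c == z for c in self.coeffs)

    def __eq__(self, other):
        if not isinstance(other, AlgebraElement):
            return NotImplemented
        self._check(other)
        return self.coeffs == other.coeffs

    def __hash__(self):
        return hash((self.algebra.field, self.coeffs))

    def __repr__(self):
        f = self.algebra.field
        terms = []
        for c, label in zip(self.coeffs, self.algebra.basis_labels):
            if c == f.zero_raw:
                continue
            cs = f.format(c)
            terms.append(label if cs == "1" else f"({cs})*{label}")
        return " + ".join(terms) if terms else "0"


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def multiply(A: Algebra, x: AlgebraElement, y: AlgebraElement) -> AlgebraElement:
    """Bilinear product: (xy)_k = sum_ij x_i y_j gamma_ijk, exact."""
    if x.algebra.n != A.n or y.algebra.n != A.n:
        raise AlgebraError("dimension mismatch in multiply")
    f = A.field
    ent = A.tensor.entries
    zero = f.zero_raw
    out = [zero] * A.n
    for i, xi in enumerate(x.coeffs):
        if xi == zero:
            continue
        for j, yj in enumerate(y.coeffs):
            if yj == zero:
                continue
            c = f.mul(xi, yj)
            row = ent[i][j]
            for k in range(A.n):
                if row[k] != zero:
                    out[k] = f.add(out[k], f.mul(c, row[k]))
    return AlgebraElement(A, out)


def weight(x: AlgebraElement) -> FieldElement:
    """The baric weight: the coefficient sum (population size 1 <=> weight 1)."""
    return x.weight()


def principal_power(A: Algebra, x: AlgebraElement, m: int) -> AlgebraElement:
    """Left-normed principal power: x^1 = x, x^{m+1} = x^m x."""
    if not isinstance(m, int) or m < 1:
        raise AlgebraError(f"principal power needs an integer exponent >= 1, got {m}")
    out = x
    for _ in range(m - 1):
        out = multiply(A, out, x)
    return out


# ---------------------------------------------------------------------------
# Exact linear algebra over a field (Gaussian elimination)
# ---------------------------------------------------------------------------


def _coerce_matrix(field: Field, M) -> list:
    return [[field.coerce(v) for v in row] for row in M]


def solve_linear(field: Field, A_rows: list, b: list):
    """Solve the (possibly overdetermined) system A x = b exactly.

    Returns ``(particular_solution, n_free)`` with free variables set to
    zero, or ``None`` if the system is inconsistent.
    """
    m = len(A_rows)
    n = len(A_rows[0]) if m else 0
    aug = [[field.coerce(v) for v in row] + [field.coerce(b[i])]
           for i, row in enumerate(A_rows)]
    zero = field.zero_raw
    pivots = []
    r = 0
    for c in range(n):
        pivot = next((i for i in range(r, m) if aug[i][c] != zero), None)
        if pivot is None:
            continue
        aug[r], aug[pivot] = aug[pivot], aug[r]
        inv = field.inv(aug[r][c])
        aug[r] = [field.mul(inv, v) for v in aug[r]]
        for i in range(m):
            if i != r and aug[i][c] != zero:
                factor = aug[i][c]
                aug[i] = [
                    field.sub(v, field.mul(factor, w))
                    for v, w in zip(aug[i], aug[r])
                ]
        pivots.append(c)
        r += 1
        if r == m:
            break
    for i in range(r, m):
        if aug[i][n] != zero:
            return None  # inconsistent
    x = [zero] * n
    for row_idx, c in enumerate(pivots):
        x[c] = aug[row_idx][n]
    return x, n - len(pivots)


def matrix_inverse(field: Field, M) -> list:
    """Exact inverse of a square matrix; raises on singular input."""
    M = _coerce_matrix(field, M)
    n = len(M)
    zero, one = field.zero_raw, field.one_raw
    aug = [list(M[i]) + [one if j == i else zero for j in range(n)] for i in range(n)]
    for c in range(n):
        pivot = next((i for i in range(c, n) if aug[i][c] != zero), None)
        if pivot is None:
            raise AlgebraError("matrix is singular")
        aug[c], aug[pivot] = aug[pivot], aug[c]
        inv = field.inv(aug[c][c])
        aug[c] = [field.mul(inv, v) for v in aug[c]]
        for i in range(n):
            if i != c and aug[i][c] != zero:
                factor = aug[i][c]
                aug[i] = [
                    field.sub(v, field.mul(factor, w))
                    for v, w in zip(aug[i], aug[c])
                ]
    return [row[n:] for row in aug]


def apply_matrix(field: Field, coeffs, M) -> list:
    """Row-vector times matrix: (v M)_j = sum_i v_i M_ij, exact."""
    M = _coerce_matrix(field, M)
    v = [field.coerce(c) for c in coeffs]
    n_out = len(M[0])
    out = [field.zero_raw] * n_out
    for i, vi in enumerate(v):
        if vi == field.zero_raw:
            continue
        for j in range(n_out):
            out[j] = field.add(out[j], field.mul(vi, M[i][j]))
    return out


def change_of_basis(A: Algebra, M, new_labels: Sequence[str]) -> Algebra:
    """Re-express the same bilinear product in a new basis.

    Row i of ``M`` gives the old-basis coordinates of the i-th new basis
    vector; an element with new coordinates c has old coordinates c M.  The
    round trip through M then M^-1 restores the original tensor exactly.
    """
    f = A.field
    Mc = _coerce_matrix(f, M)
    if len(Mc) != A.n or any(len(row) != A.n for row in Mc):
        raise AlgebraError(f"change-of-basis matrix must be {A.n}x{A.n}")
    Minv = matrix_inverse(f, Mc)  # raises on singular M
    new_entries = []
    for i in range(A.n):
        plane = []
        bi = AlgebraElement(A, Mc[i])
        for j in range(A.n):
            bj = AlgebraElement(A, Mc[j])
            prod_old = multiply(A, bi, bj)
            plane.append(apply_matrix(f, prod_old.coeffs, Minv))
        new_entries.append(plane)
    provenance = dict(A.provenance)
    provenance["change_of_basis_from"] = list(A.basis_labels)
    return Algebra(f, new_labels, StructureTensor(f, new_entries), provenance)
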