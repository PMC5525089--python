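import pytest

from laalg import (
    Algebra,
    StructureTensor,
    golden_alpha,
    make_finite_field,
    mendelian_gametic,
    star_algebra,
)


@pytest.fixture(scope="session")
def gf4():
    """GF(2^2) built from t^2 + t + 1."""
    return make_finite_field(2, 2, [1, 1, 1])


@pytest.fixture(scope="session")
def gf9():
    """GF(3^2) built from x^2 + 1."""
    return make_finite_field(3, 2, [1, 0, 1])


@pytest.fixture(scope="session")
def alpha():
    """The golden root (-1 + sqrt 5)/2 with alpha + alpha^2 = 1."""
    return golden_alpha(+1)


@pytest.fixture(scope="session")
def m3_gold(alpha):
    """The star algebra M_3 over Q(sqrt 5)."""
    return star_algebra(3, alpha.field, alpha)


@pytest.fixture(scope="session")
def m4_gf4(gf4):
    """The star algebra M_4 over GF(2^2) with alpha = t."""
    return star_algebra(4, gf4, gf4.t)


def diagonal_algebra(field, n):
    """a_i a_j = delta_ij a_i: commutative, associative, satisfies the whole
    catalog; its left identity is (1, ..., 1)."""
    one, zero = field.one_raw, field.zero_raw
    entries = [
        [[one if (i == j == k) else zero for k in range(n)] for j in range(n)]
        for i in range(n)
    ]
    return Algebra(
        field,
        [f"a{i}" for i in range(1, n + 1)],
        StructureTensor(field, entries),
        {"constructor": "diagonal_fixture"},
    )


@pytest.fixture(scope="session")
def diag_gf4(gf4):
    return diagonal_algebra(gf4, 2)


@pytest.fixture(scope="session")
def mendel2():
    return mendelian_gametic(2)


@pytest.fixture(scope="session")
def mendel3():
    return mendelian_gametic(3)
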