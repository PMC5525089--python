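"""Constructors: Mendelian, general/LA gametic, zygotic, mutation, star."""

from fractions import Fraction

import pytest

from laalg import (
    QQ,
    SymbolicField,
    algebra_from_json,
    algebra_to_json,
    check_identity,
    gametic_from_tensor,
    golden_alpha,
    gonshor_basis,
    mendelian_gametic,
    mutation_algebra,
    random_gametic,
    star_algebra,
    zygotic_duplicate,
)
from laalg.algebra import StructureTensor
from laalg.constructors import ConstructorError


class TestMendelianGametic:
    def test_two_allele_products(self, mendel2):
        a1, a2 = mendel2.basis_element(1), mendel2.basis_element(2)
        assert a1 * a2 == mendel2.element([Fraction(1, 2), Fraction(1, 2)])
        assert a1 * a1 == a1 and a2 * a2 == a2

    def test_row_sums_all_one(self, mendel3):
        for i in range(1, 4):
            for j in range(1, 4):
                assert mendel3.tensor.row_sum(i, j) == 1

    def test_is_commutative_and_bounded(self, mendel3):
        assert mendel3.tensor.is_gametic_symmetric()
        assert mendel3.tensor.is_bounded01()
        assert check_identity(mendel3, "commutative").verdict == "holds"
        assert check_identity(mendel3, "associative").verdict == "fails"

    def test_characteristic_two_rejected(self, gf4):
        with pytest.raises(ConstructorError, match="characteristic 2"):
            mendelian_gametic(2, gf4)


class TestGameticFromTensor:
    def test_accepts_mendelian_tensor(self, mendel3):
        A = gametic_from_tensor(mendel3.tensor, QQ, la_variant=False)
        assert A.tensor == mendel3.tensor

    def _asymmetric_entries(self):
        # a1a2 = a1 but a2a1 = a2: valid frequencies, no symmetry
        one, zero = Fraction(1), Fraction(0)
        return [
            [[one, zero], [one, zero]],
            [[zero, one], [zero, one]],
        ]

    def test_symmetry_enforced_unless_la_variant(self):
        entries = self._asymmetric_entries()
        with pytest.raises(ConstructorError, match="symmetry"):
            gametic_from_tensor(StructureTensor(QQ, entries), QQ)
        A = gametic_from_tensor(
            StructureTensor(QQ, entries), QQ, la_variant=True
        )
        assert not A.tensor.is_gametic_symmetric()

    def test_bad_row_sum_rejected_with_location(self):
        entries = [
            [[Fraction(1, 2), Fraction(1, 4)], [Fraction(1, 2), Fraction(1, 2)]],
            [[Fraction(1, 2), Fraction(1, 2)], [Fraction(0), Fraction(1)]],
        ]
        with pytest.raises(ConstructorError, match=r"row \(i=1, j=1\) sums to 3/4"):
            gametic_from_tensor(StructureTensor(QQ, entries), QQ)

    def test_out_of_range_entry_rejected(self):
        entries = [
            [[Fraction(3, 2), Fraction(-1, 2)], [Fraction(1, 2), Fraction(1, 2)]],
            [[Fraction(1, 2), Fraction(1, 2)], [Fraction(0), Fraction(1)]],
        ]
        with pytest.raises(ConstructorError, match=r"outside \[0, 1\]"):
            gametic_from_tensor(StructureTensor(QQ, entries), QQ)


class TestRandomGametic:
    def test_deterministic_for_fixed_seed(self):
        A = random_gametic(3, seed=7)
        B = random_gametic(3, seed=7)
        assert A.tensor == B.tensor

    @pytest.mark.parametrize("la", [False, True])
    @pytest.mark.parametrize("seed", [0, 3, 11])
    def test_output_passes_gametic_validation(self, seed, la):
        A = random_gametic(3, seed=seed, la_variant=la)
        # revalidation must not raise
        gametic_from_tensor(A.tensor, QQ, la_variant=la)
        assert A.tensor.is_row_stochastic()
        assert A.tensor.is_bounded01()

    def test_la_variant_breaks_symmetry_for_some_seed(self):
        asymmetric = [
            not random_gametic(3, seed=s, la_variant=True).tensor.is_gametic_symmetric()
            for s in range(1, 21)
        ]
        assert any(asymmetric)

    def test_plain_variant_always_symmetric(self):
        for s in range(1, 11):
            assert random_gametic(3, seed=s).tensor.is_gametic_symmetric()


class TestZygoticDuplicate:
    def test_heterozygote_cross_gives_1_2_1(self, mendel2):
        Z, idx = zygotic_duplicate(mendel2)
        e12 = Z.basis_element(idx.position(1, 2))
        expected = Z.element([Fraction(1, 4), Fraction(1, 2), Fraction(1, 4)])
        assert e12 * e12 == expected

    def test_homozygote_cross_is_fixed(self, mendel2):
        Z, idx = zygotic_duplicate(mendel2)
        e11 = Z.basis_element(idx.position(1, 1))
        assert e11 * e11 == e11

    def test_duplicated_rows_sum_to_one(self):
        G = random_gametic(3, seed=4)
        Z, _ = zygotic_duplicate(G)
        assert Z.n == 6  # n(n+1)/2 zygote types
        assert Z.tensor.is_row_stochastic()

    def test_duplication_index_is_lexicographic(self, mendel3):
        _, idx = zygotic_duplicate(mendel3)
        assert idx.pairs == ((1, 1), (1, 2), (1, 3), (2, 2), (2, 3), (3, 3))
        assert idx.position(3, 1) == 3  # unordered lookup

    def test_preserves_weight_homomorphism(self):
        G = random_gametic(2, seed=8)
        Z, _ = zygotic_duplicate(G)
        x = Z.element([Fraction(1, 2), Fraction(1, 3), Fraction(1, 6)])
        y = Z.element([2, -1, 3])
        assert (x * y).weight() == x.weight() * y.weight()

    def test_requires_row_stochastic_input(self):
        from laalg import Algebra
        entries = [[[Fraction(1, 2), Fraction(0)] for _ in range(2)]
                   for _ in range(2)]  # every row sums to 1/2
        forged = Algebra(QQ, ["a1", "a2"], StructureTensor(QQ, entries), {})
        with pytest.raises(ConstructorError, match="row-stochastic"):
            zygotic_duplicate(forged)


class TestMutationAlgebra:
    def test_zero_rates_recover_mendelian(self):
        Mu = mutation_algebra(0, 0)
        M2 = mendelian_gametic(2)
        assert Mu.tensor == M2.tensor

    def test_paper_rates(self):
        Mu = mutation_algebra(Fraction(1, 4), Fraction(1, 2))
        D, R = Mu.basis_element(1), Mu.basis_element(2)
        assert D * D == Mu.element([Fraction(3, 4), Fraction(1, 4)])
        assert D * R == Mu.element([Fraction(5, 8), Fraction(3, 8)])
        assert D * R == R * D
        assert R * R == Mu.element([Fraction(1, 2), Fraction(1, 2)])

    def test_rate_out_of_range_rejected(self):
        with pytest.raises(ConstructorError, match="outside"):
            mutation_algebra(Fraction(5, 4), 0)

    def test_commutative_and_row_stochastic(self):
        Mu = mutation_algebra(Fraction(1, 3), Fraction(1, 5))
        assert check_identity(Mu, "commutative").verdict == "holds"
        assert Mu.tensor.is_row_stochastic()


class TestGonshorBasis:
    def test_symbolic_in_the_rates(self):
        """a^2 = a - r b, ab = (1-r-s)/2 b, b^2 = 0, for symbolic r, s."""
        F = SymbolicField(["r", "s"])
        Gon = gonshor_basis(mutation_algebra("r", "s", F))
        a, b = Gon.basis_element(1), Gon.basis_element(2)
        r, s = F("r"), F("s")
        assert a * a == a + (-r) * b
        assert a * b == ((1 - r - s) / 2) * b
        assert b * a == a * b
        assert (b * b).is_zero()

    def test_paper_rates_give_ab_eighth_b(self):
        Gon = gonshor_basis(mutation_algebra(Fraction(1, 4), Fraction(1, 2)))
        a, b = Gon.basis_element(1), Gon.basis_element(2)
        assert a * b == Fraction(1, 8) * b
        assert a * a == a - Fraction(1, 4) * b
        assert (b * b).is_zero()

    def test_round_trip_restores_dr_products(self):
        Mu = mutation_algebra(Fraction(1, 4), Fraction(1, 2))
        Gon = gonshor_basis(Mu)
        from laalg import change_of_basis
        back = change_of_basis(Gon, [[1, 0], [1, -1]], ["D", "R"])
        assert back.tensor == Mu.tensor

    def test_requires_mutation_algebra(self, mendel2):
        with pytest.raises(ConstructorError, match="mutation_algebra"):
            gonshor_basis(mendel2)


class TestStarAlgebra:
    def test_basis_elements_are_idempotent(self, m3_gold):
        for i in (1, 2, 3):
            ai = m3_gold.basis_element(i)
            assert ai * ai == ai

    def test_noncommutative_on_basis(self, m3_gold):
        a1, a2 = m3_gold.basis_element(1), m3_gold.basis_element(2)
        assert a1 * a2 != a2 * a1

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ConstructorError, match="alpha \\+ alpha\\^2 = 1"):
            star_algebra(3, QQ, Fraction(1, 2))

    def test_gf4_alpha_t_and_t_squared_both_valid(self, gf4):
        for a in (gf4.t, gf4.t * gf4.t):
            A = star_algebra(2, gf4, a)
            assert check_identity(A, "left_invertive").verdict == "holds"

    @pytest.mark.parametrize("n", [2, 4, 6])
    def test_row_stochastic_any_dimension(self, n, alpha):
        A = star_algebra(n, alpha.field, alpha)
        assert A.tensor.is_row_stochastic()


class TestJsonRoundTrip:
    @pytest.mark.parametrize("make", [
        lambda: mendelian_gametic(3),
        lambda: random_gametic(3, seed=5, la_variant=True),
        lambda: mutation_algebra(Fraction(1, 4), Fraction(1, 2)),
        lambda: star_algebra(3),
        lambda: zygotic_duplicate(mendelian_gametic(2))[0],
    ])
    def test_constructor_outputs_round_trip(self, make):
        A = make()
        B = algebra_from_json(algebra_to_json(A))
        assert B.tensor == A.tensor
        assert B.basis_labels == A.basis_labels
        assert B.field == A.field

    def test_gf4_star_round_trip(self, m4_gf4):
        B = algebra_from_json(algebra_to_json(m4_gf4))
        assert B.tensor == m4_gf4.tensor
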