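import math
import warnings

import numpy as np
import pytest

from funchill import (
    AbundanceVector,
    AlignmentError,
    CommunityMatrix,
    DegenerateDistanceError,
    DistanceMatrix,
    DomainError,
    ValidationError,
    cross_pair_measures,
    diversity_profile,
    fad,
    functional_hill_number,
    functional_triple,
    hill_number,
    legacy_differentiation,
    max_distance_effective_number,
    quadratic_entropy,
    weighted_gini_simpson,
)
from naive_oracles import naive_functional_D, naive_hill


def av(labels, vals):
    return AbundanceVector(tuple(labels), np.asarray(vals, dtype=float))


class TestHillNumber:
    @pytest.mark.parametrize(
        "p, q, expected",
        [
            ((0.25, 0.25, 0.25, 0.25), 2, 4.0),
            ((0.5, 0.25, 0.25), 0, 3.0),
            ((0.5, 0.25, 0.25), 2, 1.0 / (0.25 + 2 * 0.0625)),
            ((0.6, 0.4), 1, math.exp(-(0.6 * math.log(0.6) + 0.4 * math.log(0.4)))),
        ],
    )
    def test_known_values(self, p, q, expected):
        assert hill_number(p, q) == pytest.approx(expected, rel=1e-12)

    def test_between_one_and_richness(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            p = rng.dirichlet(np.ones(5))
            for q in (0, 0.5, 1, 2, 3):
                d = hill_number(p, q)
                assert 1.0 - 1e-12 <= d <= 5.0 + 1e-12
                assert d == pytest.approx(naive_hill(list(p), q), rel=1e-12)

    def test_negative_abundance_rejected(self):
        with pytest.raises(ValidationError):
            hill_number(av("ab", [0.5, -0.1]), 1)

    def test_negative_order_rejected(self):
        with pytest.raises(DomainError):
            hill_number((0.5, 0.5), -1)


class TestQuadraticEntropy:
    def test_desk_matrices(self, case1, case2, equal_p4):
        assert quadratic_entropy(equal_p4, case1) == pytest.approx(0.125)
        assert quadratic_entropy(equal_p4, case2) == pytest.approx(0.2875)

    def test_constant_distance_gives_constant(self, constant_dm):
        dm = constant_dm("abc", c=0.7, diagonal=True)
        p = av("abc", [0.2, 0.3, 0.5])
        assert quadratic_entropy(p, dm) == pytest.approx(0.7)

    def test_two_species(self):
        dm = DistanceMatrix(("a", "b"), [[0, 0.2], [0.2, 0]])
        assert quadratic_entropy(av("ab", [0.5, 0.5]), dm) == pytest.approx(0.1)

    def test_alignment_error_names_species(self, case1):
        with pytest.raises(AlignmentError) as exc:
            quadratic_entropy(av(["a", "x"], [0.5, 0.5]), case1)
        assert "x" in str(exc.value)


class TestFad:
    def test_desk_matrices(self, case1, case2):
        assert fad(case1) == pytest.approx(2.0)
        assert fad(case2) == pytest.approx(4.6)

    def test_subset_and_single(self, case1):
        assert fad(case1, ("a", "b")) == pytest.approx(0.2)
        assert fad(case1, ("a",)) == 0.0

    def test_unknown_species(self, case1):
        with pytest.raises(AlignmentError):
            fad(case1, ("a", "nope"))


class TestFunctionalHillNumber:
    def test_equal_abundances_give_richness(self, case1, case2, equal_p4):
        for dm in (case1, case2):
            for q in (0, 0.5, 1, 2, 3):
                assert functional_hill_number(equal_p4, dm, q) == pytest.approx(4.0)

    def test_q0_closed_form(self, case1, equal_p4):
        # sqrt(FAD / Q) = sqrt(2.0 / 0.125)
        assert functional_hill_number(equal_p4, case1, 0) == pytest.approx(4.0)

    def test_constant_distance_reduces_to_hill(self, constant_dm):
        dm = constant_dm("ab", c=0.3, diagonal=True)
        p = av("ab", [0.6, 0.4])
        for q in (0, 0.5, 1, 2, 3):
            assert functional_hill_number(p, dm, q) == pytest.approx(
                hill_number(p, q), rel=1e-9
            )

    def test_matches_naive_double_sum(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            S = rng.integers(2, 6)
            d = rng.uniform(0, 1, (S, S))
            d = np.triu(d, 1)
            d = d + d.T
            dm = DistanceMatrix(tuple("abcdef"[:S]), d)
            p = av("abcdef"[:S], rng.dirichlet(np.ones(S)))
            for q in (0, 0.5, 1, 2):
                assert functional_hill_number(p, dm, q) == pytest.approx(
                    naive_functional_D(list(p.abundances), d.tolist(), q), rel=1e-10
                )

    def test_zero_entropy_multispecies_is_error(self, constant_dm):
        dm = constant_dm("ab", c=0.0)
        with pytest.raises(DegenerateDistanceError):
            functional_hill_number(av("ab", [0.5, 0.5]), dm, 2)

    def test_single_species_returns_one_with_warning(self):
        dm = DistanceMatrix(("a",), [[0.0]])
        with pytest.warns(UserWarning):
            assert functional_hill_number(av("a", [1.0]), dm, 2) == 1.0


class TestFunctionalTriple:
    def test_desk_q0(self, case1, equal_p4):
        t = functional_triple(equal_p4, case1, 0)
        assert (t.Q, t.D, t.MD, t.FD) == pytest.approx((0.125, 4.0, 0.5, 2.0))

    def test_equal_abundance_fd_equals_fad(self, case2, equal_p4):
        for q in (0, 0.5, 1, 2, 3):
            assert functional_triple(equal_p4, case2, q).FD == pytest.approx(4.6)

    def test_two_species_q2(self):
        dm = DistanceMatrix(("a", "b"), [[0, 1.0], [1.0, 0]])
        t = functional_triple(av("ab", [0.5, 0.5]), dm, 2)
        assert t.Q == pytest.approx(0.5)
        assert t.FD == pytest.approx(2.0)

    def test_internal_identities(self, case2):
        p = av("abcd", [0.4, 0.3, 0.2, 0.1])
        for q in (0, 1, 2.5):
            t = functional_triple(p, case2, q)
            assert t.MD == pytest.approx(t.Q * t.D, rel=1e-9)
            assert t.FD == pytest.approx(t.Q * t.D**2, rel=1e-9)
            assert t.D >= 1.0 - 1e-12


class TestWeightedGiniSimpson:
    def test_two_species(self):
        dm = DistanceMatrix(("a", "b"), [[0, 1.0], [1.0, 0]])
        p = av("ab", [0.5, 0.5])
        assert weighted_gini_simpson(p, dm) == pytest.approx(0.375)
        # Q^2 / (Q - GS_D) must equal the order-2 total functional diversity
        assert 0.25 / (0.5 - 0.375) == pytest.approx(
            functional_triple(p, dm, 2).FD
        )

    def test_single_species_zero(self):
        dm = DistanceMatrix(("a",), [[0.0]])
        assert weighted_gini_simpson(av("a", [1.0]), dm) == 0.0

    def test_identity_on_random_instances(self, case2):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = av("abcd", rng.dirichlet(np.ones(4)))
            Q = quadratic_entropy(p, case2)
            gs = weighted_gini_simpson(p, case2)
            fd2 = functional_triple(p, case2, 2).FD
            assert fd2 * (Q - gs) == pytest.approx(Q**2, rel=1e-10)


class TestMaxDistanceEffectiveNumber:
    def test_closed_forms(self):
        assert max_distance_effective_number(0.0, 0.2) == 1.0
        assert max_distance_effective_number(0.125, 0.2) == pytest.approx(8 / 3)
        assert max_distance_effective_number(0.2875, 0.9) == pytest.approx(
            1.469388, abs=5e-7
        )

    def test_domain_error(self):
        with pytest.raises(DomainError):
            max_distance_effective_number(0.3, 0.2)


class TestCrossPair:
    def test_disjoint_pair(self, case1):
        p1 = av("ab", [0.5, 0.5])
        p2 = av("cd", [0.5, 0.5])
        r = cross_pair_measures(p1, p2, case1, 0)
        assert r.Q_km == pytest.approx(0.2)
        assert r.FAD_km == pytest.approx(0.8)
        assert r.FD_pair == pytest.approx(0.8)  # q=0: FD = FAD_12

    def test_identical_assemblages(self, case1, equal_p4):
        r = cross_pair_measures(equal_p4, equal_p4, case1, 2)
        assert r.Q_km == pytest.approx(quadratic_entropy(equal_p4, case1))
        assert r.FD_pair == pytest.approx(r.Q_km * r.D_pair**2, rel=1e-9)

    def test_disjoint_fad_additivity(self, case1):
        # FAD(pooled) = FAD_11 + FAD_12 + FAD_21 + FAD_22 for distinct sets
        p1 = av("ab", [0.5, 0.5])
        p2 = av("cd", [0.5, 0.5])
        f11 = fad(case1, ("a", "b"))
        f22 = fad(case1, ("c", "d"))
        f12 = cross_pair_measures(p1, p2, case1, 0).FAD_km
        f21 = cross_pair_measures(p2, p1, case1, 0).FAD_km
        assert f11 + f12 + f21 + f22 == pytest.approx(fad(case1))

    def test_symmetry(self, case2):
        p1 = av("ab", [0.7, 0.3])
        p2 = av("cd", [0.2, 0.8])
        assert cross_pair_measures(p1, p2, case2, 2).Q_km == pytest.approx(
            cross_pair_measures(p2, p1, case2, 2).Q_km
        )


class TestLegacyDifferentiation:
    def test_ultrametric_desk_case(self, case1, two_assemblages):
        r = legacy_differentiation(two_assemblages, case1)
        assert r.Q_gamma == pytest.approx(0.125)
        assert r.Q_alpha == pytest.approx(0.05)
        assert r.diff_additive == pytest.approx(0.6, abs=5e-4)
        assert r.diff_debello == pytest.approx(1.0, abs=5e-4)
        assert r.diff_villeger == pytest.approx(1.0, abs=5e-4)

    def test_non_ultrametric_desk_case(self, case2, two_assemblages):
        r = legacy_differentiation(two_assemblages, case2)
        assert r.Q_gamma == pytest.approx(0.2875)
        assert r.diff_additive == pytest.approx(0.826, abs=5e-4)
        assert r.diff_debello == pytest.approx(0.559, abs=5e-4)
        assert r.diff_villeger == pytest.approx(0.388, abs=5e-4)

    def test_identical_assemblages_no_excess(self, case2):
        z = np.array([[0.4, 0.4], [0.3, 0.3], [0.2, 0.2], [0.1, 0.1]])
        Z = CommunityMatrix(("a", "b", "c", "d"), ("I", "II"), z)
        r = legacy_differentiation(Z, case2)
        assert r.diff_additive == pytest.approx(0.0, abs=1e-12)


class TestDiversityProfile:
    def test_equal_abundance_constants(self, case1, equal_p4):
        prof = diversity_profile(equal_p4, case1, (0, 1, 2))
        assert [t.D for t in prof] == pytest.approx([4.0, 4.0, 4.0])
        assert [t.FD for t in prof] == pytest.approx([2.0, 2.0, 2.0])

    def test_hill_profile_non_increasing(self):
        rng = np.random.default_rng(11)
        p = rng.dirichlet(np.ones(6))
        qs = np.linspace(0, 4, 17)
        vals = [hill_number(p, q) for q in qs]
        assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_continuity_across_unity(self, case2):
        p = av("abcd", [0.4, 0.3, 0.2, 0.1])
        prof = diversity_profile(p, case2, (1 - 1e-6, 1, 1 + 1e-6))
        d = [t.D for t in prof]
        assert abs(d[0] - d[1]) < 1e-4 and abs(d[2] - d[1]) < 1e-4
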