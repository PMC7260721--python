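import itertools
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nutrinet import (
    GeneSet,
    hypergeometric_overlap,
    mutant_nutrient_intersections,
    overlap_coefficient,
    venn_partition,
)


def enumerate_hypergeom_tail(N, size_a, size_b, observed):
    """Exhaustive oracle: count draws of size |B| with >= observed hits in A."""
    universe = list(range(N))
    a = set(universe[:size_a])
    hits = sum(
        1 for draw in itertools.combinations(universe, size_b) if len(a & set(draw)) >= observed
    )
    return hits / math.comb(N, size_b)


class TestOverlapCoefficient:
    def test_nested_is_one_disjoint_is_zero(self):
        assert overlap_coefficient({"a", "b"}, {"a", "b", "c"}) == 1.0
        assert overlap_coefficient({"a"}, {"b", "c"}) == 0.0

    def test_direct_arithmetic(self):
        a = {"g1", "g2", "g3", "g4"}
        b = {"g3", "g4", "g5", "g6", "g7", "g8"}
        assert overlap_coefficient(a, b) == pytest.approx(0.5)

    def test_symmetry_and_outside_invariance(self):
        a, b = {"x", "y"}, {"y", "z", "w"}
        assert overlap_coefficient(a, b) == overlap_coefficient(b, a)
        # enlarging the larger set leaves min(|A|, |B|) and the overlap alone
        assert overlap_coefficient(a, b | {"q9"}) == overlap_coefficient(a, b)

    def test_empty_set_error(self):
        with pytest.raises(ValueError, match="empty"):
            overlap_coefficient(set(), {"a"})


class TestHypergeometricOverlap:
    def test_zero_overlap_is_certain(self):
        u = set("abcdefgh")
        assert hypergeometric_overlap({"a"}, {"b"}, u) == pytest.approx(1.0)

    def test_worked_value_5_of_210(self):
        # N=10, |A|=5, |B|=4, overlap 4: C(5,4)C(5,0)/C(10,4) = 5/210
        u = {f"u{i}" for i in range(10)}
        a = {f"u{i}" for i in range(5)}
        b = {f"u{i}" for i in range(1, 5)}
        assert len(a & b) == 4
        assert hypergeometric_overlap(a, b, u) == pytest.approx(5 / 210, abs=1e-12)

    @pytest.mark.parametrize("N", [5, 8, 12])
    def test_matches_exhaustive_enumeration(self, N):
        u = {f"u{i}" for i in range(N)}
        for size_a in range(1, N + 1, 2):
            for size_b in range(1, N + 1, 3):
                a = {f"u{i}" for i in range(size_a)}
                b_members = [f"u{i}" for i in range(N)][-size_b:]
                b = set(b_members)
                expected = enumerate_hypergeom_tail(N, size_a, size_b, len(a & b))
                assert hypergeometric_overlap(a, b, u) == pytest.approx(expected, abs=1e-10)

    def test_monotone_in_overlap(self):
        # fixed |A|=15, |B|=10, N=40: the tail never grows with the overlap
        u = [f"u{i}" for i in range(40)]
        a = set(u[:15])
        tails = []
        for k in range(0, 11):
            b = set(u[:k]) | set(u[30 : 40 - k])
            assert len(b) == 10 and len(a & b) == k
            tails.append(hypergeometric_overlap(a, b, set(u)))
        assert all(t1 >= t2 - 1e-12 for t1, t2 in zip(tails, tails[1:]))

    def test_outside_universe_error(self):
        with pytest.raises(ValueError, match="outside"):
            hypergeometric_overlap({"a"}, {"b"}, {"a"})

    def test_monte_carlo_cross_check(self, rng):
        N, na, nb = 60, 20, 15
        u = [f"u{i}" for i in range(N)]
        a = set(u[:na])
        b = set(u[10 : 10 + nb])
        observed = len(a & b)
        draws = 20000
        hits = sum(
            1
            for _ in range(draws)
            if len(a & set(rng.choice(u, size=nb, replace=False))) >= observed
        )
        mc = hits / draws
        se = np.sqrt(mc * (1 - mc) / draws)
        assert abs(hypergeometric_overlap(a, b, u) - mc) < 4 * max(se, 1e-4)


class TestVennPartition:
    def test_disjoint_pair(self):
        regions = venn_partition([{"a", "b"}, {"c"}])
        assert regions[(True, False)] == 2
        assert regions[(False, True)] == 1
        assert regions[(True, True)] == 0

    def test_three_set_hand_enumeration(self):
        a, b, c = {"1", "2", "3"}, {"2", "3", "4"}, {"3", "4", "5"}
        r = venn_partition([a, b, c])
        assert r[(True, True, True)] == 1
        assert r[(True, True, False)] == 1
        assert r[(False, True, True)] == 1
        assert r[(True, False, False)] == 1
        assert r[(False, True, False)] == 0
        assert r[(False, False, True)] == 1
        assert r[(True, False, True)] == 0

    @given(
        st.lists(st.sets(st.integers(0, 20)), min_size=2, max_size=3),
    )
    def test_regions_partition_the_union(self, sets):
        sets = [set(map(str, s)) for s in sets]
        regions = venn_partition(sets)
        assert sum(regions.values()) == len(set().union(*sets))


class TestMutantIntersections:
    def test_planted_sizes_recovered_exactly(self, small_dataset):
        _, truth = small_dataset
        universe = GeneSet.from_iterable("universe", {f"G{i:05d}" for i in range(400)})
        results = mutant_nutrient_intersections(
            GeneSet.from_iterable("common_responsive", truth.common_responsive),
            [GeneSet.from_iterable(g, s) for g, s in sorted(truth.mutant_sets.items())],
            universe,
        )
        by_name = {r.set_b: r.intersection for r in results}
        assert by_name == truth.planted_intersections

    def test_identical_sets_have_coefficient_one(self):
        common = GeneSet.from_iterable("common", {"a", "b", "c"})
        res = mutant_nutrient_intersections(common, [common], GeneSet.from_iterable("u", "abcdef"))
        assert res[0].overlap_coefficient == 1.0

    def test_planted_enrichment_is_extreme(self):
        # standard study design: 240-gene common pool, 130-gene mutant set
        # with 40 planted shared genes in a 2000-gene universe
        from nutrinet import SimulationConfig, simulate_multistudy

        _, truth = simulate_multistudy(SimulationConfig(seed=8))
        universe = {f"G{i:05d}" for i in range(2000)}
        p = hypergeometric_overlap(truth.common_responsive, truth.mutant_sets["agb1"], universe)
        assert p < 1e-6
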