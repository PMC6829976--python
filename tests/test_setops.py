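"""Boolean set algebra, intersection lattice, overlap statistics."""

import itertools
import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from consig.genesets import GeneSet, GeneSetError
from consig.setops import (
    LatticeMode,
    SetOp,
    boolean_combine,
    build_lattice,
    hypergeom_overlap_p,
    jaccard_matrix,
)
from consig.synth import SyntheticScenario, gen_species_sets
from consig.homology import project_to_human


def _gs(set_id, members):
    return GeneSet.from_symbols(set_id, members)


class TestBooleanCombine:
    def test_intersect(self):
        out = boolean_combine(
            SetOp.INTERSECT, [_gs("1", "ABC"), _gs("2", "BCD"), _gs("3", "C")]
        )
        assert out.members == {"C"}

    def test_union_idempotent(self):
        s = _gs("1", "ABC")
        assert boolean_combine(SetOp.UNION, [s, s]).members == s.members

    def test_difference_first_minus_rest(self):
        out = boolean_combine(SetOp.DIFFERENCE, [_gs("1", "ABCD"), _gs("2", "B"), _gs("3", "C")])
        assert out.members == {"A", "D"}

    def test_zero_sets_error(self):
        with pytest.raises(GeneSetError):
            boolean_combine(SetOp.UNION, [])

    def test_difference_needs_two(self):
        with pytest.raises(GeneSetError):
            boolean_combine(SetOp.DIFFERENCE, [_gs("1", "A")])

    def test_planted_core_triple_intersection(self):
        """Three synthetic species sets with disjoint noise intersect in the planted core."""
        sc = SyntheticScenario(seed=11, core_size=96)
        species_sets, omap, _supp, truth = gen_species_sets(sc)
        projected = [
            project_to_human(species_sets[sp], omap).gene_set
            for sp in sorted(species_sets)
        ]
        core = boolean_combine(SetOp.INTERSECT, projected)
        assert sorted(core.members) == list(truth.core)
        assert len(core) == 96


class TestLattice:
    def test_single_set(self):
        lat = build_lattice([_gs("S", "ABC")])
        assert len(lat.nodes) == 1
        assert lat.nodes[0].genes == {"A", "B", "C"}

    def test_two_sets_hand_checked(self):
        sets = [_gs("1", "AB"), _gs("2", "BC")]
        at_least = build_lattice(sets, LatticeMode.AT_LEAST)
        contents = {n.child_set_ids: n.genes for n in at_least.nodes}
        assert contents == {
            ("1",): {"A", "B"},
            ("2",): {"B", "C"},
            ("1", "2"): {"B"},
        }
        exact = build_lattice(sets, LatticeMode.EXACT)
        contents = {n.child_set_ids: n.genes for n in exact.nodes}
        assert contents == {("1",): {"A"}, ("2",): {"C"}, ("1", "2"): {"B"}}

    def test_guard(self):
        sets = [_gs(str(i), {f"A{i}", "Z"}) for i in range(13)]
        with pytest.raises(GeneSetError, match="max_sets"):
            build_lattice(sets)

    @given(
        st.lists(
            st.sets(st.integers(0, 49), min_size=1, max_size=25),
            min_size=1,
            max_size=6,
        )
    )
    def test_at_least_matches_brute_force(self, families):
        sets = [_gs(f"S{i}", {f"G{g}" for g in fam}) for i, fam in enumerate(families)]
        lat = build_lattice(sets, LatticeMode.AT_LEAST)
        got = {n.child_set_ids: n.genes for n in lat.nodes}
        expected = {}
        for r in range(1, len(sets) + 1):
            for combo in itertools.combinations(sorted(s.set_id for s in sets), r):
                inter = set.intersection(
                    *[set(s.members) for s in sets if s.set_id in combo]
                )
                if inter:
                    expected[combo] = inter
        assert got == expected

    @given(
        st.lists(
            st.sets(st.integers(0, 49), min_size=1, max_size=25),
            min_size=1,
            max_size=6,
        )
    )
    def test_exact_mode_partitions_union(self, families):
        sets = [_gs(f"S{i}", {f"G{g}" for g in fam}) for i, fam in enumerate(families)]
        lat = build_lattice(sets, LatticeMode.EXACT)
        union = set().union(*(s.members for s in sets))
        sizes = sum(len(n.genes) for n in lat.nodes)
        assert sizes == len(union)
        all_genes = [g for n in lat.nodes for g in n.genes]
        assert len(all_genes) == len(set(all_genes))

    def test_edges_minimal_inclusion(self):
        sets = [_gs("1", "ABC"), _gs("2", "AB"), _gs("3", "A")]
        lat = build_lattice(sets)
        # triple node links to pair nodes, never directly skipping a level
        for parent, child in lat.edges:
            assert set(child) < set(parent)
            between = [
                n.child_set_ids
                for n in lat.nodes
                if set(child) < set(n.child_set_ids) < set(parent)
            ]
            assert not between

    def test_json_dot_export(self, tmp_path):
        lat = build_lattice([_gs("1", "AB"), _gs("2", "BC")])
        lat.write(tmp_path / "lat.json")
        lat.write(tmp_path / "lat.dot", fmt="dot")
        assert "digraph" in (tmp_path / "lat.dot").read_text()


def _brute_upper_tail(k, K, n, N):
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1)
    ) / math.comb(N, n)


class TestHypergeom:
    def test_k_zero_is_one(self):
        assert hypergeom_overlap_p(0, 5, 5, 10) == 1.0

    def test_full_overlap_exact_fraction(self):
        assert hypergeom_overlap_p(5, 5, 5, 10) == pytest.approx(1 / 252, abs=1e-15)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            hypergeom_overlap_p(6, 5, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_overlap_p(1, 11, 5, 10)

    def test_matches_enumeration_small_universe(self):
        """Every parameterization with N <= 12 agrees with brute force to 1e-12."""
        for N in range(1, 13):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(min(K, n) + 1):
                        assert hypergeom_overlap_p(k, K, n, N) == pytest.approx(
                            _brute_upper_tail(k, K, n, N), abs=1e-12
                        )

    def test_monotone_in_k(self):
        ps = [hypergeom_overlap_p(k, 10, 8, 30) for k in range(9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestJaccard:
    def test_identical_sets(self):
        stats = jaccard_matrix([_gs("1", "ABC"), _gs("2", "ABC")])
        assert stats[0].jaccard == 1.0

    def test_disjoint_sets(self):
        (s,) = jaccard_matrix([_gs("1", "AB"), _gs("2", "CD")])
        assert s.jaccard == 0.0 and s.p_value == 1.0

    def test_published_overlap_arithmetic(self):
        """|A|=2386, |B|=883, overlap 378 -> Jaccard 378/2891."""
        a = _gs("human", {f"G{i}" for i in range(2386)})
        b = _gs("mouse", {f"G{i}" for i in range(378)} | {f"M{i}" for i in range(505)})
        (s,) = jaccard_matrix([a, b])
        assert s.intersection_size == 378
        assert s.union_size == 2891
        assert s.jaccard == pytest.approx(378 / 2891, abs=1e-12)

    def test_symmetry(self):
        s1 = jaccard_matrix([_gs("1", "ABX"), _gs("2", "BCY")])[0]
        s2 = jaccard_matrix([_gs("2", "BCY"), _gs("1", "ABX")])[0]
        assert (s1.jaccard, s1.p_value) == (s2.jaccard, s2.p_value)

    def test_universe_must_contain_sets(self):
        with pytest.raises(GeneSetError):
            jaccard_matrix([_gs("1", "AB"), _gs("2", "BC")], universe=_gs("u", "AB"))

    def test_bh_adjustment_present(self):
        stats = jaccard_matrix([_gs("1", "AB"), _gs("2", "BC"), _gs("3", "CD")])
        assert all(0 <= s.q_value <= 1 and s.q_value >= s.p_value - 1e-15 for s in stats)
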