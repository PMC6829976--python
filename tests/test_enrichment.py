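"""Annotation propagation, term enrichment, cell-death flagging."""

import math

import networkx as nx
import numpy as np
import pytest

from consig.enrichment import (
    AnnotationSet,
    OntologyDAG,
    OntologyError,
    enrich,
    flag_cell_death,
    propagate_annotations,
    read_gaf,
    read_obo,
)
from consig.genesets import GeneSet


def _ann(direct):
    return AnnotationSet(direct={g: frozenset(t) for g, t in direct.items()})


class TestPropagation:
    def test_chain_closure(self, toy_dag):
        closed = propagate_annotations(toy_dag, _ann({"G1": {"T2"}}))
        assert closed.closed["G1"] == {"T0", "T1", "T2"}

    def test_part_of_propagates(self, toy_dag):
        closed = propagate_annotations(toy_dag, _ann({"G1": {"T3"}}))
        assert closed.closed["G1"] == {"T0", "T3"}

    def test_idempotent(self, toy_dag):
        once = propagate_annotations(toy_dag, _ann({"G1": {"T2"}, "G2": {"T3"}}))
        twice = propagate_annotations(toy_dag, once)
        assert dict(once.closed) == dict(twice.closed)

    def test_unknown_term_error(self, toy_dag):
        with pytest.raises(OntologyError, match="T99"):
            propagate_annotations(toy_dag, _ann({"G1": {"T99"}}))

    def test_cycle_rejected(self):
        with pytest.raises(OntologyError, match="cycle"):
            OntologyDAG(
                terms={"A": ("a", ""), "B": ("b", "")},
                edges=(("A", "B", "is_a"), ("B", "A", "is_a")),
            )

    def test_matches_reachability_oracle_on_random_dags(self):
        """Closure equals brute-force transitive reachability on 100 random DAGs."""
        rng = np.random.default_rng(2024)
        for _ in range(100):
            n = int(rng.integers(2, 15))
            ids = [f"T{i}" for i in range(n)]
            edges = []
            for i in range(1, n):
                for p in rng.choice(i, size=min(int(rng.integers(1, 3)), i), replace=False):
                    edges.append((ids[i], ids[int(p)], "is_a"))
            dag = OntologyDAG(terms={t: (t, "") for t in ids}, edges=tuple(edges))
            n_genes = int(rng.integers(1, 6))
            direct = {
                f"G{g}": {ids[int(t)] for t in rng.integers(0, n, size=2)}
                for g in range(n_genes)
            }
            closed = propagate_annotations(dag, _ann(direct))
            g = nx.DiGraph(); g.add_nodes_from(ids)
            g.add_edges_from([(c, p) for c, p, _ in edges])
            for gene, terms in direct.items():
                expected = set(terms)
                for t in terms:
                    expected |= nx.descendants(g, t)
                assert closed.closed[gene] == expected


class TestEnrich:
    def test_study_equals_background_all_p_one(self, toy_dag):
        genes = [f"G{i}" for i in range(6)]
        ann = _ann({g: {"T2" if i % 2 else "T3"} for i, g in enumerate(genes)})
        s = GeneSet.from_symbols("s", genes)
        results = enrich(s, s, toy_dag, ann)
        assert results and all(r.p_value == pytest.approx(1.0) for r in results)

    def test_root_annotating_everything_p_one(self, toy_dag):
        genes = [f"G{i}" for i in range(8)]
        ann = _ann({g: {"T0"} for g in genes})
        study = GeneSet.from_symbols("s", genes[:3])
        (res,) = enrich(study, GeneSet.from_symbols("b", genes), toy_dag, ann)
        assert res.term == "T0" and res.p_value == pytest.approx(1.0)

    def test_toy_exact_p(self, toy_dag):
        """Term annotating exactly the 4 study genes of 4/10 background genes: p = 1/C(10,4)."""
        genes = [f"G{i}" for i in range(10)]
        direct = {g: {"T2"} for g in genes[:4]}
        for g in genes[4:]:
            direct[g] = {"T3"}
        study = GeneSet.from_symbols("s", genes[:4])
        bg = GeneSet.from_symbols("b", genes)
        results = enrich(study, bg, toy_dag, _ann(direct))
        by_term = {r.term: r for r in results}
        assert by_term["T2"].p_value == pytest.approx(1 / math.comb(10, 4), abs=1e-15)
        # T1 inherits the same annotated genes by closure, so it ties T2
        assert results[0].p_value == pytest.approx(1 / math.comb(10, 4), abs=1e-15)
        assert by_term["T2"].most_specific

    def test_study_not_subset_errors(self, toy_dag):
        with pytest.raises(OntologyError):
            enrich(
                GeneSet.from_symbols("s", ["GX"]),
                GeneSet.from_symbols("b", ["GY"]),
                toy_dag,
                _ann({"GY": {"T0"}}),
            )

    def test_adding_unannotated_gene_never_decreases_p(self, toy_dag):
        genes = [f"G{i}" for i in range(9)]
        direct = {g: {"T2"} for g in genes[:3]}
        for g in genes[3:]:
            direct[g] = {"T3"}
        bg = GeneSet.from_symbols("b", genes + ["GNEW"])
        small = GeneSet.from_symbols("s", genes[:3])
        large = GeneSet.from_symbols("s2", genes[:3] + ["GNEW"])
        p_small = {r.term: r.p_value for r in enrich(small, bg, toy_dag, _ann(direct))}
        p_large = {r.term: r.p_value for r in enrich(large, bg, toy_dag, _ann(direct))}
        for term in p_small:
            assert p_large[term] >= p_small[term] - 1e-12

    def test_bh_matches_sort_oracle(self, toy_dag):
        """BH q-values agree with the direct step-up construction."""
        from scipy import stats

        rng = np.random.default_rng(5)
        ps = sorted(rng.random(80))
        qs = stats.false_discovery_control(ps, method="bh")
        m = len(ps)
        # direct oracle: q_i = min_{j >= i} (m * p_j / (j+1))
        expected = [min((m * ps[j]) / (j + 1) for j in range(i, m)) for i in range(m)]
        assert np.allclose(qs, expected, atol=1e-12)

    def test_most_specific_requires_beating_every_tested_ancestor(self, toy_dag):
        genes = [f"G{i}" for i in range(10)]
        direct = {g: {"T1"} for g in genes[:4]}  # study genes hit the middle term
        direct[genes[4]] = {"T2"}  # one non-study gene hits the leaf below it
        for g in genes[5:]:
            direct[g] = {"T3"}
        study = GeneSet.from_symbols("s", genes[:4])
        bg = GeneSet.from_symbols("b", genes)
        results = {r.term: r for r in enrich(study, bg, toy_dag, _ann(direct))}
        assert results["T1"].most_specific
        # the leaf scores p = 1, worse than its tested ancestor T1
        assert not results["T2"].most_specific


class TestCellDeathFlag:
    def test_descendant_hit_flags_true(self, toy_dag):
        ann = _ann({"G1": {"T2"}})  # T2 is_a T1 is_a T0
        flags = flag_cell_death(GeneSet.from_symbols("g", ["G1"]), toy_dag, ann, ["T1"])
        assert flags["G1"] is True

    def test_no_annotations_false(self, toy_dag):
        flags = flag_cell_death(GeneSet.from_symbols("g", ["GX"]), toy_dag, _ann({}), ["T0"])
        assert flags["GX"] is False

    def test_sibling_branch_not_flagged(self, toy_dag):
        ann = _ann({"G1": {"T3"}})
        flags = flag_cell_death(GeneSet.from_symbols("g", ["G1"]), toy_dag, ann, ["T1"])
        assert flags["G1"] is False

    def test_unknown_root_errors(self, toy_dag):
        with pytest.raises(OntologyError):
            flag_cell_death(GeneSet.from_symbols("g", ["G1"]), toy_dag, _ann({}), ["TX"])


class TestFileReaders:
    def test_obo_round_trip_toy(self, tmp_path):
        obo = """format-version: 1.2

[Term]
id: T:0001
name: root
namespace: proc

[Term]
id: T:0002
name: child
namespace: proc
is_a: T:0001 ! root

[Term]
id: T:0003
name: part
namespace: proc
relationship: part_of T:0001 ! root
"""
        p = tmp_path / "toy.obo"
        p.write_text(obo)
        dag = read_obo(p)
        assert set(dag.terms) == {"T:0001", "T:0002", "T:0003"}
        assert dag.ancestors("T:0002") == {"T:0001"}
        assert dag.ancestors("T:0003") == {"T:0001"}

    def test_gaf_reader(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("! comment\ngeneA\tT:0001\tIEA\ngenea\tT:0002\n")
        ann = read_gaf(p)
        assert ann.direct["GENEA"] == {"T:0001", "T:0002"}
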