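"""Ontology-aware term enrichment over a user-supplied ontology and
gene-term annotations.

Annotations obey the true-path rule: a gene annotated to a term is
implicitly annotated to every ancestor reachable through ``is_a`` and
``part_of`` edges.  After propagation each term's overlap with a study set
is scored with the hypergeometric upper tail against a background set, and
Benjamini–Hochberg adjusted within each ontology namespace.  A generic
reachability flag (:func:`flag_cell_death`) marks genes annotated anywhere
under a chosen family of root terms, e.g. cell-death processes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import obonet
import pandas as pd
from scipy import stats

from .genesets import GeneSet, normalize_symbol
from .setops import hypergeom_overlap_p

#: edge relations that propagate annotations (regulates-type edges do not)
DEFAULT_PROPAGATING = ("is_a", "part_of")


class OntologyError(ValueError):
    """Malformed ontology or annotation input."""


@dataclass(frozen=True)
class OntologyDAG:
    """Acyclic ontology: term metadata plus child -> parent edges by relation."""

    terms: Mapping[str, tuple[str, str]]  # id -> (name, namespace)
    edges: tuple[tuple[str, str, str], ...]  # (child, parent, relation)
    propagating: tuple[str, ...] = DEFAULT_PROPAGATING

    def __post_init__(self) -> None:
        for child, parent, _rel in self.edges:
            if child not in self.terms or parent not in self.terms:
                raise OntologyError(f"edge {child}->{parent} references unknown term")
        if not nx.is_directed_acyclic_graph(self.graph()):
            raise OntologyError("ontology contains a cycle")

    def graph(self) -> nx.DiGraph:
        """Child -> parent digraph restricted to propagating relations."""
        g = nx.DiGraph()
        g.add_nodes_from(self.terms)
        g.add_edges_from(
            (c, p) for c, p, rel in self.edges if rel in self.propagating
        )
        return g

    def ancestors(self, term: str) -> set[str]:
        """All terms reachable upward from ``term`` (excluding itself)."""
        return nx.descendants(self.graph(), term)  # edges point child -> parent

    def descendants(self, term: str) -> set[str]:
        return nx.ancestors(self.graph(), term)

    def namespace(self, term: str) -> str:
        return self.terms[term][1]


def read_obo(path: str | Path, *, propagating: Sequence[str] = DEFAULT_PROPAGATING) -> OntologyDAG:
    """Read an OBO file (term stanzas with is_a / relationship: part_of)."""
    graph = obonet.read_obo(str(path))
    terms = {
        tid: (data.get("name", tid), data.get("namespace", ""))
        for tid, data in graph.nodes(data=True)
    }
    edges = tuple(
        sorted((child, parent, rel) for child, parent, rel in graph.edges(keys=True))
    )
    return OntologyDAG(terms=terms, edges=edges, propagating=tuple(propagating))


@dataclass(frozen=True)
class AnnotationSet:
    """Gene -> term annotations, direct and (optionally) closed under the DAG."""

    direct: Mapping[str, frozenset[str]]
    closed: Mapping[str, frozenset[str]] = field(default_factory=dict)

    @property
    def is_propagated(self) -> bool:
        return bool(self.closed)


def read_gaf(path: str | Path) -> AnnotationSet:
    """Read a minimal GAF-like TSV: gene <TAB> term [<TAB> evidence].

    Lines starting with ``!`` or ``#`` are comments.
    """
    direct: dict[str, set[str]] = {}
    with Path(path).open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line[0] in "!#":
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise OntologyError(
                    f"{path}:{lineno}: expected gene<TAB>term, got {line!r}"
                )
            direct.setdefault(normalize_symbol(fields[0]), set()).add(fields[1].strip())
    return AnnotationSet(direct={g: frozenset(t) for g, t in direct.items()})


def propagate_annotations(dag: OntologyDAG, ann: AnnotationSet) -> AnnotationSet:
    """Close annotations under the true-path rule.  Idempotent.

    Raises :class:`OntologyError` listing genes annotated to unknown terms.
    """
    offenders = sorted(
        f"{g}->{t}"
        for g, terms in ann.direct.items()
        for t in terms
        if t not in dag.terms
    )
    if offenders:
        raise OntologyError(f"annotations to unknown terms: {', '.join(offenders)}")
    graph = dag.graph()
    # cache ancestor sets per distinct term
    anc: dict[str, set[str]] = {}
    closed: dict[str, frozenset[str]] = {}
    for gene, terms in ann.direct.items():
        full: set[str] = set()
        for t in terms:
            if t not in anc:
                anc[t] = nx.descendants(graph, t)  # upward reachability
            full.add(t)
            full |= anc[t]
        closed[gene] = frozenset(full)
    return AnnotationSet(direct=ann.direct, closed=closed)


@dataclass(frozen=True)
class EnrichmentResult:
    """Hypergeometric enrichment of one term in a study set."""

    term: str
    name: str
    namespace: str
    k: int  # study genes annotated
    K: int  # background genes annotated
    n: int  # study size
    N: int  # background size
    p_value: float
    q_value: float
    most_specific: bool


def enrich(
    study: GeneSet,
    background: GeneSet,
    dag: OntologyDAG,
    ann: AnnotationSet,
) -> list[EnrichmentResult]:
    """Term enrichment of a study set against a background.

    Requires ``study`` to be a subset of ``background``.  Annotations are
    propagated if they have not been already.  One result per term with at
    least one annotated background gene; BH adjustment is applied across
    all tested terms within each namespace; results are sorted by p-value
    then term id.  ``most_specific`` marks terms whose p-value is <= that
    of every tested ancestor.
    """
    if not study.members <= background.members:
        extra = sorted(study.members - background.members)[:5]
        raise OntologyError(f"study set is not a subset of background (e.g. {extra})")
    if not ann.is_propagated:
        ann = propagate_annotations(dag, ann)

    n = len(study.members)
    N = len(background.members)
    term_genes: dict[str, set[str]] = {}
    for gene in background.members:
        for term in ann.closed.get(gene, ()):
            term_genes.setdefault(term, set()).add(gene)

    rows: list[tuple[str, int, int, float]] = []
    for term in sorted(term_genes):
        bg_genes = term_genes[term]
        K = len(bg_genes)
        k = len(bg_genes & study.members)
        p = hypergeom_overlap_p(k, K, n, N)
        rows.append((term, k, K, p))

    # BH within namespace
    qmap: dict[str, float] = {}
    by_ns: dict[str, list[tuple[str, float]]] = {}
    for term, _k, _K, p in rows:
        by_ns.setdefault(dag.namespace(term), []).append((term, p))
    for ns_rows in by_ns.values():
        qs = stats.false_discovery_control([p for _, p in ns_rows], method="bh")
        for (term, _p), q in zip(ns_rows, qs):
            qmap[term] = float(q)

    pmap = {term: p for term, _k, _K, p in rows}
    results: list[EnrichmentResult] = []
    for term, k, K, p in rows:
        tested_anc = [a for a in dag.ancestors(term) if a in pmap]
        most_specific = all(p <= pmap[a] for a in tested_anc)
        name, namespace = dag.terms[term]
        results.append(
            EnrichmentResult(
                term=term,
                name=name,
                namespace=namespace,
                k=k,
                K=K,
                n=n,
                N=N,
                p_value=p,
                q_value=qmap[term],
                most_specific=most_specific,
            )
        )
    results.sort(key=lambda r: (r.p_value, r.term))
    return results


def results_to_frame(results: Sequence[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def flag_cell_death(
    genes: GeneSet,
    dag: OntologyDAG,
    ann: AnnotationSet,
    root_terms: Iterable[str],
) -> dict[str, bool]:
    """Flag genes whose closed annotations touch the root terms or any descendant.

    The canonical use marks genes associated with any aspect of cell death,
    with the apoptosis/cell-death branch roots supplied by the caller.
    """
    roots = list(root_terms)
    for term in roots:
        if term not in dag.terms:
            raise OntologyError(f"unknown root term {term!r}")
    hit_terms: set[str] = set(roots)
    for term in roots:
        hit_terms |= dag.descendants(term)
    if not ann.is_propagated:
        ann = propagate_annotations(dag, ann)
    return {
        gene: bool(ann.closed.get(gene, frozenset()) & hit_terms)
        for gene in sorted(genes.members)
    }
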