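"""Boolean set algebra, the hierarchical-similarity intersection lattice,
and Jaccard / hypergeometric overlap statistics.

The intersection lattice generalises a Venn diagram to an arbitrary family
of gene sets: leaves are the input sets and an internal node holds the
genes common to every set named in its ``child_set_ids``.  In ``AT_LEAST``
mode a node carries the plain intersection of its member sets; in ``EXACT``
mode each gene is assigned to the single node naming precisely the sets
that contain it, so node contents partition the union of the inputs.

Overlap significance uses the hypergeometric upper tail: the probability
of drawing at least ``k`` shared genes when one set is sampled at random
from a fixed universe.  Benjamini–Hochberg adjusted values accompany every
raw p-value.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

from scipy import stats

from .genesets import GeneSet, GeneSetError

#: combinatorial guard: 2**12 - 1 candidate nodes at most by default
DEFAULT_MAX_SETS = 12


class SetOp(str, Enum):
    UNION = "UNION"
    INTERSECT = "INTERSECT"
    DIFFERENCE = "DIFFERENCE"


class LatticeMode(str, Enum):
    AT_LEAST = "AT_LEAST"
    EXACT = "EXACT"


def boolean_combine(op: SetOp | str, sets: Sequence[GeneSet]) -> GeneSet:
    """Exact set algebra over gene sets.

    ``UNION`` and ``INTERSECT`` fold over all inputs; ``DIFFERENCE`` is the
    first set minus the union of the rest (and requires >= 2 sets).  The
    result records the operation and input ids in its provenance.
    """
    op = SetOp(op)
    if len(sets) == 0:
        raise GeneSetError("boolean_combine requires at least one set")
    if op is SetOp.DIFFERENCE and len(sets) < 2:
        raise GeneSetError("DIFFERENCE requires at least two sets")
    members = set(sets[0].members)
    for gs in sets[1:]:
        if op is SetOp.UNION:
            members |= gs.members
        elif op is SetOp.INTERSECT:
            members &= gs.members
        else:
            members -= gs.members
    ids = ",".join(gs.set_id for gs in sets)
    return GeneSet(
        set_id=f"{op.value.lower()}({ids})",
        label=f"{op.value} of {len(sets)} sets",
        species=sets[0].species,
        members=frozenset(members),
        provenance=(f"{op.value}:{ids}",),
    )


@dataclass(frozen=True)
class LatticeNode:
    """One subset-intersection node: which input sets, and which genes."""

    child_set_ids: tuple[str, ...]  # sorted input set ids this node intersects
    genes: frozenset[str]

    @property
    def depth(self) -> int:
        return len(self.child_set_ids)


@dataclass(frozen=True)
class IntersectionLattice:
    """DAG of gene-set intersections over a family of input sets."""

    nodes: tuple[LatticeNode, ...]
    edges: tuple[tuple[tuple[str, ...], tuple[str, ...]], ...]  # parent -> child ids
    mode: LatticeMode

    def node_by_ids(self, set_ids: Iterable[str]) -> LatticeNode | None:
        key = tuple(sorted(set_ids))
        for node in self.nodes:
            if node.child_set_ids == key:
                return node
        return None

    def to_json(self) -> str:
        payload = {
            "mode": self.mode.value,
            "nodes": [
                {"child_set_ids": list(n.child_set_ids), "genes": sorted(n.genes)}
                for n in self.nodes
            ],
            "edges": [[list(p), list(c)] for p, c in self.edges],
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def to_dot(self) -> str:
        """Graphviz DOT rendering (node label: set ids and gene count)."""
        lines = ["digraph lattice {", "  rankdir=BT;"]
        idx = {n.child_set_ids: i for i, n in enumerate(self.nodes)}
        for node in self.nodes:
            label = "&cap;".join(node.child_set_ids)
            lines.append(
                f'  n{idx[node.child_set_ids]} [label="{label}\\n{len(node.genes)} genes"];'
            )
        for parent, child in self.edges:
            lines.append(f"  n{idx[parent]} -> n{idx[child]};")
        lines.append("}")
        return "\n".join(lines)

    def write(self, path: str | Path, fmt: str = "json") -> None:
        text = self.to_json() if fmt == "json" else self.to_dot()
        Path(path).write_text(text + "\n", encoding="utf-8")


def build_lattice(
    sets: Sequence[GeneSet],
    mode: LatticeMode | str = LatticeMode.AT_LEAST,
    *,
    max_sets: int = DEFAULT_MAX_SETS,
) -> IntersectionLattice:
    """Enumerate all non-empty subset intersections of a family of gene sets.

    Nodes are ordered by depth (number of intersected sets) then
    lexicographically by set ids, so output is deterministic.  Edges link
    each node to its minimal supersets present in the lattice (parent
    ``child_set_ids`` strictly contains the child's, with no retained node
    strictly between).

    Raises :class:`GeneSetError` when the family exceeds ``max_sets``
    (override explicitly for larger families).
    """
    mode = LatticeMode(mode)
    if not sets:
        raise GeneSetError("build_lattice requires at least one set")
    if len(sets) > max_sets:
        raise GeneSetError(
            f"{len(sets)} sets exceeds the lattice guard of {max_sets}; "
            "pass max_sets explicitly to override"
        )
    ids = [gs.set_id for gs in sets]
    if len(set(ids)) != len(ids):
        raise GeneSetError("input set ids must be unique")
    by_id = {gs.set_id: gs for gs in sets}

    candidates: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(sets) + 1):
        for combo in itertools.combinations(sorted(ids), r):
            inter = set(by_id[combo[0]].members)
            for sid in combo[1:]:
                inter &= by_id[sid].members
            if inter:
                candidates[combo] = inter

    if mode is LatticeMode.EXACT:
        # each gene belongs to the node of exactly the sets containing it
        exact: dict[tuple[str, ...], set[str]] = {}
        universe = set().union(*(gs.members for gs in sets))
        for gene in universe:
            key = tuple(sorted(sid for sid in ids if gene in by_id[sid].members))
            exact.setdefault(key, set()).add(gene)
        candidates = exact

    keys = sorted(candidates, key=lambda k: (len(k), k))
    nodes = tuple(
        LatticeNode(child_set_ids=k, genes=frozenset(candidates[k])) for k in keys
    )

    # covering edges: for each child scan supersets in ascending size; a
    # superset is a cover iff it contains no already-accepted (hence smaller)
    # minimal superset of the child
    edges: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    key_frozen = {k: frozenset(k) for k in keys}
    for child in keys:
        cs = key_frozen[child]
        accepted: list[frozenset[str]] = []
        for parent in keys:  # keys sorted by (size, ids): ascending size
            ps = key_frozen[parent]
            if len(ps) <= len(cs) or not cs < ps:
                continue
            if not any(q < ps for q in accepted):
                accepted.append(ps)
                edges.append((parent, child))
    return IntersectionLattice(nodes=nodes, edges=tuple(sorted(edges)), mode=mode)


def hypergeom_overlap_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric probability P(X >= k).

    ``X`` counts the overlap when a set of size ``n`` is drawn uniformly
    from a universe of ``N`` genes of which ``K`` belong to the other set.
    Computed through the survival function for numerical stability.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(
            f"invalid hypergeometric parameters k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass(frozen=True)
class OverlapStats:
    """Pairwise overlap measures between two gene sets."""

    set_a: str
    set_b: str
    intersection_size: int
    union_size: int
    jaccard: float
    p_value: float
    q_value: float
    universe_size: int


def jaccard_matrix(
    sets: Sequence[GeneSet], universe: GeneSet | None = None
) -> list[OverlapStats]:
    """Jaccard index and hypergeometric overlap p for every unordered pair.

    The universe defaults to the union of the inputs; an explicit
    background (e.g. all protein-coding genes) may be supplied, but must
    contain every input set.  Benjamini–Hochberg adjusted p-values are
    computed across all pairs.
    """
    if len(sets) < 2:
        raise GeneSetError("jaccard_matrix requires at least two sets")
    if universe is None:
        univ = set().union(*(gs.members for gs in sets))
    else:
        univ = set(universe.members)
        for gs in sets:
            if not gs.members <= univ:
                raise GeneSetError(
                    f"universe does not contain set {gs.set_id!r}"
                )
    N = len(univ)
    raw: list[tuple[str, str, int, int, float, float]] = []
    for a, b in itertools.combinations(sorted(sets, key=lambda g: g.set_id), 2):
        inter = len(a.members & b.members)
        union = len(a.members | b.members)
        jac = inter / union if union else 0.0
        p = hypergeom_overlap_p(inter, len(a.members), len(b.members), N)
        raw.append((a.set_id, b.set_id, inter, union, jac, p))
    pvals = [r[5] for r in raw]
    qvals = list(stats.false_discovery_control(pvals, method="bh")) if pvals else []
    return [
        OverlapStats(
            set_a=sa,
            set_b=sb,
            intersection_size=inter,
            union_size=union,
            jaccard=jac,
            p_value=p,
            q_value=float(q),
            universe_size=N,
        )
        for (sa, sb, inter, union, jac, p), q in zip(raw, qvals)
    ]
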