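"""Ortholog projection: map species gene sets into the human symbol
namespace so cross-species set intersections are well defined.

One-to-many homology uses union semantics — a species gene contributes all
of its human orthologs — because conservation asks whether *any* homolog
carries the chemical association.  Unmapped genes are dropped and counted
in the projection report rather than raising.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genesets import GeneSet, GeneSetError, OrthologMap


@dataclass(frozen=True)
class ProjectionResult:
    """Outcome of projecting one gene set into human symbols."""

    gene_set: GeneSet
    dropped: tuple[str, ...]  # species symbols with no human ortholog

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)


def project_to_human(gs: GeneSet, m: OrthologMap) -> ProjectionResult:
    """Project a gene set into human symbols through an ortholog map.

    Human input is returned unchanged (identity projection).  For other
    species the result is the union of each member's human orthologs;
    members without any mapping are dropped and listed in the report.

    Raises :class:`GeneSetError` if the set's species is not covered by the
    map.
    """
    if gs.species == "human":
        return ProjectionResult(gene_set=gs, dropped=())
    if gs.species not in m.species_list:
        raise GeneSetError(
            f"species {gs.species!r} not covered by ortholog map "
            f"(covers {m.species_list})"
        )
    projected: set[str] = set()
    dropped: list[str] = []
    for sym in sorted(gs.members):
        humans = m.human_orthologs(gs.species, sym)
        if humans:
            projected.update(humans)
        else:
            dropped.append(sym)
    out = GeneSet(
        set_id=f"{gs.set_id}_human",
        label=f"{gs.label} (projected to human)".strip(),
        species="human",
        members=frozenset(projected),
        provenance=gs.provenance + (f"project_to_human:{gs.set_id}",),
    )
    return ProjectionResult(gene_set=out, dropped=tuple(dropped))
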