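"""Gene x subtype regulation matrix and the resistant-subtype signature rule.

Given per-subtype up/down differentially-expressed gene sets and a focus
set (the conserved chemical-associated genes), the regulation matrix
records for every focus gene with at least one call whether it is UP,
DOWN, BOTH (listed in both the up and the down set of one subtype — a
curation conflict) or NONE in each subtype.

The resistance signature formalises "different expression behaviour in the
resistant subtypes compared to the sensitive subtypes": a gene is a
signature member iff some resistant subtype carries an UP or DOWN status
that differs from the gene's status in *every* sensitive subtype.  BOTH
statuses in a resistant subtype count as differential but match neither UP
nor DOWN.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .genesets import GeneSet, GeneSetError, normalize_symbol

logger = logging.getLogger(__name__)

STATUSES = ("UP", "DOWN", "BOTH", "NONE")


@dataclass(frozen=True)
class RegulationMatrix:
    """Ordered gene x subtype table of regulation statuses."""

    genes: tuple[str, ...]
    subtypes: tuple[str, ...]
    status: Mapping[tuple[str, str], str]

    def status_of(self, gene: str, subtype: str) -> str:
        """Status for a (gene, subtype) pair; NONE for genes outside the matrix."""
        return self.status.get((normalize_symbol(gene), subtype), "NONE")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            [[self.status[(g, st)] for st in self.subtypes] for g in self.genes],
            index=list(self.genes),
            columns=list(self.subtypes),
        )
        df.index.name = "gene"
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "RegulationMatrix":
        df = pd.read_csv(path, index_col="gene")
        genes = tuple(normalize_symbol(g) for g in df.index)
        subtypes = tuple(df.columns)
        status = {
            (g, st): str(df.loc[raw, st]).upper()
            for g, raw in zip(genes, df.index)
            for st in subtypes
        }
        for val in status.values():
            if val not in STATUSES:
                raise GeneSetError(f"invalid regulation status {val!r}")
        return cls(genes=genes, subtypes=subtypes, status=status)


def build_regulation_matrix(
    up_sets: Mapping[str, GeneSet],
    down_sets: Mapping[str, GeneSet],
    focus: GeneSet,
) -> RegulationMatrix:
    """Regulation matrix of the focus genes over the given subtypes.

    Rows are restricted to focus genes with at least one non-NONE status.
    A gene present in both the up and the down set of one subtype is
    recorded as BOTH with a logged warning (curation conflicts occur in
    real differential-expression compendia).
    """
    if set(up_sets) != set(down_sets):
        raise GeneSetError(
            f"subtype labels differ between up ({sorted(up_sets)}) "
            f"and down ({sorted(down_sets)}) sets"
        )
    subtypes = tuple(sorted(up_sets))
    status: dict[tuple[str, str], str] = {}
    genes: list[str] = []
    for gene in sorted(focus.members):
        any_call = False
        for st in subtypes:
            in_up = gene in up_sets[st].members
            in_down = gene in down_sets[st].members
            if in_up and in_down:
                val = "BOTH"
                logger.warning(
                    "gene %s listed in both up and down sets of subtype %s", gene, st
                )
            elif in_up:
                val = "UP"
            elif in_down:
                val = "DOWN"
            else:
                val = "NONE"
            status[(gene, st)] = val
            any_call = any_call or val != "NONE"
        if any_call:
            genes.append(gene)
        else:
            for st in subtypes:
                del status[(gene, st)]
    return RegulationMatrix(genes=tuple(genes), subtypes=subtypes, status=status)


@dataclass(frozen=True)
class RegulationSummary:
    """Per-subtype UP/DOWN/BOTH counts and any-subtype totals."""

    up: Mapping[str, int]
    down: Mapping[str, int]
    both: Mapping[str, int]
    genes_up_in_any: int
    genes_down_in_any: int
    n_genes: int


def summarize_counts(m: RegulationMatrix) -> RegulationSummary:
    """Count UP/DOWN/BOTH per subtype; BOTH is counted in neither UP nor DOWN."""
    up = {st: 0 for st in m.subtypes}
    down = {st: 0 for st in m.subtypes}
    both = {st: 0 for st in m.subtypes}
    up_any: set[str] = set()
    down_any: set[str] = set()
    for gene in m.genes:
        for st in m.subtypes:
            val = m.status[(gene, st)]
            if val == "UP":
                up[st] += 1
                up_any.add(gene)
            elif val == "DOWN":
                down[st] += 1
                down_any.add(gene)
            elif val == "BOTH":
                both[st] += 1
                up_any.add(gene)
                down_any.add(gene)
    return RegulationSummary(
        up=up,
        down=down,
        both=both,
        genes_up_in_any=len(up_any),
        genes_down_in_any=len(down_any),
        n_genes=len(m.genes),
    )


@dataclass(frozen=True)
class SignatureResult:
    """Genes whose resistant-subtype regulation differs from every sensitive status."""

    signature_genes: tuple[str, ...]
    per_gene_basis: Mapping[str, tuple[tuple[str, str], ...]]
    exclusivity: Mapping[str, tuple[str, ...]]  # partition key -> genes

    def to_json(self) -> str:
        payload = {
            "signature_genes": list(self.signature_genes),
            "per_gene_basis": {
                g: [list(pair) for pair in basis]
                for g, basis in self.per_gene_basis.items()
            },
            "exclusivity": {k: list(v) for k, v in self.exclusivity.items()},
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _differs_from_all_sensitive(
    m: RegulationMatrix, gene: str, r_status: str, sensitive: Sequence[str]
) -> bool:
    # BOTH counts as differential and matches neither UP nor DOWN
    for s in sensitive:
        s_status = m.status[(gene, s)]
        if r_status == s_status and r_status != "BOTH":
            return False
    return True


def resistant_signature(
    m: RegulationMatrix,
    resistant: Sequence[str],
    sensitive: Sequence[str],
) -> SignatureResult:
    """Extract the resistance signature from a regulation matrix.

    A gene is included iff some resistant subtype ``r`` has
    ``status(g, r) != NONE`` and that status differs from ``status(g, s)``
    for every sensitive subtype ``s``.  The exclusivity partition groups
    signature genes by which resistant subtypes contributed: exclusively
    the first label, exclusively the second, or both (for two resistant
    subtypes; with more, keys are sorted tuples of contributing labels).
    """
    resistant = list(resistant)
    sensitive = list(sensitive)
    if not resistant or not sensitive:
        raise GeneSetError("resistant and sensitive groups must be non-empty")
    if set(resistant) & set(sensitive):
        raise GeneSetError("resistant and sensitive groups must be disjoint")
    for st in (*resistant, *sensitive):
        if st not in m.subtypes:
            raise GeneSetError(f"subtype {st!r} not in matrix subtypes {m.subtypes}")

    sig: list[str] = []
    basis: dict[str, tuple[tuple[str, str], ...]] = {}
    for gene in m.genes:
        contributing: list[tuple[str, str]] = []
        for r in resistant:
            r_status = m.status[(gene, r)]
            if r_status == "NONE":
                continue
            if _differs_from_all_sensitive(m, gene, r_status, sensitive):
                contributing.append((r, r_status))
        if contributing:
            sig.append(gene)
            basis[gene] = tuple(contributing)

    exclusivity: dict[str, list[str]] = {}
    for gene in sig:
        labels = sorted({r for r, _ in basis[gene]})
        key = "+".join(labels) if len(labels) > 1 else f"only-{labels[0]}"
        exclusivity.setdefault(key, []).append(gene)
    return SignatureResult(
        signature_genes=tuple(sig),
        per_gene_basis=basis,
        exclusivity={k: tuple(v) for k, v in sorted(exclusivity.items())},
    )
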