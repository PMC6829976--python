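"""Gene identifiers, gene sets, and readers/writers for the flat formats
the pipeline consumes (GMT gene-set files, TSV ortholog tables).

All gene symbols are normalized to uppercase HGNC-style strings on entry;
every container in the package holds normalized symbols only, so set
operations across sources are well defined.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple

logger = logging.getLogger(__name__)

#: taxon labels accepted for gene sets
SPECIES_LABELS = ("human", "mouse", "rat", "other")

#: taxon labels an ortholog table may map from
ORTHOLOG_SPECIES = ("mouse", "rat")


class GeneID(NamedTuple):
    """A normalized gene identifier plus the scheme it belongs to."""

    symbol: str
    namespace: str = "HGNC-symbol"


class GeneSetError(ValueError):
    """Malformed gene-set input (bad GMT line, bad species label, ...)."""


def normalize_symbol(raw: str) -> str:
    """Normalize a gene symbol: strip surrounding whitespace, uppercase.

    Idempotent: ``normalize_symbol(normalize_symbol(x)) == normalize_symbol(x)``.
    Raises :class:`GeneSetError` for empty symbols or symbols with interior
    whitespace, which cannot be valid HGNC-style identifiers.
    """
    sym = raw.strip().upper()
    if not sym:
        raise GeneSetError(f"empty gene symbol (from {raw!r})")
    if any(ch.isspace() for ch in sym):
        raise GeneSetError(f"gene symbol contains whitespace: {raw!r}")
    return sym


@dataclass(frozen=True)
class GeneSet:
    """A named, unordered collection of normalized gene symbols.

    Parameters
    ----------
    set_id : str
        Identifier, unique within a collection.
    label : str
        Free-text description.
    species : str
        One of ``human``, ``mouse``, ``rat``, ``other``.
    members : frozenset of str
        Normalized symbols, duplicates collapsed.
    provenance : tuple of str
        How the set was derived (input set ids, operations applied).
    """

    set_id: str
    label: str = ""
    species: str = "human"
    members: frozenset[str] = frozenset()
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.species not in SPECIES_LABELS:
            raise GeneSetError(
                f"unknown species {self.species!r}; allowed: {SPECIES_LABELS}"
            )
        object.__setattr__(self, "members", frozenset(self.members))

    @classmethod
    def from_symbols(
        cls,
        set_id: str,
        symbols: Iterable[str],
        *,
        label: str = "",
        species: str = "human",
        provenance: tuple[str, ...] = (),
    ) -> "GeneSet":
        """Build a set from raw symbols, normalizing and collapsing duplicates."""
        seen: set[str] = set()
        n_dup = 0
        for raw in symbols:
            sym = normalize_symbol(raw)
            if sym in seen:
                n_dup += 1
            seen.add(sym)
        if n_dup:
            logger.warning(
                "gene set %s: collapsed %d duplicate member(s) after normalization",
                set_id,
                n_dup,
            )
        return cls(
            set_id=set_id,
            label=label,
            species=species,
            members=frozenset(seen),
            provenance=provenance,
        )

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, symbol: str) -> bool:
        return normalize_symbol(symbol) in self.members


def read_gmt(path: str | Path, *, species: str = "human") -> list[GeneSet]:
    """Read gene sets from a GMT file (tab-separated: id, description, members...).

    One :class:`GeneSet` per non-empty line; member symbols are normalized
    and duplicates collapsed with a logged warning.  Lines with fewer than
    two fields raise :class:`GeneSetError` naming the line number.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    seen_ids: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise GeneSetError(
                    f"{path}:{lineno}: malformed GMT line "
                    f"(expected >= 2 tab-separated fields, got {len(fields)})"
                )
            set_id, label, *members = fields
            if set_id in seen_ids:
                raise GeneSetError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            seen_ids.add(set_id)
            sets.append(
                GeneSet.from_symbols(
                    set_id,
                    (m for m in members if m.strip()),
                    label=label,
                    species=species,
                    provenance=(f"gmt:{path.name}",),
                )
            )
    return sets


def write_gmt(sets: Iterable[GeneSet], path: str | Path) -> None:
    """Write gene sets to GMT, members in lexicographic order.

    ``read_gmt(write_gmt(sets))`` is the identity on (set_id, label, members).
    """
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for gs in sets:
            fields = [gs.set_id, gs.label, *sorted(gs.members)]
            fh.write("\t".join(fields) + "\n")


@dataclass(frozen=True)
class OrthologMap:
    """Many-to-many mapping from (species, species_gene) to human symbols."""

    forward: Mapping[tuple[str, str], frozenset[str]]
    species_list: tuple[str, ...] = field(default=())

    def human_orthologs(self, species: str, gene: str) -> frozenset[str]:
        """Human symbols for a species gene; empty if unmapped."""
        return self.forward.get((species, normalize_symbol(gene)), frozenset())

    def reverse(self) -> dict[str, set[tuple[str, str]]]:
        """Index human symbol -> {(species, species_gene), ...}."""
        rev: dict[str, set[tuple[str, str]]] = {}
        for (species, gene), humans in self.forward.items():
            for h in humans:
                rev.setdefault(h, set()).add((species, gene))
        return rev

    def __len__(self) -> int:
        return len(self.forward)


def read_ortholog_table(path: str | Path) -> OrthologMap:
    """Read a TSV ortholog table with rows ``species<TAB>species_gene<TAB>human_gene``.

    Multiple rows for one species gene accumulate (many-to-many).  Lines
    starting with ``#`` are comments.  An unknown species label raises
    :class:`GeneSetError` listing the allowed labels.
    """
    path = Path(path)
    forward: dict[tuple[str, str], set[str]] = {}
    species_seen: set[str] = set()
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise GeneSetError(
                    f"{path}:{lineno}: expected 3 tab-separated fields, got {len(fields)}"
                )
            species = fields[0].strip().lower()
            if species not in ORTHOLOG_SPECIES:
                raise GeneSetError(
                    f"{path}:{lineno}: unknown species {species!r}; "
                    f"allowed: {ORTHOLOG_SPECIES}"
                )
            key = (species, normalize_symbol(fields[1]))
            forward.setdefault(key, set()).add(normalize_symbol(fields[2]))
            species_seen.add(species)
    frozen = {k: frozenset(v) for k, v in forward.items()}
    return OrthologMap(forward=frozen, species_list=tuple(sorted(species_seen)))


def write_ortholog_table(m: OrthologMap, path: str | Path) -> None:
    """Write an ortholog map as the TSV dialect :func:`read_ortholog_table` reads."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for (species, gene) in sorted(m.forward):
            for human in sorted(m.forward[(species, gene)]):
                fh.write(f"{species}\t{gene}\t{human}\n")
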