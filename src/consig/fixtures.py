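"""Packaged fixtures transcribing the published gene-set catalogue, the
20-gene regulation table, and the 13-gene resistance signature.

The regulation fixture is validated on load: malformed statuses, missing
death flags or a wrong gene count raise :class:`FixtureError` naming the
violated constraint.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from importlib import resources
from typing import Mapping

import pandas as pd

from .genesets import GeneSet, normalize_symbol

SUBTYPES = ("BL1", "BL2", "M", "LAR")
VALID_STATUS = ("UP", "DOWN", "NONE")


class FixtureError(ValueError):
    """A packaged fixture failed its consistency checks."""


def _data_path(name: str):
    return resources.files("consig.data").joinpath(name)


@dataclass(frozen=True)
class RegulationFixture:
    """Gene x subtype regulation statuses plus a per-gene cell-death flag."""

    genes: tuple[str, ...]
    subtypes: tuple[str, ...]
    status: Mapping[tuple[str, str], str]
    death_flag: Mapping[str, bool]

    def status_of(self, gene: str, subtype: str) -> str:
        return self.status[(normalize_symbol(gene), subtype)]

    def up_down_sets(self) -> tuple[dict[str, GeneSet], dict[str, GeneSet]]:
        """Derive per-subtype up/down gene sets from the status table."""
        ups: dict[str, GeneSet] = {}
        downs: dict[str, GeneSet] = {}
        for st in self.subtypes:
            up = [g for g in self.genes if self.status[(g, st)] == "UP"]
            down = [g for g in self.genes if self.status[(g, st)] == "DOWN"]
            ups[st] = GeneSet.from_symbols(f"{st}_up", up, label=f"up in {st}")
            downs[st] = GeneSet.from_symbols(f"{st}_down", down, label=f"down in {st}")
        return ups, downs


def load_table2_fixture() -> RegulationFixture:
    """Load the 20-gene regulation fixture, checking its invariants."""
    genes: list[str] = []
    status: dict[tuple[str, str], str] = {}
    death: dict[str, bool] = {}
    with _data_path("table2_regulation.csv").open(encoding="utf-8") as fh:
        rows = [r for r in csv.DictReader(filter(lambda l: not l.startswith("#"), fh))]
    for row in rows:
        gene = normalize_symbol(row["gene"])
        if gene in death:
            raise FixtureError(f"duplicate gene {gene} in regulation fixture")
        genes.append(gene)
        for st in SUBTYPES:
            val = row[st].strip().upper()
            if val not in VALID_STATUS:
                raise FixtureError(
                    f"invalid status {val!r} for ({gene}, {st}); allowed {VALID_STATUS}"
                )
            status[(gene, st)] = val
        if row["death"].strip() not in {"0", "1"}:
            raise FixtureError(f"death flag for {gene} must be 0 or 1")
        death[gene] = row["death"].strip() == "1"
    if len(genes) != 20:
        raise FixtureError(f"regulation fixture must contain 20 genes, found {len(genes)}")
    for gene in genes:
        if all(status[(gene, st)] == "NONE" for st in SUBTYPES):
            raise FixtureError(f"gene {gene} has no differential status in any subtype")
    return RegulationFixture(
        genes=tuple(genes), subtypes=SUBTYPES, status=status, death_flag=death
    )


def load_table3_fixture() -> dict[str, dict[str, str]]:
    """The 13-gene resistance signature: gene -> {resistant subtype: direction}."""
    out: dict[str, dict[str, str]] = {}
    with _data_path("table3_signature.csv").open(encoding="utf-8") as fh:
        for row in csv.DictReader(filter(lambda l: not l.startswith("#"), fh)):
            gene = normalize_symbol(row["gene"])
            subtype = row["subtype"].strip()
            if subtype not in ("LAR", "M"):
                raise FixtureError(f"signature subtype must be LAR or M, got {subtype!r}")
            out.setdefault(gene, {})[subtype] = row["direction"].strip().upper()
    if len(out) != 13:
        raise FixtureError(f"signature fixture must contain 13 genes, found {len(out)}")
    return out


def load_table1_fixture() -> pd.DataFrame:
    """Catalogue of the published gene sets (id, size, species, subtype, direction)."""
    with _data_path("table1_gene_sets.csv").open(encoding="utf-8") as fh:
        df = pd.read_csv(fh, dtype={"n_genes": int}, keep_default_na=False)
    return df


def load_narrative_counts() -> dict:
    """Published summary counts (set sizes, overlaps, conserved-core size...)."""
    with _data_path("narrative_counts.json").open(encoding="utf-8") as fh:
        return json.load(fh)


def supplemental_conserved_genes() -> GeneSet:
    """The six conserved genes contributed by the supplemental chemical set."""
    counts = load_narrative_counts()
    return GeneSet.from_symbols(
        "supplemental_conserved",
        counts["supplemental_conserved_genes"],
        label="conserved genes added by the supplemental chemical-association set",
    )
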