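"""End-to-end orchestration: conserved-core construction, signature
extraction, the packaged-table replay, and report serialization.

The replay (:func:`run_table_replay`) rebuilds every published summary
count from the packaged regulation fixture alone — per-subtype up/down
gene sets are derived from the fixture statuses, the regulation matrix is
rebuilt from those sets, and the signature, exclusivity partition,
cell-death and supplemental-gene counts are recomputed and checked against
the published values.  Any mismatch raises :class:`ReplayMismatchError`
naming the failed check.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import fixtures
from .genesets import GeneSet, GeneSetError, OrthologMap
from .homology import project_to_human
from .regulation import (
    RegulationMatrix,
    RegulationSummary,
    SignatureResult,
    build_regulation_matrix,
    resistant_signature,
    summarize_counts,
)
from .setops import SetOp, boolean_combine


class ReplayMismatchError(RuntimeError):
    """A recomputed count disagrees with the published value."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration for a pipeline run (file inputs or a synthetic scenario)."""

    species_set_paths: Mapping[str, str] | None = None  # species -> GMT path
    ortholog_path: str | None = None
    up_set_path: str | None = None  # GMT, one set per subtype
    down_set_path: str | None = None
    supplemental_path: str | None = None
    ontology_path: str | None = None
    annotation_path: str | None = None
    scenario_seed: int | None = None  # synthetic mode
    resistant: tuple[str, ...] = ("LAR", "M")
    sensitive: tuple[str, ...] = ("BL1", "BL2")
    lattice_mode: str = "AT_LEAST"
    universe: str | None = None  # optional GMT with a single background set
    outdir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        real = self.species_set_paths is not None
        synth = self.scenario_seed is not None
        if real == synth:
            raise GeneSetError(
                "exactly one of file inputs (species_set_paths) or a "
                "synthetic scenario (scenario_seed) must be provided"
            )
        if set(self.resistant) & set(self.sensitive):
            raise GeneSetError("resistant and sensitive groups must be disjoint")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with Path(path).open(encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        for key in ("resistant", "sensitive"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def digest(self) -> str:
        """Hash of the scientific configuration (the output path is excluded)."""
        payload = json.dumps(
            {
                k: list(v) if isinstance(v, tuple) else v
                for k, v in self.__dict__.items()
                if k != "outdir"
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def conserved_set(
    species_sets: Mapping[str, GeneSet],
    omap: OrthologMap,
    supplemental: GeneSet | None = None,
) -> tuple[GeneSet, dict]:
    """Build the evolutionarily conserved chemical-associated gene set.

    Each species set is projected into human symbols and the projections
    are intersected.  A supplemental human set (found through an
    additional source) contributes genes that are also present in every
    non-human projection but missing from the plain intersection — the
    conserved additions.  Returns the conserved set (intersection plus
    additions) and a detail record with projection drop counts and the
    addition list.
    """
    projections: dict[str, GeneSet] = {}
    dropped: dict[str, int] = {}
    for sp in sorted(species_sets):
        res = project_to_human(species_sets[sp], omap)
        projections[sp] = res.gene_set
        dropped[sp] = res.n_dropped
    core = boolean_combine(SetOp.INTERSECT, [projections[sp] for sp in sorted(projections)])

    additions: tuple[str, ...] = ()
    if supplemental is not None:
        non_human = [projections[sp] for sp in sorted(projections) if sp != "human"]
        supp_conserved = boolean_combine(SetOp.INTERSECT, [supplemental, *non_human])
        additions = tuple(sorted(supp_conserved.members - core.members))

    conserved = GeneSet(
        set_id="conserved_chem",
        label="conserved chemical-associated genes (triple intersection + supplemental)",
        species="human",
        members=core.members | set(additions),
        provenance=core.provenance + (f"supplemental_additions:{len(additions)}",),
    )
    detail = {
        "core_size": len(core),
        "core_members": sorted(core.members),
        "supplemental_additions": list(additions),
        "dropped_in_projection": dropped,
        "total": len(conserved),
    }
    return conserved, detail


@dataclass(frozen=True)
class RunReport:
    """Every count the pipeline reports, plus the objects behind them."""

    matrix: RegulationMatrix
    summary: RegulationSummary
    signature: SignatureResult
    death_flags: Mapping[str, bool]
    counts: Mapping[str, object]
    conserved_detail: Mapping[str, object] = field(default_factory=dict)
    provenance: Mapping[str, object] = field(default_factory=dict)

    def to_json(self) -> str:
        payload = {
            "counts": self.counts,
            "conserved": self.conserved_detail,
            "exclusivity": {k: list(v) for k, v in self.signature.exclusivity.items()},
            "signature_genes": list(self.signature.signature_genes),
            "death_flags": dict(self.death_flags),
            "provenance": self.provenance,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    def write(self, outdir: str | Path) -> None:
        """Serialize the report and all intermediates needed to recompute it."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "report.json").write_text(self.to_json() + "\n", encoding="utf-8")
        self.matrix.to_csv(outdir / "regulation_matrix.csv")
        (outdir / "signature.json").write_text(
            self.signature.to_json() + "\n", encoding="utf-8"
        )
        lines = ["pipeline report", "================", ""]
        for key in sorted(self.counts):
            lines.append(f"{key}: {self.counts[key]}")
        lines.append("")
        lines.append("signature genes: " + ", ".join(self.signature.signature_genes))
        (outdir / "report.txt").write_text("\n".join(lines) + "\n", encoding="utf-8")


def _check(label: str, got, expected) -> None:
    if got != expected:
        raise ReplayMismatchError(f"{label}: computed {got!r}, published {expected!r}")


def run_table_replay(*, strict: bool = True) -> RunReport:
    """Recompute all published Table 2/3 summary counts from the fixtures.

    With ``strict`` (default) any disagreement with the published values
    raises :class:`ReplayMismatchError`; the report is returned otherwise.
    """
    fixture = fixtures.load_table2_fixture()
    narrative = fixtures.load_narrative_counts()
    supplemental = fixtures.supplemental_conserved_genes()

    ups, downs = fixture.up_down_sets()
    focus = GeneSet(
        set_id="conserved_focus",
        label="conserved chemical-associated genes under study",
        members=frozenset(fixture.genes) | supplemental.members,
    )
    matrix = build_regulation_matrix(ups, downs, focus)
    summary = summarize_counts(matrix)
    signature = resistant_signature(
        matrix,
        tuple(narrative["resistant_subtypes"]),
        tuple(narrative["sensitive_subtypes"]),
    )
    death_flags = dict(fixture.death_flag)
    n_death = sum(death_flags.values())
    supp_de = sorted(supplemental.members & set(matrix.genes))

    counts: dict[str, object] = {
        "overlap_gene_count": len(matrix.genes),
        "up_in_any": summary.genes_up_in_any,
        "down_in_any": summary.genes_down_in_any,
        "signature_size": len(signature.signature_genes),
        "death_flagged": n_death,
        "supplemental_de_count": len(supp_de),
        "exclusivity_sizes": {
            k: len(v) for k, v in signature.exclusivity.items()
        },
        "per_subtype_up": dict(summary.up),
        "per_subtype_down": dict(summary.down),
    }

    if strict:
        _check("overlap gene count", counts["overlap_gene_count"], narrative["overlap_gene_count"])
        _check("up-in-any", counts["up_in_any"], narrative["up_in_any"])
        _check("down-in-any", counts["down_in_any"], narrative["down_in_any"])
        _check("signature size", counts["signature_size"], narrative["signature_size"])
        _check("death flagged", counts["death_flagged"], narrative["death_flagged"])
        _check(
            "supplemental DE count",
            counts["supplemental_de_count"],
            narrative["supplemental_de_count"],
        )
        _check(
            "exclusivity partition",
            counts["exclusivity_sizes"],
            narrative["exclusivity_sizes"],
        )
        for st, expected in narrative["subtype_overlap_counts"].items():
            _check(f"{st} up count", summary.up[st], expected["up"])
            _check(f"{st} down count", summary.down[st], expected["down"])
        table3 = fixtures.load_table3_fixture()
        _check(
            "signature membership",
            sorted(signature.signature_genes),
            sorted(table3),
        )
        for gene, basis in signature.per_gene_basis.items():
            _check(
                f"signature direction for {gene}",
                {st: status for st, status in basis},
                table3[gene],
            )

    return RunReport(
        matrix=matrix,
        summary=summary,
        signature=signature,
        death_flags=death_flags,
        counts=counts,
        provenance={"mode": "fixture-replay"},
    )


def run_synthetic(cfg: RunConfig) -> RunReport:
    """Full pipeline over a synthetic scenario: conserved core -> signature."""
    from .synth import SyntheticScenario, gen_species_sets, gen_subtype_sets

    sc = SyntheticScenario(seed=int(cfg.scenario_seed))
    species_sets, omap, supplemental, sp_truth = gen_species_sets(sc)
    conserved, detail = conserved_set(species_sets, omap, supplemental)
    up_sets, down_sets, st_truth = gen_subtype_sets(sc)
    matrix = build_regulation_matrix(up_sets, down_sets, conserved)
    summary = summarize_counts(matrix)
    signature = resistant_signature(matrix, cfg.resistant, cfg.sensitive)
    counts: dict[str, object] = {
        "conserved_core": detail["core_size"],
        "conserved_total": detail["total"],
        "overlap_gene_count": len(matrix.genes),
        "up_in_any": summary.genes_up_in_any,
        "down_in_any": summary.genes_down_in_any,
        "signature_size": len(signature.signature_genes),
        "planted_core_recovered": int(
            detail["core_members"] == sorted(sp_truth.core)
        ),
        "planted_signature_recovered": int(
            sorted(signature.signature_genes)
            == sorted(st_truth.intended_signature.signature_genes)
        ),
    }
    return RunReport(
        matrix=matrix,
        summary=summary,
        signature=signature,
        death_flags={},
        counts=counts,
        conserved_detail=detail,
        provenance={
            "mode": "synthetic",
            "scenario_seed": cfg.scenario_seed,
            "config_digest": cfg.digest(),
        },
    )


def run_from_files(cfg: RunConfig) -> RunReport:
    """Full pipeline over user-supplied GMT/TSV inputs."""
    from .genesets import read_gmt, read_ortholog_table

    species_sets: dict[str, GeneSet] = {}
    for sp, path in sorted(cfg.species_set_paths.items()):
        sets = read_gmt(path, species=sp)
        if len(sets) != 1:
            raise GeneSetError(f"{path}: expected one gene set per species file")
        species_sets[sp] = sets[0]
    omap = read_ortholog_table(cfg.ortholog_path)
    supplemental = None
    if cfg.supplemental_path:
        supp_sets = read_gmt(cfg.supplemental_path)
        if len(supp_sets) != 1:
            raise GeneSetError("supplemental GMT must contain exactly one set")
        supplemental = supp_sets[0]
    conserved, detail = conserved_set(species_sets, omap, supplemental)

    up_sets = {gs.set_id: gs for gs in read_gmt(cfg.up_set_path)}
    down_sets = {gs.set_id: gs for gs in read_gmt(cfg.down_set_path)}
    # GMT ids are "<subtype>_up" / "<subtype>_down"; strip the suffix
    up_sets = {sid.removesuffix("_up"): gs for sid, gs in up_sets.items()}
    down_sets = {sid.removesuffix("_down"): gs for sid, gs in down_sets.items()}
    matrix = build_regulation_matrix(up_sets, down_sets, conserved)
    summary = summarize_counts(matrix)
    signature = resistant_signature(matrix, cfg.resistant, cfg.sensitive)
    counts = {
        "conserved_core": detail["core_size"],
        "conserved_total": detail["total"],
        "overlap_gene_count": len(matrix.genes),
        "up_in_any": summary.genes_up_in_any,
        "down_in_any": summary.genes_down_in_any,
        "signature_size": len(signature.signature_genes),
    }
    return RunReport(
        matrix=matrix,
        summary=summary,
        signature=signature,
        death_flags={},
        counts=counts,
        conserved_detail=detail,
        provenance={"mode": "files", "config_digest": cfg.digest()},
    )


def run(cfg: RunConfig) -> RunReport:
    """Dispatch on configuration mode and write the report to ``cfg.outdir``."""
    report = run_synthetic(cfg) if cfg.scenario_seed is not None else run_from_files(cfg)
    report.write(cfg.outdir)
    return report
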