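"""Synthetic-data generators with planted ground truth.

The generators emulate the statistical structure of the pipeline's real
inputs — chemical-association gene sets for three species sharing a
conserved core, per-subtype up/down differential-expression sets carrying
a resistant-vs-sensitive signature, and a toy ontology with one planted
enriched term — so every stage can be tested against known truth without
any external database.

Defaults reproduce the study conditions: a 96-gene conserved core inside
species sets of 2386 (human), 883 (mouse) and 616 (rat) genes, a 319-gene
supplemental chemical set contributing 6 additional conserved genes, and
subtype up/down set sizes 215/251 (BL1), 154/127 (BL2), 247/446 (M) and
805/382 (LAR) with a planted 20-gene differential pattern whose
resistance signature has 13 members.

All randomness flows from the scenario seed through numpy's Generator
with integer sampling only, so outputs are bit-identical across platforms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .fixtures import load_table2_fixture
from .genesets import GeneSet, OrthologMap
from .regulation import RegulationMatrix, SignatureResult, resistant_signature

DEFAULT_SUBTYPE_SPEC: dict[str, tuple[int, int]] = {
    "BL1": (215, 251),
    "BL2": (154, 127),
    "M": (247, 446),
    "LAR": (805, 382),
}

DEFAULT_SPECIES_EXTRA = {"human": 2290, "mouse": 781, "rat": 514}

_SPECIES_PREFIX = {"mouse": "MM_", "rat": "RN_"}


class ScenarioError(ValueError):
    """Invalid synthetic-scenario parameters."""


@dataclass(frozen=True)
class SyntheticScenario:
    """Planted-truth parameters for the synthetic generators.

    Parameters
    ----------
    seed : int
        Root seed; every generator derives an independent stream from it.
    universe_size : int
        Number of human gene symbols available.
    core_size : int
        Planted conserved genes shared by all three species sets.
    species_extra : mapping
        Per-species count of non-core genes (disjoint across species by
        default so the triple intersection is exactly the core).
    ortholog_fanout : float
        Probability a mouse/rat gene maps to one extra human gene (decoy
        target outside all sets), exercising many-to-many homology.
    supplemental_conserved : int
        Genes present in the supplemental set and in the mouse and rat sets
        but not the human set — the conserved additions the supplemental
        analysis contributes.
    supplemental_extra : int
        Other supplemental-set genes, disjoint from everything.
    subtype_spec : mapping
        subtype -> (n_up, n_down) set sizes.
    planted_signature : mapping or None
        gene -> {subtype: UP/DOWN} differential pattern.  ``None`` plants
        the packaged 20-gene pattern on the first 20 core genes.
    noise_rate : float
        Probability each planted membership is independently dropped.
    flip_rate : float
        Probability a planted up/down status is flipped (optional noise).
    resistant, sensitive : tuples
        Subtype groups used to define the intended signature truth.
    """

    seed: int
    universe_size: int = 20_000
    core_size: int = 96
    species_extra: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_EXTRA)
    )
    ortholog_fanout: float = 0.0
    supplemental_conserved: int = 6
    supplemental_extra: int = 313
    subtype_spec: Mapping[str, tuple[int, int]] = field(
        default_factory=lambda: dict(DEFAULT_SUBTYPE_SPEC)
    )
    planted_signature: Mapping[str, Mapping[str, str]] | None = None
    noise_rate: float = 0.0
    flip_rate: float = 0.0
    resistant: tuple[str, ...] = ("LAR", "M")
    sensitive: tuple[str, ...] = ("BL1", "BL2")

    def __post_init__(self) -> None:
        if self.core_size > self.universe_size:
            raise ScenarioError(
                f"core_size {self.core_size} exceeds universe_size {self.universe_size}"
            )
        needed = (
            self.core_size
            + self.supplemental_conserved
            + self.supplemental_extra
            + sum(self.species_extra.values())
        )
        if needed > self.universe_size:
            raise ScenarioError(
                f"universe_size {self.universe_size} too small for the "
                f"requested disjoint regions ({needed} genes)"
            )
        if not (0.0 <= self.noise_rate <= 1.0):
            raise ScenarioError("noise_rate must be in [0, 1]")
        if self.planted_signature is not None:
            known = set(self.subtype_spec)
            for gene, pattern in self.planted_signature.items():
                for st, status in pattern.items():
                    if st not in known:
                        raise ScenarioError(
                            f"planted pattern for {gene} names unknown subtype {st!r}"
                        )
                    if status not in ("UP", "DOWN"):
                        raise ScenarioError(
                            f"planted status for ({gene}, {st}) must be UP or DOWN"
                        )


def default_planted_patterns() -> dict[int, dict[str, str]]:
    """The packaged 20-gene differential pattern, keyed by core-gene rank.

    Pattern ``i`` is applied to the i-th planted core gene; 13 of the 20
    patterns satisfy the resistance-signature rule by construction.
    """
    fixture = load_table2_fixture()
    patterns: dict[int, dict[str, str]] = {}
    for i, gene in enumerate(fixture.genes):
        pat = {
            st: fixture.status[(gene, st)]
            for st in fixture.subtypes
            if fixture.status[(gene, st)] != "NONE"
        }
        patterns[i] = pat
    return patterns


@dataclass(frozen=True)
class _Partition:
    """Deterministic disjoint allocation of the synthetic gene universe."""

    core: tuple[str, ...]
    supp_conserved: tuple[str, ...]
    species_extra: Mapping[str, tuple[str, ...]]
    supp_extra: tuple[str, ...]
    decoy_pool: tuple[str, ...]  # fan-out targets, in no real set
    de_background: tuple[str, ...]  # DE filler genes, disjoint from the core


def _partition(sc: SyntheticScenario) -> _Partition:
    symbols = np.array([f"G{i:05d}" for i in range(sc.universe_size)])
    rng = np.random.default_rng([sc.seed, 0])
    order = rng.permutation(sc.universe_size)
    shuffled = symbols[order]
    pos = 0

    def take(n: int) -> tuple[str, ...]:
        nonlocal pos
        out = tuple(shuffled[pos : pos + n])
        pos += n
        return out

    core = take(sc.core_size)
    supp_conserved = take(sc.supplemental_conserved)
    extra = {sp: take(n) for sp, n in sorted(sc.species_extra.items())}
    supp_extra = take(sc.supplemental_extra)
    n_left = sc.universe_size - pos
    decoy = take(min(1000, n_left // 4))
    de_background = take(sc.universe_size - pos)
    return _Partition(
        core=core,
        supp_conserved=supp_conserved,
        species_extra=extra,
        supp_extra=supp_extra,
        decoy_pool=decoy,
        de_background=de_background,
    )


def _drop(rng: np.random.Generator, items: Sequence[str], rate: float) -> list[str]:
    if rate <= 0.0:
        return list(items)
    keep = rng.random(len(items)) >= rate
    return [x for x, k in zip(items, keep) if k]


@dataclass(frozen=True)
class SpeciesSetsTruth:
    core: tuple[str, ...]
    supplemental_additions: tuple[str, ...]


def gen_species_sets(
    sc: SyntheticScenario,
) -> tuple[dict[str, GeneSet], OrthologMap, GeneSet, SpeciesSetsTruth]:
    """Generate the three species chemical-association sets plus extras.

    Returns ``(species_sets, ortholog_map, supplemental_set, truth)``.
    The mouse and rat sets are in their own symbol namespaces and map to
    human through the returned ortholog map.  With ``noise_rate = 0`` the
    human projections intersect in exactly the planted core, and the
    supplemental set shares exactly ``supplemental_conserved`` genes with
    the mouse and rat projections that are absent from the human set.
    """
    part = _partition(sc)
    rng = np.random.default_rng([sc.seed, 1])

    human_members = _drop(
        rng, list(part.core) + list(part.species_extra["human"]), sc.noise_rate
    )
    sets: dict[str, GeneSet] = {
        "human": GeneSet.from_symbols(
            "human_chem",
            human_members,
            species="human",
            label="synthetic human chemical-association set",
        )
    }

    forward: dict[tuple[str, str], set[str]] = {}
    for sp in ("mouse", "rat"):
        prefix = _SPECIES_PREFIX[sp]
        human_side = (
            list(part.core) + list(part.supp_conserved) + list(part.species_extra[sp])
        )
        human_side = _drop(rng, human_side, sc.noise_rate)
        members = []
        for h in human_side:
            sp_gene = prefix + h
            members.append(sp_gene)
            targets = {h}
            if sc.ortholog_fanout > 0 and rng.random() < sc.ortholog_fanout:
                extra_idx = int(rng.integers(0, len(part.decoy_pool)))
                targets.add(part.decoy_pool[extra_idx])
            forward[(sp, sp_gene)] = set(targets)
        sets[sp] = GeneSet.from_symbols(
            f"{sp}_chem",
            members,
            species=sp,
            label=f"synthetic {sp} chemical-association set",
        )

    omap = OrthologMap(
        forward={k: frozenset(v) for k, v in forward.items()},
        species_list=("mouse", "rat"),
    )
    supplemental = GeneSet.from_symbols(
        "supplemental_chem",
        _drop(rng, list(part.supp_conserved) + list(part.supp_extra), sc.noise_rate),
        species="human",
        label="synthetic supplemental chemical-association set",
    )
    truth = SpeciesSetsTruth(
        core=tuple(sorted(part.core)),
        supplemental_additions=tuple(sorted(part.supp_conserved)),
    )
    return sets, omap, supplemental, truth


@dataclass(frozen=True)
class SubtypeSetsTruth:
    planted: Mapping[str, Mapping[str, str]]  # gene -> subtype -> status (clean)
    intended_signature: SignatureResult


def _resolve_planted(
    sc: SyntheticScenario, part: _Partition
) -> dict[str, dict[str, str]]:
    if sc.planted_signature is not None:
        return {g: dict(p) for g, p in sc.planted_signature.items()}
    patterns = default_planted_patterns()
    if len(part.core) < len(patterns):
        raise ScenarioError(
            f"default planted pattern needs {len(patterns)} core genes, "
            f"core_size is {len(part.core)}"
        )
    return {part.core[i]: pat for i, pat in patterns.items()}


def _clean_truth(
    sc: SyntheticScenario, planted: Mapping[str, Mapping[str, str]]
) -> SubtypeSetsTruth:
    subtypes = tuple(sorted(sc.subtype_spec))
    genes = tuple(sorted(planted))
    status = {
        (g, st): planted[g].get(st, "NONE") for g in genes for st in subtypes
    }
    matrix = RegulationMatrix(genes=genes, subtypes=subtypes, status=status)
    sig = resistant_signature(matrix, sc.resistant, sc.sensitive)
    return SubtypeSetsTruth(planted=planted, intended_signature=sig)


def gen_subtype_sets(
    sc: SyntheticScenario,
) -> tuple[dict[str, GeneSet], dict[str, GeneSet], SubtypeSetsTruth]:
    """Generate per-subtype up/down DE sets realizing the planted pattern.

    Background filler genes are sampled from a pool disjoint from the
    conserved core, so a regulation matrix focused on the core contains
    exactly the planted genes.  Up and down sets of one subtype never
    share a filler gene.  Returns ``(up_sets, down_sets, truth)`` where
    the truth lists the planted pattern and the signature it implies.
    """
    part = _partition(sc)
    planted = _resolve_planted(sc, part)
    truth = _clean_truth(sc, planted)
    rng = np.random.default_rng([sc.seed, 2])

    noisy: dict[str, dict[str, str]] = {}
    for gene in sorted(planted):
        pat: dict[str, str] = {}
        for st in sorted(planted[gene]):
            status = planted[gene][st]
            if sc.noise_rate > 0 and rng.random() < sc.noise_rate:
                continue  # dropped membership
            if sc.flip_rate > 0 and rng.random() < sc.flip_rate:
                status = "DOWN" if status == "UP" else "UP"
            pat[st] = status
        noisy[gene] = pat

    up_sets: dict[str, GeneSet] = {}
    down_sets: dict[str, GeneSet] = {}
    pool = np.array(part.de_background)
    for st in sorted(sc.subtype_spec):
        n_up, n_down = sc.subtype_spec[st]
        up_planted = [g for g in sorted(noisy) if noisy[g].get(st) == "UP"]
        down_planted = [g for g in sorted(noisy) if noisy[g].get(st) == "DOWN"]
        if len(up_planted) > n_up or len(down_planted) > n_down:
            raise ScenarioError(
                f"subtype {st}: planted genes exceed requested set sizes"
            )
        n_fill = (n_up - len(up_planted)) + (n_down - len(down_planted))
        if n_fill > len(pool):
            raise ScenarioError("DE background pool exhausted; grow universe_size")
        fill_idx = rng.choice(len(pool), size=n_fill, replace=False)
        fill = [str(pool[i]) for i in fill_idx]
        up_fill = fill[: n_up - len(up_planted)]
        down_fill = fill[n_up - len(up_planted) :]
        up_members = _drop(rng, up_fill, sc.noise_rate) + up_planted
        down_members = _drop(rng, down_fill, sc.noise_rate) + down_planted
        up_sets[st] = GeneSet.from_symbols(
            f"{st}_up", up_members, label=f"synthetic genes up in {st}"
        )
        down_sets[st] = GeneSet.from_symbols(
            f"{st}_down", down_members, label=f"synthetic genes down in {st}"
        )
    return up_sets, down_sets, truth


@dataclass(frozen=True)
class ToyOntologyTruth:
    planted_term: str
    exact_p: float  # brute-force hypergeometric upper tail for the planted term
    study_genes: tuple[str, ...]
    background_genes: tuple[str, ...]


def _exact_upper_tail(k: int, K: int, n: int, N: int) -> float:
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i) for i in range(k, min(K, n) + 1)
    ) / total


def gen_toy_ontology(
    sc: SyntheticScenario,
    *,
    n_terms: int = 30,
    n_background: int = 30,
    study_size: int = 5,
):
    """Generate a small acyclic ontology with one planted enriched term.

    Terms after the root draw one or two parents among earlier terms
    (mostly ``is_a``, occasionally ``part_of``), guaranteeing acyclicity.
    A leaf term is annotated to exactly the designated study genes, making
    it the uniquely smallest-p term.  Returns
    ``(OntologyDAG, AnnotationSet, ToyOntologyTruth)``; the truth carries
    the exact enumeration-based hypergeometric p for the planted term.
    """
    from .enrichment import AnnotationSet, OntologyDAG, propagate_annotations

    if n_terms > 50:
        raise ScenarioError("toy ontologies are capped at 50 terms")
    rng = np.random.default_rng([sc.seed, 3])
    term_ids = [f"T{i:03d}" for i in range(n_terms)]
    terms = {t: (f"toy term {i}", "toy_process") for i, t in enumerate(term_ids)}
    edges: list[tuple[str, str, str]] = []
    for i in range(1, n_terms):
        n_parents = 1 + int(rng.random() < 0.3)
        parents = rng.choice(i, size=min(n_parents, i), replace=False)
        for p in parents:
            rel = "part_of" if rng.random() < 0.2 else "is_a"
            edges.append((term_ids[i], term_ids[int(p)], rel))

    genes = [f"YG{i:03d}" for i in range(n_background)]
    study = tuple(genes[:study_size])

    has_child = {p for _c, p, _r in edges}
    leaves = [t for t in term_ids[1:] if t not in has_child]
    planted_term = leaves[-1] if leaves else term_ids[-1]

    direct: dict[str, set[str]] = {g: set() for g in genes}
    annotatable = [t for t in term_ids if t != planted_term and t != term_ids[0]]
    for g in genes:
        n_ann = 1 + int(rng.integers(0, 2))
        for idx in rng.choice(len(annotatable), size=n_ann, replace=False):
            direct[g].add(annotatable[int(idx)])
    for g in study:
        direct[g].add(planted_term)

    dag = OntologyDAG(terms=terms, edges=tuple(sorted(edges)))
    ann = propagate_annotations(
        dag, AnnotationSet(direct={g: frozenset(t) for g, t in direct.items()})
    )

    # guarantee the planted term is the unique minimum: no other term may be
    # annotated (after closure) to exactly a subset of the study genes
    planted_closed = {planted_term} | dag.ancestors(planted_term)
    for term in term_ids:
        if term in planted_closed:
            continue
        annotated = {g for g in genes if term in ann.closed[g]}
        if annotated and annotated <= set(study):
            direct[genes[-1]].add(term)  # a non-study gene breaks the tie
    ann = propagate_annotations(
        dag, AnnotationSet(direct={g: frozenset(t) for g, t in direct.items()})
    )

    truth = ToyOntologyTruth(
        planted_term=planted_term,
        exact_p=_exact_upper_tail(study_size, study_size, study_size, n_background),
        study_genes=study,
        background_genes=tuple(genes),
    )
    return dag, ann, truth


def with_noise(sc: SyntheticScenario, noise_rate: float) -> SyntheticScenario:
    """A copy of the scenario at a different drop-noise level."""
    return replace(sc, noise_rate=noise_rate)
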