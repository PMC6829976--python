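# Methods

## Model and procedure

The pipeline treats a "gene set" as an unordered collection of normalized
human gene symbols (uppercase, whitespace-free, HGNC-style). Symbols that
cannot be normalized are rejected at the boundary; genes that cannot be
mapped during ortholog projection are dropped and counted in a projection
report rather than raising, mirroring curation practice where ambiguous
identifiers are excluded from analysis sets.

**Conserved core.** Mouse and rat chemical-association sets are projected
into human symbols through a many-to-many ortholog map and intersected
with the human set. One-to-many homology uses union semantics: a species
gene contributes all of its human orthologs. The rationale is that
conservation of a chemical association asks whether *any* homolog carries
it; intersection-style semantics would silently discard genuine conserved
associations whenever a duplication event split the annotation. A
supplemental human set (a second, independently curated chemical
association source) contributes genes that are present in every non-human
projection but absent from the plain triple intersection; these
"conserved additions" are unioned into the core.

**Intersection lattice.** Families of sets are summarised as a DAG with
one node per non-empty subset intersection. `AT_LEAST` mode (default)
stores the plain intersection of each subset of sets; `EXACT` mode
assigns every gene to the unique node naming precisely the sets that
contain it, so node contents partition the union. The default matches how
pairwise overlaps and the triple intersection are usually reported side
by side without exclusivity. Edges are covering relations (minimal
subset inclusion), found by scanning supersets in ascending size and
accepting those that contain no previously accepted minimal superset.
Node order is deterministic: by number of parent sets, then
lexicographically by set ids. A guard refuses families larger than 12
sets unless overridden, since candidate nodes grow as 2^m.

**Overlap statistics.** Overlap significance is the hypergeometric upper
tail P(X ≥ k), computed through `scipy.stats.hypergeom.sf` for numerical
stability, with k = |A∩B|, K = |A|, n = |B| and N the universe size. The
universe defaults to the union of the inputs and can be set to an
explicit background (e.g. all protein-coding genes); the choice matters —
the union-universe default is conservative for large sets. Raw p-values
are reported alongside Benjamini–Hochberg adjusted values
(`scipy.stats.false_discovery_control`); BH was chosen as the standard
FDR procedure for exchangeable overlap tests.

**Regulation matrix.** For each conserved gene and subtype the status is
UP, DOWN, BOTH (present in both the up and the down set of that subtype —
a curation conflict, logged as a warning) or NONE. Rows are restricted to
genes with at least one call. Summary counts report per-subtype UP and
DOWN (BOTH tallied separately, in neither) and the number of genes up/
down in at least one subtype; for the any-counts a BOTH call is evidence
of both directions.

**Signature rule.** The informal notion "different expression behaviour
in resistant vs sensitive subtypes" is formalized as: gene g is a
signature member iff there exists a resistant subtype r with
status(g,r) ≠ NONE and status(g,r) ≠ status(g,s) for every sensitive
subtype s. BOTH in a resistant subtype counts as differential and
matches neither UP nor DOWN (it cannot occur in the packaged four-subtype
table; the handling is unit-tested on constructed inputs). This is the
strictest natural reading — a single sensitive subtype sharing the status
vetoes that resistant subtype's contribution — and it is pinned down by
the packaged table: it reproduces the 13-gene membership and excludes the
other 7 genes. The exclusivity partition groups signature genes by the
set of resistant subtypes that contributed a qualifying status.

**Enrichment.** Annotations are closed under the true-path rule along
`is_a` and `part_of` edges only (regulates-type edges are excluded, as in
conventional ontology closure; the propagating relation list is
configurable). Each term annotating at least one background gene is
scored with the same hypergeometric primitive used for set overlaps, and
BH-adjusted within its namespace. "Most specific" flags terms whose
p-value is no worse than that of every tested ancestor; this is a
p-ordering heuristic, not a reimplementation of any particular tool's
filter. The cell-death-style flag marks genes whose closed annotations
touch a caller-chosen family of root terms or any of their descendants.
The packaged regulation table carries the published cell-death flags as
data; the ontology-driven path is exercised on generated toy ontologies.

## Packaged fixtures

The packaged tables transcribe the published gene-set catalogue (20 sets
with sizes), the 20-gene regulation table with cell-death flags, and the
13-gene signature with directions. The transcription of the regulation
table was fixed by constraint satisfaction: the encoding must reproduce
the published per-subtype ratios (BL1 2 up/5 down, BL2 4/0, M 5/3, LAR
8/3), the 16/11 up/down-in-any totals, the 13-gene signature with its
7/3/3 exclusivity split, and the 15-of-20 cell-death flags. Within those
constraints one degree of freedom remains (which sensitive subtype hosts
the UP status of ADM, CAV1, HSPB1, MSH2 and PTK2); the packaged choice is
documented in the fixture file and does not affect any derived count. The
catalogue records both published values of the rat–mouse pairwise overlap
(151 in prose, 150 in the table); nothing downstream depends on it.

## Synthetic scenarios

The generator emulates the *structure* of the real inputs, not their
content: a planted conserved core shared by all three species sets,
species-specific genes sampled disjointly (so the triple intersection is
exactly the core), a supplemental set sharing exactly its planted
additions with the non-human sets, and subtype up/down sets realizing a
planted differential pattern with background filler drawn from outside
the core. Defaults are fixed at the study's scale: core 96; species sets
2386/883/616; supplemental set 319 with 6 conserved additions; subtype
sizes 215/251 (BL1), 154/127 (BL2), 247/446 (M), 805/382 (LAR); the
default planted pattern is the packaged 20-gene table mapped onto core
genes, so the implied signature has 13 members with the 7/3/3 split. The
universe holds 20,000 symbols, the scale of the human protein-coding
complement.

What the generator does **not** emulate: realistic pairwise (two-species)
overlap beyond the core, correlated membership between subtype sets,
HGNC synonym noise, or the topology and annotation depth of the real
Gene Ontology. Recovery results on synthetic data therefore demonstrate
correctness of the set algebra and the signature rule under the planted
model, not robustness to real curation noise.

Noise is a per-membership independent drop with probability
`noise_rate` (optionally direction flips with `flip_rate`); there is no
claim that real curation error looks like this — it exists to verify
that recovery degrades monotonically rather than catastrophically. An
`ortholog_fanout` parameter gives species genes an extra human target
drawn from a decoy pool, exercising many-to-many projection without
perturbing the planted intersections.

All randomness flows from a single integer seed through
`numpy.random.default_rng` with integer-based sampling, so outputs are
bit-identical across platforms; the same seed always regenerates the
same scenario, and serialized reports from identical configurations are
byte-identical (timestamps are deliberately excluded from reports).

## Numerical and degenerate-input choices

- Hypergeometric tails use the survival function, never 1 − CDF; the
  k = 0 tail is exactly 1.
- Jaccard of two empty sets is defined as 0.
- Empty gene sets are legal everywhere (empty projections, empty
  lattices of one empty set are rejected only where an operation is
  undefined, e.g. zero-set boolean combinations).
- All serialized outputs (GMT members, lattice nodes, report JSON keys)
  are sorted, making byte-stable output a property rather than an
  accident.
- Test problem sizes: oracle equivalence enumerates every hypergeometric
  parameterization with N ≤ 20, 200 random set families of ≤ 6 sets over
  a 50-gene universe, and 100 random DAGs of ≤ 20 terms; parameter
  recovery uses 20 replicates per condition at full study scale, which
  keeps the whole suite under ten seconds.

## Known limitations

- Enrichment p-values are not comparable to any specific published
  tool's output: they depend on the annotation file version, the
  propagating relation set, and the correction procedure. The packaged
  replay therefore checks ontology-independent counts only.
- The signature rule treats subtypes symmetrically; it does not model
  effect sizes, fold-change thresholds or partial membership — inputs
  are already-called up/down lists.
- The ortholog map is an input; no homology inference is attempted.
- The exclusivity partition is defined for any number of resistant
  subtypes, but keys are only human-friendly ("only-X", "X+Y") for the
  two-group case the study design uses.
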