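# Methods

## The concavity model

R_inaccess quantifies how deeply a point in space sits within a molecular
surface concavity: the radius of the smallest spherical probe, drawn from an
ascending sweep, that cannot reach the point from bulk solvent. The sweep is
2.5–10.5 Å in 1.0 Å steps (nine radii) by default and is configurable; the
endpoints matter (2.5 Å ≈ the floor below which crevices are effectively
closed; 10.5 Å ≈ flat), the step only sets the resolution of the resulting
ordinal scale. Values feed rank and mean statistics, never arithmetic on
physical radii, so the coarse step is deliberate.

The field is realized on a voxel grid (default spacing 0.8 Å, smaller than
the smallest probe) by morphological opening per probe radius r:

1. **Erosion.** Probe-center voxels are those whose *exact* Euclidean
   clearance to the nearest atom van der Waals surface is ≥ r. Clearance is
   computed from atom centers with a KD-tree (minimum of center distance
   minus radius over the nearest neighbours), not from a voxelized
   occupancy mask — the mask-based distance transform overestimates
   clearance by up to half a voxel diagonal and shifts every pocket reading
   by one sweep step.
2. **Bulk restriction.** Only center voxels 6-connected to a box face count
   as bulk solvent. Enclosed interior cavities are therefore never
   accessible at any radius and read the sweep floor; this is intended
   behaviour, documented rather than special-cased.
3. **Dilation.** The swept volume is every voxel within r of a retained
   center (a second exact distance transform).

Accessible sets are intersected cumulatively along the ascending sweep. In
the continuum, openings by growing balls form a granulometry and nest
automatically; on a grid the raw openings can violate nesting on a thin
fringe of voxels (measured ≈ 2 % on pocket fixtures), and the intersection
restores the property exactly, keeping R_inaccess single-valued.

Probe centers are voxel-quantized, so placements whose true clearance
margin is smaller than the grid can be missed; the `probe_slack` parameter
of `compute_field` can relax the erosion threshold to stand for off-center
placements, but the default is 0 (a probe fits only where the sampled
clearance reaches r). The test suite validates the field against an
independent brute-force oracle that enumerates every ball placement on a
0.4 Å grid with KD-tree queries and no morphology; with the field run at
the same 0.4 Å spacing the two agree on 100 % of pocket voxels for
hemispherical pockets of radius 3–8 Å, and near-bottom samples equal the
smallest sweep radius exceeding the pocket radius.

Atoms are scored at their nearest voxel (values are categorical radii, so
interpolation would be meaningless). A query atom inside the partner's
occupancy mask — marginal clashes occur in low-resolution structures —
receives the floor value with a warning rather than an error; an atom
outside the grid receives the cap with a warning. The field is always
computed from the binding partner only: antibody atoms are sampled in the
antigen's field and vice versa.

**Residue and group summaries.** Per residue, both the minimum ("deepest")
and mean ("average") of the atomic values are kept. Averaging dilutes deep
side-chain atoms with shallow backbone atoms, so the deepest value is the
analysis default; both modes are first-class because each answers a
different question (extreme vs typical engagement). Group summaries take,
per complex, the group's minimum (deepest use) or mean over interface
residues (average use), then average across complexes; a complex lacking
the group is skipped for that group.

## SASA and buried surface area

Shrake–Rupley quadrature with a deterministic golden-angle (Fibonacci)
spiral of 960 points per atom — no random numbers, bit-reproducible, and
within 1 % of the 480-point result on the fixtures. Radii follow a packaged
NACCESS-style table keyed by (residue, atom name) with element fallbacks
(N 1.65, O 1.40, S 1.85, tetrahedral C 1.87, trigonal/aromatic C 1.76 Å);
an atom with no entry gets a configurable 1.80 Å fallback plus a warning.
The solvent probe is 1.4 Å. Cα counts as main chain for side-chain
classification. BSA = SASA(antibody) + SASA(antigen) − SASA(complex),
computed on full chains (the definition is stated on whole-side areas, and
interface-trimming would change the free-state reference). The suite
cross-checks totals against an independent Shrake–Rupley implementation
(biotite) on identical radii, and per-atom burial against the closed-form
spherical-cap area for a two-atom system.

## Interface and interactions

A residue is interfacial iff any heavy atom lies within 5.0 Å (closed
interval) of any heavy atom of the partner side. Hydrogens are excluded
throughout: structures at the ≤ 3 Å resolution this pipeline targets rarely
resolve them, so hydrogen-bond detection is distance-only over a shipped
per-residue donor/acceptor role table (backbone N donor except proline,
backbone O/OXT acceptor, standard side-chain roles). Rules, all cutoffs
config-exposed:

- hydrogen bond: compatible donor→acceptor pair ≤ 3.5 Å;
- polar contact: any donor/acceptor pair ≤ 4.0 Å failing the above
  (includes donor–donor and acceptor–acceptor proximity);
- hydrophobic: carbons bonded only to C/H/S, pairwise ≤ 4.5 Å;
- ring–ring: aromatic centroids ≤ 6.0 Å across the interface;
- ring–atom / atom–ring: polar or cationic heavy atom ≤ 4.5 Å from a ring
  centroid and within 45° of the ring normal; the class name encodes ring
  ownership (antibody ring → `ring_atom`, antigen ring → `atom_ring`);
- cation-π: the subset of ring-class records whose atom is LYS NZ or
  ARG NE/NH1/NH2, carried as a flag and also reported as its own count.

Rings come from residue templates (PHE/TYR six-ring, HIS five-ring, TRP
five- and six-rings sharing the CD2–CE2 edge) with best-fit-plane normals;
incomplete rings are skipped with a warning. Within atom–atom pairs the
precedence hydrogen bond > polar > hydrophobic guarantees at most one
record per pair. Counts are normalized to interactions per 100 Å² of BSA.
Hydrophobic counts enumerate every qualifying carbon pair and therefore
carry a systematic multiplicity bias; they are reported as their own class
and never merged with the others. The full SMARTS-typed rule sets of
dedicated contact annotators are out of scope: the landscape analysis
consumes only per-class counts per unit interface area.

## Redundancy workflow

Greedy incremental clustering per chain role at 0.95 identity: sequences
sorted by length descending (ties by id), each joining the first cluster
whose representative reaches the threshold. Identity is identical aligned
positions divided by the shorter sequence length, from a global pairwise
alignment (match 1, mismatch 0, gap −1); no k-mer prefilter heuristics are
used — exact alignment is affordable at desk scale. Complex labels are
`heavy_light_ag1:ag2` with antigen cluster ids sorted ascending and a
missing light chain encoded as `-`.

Interface similarity between two complexes compares their paratope∪epitope
residue key sets; keys are (side, IMGT position, insertion, amino acid) —
including the amino acid makes the measure sensitive to interface mutations
between 95 %-identical sequences (a config flag relaxes this). The shared
fraction is computed from each complex's perspective and averaged; a pair
at or above 0.90 is redundant. The alternative reading that paratope and
epitope must each stay below the threshold is available via `per_side`.
Deduplication keeps the first complex per label (stable input order), then
walks the rest in order, reinstating any complex dissimilar to *every*
retained member of its group; reinstated complexes immediately join the
comparison pool, making the greedy procedure deterministic. Pairwise
comparisons stay within label groups — the structural check refines the
sequence-level grouping, it does not replace it.

## Statistics

One-way ANOVA from direct sums of squares (the fully degenerate
no-variance case is reported as F = 0, p = 1), with Tukey HSD post-hoc
comparisons via the studentized-range distribution (statsmodels), using
Tukey–Kramer handling since group sizes in this domain are always unequal.
Pearson correlations with p-values from the t transform of r, plus the
least-squares line. The observation unit is one value per complex per
group throughout (a per-residue option exists on the table-building side).
A CDR whose lengths take fewer than four distinct values is flagged
"insufficient length diversity" instead of reported — a correlation over
one to three length subgroups is not meaningful. No multiple-testing
correction is applied beyond Tukey.

## Synthetic data

The generators produce the fixtures the analysis is validated on, each
emitting its ground truth alongside (never recomputed from the fixture):

- **Slabs**: cubic-lattice atom slabs (default spacing 1.5 Å, radius
  1.8 Å, ≥ 3 layers plus enough depth that no cavity pierces the
  underside). Cavities are carved by removing atoms whose vdW sphere
  intersects the ideal cavity volume, so the effective wall radius equals
  the requested one; `pocket_depth > pocket_radius` produces a
  hemisphere-bottomed shaft (the sub-probe crevice fixture). Slab extent
  40 Å is used for the anchor fixtures: a probe over the *center* needs
  only local flatness, and edge effects can only increase accessibility,
  so the flat anchor is unaffected by finite extent.
- **Toy complexes**: an antibody-like chain with IMGT-numbered CDR loops
  (windows 27–38 / 56–65 / 105–117; symmetric-insertion letters at the
  window midpoint) floating 8 Å above a slab antigen, with one H3 residue
  protruding to the surface or into a pocket. Residues use real heavy-atom
  name sets — planar fused rings for tryptophan — so radii lookup,
  side-chain logic, and interaction typing run on realistic names; the
  default protruding residue is methionine, whose terminal carbons are
  genuinely apolar. Backbone geometry is schematic by design: no rotamers,
  no physical energetics.
- **Sequence families**: a random reference plus mutants at a controlled
  identity, substitutions uniform over non-identical residues at positions
  drawn without replacement, one documented RNG seeded per call.
- **Accounting manifests**: dataset-scale filter and redundancy fixtures
  reproducing the exclusion-category bookkeeping (4915 → 2417 retained;
  670 representatives + 553 reinstated = 1223) without any coordinates.

What passing tests show — and do not show — about real data: the fixtures
validate the geometry and bookkeeping exactly, but they contain no
conformational flexibility, no crystallographic noise, no missing atoms
beyond the constructed cases, and schematic loop geometry; dataset-scale
biological findings require real structure sets and are out of scope.

## Dataset filtering

Exclusion rules apply in a fixed order — unbound/non-protein antigen,
duplicate entry, resolution > 3.0 Å (missing resolution fails this rule,
with a warning), any UNK residue, light-chain-dimer format — and a record
failing several rules counts only toward the first, making per-rule counts
well-defined. Filtering is idempotent and counts always sum to the input
size. Structure I/O (PDB/mmCIF) goes through gemmi; one alternate location
is kept per atom (highest occupancy, ties by altloc letter); IMGT numbers
are consumed from a sidecar TSV (renumbering from raw sequence is a solved
external problem and out of scope) with author numbering copied when no
mapping is given. Insertion codes order lexicographically after the bare
position; only set membership, not ordering, affects downstream statistics.

## Problem sizes and determinism

Default test and acceptance fixtures: 40 Å slabs (≈ 3 600–15 000 atoms),
concavity grids of ≈ 0.2–2 M voxels at 0.8 Å (0.4 Å where the brute-force
oracle comparison demands matched placement resolution), toy complexes of
≈ 3 400 atoms, and 3–6-complex pipeline runs with 240-point SASA
quadrature — sizes chosen so the full validation cycle runs on a laptop in
about a minute. Every analysis stage is deterministic; the single RunConfig
seed governs only synthetic-fixture generation. Pipeline TSVs carry a
sha256 hash of the analysis parameters (output location excluded), and
reruns are bit-identical.

## Known limitations

- The concavity scale is ordinal at the sweep resolution; a pocket whose
  radius falls exactly on a sweep value sits on a knife edge, and voxel
  quantization decides which side it lands on (the grid-refinement test
  bounds how often this moves values by more than one step).
- Probe accessibility ignores bulk connectivity in the test oracle (valid
  for open slab fixtures only); the implementation itself enforces it.
- Hydrogen-bond detection is distance-only; donor geometry is not checked.
- Greedy clustering order (longest-first) is a convention; other orders
  give different but equally defensible partitions at the same threshold.
- The interface-similarity measure counts shared residue identities, not
  contact geometry; two complexes using the same residues in different
  poses are indistinguishable to it.
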