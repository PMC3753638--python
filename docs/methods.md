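# Methods

This note records the models, parameter choices and numerical conventions
behind `ribodomain`, and what its synthetic benchmarks do and do not
demonstrate about real structures.

## Contact detection

**Base pairs.** A pair is called between two residues when (i) at least two
polar-atom contacts (base N/O atoms plus the ribose O2′) lie within the
hydrogen-bond ceiling, default 3.5 Å; (ii) the two base-plane normals differ
by at most 65° — generous enough for sheared non-canonical pairs; and
(iii) the contacting atoms of each partner lie within 2.0 Å (mean absolute
offset) of the other base's plane. The third criterion is what separates
edge-on pairing from stacking: a stacked neighbour passes the angle test
(parallel planes) but sits a full rise (~2.8–3.4 Å) out of plane. Base planes
are least-squares fits to the ring atoms. A nucleotide may participate in
more than one pair (base triples are real and are reported).

Edges follow fixed per-base atom tables (purine Watson–Crick edge N1/C2/N6 or
O6; Hoogsteen N7/C8/N6 or O6; sugar edge N3, the 2-amino group and O2′, with
pyrimidine analogues). The label is the plurality vote of the contacting
atoms, ties broken by smaller mean contact distance and then by the fixed
order WC > Hoogsteen > Sugar. Orientation is cis when the two glycosidic-bond
vectors fall on the same side of the C1′–C1′ axis (their components
perpendicular to the axis have positive dot product), trans otherwise. The
`canonical` flag marks cis WC/WC pairs of AU/GC/GU identity. Protonated and
water-mediated pairs are out of scope.

**Stacking.** Two bases stack when their ring centroids are within 5.5 Å,
normals within 30°, vertical separation (mean projection of the centroid
offset on the two normals) between 2.0 and 4.5 Å, and their projected
footprints overlap. The footprint is the convex hull of the heavy base atoms
(ring + exocyclic substituents) buffered by 0.5 Å to represent the lateral
extent of the π system beyond atom centers; overlap must be strictly
positive. Without the buffer, idealized pyrimidine→purine steps in a
straight (zero-roll) helix have tangent footprints and sequence-contiguous
stacking would be under-called.

**Base–phosphate / base–sugar.** A base polar atom within 3.5 Å of another
residue's phosphate oxygen (OP1/OP2/O5′/O3′) or sugar oxygen (O2′/O4′);
contacts to a residue's own backbone are excluded; one contact (the closest
atom pair) is reported per residue pair so downstream counts are
well-defined.

**Mg²⁺ bridges.** A magnesium ion bridges the residues whose atoms lie
strictly inside its first coordination shell, < 2.6 Å; ions with fewer than
two first-shell residues are not bridges. The inequality is strict: an atom
at exactly 2.6 Å is outside the shell.

All thresholds live in `DetectionParams` and are copied into every
`ContactSet` and run manifest, because every downstream count is
threshold-sensitive.

## Helix partitioning

Pairs are chained into helices by stacking contiguity: two pairs are adjacent
when, for one of the two strand alignments, one side carries a stacking
contact and the other side is stacked too or sequence-close. "Sequence-close"
allows a bulge of up to two extruded nucleotides on one strand, which is
exactly the allowance needed for helices with a single extruded base inside a
base triple. Whether contiguity should require both strands or either strand
to stack is a genuinely open design point; the either-strand-with-bulge rule
is the default and is exposed as a parameter. Extruded nucleotides interior
to a helix's strand segments are counted as members of that helix.

Unique membership is enforced before chaining: when a nucleotide sits in more
than one pair (a triple), the pair with more hydrogen bonds is kept (ties by
mean contact distance, then lexicographic reference order) and the rest are
demoted to the unassigned pool. Helices need at least two pairs; lone pairs
are unassigned and therefore tertiary. A greedy hill-climbing pass then
reassigns boundary pairs between adjacent helices whenever this strictly
increases the total intra-helix stacking count, the partition's optimality
criterion. The result is invariant to the input order of the pair and stack
lists (everything is canonically sorted first).

A pair is **secondary** iff it is a member pair of some helix in the adopted
inventory; all other pairs — including the demoted pairs of triples — are
**tertiary**. Comparing the strata maps of two inventories yields the list of
reclassified pairs directly as a set difference.

The bundled new-helix table defines each helix by its strand residue ranges
(e.g. helix 26a as 1262–1270 paired with 2010–2017); where historical
annotations disagree internally about individual partner residues, the
strand-range definition is taken as authoritative.

Naming maps detected helices onto a reference table of named residue ranges:
a helix adopts a name when ≥ 50% of its members fall inside the name's
ranges; an exact tie between two names is an error rather than a silent
choice; unmatched helices get sequential `HX###` identifiers. Measurement and
presentation are kept separate: the partitioner always reports the
structurally detected helix, and display conventions (e.g. drawing a small
helix as a loop) belong in a separate override table, not in the measurement.

## Domain architecture

Architectures are lists of inclusive author-number ranges, one list per
domain; ranges may not overlap, and residues outside every range are reported
rather than dropped. The bundled seven-domain table assigns 159 nucleotides
to the central core domain.

The interaction matrix counts, per domain pair: base pairs excluding the
adopted inventory's secondary pairs ("local secondary interactions
excluded"), base–phosphate and base–sugar contacts, and Mg²⁺ bridges — a
bridge with k partner residues contributes all C(k,2) partner pairs, a
documented reading since the multiplicity convention is not otherwise fixed.
Stacking is excluded from the default matrix (the counted classes are
base–base, backbone-mediated and Mg-mediated); a policy flag can include it,
minus sequence-neighbour stacks, because the source conventions for these
counts are ambiguous and both readings should be computable. Scaling divides
the diagonal by N_i and the off-diagonal by (N_i+N_j)/2, making differently
sized domains comparable; the identities are exact by construction and are
property-tested on random matrices.

Boundary refinement is deterministic greedy hill-climbing: the candidate
moves are the first/last nucleotides of each contiguous same-domain run
switching to the neighbouring run's domain; the objective is the weighted
inter-domain interaction count with default weights 8/4/2/1 for
pairing/stacking/base-phosphate/base-sugar, following the stated priority
order of the interaction classes. Mg²⁺ bridges are not part of the
refinement objective because the priority order does not rank them. Moves
that would split a helix's members across domains are illegal regardless of
gain. Each accepted move strictly decreases the objective, so termination is
guaranteed; the result is a local optimum, which suffices to restore planted
boundaries whenever the contact network actually determines them (boundary
nucleotides anchored by contacts into their domain's interior). A boundary
region whose nucleotides are tied only to each other is not decidable by any
interaction-based method, and the synthetic benchmark deliberately avoids
that degenerate construction.

The foldable-sequence export concatenates a domain's fragments in ascending
range order ("linked at the strand termini"), records the junction indices,
and applies explicit range→sequence substitutions — the intended use is
replacing a non-canonical helix with a canonical duplex (e.g.
5′GUAUAUGC3′:5′GCAUAUAC3′) before handing the sequence to a
nearest-neighbour folding program, which itself is outside this package's
scope.

## Shape metrics

Volume and surface area come from a signed-distance field min_i(|x−a_i|−r_i)
sampled on a regular grid (default spacing 0.5 Å; 1.0 Å for routine per-domain
reports). With zero probe the envelope is the van der Waals union; with a
probe (default 1.5 Å) the field is dilated by the probe and eroded back via a
Euclidean distance transform — a solvent-excluded surface on the voxel grid.
The isosurface is triangulated by marching cubes; the area is the mesh area
and the volume the mesh's enclosed volume (divergence theorem) rather than a
voxel count, which keeps the error smooth in the grid spacing and preserves
the Ψ ≤ 1 bound that voxel-face area counting systematically violates. On a
10 Å sphere the errors at 0.3 Å spacing are below 0.1% for both V and SA, and
|Ψ−1| decreases monotonically as the grid is refined 1.0 → 0.5 → 0.25 Å.
Atomic radii are a standard crystallographic table (C 1.70, N 1.55, O 1.52,
P 1.80 Å …), configurable because absolute V and SA depend on it.

Per-domain sphericity is computed on each domain's isolated atoms; the
summary is the unweighted mean across domains (a nucleotide-weighted mean is
available, since which average is meant by a "mean sphericity" is ambiguous
in general). The distance ("onion") map measures from a user-supplied
reference — an explicit point or a (chain, residue, atom) triple such as a
PTC-adjacent 23S residue; the tool deliberately does not hard-code a
biological reference residue. Each nucleotide is represented by C1′, falling
back to its atom centroid.

## Conservation

Entropy is in bits (log₂), which makes the range exactly 0–2 over four
nucleotide types. The default gap policy excludes gaps and ambiguity codes
and renormalizes over A/C/G/U, since the entropy sum runs over the four
types; a count-gaps-in-denominator policy is provided for comparison.
Columns with > 50% gaps are flagged low-coverage; an all-gap column has
*undefined* entropy, reported as such rather than as 0 (0 would falsely mean
"universally conserved"). Column↔structure anchoring goes through one
designated reference row whose ungapped positions carry the author
numbering.

Conservation groups for paired columns use two documented thresholds, both
0.9 by default because the underlying grouping is qualitative: group 1 needs
base identity ≥ 0.9 in both columns plus a consistent annotated pairing
geometry; group 2 needs the geometry without the identity; group 3 needs
canonical complementarity (the fraction of rows forming AU/GC/GU pairs)
≥ 0.9 without identity conservation — co-variation, the classic signature of
a conserved canonical pair.

## Synthetic structures

The generator is the package's ground-truth authority. Duplexes are built
from ideal residue templates posed in the published standard base reference
frames; the partner base of a Watson–Crick pair is the standard-frame
coordinates transformed by (x, −y, −z), which realizes textbook hydrogen-bond
distances (2.9–3.1 Å) with no fitting; wobble pairs add an in-plane shear
refined onto the G·U hydrogen-bond distances. Successive pairs are stacked
with 32.7° twist and 2.81 Å rise about the pair-center axis. This produces a
straight, zero-roll, zero-inclination helix: base geometry (pairing edges,
coplanarity, stacking separations) is faithful; backbone conformation is not
— each residue's sugar-phosphate moiety rides rigidly on its base, so
backbone torsions and O3′–P connectivity are not physical. Consequently the
generator validates base-centric detection exactly, while base–backbone
contact geometry in real structures (A-minor motifs, ribose zippers) is only
emulated by explicitly planted contacts at exposed atoms.

Assemblies place additional helices either explicitly or at seeded random
poses, rejecting placements with any inter-helix atom pair within 4 Å
(100 retries, then a deterministic error). A planted inter-helix contact
docks the incoming helix along opposed outward directions (radial or axial,
from a PCA axis estimate) so the two bodies stay tangent; near the planted
junction only a 2.2 Å hard-sphere floor applies — a genuine contact brings
whole residue neighbourhoods together — while every atom pair away from the
junction stays above 3.6 Å, just outside hydrogen-bond detection range, so
the only *detectable* cross-helix contacts are the planted ones. Mg²⁺ sites
are solved geometrically: among all O/N atom pairs of the two partner
residues, the ion is placed on the circle equidistant (at the exact target
distance) from an atom of each, at a position where no other atom intrudes
into the first shell; this makes cutoff-flip tests (2.5 Å detected, 2.7 Å
not) exact by construction. Alignments are sampled i.i.d. per column from
user profiles, whose analytic entropy is the estimator oracle.

Every generator output is a pure function of its spec and seed.

What passing the synthetic suite shows: the detectors implement their stated
geometry exactly, the partitioner recovers planted helix inventories, the
matrix algebra and refinement behave as specified. What it does not show:
performance on crystallographic coordinate noise beyond the σ = 0.1 Å
perturbation test, on chemically modified residues beyond parent-base
mapping, or on backbone-mediated motif geometry — those require real
structures, for which all thresholds are exposed and recorded.

## Problem sizes used in the checks

The routine checks run on duplexes of 2–17 bp, assemblies of 2–8 helices
(3–12 bp each), 200 seeded assemblies for the recovery benchmark, 1000
random matrices for the scaling identities, 100 seeded trials for boundary
restoration, 5000-row alignments for estimator consistency, and a 0.25–0.3 Å
grid for the sphere benchmarks. These sizes make the full suite complete in
about a minute on one CPU while keeping every statistical check at the
stated sample size.

## Known limitations

* The helix partitioner's hill-climbing is locally, not globally, optimal;
  pathological stacking networks could in principle admit a better partition
  it does not reach.
* FR3D-style discrepancy scoring and isostericity are not implemented; the
  LW classifier is a geometric plurality vote with pinned thresholds, so
  agreement with FR3D annotations on borderline pairs depends on matching
  thresholds.
* The voxel SES is a grid construction; for probe > 0 the distance-transform
  erosion introduces a small grid-dependent bias in concave creases.
* Multi-model structures use model 1 only; altlocs keep the
  highest-occupancy conformer.
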