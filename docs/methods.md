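# Methods

`lhckit` automates three structural analyses that are usually done by
hand on photosystem–antenna supercomplexes: transmembrane helix-height
("membrane rippling") maps, chlorophyll distance networks as proxies
for excitation energy transfer (EET), and map–model Q-scores for
assigning light-harvesting-complex (LHC/FCP) subfamilies to
medium-resolution cryoEM maps.  This note records the models, the
conventions, and the choices made where the design was genuinely open.

## Membrane frame

The membrane is a planar slab described by a unit normal **n**, a
midplane point **p₀** and a stromal sign s ∈ {+1, −1}.  The signed
height of a point x is s·(x − p₀)·**n**; positive values are stromal.
All sidedness calls and height projections derive from this frame.

The frame is estimated from the structure itself: **n** is the first
principal axis of the transmembrane helix end-to-end unit vectors
(eigenvector of Σᵢ uᵢuᵢᵀ), **p₀** is the centroid of helix axis
midpoints, and s is set so a stromal reference subunit — by default the
chain annotated PsaC, which sits entirely on the stromal face — lies on
the positive side.  If the second eigenvalue exceeds 60 % of the first,
the helix directions do not define a plane normal and the caller is
asked for an explicit vector, which is honored verbatim after
normalization.  Published structures place the membrane by eye; the
principal-axis estimate makes the same call reproducible, and the
override preserves comparability with any external convention.

## Helix detection and height measurement

Detection is purely Cα-geometric, so no external secondary-structure
program is needed and results are bit-reproducible:

* a five-residue window i…i+4 is *helical* when its residues are
  consecutive in sequence, the Cα(i)→Cα(i+4) distance lies in
  [4.8, 6.6] Å, and the local axis rise per residue lies in
  [1.1, 1.9] Å (an ideal α-helix gives 6.2 Å and 1.5 Å);
* runs of helical residues shorter than 8 are discarded, and runs are
  split at chain breaks (non-consecutive numbering) so adjacent helices
  never merge;
* kinks — interior axis-direction changes above 40°, measured between
  arm directions that skip the centroids nearest the bend — split a
  helix in two, since a single arc length across a kink would inflate
  the height.

The helix axis is the sliding centroid of four consecutive Cα, smoothed
by a second four-point moving average.  Four points of an α-helix do
not cancel the 100°-per-residue spiral exactly; the residual wobble is
≈ 0.26 Å for single centroids and ≈ 0.02 Å after the second average.
The smoothed polyline is extrapolated by three local steps at each end
so it spans residues 1…n (a window centroid sits three residues inside
the helix).

**Height** is the piecewise arc length of the axis polyline split into
k ≥ 3 sub-segments of equal residue count (default k = 3; requiring at
least three sub-segment measurements keeps curved helices honest, and
k > 3 changes ideal-helix heights by < 0.5 Å).  The **projected span**
along the membrane normal is reported alongside, because published
helix heights do not always state which convention was used; the
acceptance tolerance when comparing across conventions is ±2 Å.
A helix is *transmembrane* when its axis spans ≥ 15 Å along the normal
(configurable) **and** crosses the midplane; this excludes surface and
amphipathic helices.

On synthetic bundles with prescribed heights of 24–48 Å, tilts to 25°
and arc curvature down to 100 Å radius, the pipeline recovers true
heights with a mean absolute error well below 0.1 Å; the 1 Å bound
asserted by the test suite is conservative.

## Aggregation

Per-subunit heights are means over a chain's transmembrane helices.
Chains whose whole-subunit Cα superposition RMSD is below 0.55 Å are
pooled and reported once (chains of incommensurate length — below 90 %
mutual coverage — are never pooled).  Subfamily means across structures
are flagged *under-sampled* below five representative chains.

## Rippling graphs and hydrophobic mismatch

Each transmembrane helix becomes a node at its stromal axis endpoint
projected onto the midplane, binned by height in 5 Å steps from 20 Å to
45+ Å (out-of-range heights clamp rather than error).  Edges join
helices whose stromal projections lie within 16 Å — a typical
helix-packing neighbour distance; the cutoff is configurable and the
brute-force all-pairs check is part of the test surface.  Edges carry
|Δheight|, binned in 5 Å steps from 5 to 20+ Å; differences below 5 Å
are flagged *suppressed* (they are conventionally not drawn) but are
retained so statistics use all edges.  The hydrophobic mismatch between
two subunit groups is the max/mean/min of |Δheight| over cross-group
edges.  A synthetic ring of one 48 Å core bundle and six 31 Å belt
bundles yields a maximum core-to-belt mismatch of exactly 17 Å on
generator truth, which the measurement pipeline reproduces to ≈ 0.03 Å.

## Chromophore networks

A configurable catalog maps hetero residue names to pigment kinds
(defaults cover chlorophyll *a*, chlorophyll *c1/c2*, β-carotene,
fucoxanthin, diadinoxanthin and common xanthophylls).  For chlorophylls
the *macrocycle set* is every heavy atom except the plain-numbered
phytol-tail carbons (C1…C20 in the standard component nomenclature):
the four pyrrole nitrogens, the tetrapyrrole ring carbons with meso
carbons and fused-ring atoms, first-shell substituents, and the central
Mg.  Including the tail would corrupt minimum distances.

* **edge-to-edge** = minimum heavy-atom distance between two macrocycle
  sets (the standard "porphyrin-ring" distance);
* **Mg–Mg** = central-metal distance; since the metal belongs to the
  macrocycle set, edge-to-edge ≤ Mg–Mg always;
* **side** = sign of the metal (or macrocycle centroid) height; pigments
  within ±2 Å of the midplane are left *unassigned* rather than forced.

EET candidate networks connect chlorophyll pairs with edge-to-edge
≤ 15 Å — the distance beyond which transfer becomes inefficient — with
a strict-inequality option for "closer than" phrasings.  Carotenoids
are extracted and reported but excluded from networks by default.
Neighbour candidates come from a k-d tree on macrocycle centroids with
a radius bound of cutoff + 2·(max macrocycle radius), which is exact by
the triangle inequality; tests compare against the O(n²) all-pairs
computation up to 2000 chromophores.

Cross-structure comparison superposes models by Kabsch least squares on
Cα atoms of user-paired chains (residue-number pairing, ungapped
best-offset fallback, ≥ 20 matched atoms required).  Gain/loss
accounting then matches chlorophylls greedily by Mg proximity in
ascending-distance order under a 5 Å cutoff (chl↔chl only; kind may
differ, since chlorophyll *a*/*c* assignment is itself uncertain at
medium resolution).  The matching is a partial injection: every
reference pigment is matched or *lost*, every query pigment matched or
*gained*, none twice.  The 5 Å cutoff is a design choice — published
gain/loss calls do not state one — and a 3–7 Å sensitivity sweep is a
one-line loop over `match_cutoff`.

## Density simulation, low-pass filtering and Q-scores

Simulated maps are sums of isotropic atom Gaussians with
σ_atom = 0.225 × resolution (the molmap convention, stated explicitly
because conventions differ between packages) and amplitude proportional
to atomic number, on a grid padded by 5 Å + 3σ so Gaussians are never
truncated at the box edge; the total density matches the analytic
Gaussian integral to < 1 %.

The low-pass target names the resolution of the **output** map: the
Gaussian frequency filter applies only the attenuation needed beyond
the map's declared resolution, with total attenuation reaching half
amplitude at spatial frequency 1/target.  Filtering a map to its own
resolution is therefore the identity, filtering a map of unknown
resolution applies the full half-amplitude filter, and simulating at
3 Å then filtering to 6 Å agrees with simulating at 6 Å directly
(voxelwise correlation > 0.98).  Sharpening requests are errors.

**Q-score.**  For each atom, map values are sampled (trilinear) at the
atom centre and on 8 spherical shells of radii up to 2.0 Å with 8
points per shell on a fixed Fibonacci layout — no randomness — with
sample points closer to another atom rejected.  The score is the
Pearson correlation between the samples and the reference profile
g(r) = A·exp(−r²/(2·0.6²)) + B, with A = μ + 10σ and B = μ − σ of the
map (the high/low reference values; Pearson is invariant to this affine
choice but it is recorded with every result).  q ∈ [−1, 1]; atoms with
zero-variance samples (empty map regions) get q = 0 and a flag.
Self-fit against a map simulated from the same model at 1.3 Å gives a
mean Q ≈ 0.91, and mean Q decreases monotonically as the same map is
filtered through 3 → 5 → 8 Å.

**Rigid fitting.**  Candidates are assumed pre-positioned (placements
are inputs, as when focused maps are fit interactively); refinement is
a bounded local search (≤ 3 Å translation, ≤ 10° rotation about the
model centroid) by deterministic coordinate descent with step sizes
shrinking 1.0 → 0.125 Å and 4 → 0.5°.  The objective is the true
real-space cross-correlation between the Gaussian-atom model density
and the map: for Gaussian atoms ⟨ρ_model, ρ_map⟩ reduces to a weighted
sum of the σ-smoothed map at the atom positions, and both norms are
pose-invariant, so one precomputed smoothed grid (cubic-spline
interpolated; trilinear ripple of ~0.3 % otherwise biases the pose)
makes each evaluation exact and cheap.  A minimum accepted gain of
1e-5 stops drift along the near-flat plateau around the optimum.  The
refined correlation is never below the initial one, a displaced start
2 Å from truth is recovered to < 0.5 Å RMSD, and a start at the true
pose stays within 0.2 Å / 1°.

**Cross-fit and discrimination.**  The cross-fit matrix holds the
per-model mean Q of every candidate refined into every map.  Per map,
the best candidate is the arg-max; the margin is Q(best) − Q(runner-up)
and calls below a 0.02 margin threshold are flagged ambiguous (the
threshold is configurable; no published value exists).  On synthetic
three-helix "LHC-like" analogs that differ in helix C — the short
analog straight, the long one 8 residues longer, tilted 12° and gently
curved, mirroring the short-straight-helix-C signature that separates
Lhcf from Lhcr/Lhcq proteins — the matrix is diagonal-dominant with
both maps confidently and correctly assigned at 5 Å, margins shrink
monotonically as maps degrade from 4 to 10 Å, and at 15 Å
discrimination fails: the long analog's own map is won by the wrong
candidate with a sub-threshold margin.  One caveat is deliberate: the
synthetic maps are noiseless, so envelope-level contrast (extra atoms
in weak density) survives arbitrary blurring and one map retains a
~0.03 margin at 15 Å; real medium-resolution maps carry noise that
erodes this faster.

## Synthetic data — what it emulates, and what it does not

Generated fixtures are ideal α-helical Cα traces (radius 2.3 Å,
100°/residue) wound about straight or circularly-arced axes, arranged
as a tall core ringed by shorter belt bundles; chlorophyll-like pigments
are idealized flat 25-atom tetrapyrroles (Mg + 4 N at 2.0 Å + 20 ring
carbons at 3.3 Å, standard component atom names) placed on prescribed
membrane sides, with constrained pairs solved to a target edge-to-edge
distance by bisection along the inter-ring axis (satisfied to < 1e-3 Å).
Every fixture ships with machine-readable truth — analytic axis arc
lengths (the true height of a helix *is* the arc length of its
generating curve), residue ranges, pair distances, the frame, subfamily
labels — and scenes are rejected if any inter-residue heavy-atom
distance falls below 1.5 Å.  A single integer seed governs all draws;
identical spec + seed produce byte-identical files.

What this does **not** emulate: side chains and backbone atoms beyond
Cα, experimental map noise and B-factor falloff, membrane curvature of
real thylakoids, partial occupancy and alternate conformers, and
chemically real pigment geometry (ring substituents, phytol tails).
Passing tests therefore demonstrate the correctness of the geometry,
graph and scoring machinery under known ground truth — not that any
particular biological structure has been reproduced.  Analyses of
deposited structures additionally require a user-supplied annotation
table (chain → subunit, belt role, subfamily) and, for pigment-level
claims, the deposition-specific chlorophyll numbering.

## Numerical choices and degenerate inputs

* Alternate locations collapse to the highest-occupancy conformer
  (first-encountered on ties); hydrogens are dropped; waters and lone
  ions are skipped.  All distances are heavy-atom.
* Chain naming follows author-assigned ids (what figures and annotation
  tables use) with a switch for mmCIF label ids.
* MRC axis order is normalized to x, y, z on read; origin honours the
  ORIGIN header words, falling back to start indices.
* Ties in closest-pair and gain/loss matching break by (chain, residue)
  order; node ordering in graphs is (chain, start residue) — all
  outputs are deterministic.
* Problem sizes in the test suite and acceptance script (50 bundles,
  500-helix and 2000-chromophore fields, two analogs × two maps) were
  chosen as the smallest scenes that exercise every code path at
  realistic packing density; all complete in seconds.

## Known limitations

* Helix detection assumes roughly ideal α-helical geometry; severely
  distorted or π/3₁₀ segments may fragment.
* The frame estimate needs a helix bundle with a dominant direction;
  single-helix or planar-fan inputs require an explicit normal.
* Q-scores use trilinear interpolation and 65 sample points per atom;
  absolute values differ slightly from implementations with denser
  shells, so only Q differences within one parameter set are
  meaningful (parameters are recorded in every result).
* The rigid fit is local by design; grossly wrong initial placements
  are out of scope.
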