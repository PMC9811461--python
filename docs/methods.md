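# Methods

## Scope and model

The package analyzes coarse-grained bead configurations of fed-state
intestinal fluid: bile salts (taurocholate, taurodeoxycholate,
glycocholate, glycodeoxycholate), phospholipids (single-tail PPC,
double-tail POPC), free fatty acids (16–18 carbons, four tail beads),
mono-/di-/tri-acylglycerides, cholesterol, water/antifreeze solvent, ions
and drug (API) placeholders. Only bead counts, roles (head, tail, linker,
solvent) and relative masses enter any computation; no force-field
parameters, bonded terms or energies are represented, and no dynamics are
integrated. Trajectories are sequences of coordinate files produced
elsewhere.

## Species registry

Per-species bead layouts are registry entries (YAML, overridable by the
user). Glyceride tails are four beads each. The layouts are chosen so the
digestion identities hold exactly: `n(TAG) = n(DAG) + n(FA) = 15` and
`n(DAG) = 2·n(FA) = 10` beads. Bile salts are 4 ring beads plus one
conjugate head; POPC is 2 head + 2 linker + 8 tail, PPC 2 + 1 + 4;
cholesterol 4 beads. Bead masses default to 1.0 (Martini beads are
near-uniform in mass); mass-weighted inertia is available by overriding
per-bead masses. `check_digestion_conservation` verifies both identities
and digestion refuses to run on a registry that breaks them.

## Composition → counts

`N = round(c · N_A · 10⁻²⁴ · L³)` with `N_A·10⁻²⁴ = 6.02214×10⁻⁴`
molecules · nm⁻³ · mM⁻¹. Species splits inside a class (bile salts,
phospholipids) use largest-remainder rounding so class totals are exact.
Defaults: equal quarters across the four bile salts, 50/50 PPC/POPC —
the measured compositions quantify classes, not individual species, so
the splits are uniform priors and configurable. Water fills the residual
volume at 8.0 beads/nm³ (one CG water bead ≈ 4 H₂O; 55.5 M / 4 ≈ 8.3
beads/nm³, rounded down to keep a margin for solute excluded volume,
which is accounted at 0.1 nm³/bead). Builder modes: random placement
(compact self-avoiding chains with 0.47 nm bonds, uniform random centers
and orientations), glyceride-free (MAG/DAG/TAG zeroed), and overlay
(insertion into an existing frame with 0.3 nm clearance, displacing
overlapping water). All builders are deterministic for a fixed seed.

## Colloid detection

Two molecules are linked when any bead–bead minimum-image distance is
≤ 0.5 nm (inclusive; "within" includes the boundary). Colloids are the
connected components with ≥ 2 molecules; single molecules are monomers;
water, antifreeze and ions never participate. The neighbor search uses
`scipy.spatial.cKDTree` with periodic `boxsize` (equivalent to a cell
list); every candidate pair is re-measured with the same minimum-image
arithmetic as the brute-force oracle, so accelerated and O(n²) detection
agree exactly, not just approximately. Manual merges (for visually
adjacent micelles) are explicit, logged operations — no automatic
distance rule is applied, since any such rule would be arbitrary.

Unwrapping reconnects a cluster across periodic faces: each molecule is
first made whole relative to its own first bead, then a breadth-first
traversal of the adjacency graph shifts each newly discovered molecule by
the exact lattice vector that places it next to its discovered neighbor.
This is valid when molecule extents and the colloid diameter stay below
L/2; the synthetic generator keeps molecules compact (see below), and
scenes should keep colloid diameters under ~0.6 L.

## Metrics

* **D_max** — the exact point-set diameter, computed on hull vertices
  (falling back to all points for degenerate clouds); equal to the O(n²)
  maximum by construction.
* **Shape factor** — λ_max/λ_min of the inertia tensor about the center
  of mass, equal masses by default. A uniform solid ellipsoid with
  semi-axes a ≥ b ≥ c has λ ∝ (b²+c², a²+c², a²+b²), so the closed form
  (a²+b²)/(b²+c²) anchors all lattice tests. Collinear clusters
  (λ_min ≈ 0) raise instead of returning an unstable ratio.
* **Water core** — water beads are single-linkage clustered at 0.6 nm
  under periodic boundaries; a component of ≥ 10 beads counts as an
  enclosed core when ≥ 90% of its beads lie inside the convex hull of
  the unwrapped colloid. Containment is evaluated after shifting each
  component to the periodic image nearest the colloid. The containment
  test alone excludes bulk water, which surrounds the colloid whether it
  forms one component or fragments at low density; the 10-bead floor
  suppresses single trapped beads.
* **Classification** — vesicle (has core) ≻ elongated (shape factor > 2)
  ≻ oblate/prolate. The oblate/prolate split follows the eigenvalue
  pattern of uniform ellipsoids: a disc has one large moment (about its
  symmetry axis) and two nearly equal smaller ones, so its sorted triple
  is (small, small, big) with λ_mid ≈ λ_min; a rod is the mirror image
  with λ_mid ≈ λ_max. Hence oblate iff λ_mid/λ_max < λ_min/λ_mid; exact
  ties (spheres) fall to prolate, matching the prolate-or-spherical
  micelle family.
* **Surface coverage** — a deterministic probe-accessibility test: a
  0.25 nm grid over the unwrapped cluster, cells within
  r_bead + r_probe (0.235 + 0.26 nm) of any bead blocked, exterior cells
  found by flood fill from the grid boundary, and beads within reach of
  an exterior cell marked as surface. Reported as each molecule class's
  fraction of surface beads (sums to 1). This is an intrinsic-surface
  identification in the spirit of ITIM-style probe methods, implemented
  on a grid so it is exactly reproducible.

* **Composition ratios** — bile-salt/phospholipid and
  bile-salt/fatty-acid molecule-count ratios; zero denominators yield
  `nan` rather than raising, since colloids without phospholipids are
  legitimate.

## Synthetic colloids

The generator produces geometric fixtures, not physically relaxed
structures. Micelles are jittered simple-cubic lattices clipped to an
ellipsoid; vesicles are concentric Fibonacci-sphere shells spanning the
bilayer, with the interior filled with water at 8 beads/nm³. Site
spacing adapts to the composition's total bead count, capped at 0.45 nm
(jitter ±6% of spacing) so nearest neighbors stay below the 0.5 nm
criterion and each colloid is one cluster by construction; compositions
whose implied spacing would exceed 0.497 nm are rejected as too sparse.
Sites are layered by depth — glycerides and drugs innermost, tails and
cholesterol in between, bile salts and fatty-acid/phospholipid head
groups at the water-facing surface(s) — and carved into molecules by a
shuffled single pass with nearest-site grabs, preferring the designated
layer with a distance penalty for neighbors, which keeps every molecule
compact (observed extents ≤ ~6.5 nm for vesicles of radius 4.5). Scenes
place colloids at uniform random centers (so boundary-straddling occurs
naturally) with ≥ 2 nm surface gaps, free monomers with ≥ 1.2 nm
clearance, and bulk water on a jittered lattice; detection therefore
recovers the recorded ground truth exactly.

What the fixtures do **not** emulate: thermal disorder, realistic packing
densities and order parameters, interfacial roughness, molecular
conformations, or any time evolution. Tests passing on them demonstrate
the correctness of the analysis operators (clustering, unwrapping,
moments, containment, counting), not the physics of self-assembly.

## Remodeling

Digestion reuses bead positions in place: the first n(DAG) beads of each
TAG become the DAG (glycerol-proximal beads stay together, following the
stored bead order), the remainder the fatty acid; analogously DAG → two
fatty acids. Bead counts are conserved exactly and re-detected
membership is unchanged because no coordinate moves. The biorelevant
DAG → MAG + FA split is not offered: although the shipped layouts happen
to match its bead count (10 = 5 + 5), the role mapping does not — a
DAG's second glycerol bead would have to become a fatty-acid carboxyl —
so the pipeline uses complete digestion (DAG → 2 FA), which is exact for
any registry satisfying the conservation identities. Absorption removes
`round(fraction × N_FA)` fatty acids (default 60%, the intra-individual
fed-state concentration drop) in seeded uniform-random batches of five,
with a partial final batch when the target is not a multiple of five,
emitting a snapshot per batch; relaxation between batches is external to
this package.

## Solubilization

Contacts are bead pairs within 0.6 nm (first CG neighbor shell; the
cutoff is configurable because the original contact tooling does not fix
one). Drug molecules never count as colloid material even when detection
assigns them to the cluster. The per-frame ratio is
contacts(API–colloid)/contacts(API–water); the summary is the mean of
per-frame ratios over the final 25 frames (frames with zero water
contacts are excluded with a warning; the alternative — ratio of summed
contacts — is available from the stored profiles). The per-class
breakdown divides each class's contact share by its molecule-count share
of the colloid, so 1 means proportional contact. Group comparisons:
Kruskal–Wallis with Dunn's tie-corrected z-tests (Bonferroni by default,
Holm optional) for affinity ratios; ordinary one-way ANOVA with Tukey
HSD for composition ratios.

## Numerical choices

* Rounding of counts is half-up throughout (`floor(x + 0.5)`), applied
  identically in builders and operators.
* Distance comparisons at exactly the cutoff count as connected; k-d-tree
  queries use a 10⁻⁹-inflated radius and re-filter with exact
  minimum-image arithmetic so accelerated paths equal brute force bit for
  bit.
* Cluster sort order (size, then smallest molecule id) makes partitions
  deterministic; all randomness flows through explicit integer seeds into
  `numpy.random.default_rng`.
* Degenerate inputs raise explicit errors: < 2 beads for D_max,
  collinear clusters for shape factors, disconnected clusters for
  unwrapping, vesicles with thickness ≥ radius, compositions too sparse
  to tile their geometry.

## Problem sizes

Default test and acceptance workloads use 10–18 nm boxes, colloids of
~100–900 molecules, and 20-scene/50-instance property suites — sizes at
which the brute-force oracles remain exact and cheap while every code
path (periodic wrap, hull degeneracy, partial batches, zero-water
frames) is exercised. Full 45 nm fed-state builds run in seconds but are
exercised through the count arithmetic rather than full-system
clustering in the test suite.

## Known limitations

* MD-derived observables (size/N_agg/shape distributions of relaxed
  fluids, their statistics) are outside scope: they require microsecond
  simulations, and this package only supplies the machinery that would
  analyze them.
* The unwrap procedure assumes each cluster fits in half the box; a
  percolating aggregate would be mis-unwrapped (detection itself is
  unaffected).
* Surface coverage depends mildly on grid resolution and probe radius;
  both are parameters with documented defaults, not physical constants.
* The ion content needed to neutralize specific compositions is not
  tabulated; ion counts are a user input.
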