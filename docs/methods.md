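# Methods

This note records the models, parameter choices and numerical decisions
behind `invdock`, and what the desk-scale tests do and do not establish.

## Binding-site database

A binding site is the region around a co-crystallized ligand. The build
follows the standard proteome-wide recipe:

- **Ligand filter.** HETATM groups with more than 7 heavy atoms whose
  closest heavy atom lies strictly within 3.0 Å of a protein chain.
  Waters are never ligands; a configurable cofactor code list (heme,
  nucleotide and vitamin cofactors by default, `DEFAULT_COFACTOR_CODES`)
  is excluded as well, since cofactors occupy pockets without defining a
  druggable site. All distance comparisons are strict (`<`), and use
  heavy atoms only.
- **Binding residues.** Any residue with an atom strictly within 5.0 Å of
  any ligand atom.
- **Assemblies, altlocs, models.** REMARK 350 transforms are applied when
  present (identity otherwise); for alternate locations the highest
  occupancy atom wins; only the first model of multi-model files is read.
- **Sequence clustering** groups chains with identical sequences (100%
  identity cutoff; the fraction is configurable, compared position-wise
  without alignment below 1.0).
- **Site similarity.** Published pipelines use a local structural
  alignment tool as a black box with a z ≥ 2.0 clustering threshold; we
  supply a defined surrogate with the same interface: the raw score is
  the size of the best residue-label-compatible, distance-consistent
  correspondence between the two sites' Cα sets (seeded from
  label-compatible pairs, grown greedily under a 1.5 Å internal-distance
  tolerance, requiring at least a consistent triplet), and z standardizes
  it against ≥ 100 seeded random label permutations of the second site.
  When the label multiset is degenerate the permutation null has zero
  variance; the null sd is floored at one residue so z stays finite.
- **Representatives.** Within a cluster, the site with the most source
  ligands wins, ties broken by lexicographic site id (the criterion used
  in published pipelines is unstated; this one is deterministic and
  favors well-characterized sites).
- **Centroids.** A greedy sphere cover of the source-ligand heavy atoms:
  seed on the first uncovered atom, absorb uncovered atoms within half
  the maximum radius, center the sphere on their mean with a 0.5 Å
  margin. Radii lie in [1.5, 4.0] Å and the union always covers every
  ligand atom (asserted).

## Docking engine

The query is fragmented at rotatable bonds — single, acyclic (bridges of
the heavy-atom graph), non-terminal, non-amide — giving rigid fragments
joined by links that remember the cut bond's reference length. Because
rotatable bonds are bridges, #fragments = #cuts + 1, and reassembling
fragments through their links reproduces the input bond graph exactly
(both are asserted in tests).

**Scoring.** A knowledge-based potential over element types
(C, N, O, S, P, halogen) in 0.5 Å bins to a 6 Å cutoff:
`−log[(observed + ε)/(reference + ε)]`, ε = 1, where the reference is
the *radial mean* — the pair's total count spread over bins in
proportion to shell volume (r³ differences). Scores are sums over all
protein–ligand heavy-atom pairs inside the cutoff; lower is better; the
units are internal and not comparable to other programs' scores.
Training pools all co-crystal complexes supplied; single-complex
statistics are usable but noisy.

**Sampling.** Grid points at 1.0 Å spacing (origin-anchored lattice)
inside the centroid union; each fragment centroid visits every point
under `n_rotations` seeded uniform orientations (identity included),
clashing placements (protein atom < 2.0 Å) are dropped, and the
`k_keep` best per fragment are retained. Defaults (grid 1.0 Å, 24
rotations, keep 20, clash 2.0 Å, overlap 1.5 Å, link tolerance 1.0 Å)
suit screening throughput; the re-docking tests pass 60 rotations and
keep 30 because 24 orientations under-sample rotation space for
ring-flip discrimination.

**Assembly.** Compatibility graph over (fragment, pose) nodes; edges
require distinct fragments, no atom pair closer than 1.5 Å, and every
shared cut bond within 1.0 Å of its reference length. Cliques covering
all fragments are enumerated exactly (Bron–Kerbosch with pivoting via
networkx) up to 64 nodes, greedily above. Assembled candidates are
snapped to exact cut-bond lengths by translating fragments along the
bond direction, breadth-first from the largest fragment. When no clique
covers every fragment — common for highly flexible ligands whose
independent fragment optima are scattered — the pipeline falls back to
hierarchical growth: anchor each kept pose of the largest fragment and
attach the remaining fragments breadth-first at exact bond geometry
under the seeded orientation set, keeping the best clash-free placement
per fragment.

**Refinement.** Degrees of freedom are rigid-body translation/rotation
plus one torsion per cut bond, so intra-fragment geometry and bond
lengths are preserved exactly. The binned score is piecewise constant
and gives line searches no slope, so descent (Powell's method, ≤ 200
iterations, 10⁻⁴ score tolerance, 10⁻³ step tolerance) runs on a
linearly interpolated version of the potential; the returned pose
carries the binned score and is kept only when it improves on the
input, which makes refinement monotone in the reported score by
construction.

**Determinism.** Every stochastic step takes an explicit seed; screens
default to seed 0. Identical inputs and seeds give identical poses and
byte-identical output files.

## Prioritization

Screen-wide best scores are treated as draws from a normal background
(supported by a normal Q-Q plot; `qq_points` uses plotting positions
(i − 0.5)/n). The fit is maximum-likelihood (population sd; an unbiased
sd flag exists, the difference is negligible at screen scale). The "95%
interval" is the central probability interval of the fitted normal,
μ ± 1.959964σ — not a confidence interval of the mean, which would be
orders of magnitude narrower at screen sizes — and selection keeps
scores strictly below the lower edge, sorted ascending with protein-id
tie-breaks.

## Validation metrics

All metrics operate on a ranking sorted ascending by score (best first)
with id tie-breaks. ROC handles tied scores by diagonal segments, making
the trapezoidal AUC equal to the tie-corrected Mann–Whitney statistic.
EF(χ) = [actives in top ⌈χN⌉/⌈χN⌉]/(n/N).
RIE = Σ_active e^(−α·rank/N) normalized by its uniform-ranking
expectation (n/N)(1 − e^(−α))/(e^(α/N) − 1);
BEDROC = RIE·Ra·sinh(α/2)/(cosh(α/2) − cosh(α/2 − α·Ra)) + 1/(1 − e^(α(1−Ra))).
α defaults to 20 — the conventional weight, emphasizing roughly the top
8% of the list; the published (RIE, BEDROC) pair for the curcumin screen
is mutually consistent only near this value, which fixes the choice.
The predictiveness curve fits a plain logistic regression of the active
flag on the (internally standardized) score by deterministic Newton ML;
standardization is an affine reparameterization that changes neither
probabilities nor TG. TG = mean|p̂ − p̄|/(2p̄(1 − p̄)). Perfect
separation triggers a ridge-stabilized refit (L2, α = 10⁻³) and a flag
in the result.

## Interaction profiler

Detection windows follow widely used profiler defaults (all config
keys): H-bond donor–acceptor ≤ 3.5 Å with D–H⋯A ≥ 120° when a hydrogen
position is available (distance-only otherwise — protein fixtures and
many PDB files carry no hydrogens); hydrophobic apolar C⋯C in
3.3–4.0 Å; π-stacking ring centroids ≤ 5.0 Å at ≤ 30° (parallel) or
60–90° (T-shaped); π-cation ≤ 5.0 Å; salt bridges between charged-group
centroids ≤ 5.0 Å (Asp/Glu negative, Lys/Arg positive, ligand formal
charges); water bridges via a water oxygen within H-bond range of both
sides; halogen bonds C–X⋯A ≤ 3.8 Å at ≥ 140°. Tryptophan contributes
its five- and six-membered rings separately, so a ligand ring stacked on
both naturally yields two records. Records re-validate against their
windows in a self-audit, and output is invariant to input order.

## Synthetic fixtures

Toy complexes are concave shells of Cα/Cβ pseudo-residues on a jittered
sphere (default radius 10 Å, 30 residues, names cycled through a
ten-residue roster so site-similarity label matching is non-degenerate),
holding a 9-atom two-ring ligand with one rotatable bridge. The ligand
is anchored with its closest contact just under the 3 Å extraction
cutoff and clash-free above 2.2 Å. Each complex also carries a "cradle":
one or two contact atoms of the same element 3.4 Å outward of each
ligand atom. The cradle is what makes re-docking well-posed at toy
scale: it gives the crystal placement a distinctive element-matched
contact signature, so a potential trained on these complexes has its
minimum at the crystal pose — the same premise that makes
knowledge-based docking work on real structures, compressed into one
geometric motif. Labeled score tables draw actives and inactives from
two normals with configurable means and shared sd; the default shape
(21 actives among 13,553) mirrors the reference screen.

What the fixtures do **not** emulate: real fold topology, side-chain
chemistry beyond the template atoms, solvent, or crystallographic noise.
Passing tests therefore establish the engine's internal correctness
(scoring identities, clique enumeration, monotone refinement, pose
recovery in well-posed pockets), not performance on real PDB entries.

## Problem sizes and known limitations

- Re-docking recovery (≤ 2 Å) is asserted on five seeded toy complexes
  with the potential pooled over an eight-complex corpus. Across the
  first eight seeds, seven recover; one (seed 0) is trapped in an
  adjacent basin — near-native candidates exist at ~1 Å but refinement
  terminates in a neighboring minimum that scores above the crystal
  basin. This mirrors a genuine docking failure mode and is left
  visible rather than tuned away.
- The clique-vs-brute-force, score-vs-double-loop and
  clustering-vs-union-find oracles run on ≤ 15-node graphs, 50×30-atom
  systems and ≤ 200-atom fixtures respectively; these sizes exercise
  every code path while keeping the default suite around a minute of
  compute.
- Absolute docking scores are internal to this engine's potential and
  are not comparable to any published program's values; only orderings
  and thresholds derived from the same screen are meaningful.
- The screen-wide normal assumption is adopted from the protocol, not
  tested formally; `qq_points` provides the visual check the protocol
  relies on.
- Receptor flexibility is honored only through ligand refinement
  against a rigid receptor; receptor minimization is out of scope.
- The curcumin reference structure is stored as the enol tautomer,
  neutral protonation — the species dominating at physiological pH;
  tautomer and protonation enumeration are out of scope.
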