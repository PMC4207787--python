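# Methods

This note documents the models, parameters and numerical choices behind
`dimerstab`, and what the synthetic benchmarks do and do not demonstrate.

## Problem setting

A missense mutation near a homo-dimer interface can destabilize the dimer
and abolish function even when the active site is untouched. A rescue
strategy is to find small molecules that bind pockets at or near the
weakened interface and stabilize the assembled dimer. The computational
funnel that supports such a campaign has six stages — ensemble validation,
binding-site conformation selection, pocket triage, compound filtering,
consensus docking-rank aggregation, and binding-energy rescoring — and
this package implements all of them as a library with a thin CLI.

## Ensemble validation (`dimerstab.dynamics`)

Superposition is closed-form Kabsch via SVD with the determinant
correction, so the rotation is always proper (det = +1) even for
reflection-related point sets. Degenerate inputs (fewer than three atoms,
or a collinear set detected by a vanishing second singular value of the
centered coordinates, tolerance 1e−9) raise rather than return an
arbitrary rotation.

The average structure is the iterative mean: all frames are superposed
onto the running mean (seeded by the first frame) until the mean moves by
at most 1e−6 Å, with a cap of 50 iterations. No force-field minimization
of the mean is performed — there is no force field in scope — so the mean
is a purely geometric object and is labelled as such (`"ave"`). The mean
is defined only up to a global rigid motion; comparisons against it should
superpose first.

RMSF is computed per selected atom after superposing every frame onto the
iterative average; the default validation profile uses Cα atoms, while
global RMSD traces default to backbone atoms (N, CA, C, O). Both are
configurable through the selection language
(`"chain=C,D;res=1-120;atoms=backbone"`). The pseudo-B-factor conversion
is the standard isotropic relation B = (8π²/3)·RMSF². No numeric
correspondence between simulated RMSF and crystallographic B-factors is
asserted anywhere — the comparison is qualitative by nature.

## Binding-site conformation selection (`dimerstab.cluster`)

The pairwise matrix holds the RMSD over the binding-site selection between
every pair of snapshots, each pair optimally superposed beforehand. By
default the superposition uses the same binding-site selection (a local
fit); a global-backbone fit and a no-superposition mode are also available
since the right choice depends on how the input frames were aligned. The
same-selection path uses the singular-value identity
m·d² = |A|² + |B|² − 2(σ₁+σ₂+sign(det H)σ₃), batched over frame pairs, and
is checked in the tests against a naive Kabsch loop.

Ward agglomeration runs on the condensed distance matrix with ward.D2
semantics (Lance–Williams recurrence on squared distances, heights
reported in Å) — the textbook Ward objective. The flat clustering is the
set of connected dendrogram groups below the cut height, 1.3 Å by default;
a fixed-cluster-count mode exists as well, but the emergent count is the
scientifically meaningful reading: the number of distinct binding-site
shapes is an output, not an input. Heights are checked for monotonicity
(Ward cannot invert on any symmetric input, so a violation indicates a
corrupted matrix and is an error). Tests verify the merge sequence and
heights against an independent greedy agglomerator that recomputes every
merge cost from the original squared distances through the centroid
identity, never through the recurrence.

Cluster representatives are **medoids** — actual snapshots minimizing mean
distance to their cluster (ties to the lowest frame index) — because
downstream docking needs a real geometry, not an averaged one. The
population-density count (frames within a radius of a snapshot, default
radius 1.5 Å) quantifies how typical a medoid is: with clustering done
over binding-site atoms only, a medoid can be locally representative yet
rare globally, and the count makes that visible instead of hiding it.

## Pocket druggability (`dimerstab.pockets`)

Cavity detection is a transparent grid-probe scheme: Bondi-type van der
Waals radii stamp the protein volume onto a cubic grid (spacing 0.5–1.5 Å,
default 1.0 Å; probe radius 1.4 Å); non-protein cells are probed for
burial along the 26 grid directions, and cells seeing protein in at least
`burial_threshold` directions (default 16) and lying within 8 Å of the
molecular surface are cavity cells. Face-connected components smaller than
30 ų are discarded. Descriptors: volume = cells × spacing³; surface =
exposed cavity faces × spacing²; lipophilic surface = faces whose nearest
atom is an apolar carbon/sulfur (apolar = C/S with no N/O within a 1.9 Å
bond distance); depth = largest cell distance to bulk solvent (Euclidean
distance transform × spacing); lining residues have any atom within 4 Å of
a cavity cell. Watershed subpocket splitting is deliberately not enabled
by default; subpockets are descriptive, not decision-relevant.

The druggability score is a fixed logistic,

    score = σ(w₀ + w_v·min(V,1500)/1500 + w_l·lipo/surface
              + w_d·min(depth,10)/10)

with defaults w₀ = −4.5, w_v = 3, w_l = 2, w_d = 3, chosen so that a deep,
predominantly lipophilic pocket of ~1500 ų clears the 0.80 triage floor
while a shallow 50 ų dimple stays far below 0.3, and monotone increasing
in every normalized descriptor by construction. **This is not a trained
druggability model**: absolute values are not comparable to SVM-based
scorers, and published per-pocket scores are not reproduction targets —
only the [0, 1] range and the triage role (keep pockets scoring above the
floor near the target residue) carry over. Because the grid is anchored to
the structure's bounding box, descriptors are exactly translation
invariant; rotation invariance is approximate at the grid resolution.

## Compound filtering and similarity (`dimerstab.chem`)

Descriptors come from RDKit: molecular weight, Crippen logP, Ertl tPSA,
H-bond donors/acceptors (acceptor-typed, consistent with the tPSA/donor
typing), and rotatable bonds. The PPI-adapted windows are strictly
exclusive exactly as written — 100 < MW < 700, 0 < tPSA < 160,
−4 < logP < 6, 0 < HBD < 5, 0 < HBA < 10, 0 < RotBonds < 15 — which
notably means a zero-valued count descriptor fails; the generator plants
its ground truth under the same literal rule. A missing descriptor is an
error, never a silent pass, and all violated rules are reported. The
radar-profile rendering maps each descriptor to its fractional position in
the window; "polygon inside" is provably the same predicate as the filter
and is tested as such.

Fingerprints are radius-2 circular fingerprints with pharmacophoric
(functional-class) atom invariants folded to 2048 bits — the open
equivalent of an FCFP-4. Bit-for-bit equality with proprietary FCFP
implementations is a non-goal. Tanimoto similarity is |a∧b|/|a∨b| with the
all-empty pair defined as identical (similarity 1), so the measure stays
total. Diversity selection is leader/sphere-exclusion clustering at
maximum distance 0.3, processing records in descending id order for
determinism; representatives are therefore pairwise farther than 0.3 and
every member is within 0.3 of its representative. Scaffold grouping of
actives is single-linkage (connected components at similarity ≥ 0.6). The
liability screen is a small, documented SMARTS subset (acyl halides,
aldehydes, Michael acceptors, isocyanates, epoxides, alkyl halides,
quinones, catechols, hydrazones, nitroaromatics) — a placeholder for a
full curation, each rule pinned by an exemplar in the tests.
Stereochemistry is ignored throughout (no 3D generation in scope).

## Consensus aggregation (`dimerstab.consensus`)

Each engine table is ranked best-first under its own convention (ties
broken lexicographically by compound id for determinism). Top-N keeps all
compounds tied at the boundary score — the set may then exceed N, which is
logged rather than silently truncated. The per-conformation consensus is
the plain intersection of the two engines' top sets; both engines must
have scored the same compound universe, and a mismatch is an error rather
than an implicit inner join. Pooling reports **both** the union of the
per-conformation sets and the sum of their sizes: with three overlapping
conformations these genuinely differ, and publishing only one of them is
ambiguous. The "interactive visual triage" step of a human campaign is not
automatable and is not imitated; an optional score-margin filter exists
but is clearly labelled non-equivalent.

## Binding-energy protocols (`dimerstab.energy`)

Both protocols average the last 20 snapshots (1 ps apart) of the energy
streams, anchored at the trajectory end; the window is configurable.
Rigid requires the dimer/ligand streams to be tagged as extracted from the
complex snapshots and snapshot-aligned; relaxed requires independent-run
tags. Mixing tags is an error — the two protocols answer different
questions and silently swapping streams between them is the classic
bookkeeping mistake. Entropy is not modelled explicitly; the
separate-trajectory protocol captures relaxation of the free species
implicitly, and the package documents exactly that stance rather than
claiming more. Selection keeps a compound when rigid OR relaxed is ≤ the
threshold (−20 kcal/mol default; "better" = more negative), sorts
ascending by the better of the two (ties by id) and truncates to the final
candidate count (default 51).

The toy pair potential — Lennard-Jones with Lorentz–Berthelot combining
plus Coulomb under a distance-dependent dielectric ε(r) = 4r, i.e.
332.06·qᵢqⱼ/(4r²), no cutoff — exists so the protocol is exercisable end
to end; it claims no force-field equivalence and its parameters ship as
plain data.

## Synthetic ground truth (`dimerstab.synth`)

One integer seed, split into fixed named substreams per artifact kind,
reproduces every byte of every artifact. Planted truths (state labels,
pass flags, binder ids, true ΔΔG) are emitted as side-cars and never read
by the pipeline's decision logic.

* **Toy dimer**: two parallel ideal backbone helices (rise 1.5 Å/res,
  100°/turn), chains C and D, 9 Å axis separation with opposed phases so
  the closest backbone atoms face each other across a ~4.5 Å groove.
* **Ensemble**: binding-site residues are those within 6 Å of the other
  chain. Conformational states are realised as one shared random per-atom
  displacement field on the binding-site atoms with the six rigid-body
  modes projected out and unit RMS, scaled per state by
  s·state_amplitude. Projecting out the rigid modes matters: a rigid
  sub-motion would be absorbed by the local superposition used for the
  RMSD matrix and the states would be unrecoverable by construction.
  Thermal noise is i.i.d. Gaussian per coordinate. Defaults:
  amplitude 3 Å (minimum inter-state binding-site RMSD), σ = 0.15 Å
  (frame-to-frame intra-state RMSD ≈ σ√6 ≈ 0.37 Å, i.e. ~8× below the
  state separation and comfortably below the 1.3 Å cut), 1500 snapshots
  at 1 ps. Ward internal merge heights for i.i.d. noise plateau near the
  intra-state RMSD regardless of cluster size, which is why a fixed
  1.3 Å cut separates states cleanly across k.
* **Library**: 5000 records; descriptors of passing records drawn from
  normals truncated inside every filter window (MW ~ N(400, 120²),
  tPSA ~ N(80, 40²), logP ~ N(1.5, 2²), counts from shifted binomials);
  25% of records get one random descriptor pushed outside its window.
  SMILES are simple parseable chains — chemical realism beyond
  parseability is explicitly not emulated.
* **Scores**: a shared latent affinity drives both engines
  (engine A higher-is-better ≈ [4, 9]; engine B lower-is-better ≈
  [−9, −4]); 10 planted binders sit at latent 6.0 ± 0.25 versus N(0, 1)
  for the rest, with per-engine noise σ = 0.5, so binders land in both
  engines' top tails without being rank-exact.
* **Energies**: E(complex) = E(dimer) + E(ligand) + ΔΔG_true + ε,
  ε ~ N(0, 2²) per snapshot; ΔΔG_true is −25 kcal/mol for binders and −5
  for non-binders. Independent runs are the extracted streams lowered by
  deterministic relaxation offsets (dimer 1.5, ligand 0.5 kcal/mol), so
  relaxed − rigid equals the planted offset exactly at any noise level
  and the rigid estimator has SD exactly σ/√20.

**What passing tests show — and don't.** The synthetic ensemble has
discrete, well-separated states with isotropic noise; real trajectories
have continuous, anisotropic, correlated motions, so exact state recovery
here demonstrates correctness of the machinery, not expected field
performance. Likewise the planted score tables have a single latent
affinity (real engines disagree more richly), and the energy streams have
i.i.d. noise (real MD energies are autocorrelated, making the effective
window smaller than 20). The benchmarks validate bookkeeping, estimators
and thresholds — not docking accuracy.

## Pipeline and problem sizes (`dimerstab.pipeline`)

Configuration is a flat key=value text file with a fully enumerated key
set; unknown keys fail fast because a silently ignored typo corrupts a
screen. Each stage logs one structured line; the report is JSON with
counts, metrics and the selected ids, and the compound funnel
(library ≥ filtered ≥ consensus union ≥ selected) is asserted monotone.
Reruns with the same seed are bitwise identical apart from the timestamp
field.

Default problem sizes — 1500 snapshots × 480 atoms, 5000 compounds, three
receptor conformations, top-2000 consensus, 60-snapshot energy streams —
were chosen as the package's reference desk-scale conditions: the full
funnel completes in well under a minute on one CPU while keeping every
stage's statistics meaningful (the 1500-frame RMSD matrix alone is ~1.1
million superposed pairs, computed via the batched singular-value path).

## Known limitations

* The pocket detector is grid-based and axis-aligned; scores are exactly
  translation invariant but only approximately rotation invariant, and
  the druggability formula is a fixed heuristic, not a trained model.
* The average structure is unminimized; for real ensembles it can contain
  locally strained geometry.
* HBA counting conventions differ between tools; the acceptor-typed count
  used here can disagree with N+O counting near the filter boundaries
  (the convention is switchable).
* The liability SMARTS list is a minimal subset, not a curated catalogue.
* Docking itself, MD itself, protonation and 3D conformer generation are
  out of scope; score tables and energy streams are consumed as data.
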