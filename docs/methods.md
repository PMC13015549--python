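# Methods

This note documents the models, parameters and numerical choices behind
`metamorphscan`, and what the synthetic-data generators do and do not
emulate.

## Fold classification

**Secondary-structure assignment.** A Kabsch–Sander style
hydrogen-bond pattern analysis over backbone N, CA, C, O atoms. The
amide hydrogen is rebuilt geometrically 1.01 Å from N along the
bisector pointing away from C(prev) and CA; a (CO, NH) pair is bonded
when the electrostatic energy
E = 0.084·332·(1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol is below
−0.5 kcal/mol, with a 9 Å Cα–Cα prefilter and the shared peptide bond
(j = i+1) excluded. Letters follow the classical pattern rules: H from
two consecutive i→i+4 turns, E from bridge ladders (two or more
consecutive parallel/antiparallel bridges), B for isolated bridges,
G/I from i→i+3 / i→i+5 turn runs, T for remaining turn interiors, C
otherwise. Priority is H, E, B, G, I, T. Residues with missing
backbone atoms are C; chains shorter than 3 residues are all C. The
assigner reproduces the H/E cores reported by an external DSSP
implementation on ideal geometry (cross-checked in the test suite);
exact letter-by-letter parity with any particular external program is
not promised and not needed — only strict H and strict E enter the
classifier.

**CTD location.** The fold-switching region is located per query by
global alignment to the reference sequence; the returned window is the
smallest query region covering all residues aligned to the reference
region (default 110–162, configurable — the region is the same one
used as the steering collective variable, since no separate window is
defined anywhere else). Alignments covering < 50 % of the reference
region raise a "CTD unresolved" error carrying the coverage; in
ensemble summaries such models are counted and labelled NONE rather
than dropped.

**Classification rule.** With thresholds (32.5, 2.5, 30.0, 2.5, 2.5)
all inequalities strict: ALPHA if %H > 32.5 and %E < 2.5; BETA if
%E > 30.0 and %H < 2.5; MIXED if both > 2.5 and neither strong rule
fires; NONE otherwise. Percentages are computed over the full located
CTD window including coil/turn/3₁₀/π/bridge residues; only strict 'H'
and 'E' count. The rule is total and unambiguous (verified
exhaustively on a 0.1-step grid). Majority ties in ensembles break by
the fixed precedence ALPHA > BETA > MIXED > NONE — deterministic
reporting; because per-model counts are also reported, any per-sequence
convention (majority, best model, "at least 2 of 5 models") can be
reconstructed, and `EnsembleSummary.labels_with_min_count` exposes the
last directly.

## Sequence mapping and salt-bridge distances

Global Needleman–Wunsch alignment with affine gaps (BLOSUM62, gap open
−10, extend −1; a gap of length L costs open + (L−1)·extend; terminal
gaps are penalized). The scoring is conventional rather than
prescribed, and configurable. Position mapping uses pairwise
alignments to the reference rather than a family MSA: for locating two
reference positions the pairwise map is equivalent and removes the MSA
dependency. A reference position aligned to a gap maps to "missing";
missing records are excluded from distance statistics but counted, so
n_total = n_used + n_missing always holds. Distances are Euclidean
Cβ–Cβ (Cα for glycine). Summaries use linear-interpolation (type-7)
quantiles: median, 25/75 quartiles, 1st/99th percentiles.

## Superposition, RMSD and TM-score

Kabsch superposition by SVD with the determinant correction that
excludes reflections. Region RMSD against a reference state uses
Cα pairs from the sequence alignment (identity mapping when sequences
match); with a separate fit region (the rigid NTD) the transform is
computed there and applied to the evaluated region without refitting.
TM-score uses d0 = 1.24·(L_norm − 15)^⅓ − 1.8 (defined only for
L_norm ≥ 16) and the standard iterative heuristic: superpositions
seeded from sliding fragments of lengths L, L/2, L/4, then up to 20
refinement rounds on the residue subset within d0 (cutoff relaxed in
0.5 Å steps when fewer than three residues qualify), keeping the best
score. Self-score is exactly 1; parity with any external TM-score
binary is not claimed.

## Trajectory analysis

The steering restraint energy is E = ½·k·N·(RMSD(t) − RMSD_target)²
with k in kcal/(mol·Å²) and N the number of collective-variable atoms
(252 backbone atoms for the 53-residue reference region). The
universal PCA map superposes every frame on the first frame's
fit-region Cα, computes the covariance of the flattened
analysis-region Cα coordinates and diagonalises it; eigenvalues are
clipped at zero and sorted descending, and an all-identical-frames
input yields zero variance with a warning rather than an error.
k-means is Lloyd's algorithm with k-means++ initialisation, a mandatory
seed, ≤ 300 iterations and tolerance 1e-6 (scikit-learn, n_init = 1
for determinism). Representative trajectories are the owners of each
cluster's centroid-nearest frame; duplicates collapse, so ≤ k
trajectories come back, and empty clusters are skipped with a warning.
Structure-level clustering uses the 2-vector (RMSD to state A, RMSD to
state B) as feature space — matching the axes on which such decoys are
usually displayed; a full pairwise-RMSD matrix would be an alternative
reading — with the medoid (minimal summed in-cluster distance, ties to
the lowest index) as representative.

## Genomic context

Coordinates are 1-based inclusive. Intergenic distance is
next.start − prev.end − 1, clipped at 0 for overlapping genes
(convention; not otherwise specified). A long operon is a **maximal**
run of ≥ 2 consecutive same-strand genes with all gaps ≤ 200 bp whose
genomic **span** (last end − first start + 1) strictly exceeds
5,000 bp; span was chosen over summed gene lengths as the conventional
reading of "total length", and both the gap and span cutoffs are
configurable. Input must be coordinate-sorted (unsorted input is an
error, never silently reordered). Proximity: a focal gene inside the
span is INSIDE; otherwise the distance is |focal.end − span start| for
a '+' operon and |focal.start − span end| for a '−' operon (the
promoter-proximal end in each case, applied literally even when focal
and operon partially overlap), NEAR_* below 1,000 bp split by strand
equality, DISTANT otherwise. The focal gene participates in operon
construction, which is what makes INSIDE reachable. Product text is
scanned for lipopolysaccharide-related keywords to flag candidate
target operons.

## Synthetic data

Backbones are built by Natural Extension Reference Frame placement
with ideal geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, standard
angles, ω = 180°). Helices use (φ, ψ) = (−57°, −47°). Strands use
(−139°, 136.46°): ψ is nudged from the textbook 135° to the value at
which the 2-residue repeat is an exact translation (zero strand
twist), because two *rigid* copies of a twisted ideal strand can only
hydrogen-bond locally — with flat strands the antiparallel pairing
holds at any length. The β-hairpin places the second strand as the
exact 2-fold (dyad) image of the first; the dyad orientation,
half-separation and register are grid-searched against the same
Kabsch–Sander energy the assigner uses (clash-rejecting, energies
clamped at −3 kcal/mol so 1/r singularities cannot win), coarse then
fine, cached per residue-count phase class (mod 4). Connecting turns
and linkers are geometric interpolations, not ideal peptides — they
read as coil, which is all the classifier requires.

Two-domain decoys place an NTD stub (helix + extended tail), a
4-residue linker and a CTD built per planted label (ALPHA: two helices
with a loop; BETA: a β-hairpin; MIXED: one helix plus a strand pair,
helix sized to ~30 % of the CTD so both contents clear 2.5 % without
tripping the ALPHA rule; NONE: extended coil). Marker residues (GLU in
the NTD, ARG in the CTD) are positioned so their Cβ–Cβ distance equals
the recipe value exactly, with the CTD body rotated to point away from
the NTD so proximity cannot create spurious inter-domain bridges.
B-factors are constant and controllable (default 90), standing in for
pLDDT.

Trajectories are linear coordinate interpolations with seeded
isotropic Gaussian noise — statistical stand-ins for steered-MD
output with no solvent, thermostat or force field; defaults (50
frames, matching 100 ps sampled every 2 ps) mirror the sampling scheme
of the simulations they emulate. Gene neighborhoods surround the
focal gene with ~10 background genes whose gaps always exceed the
intergenic cutoff, so the planted operon (default three 2,000-bp genes
with 50-bp gaps, offset 500 bp) is the only possible call and the
expected proximity category is computable from the recipe arithmetic;
a same-strand operon planted within the gap cutoff of the focal gene
absorbs it, and the planted truth then becomes INSIDE.

**What passing tests show.** Generators produce ideal geometry,
isotropic noise and clean operon structure; real predicted models have
loops, partial disorder and borderline content values near the
thresholds, real trajectories are not linear, and real neighborhoods
contain overlapping and nested transcripts. Planted-truth recovery
demonstrates correctness of the decision rules and the plumbing, not
classifier performance on borderline real data.

## Problem sizes and determinism

All stochastic operations take explicit seeds; identical recipes and
seeds give bit-identical outputs. The acceptance script uses 60
decoys, 500 random gene tables, 500 neighborhoods, 200 alignment
pairs, 12 × 50-frame trajectories and the full 1001 × 1001
classification grid — sizes chosen so the whole run completes in well
under a minute of CPU beyond the one-off hairpin placement scans,
while every rate is measured from at least dozens to hundreds of
independent cases.

## Known limitations

* The assigner omits torsion-based refinements of turn subtypes; G/I/T
  boundaries can differ from other programs (irrelevant to the strict
  H/E counts used downstream).
* TM-score and alignment are heuristic/conventional where the upstream
  procedure left them unspecified (fragment seeding; BLOSUM62 −10/−1).
* Multi-chain structures, mmCIF, occupancies and alternate locations
  beyond the first are out of scope; only the first chain of each
  model is read.
* The decoy generator does not emulate predicted-model diversity or
  realistic pLDDT profiles; B-factors are constant per structure.
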