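# Methods

This note records the models, conventions, parameter choices and known
limitations behind `statescope`, in the order the analysis runs.

## Coordinate handling

Multi-model PDB files are read through gemmi into a frame/ensemble
container keyed by (chain, author residue number, insertion code, atom
name).  Alternate locations are reduced to a single conformer by keeping
blank or 'A' altlocs only, so every downstream distance and projection is
computed on deterministic single-conformer geometry.  Waters are dropped.
The shared topology of an ensemble is the intersection of atoms present
in every frame; coordinate selections are ordered by ascending residue
number and atom name within one chain (default: the first chain), which
makes every matrix layout reproducible.  Insertion-coded residues are
excluded from the shared topology rather than silently merged into the
numbering.

## Secondary structure

A three-state (H/E/C) assignment based on the Kabsch–Sander backbone
hydrogen-bond energy,

E = 0.084 · 332 · (1/r_ON + 1/r_CH − 1/r_OH − 1/r_CN) kcal/mol,

with a bond accepted below −0.5 kcal/mol.  Amide hydrogens missing from
the coordinates (the usual case for crystal structures) are constructed
on the peptide plane opposite the bisector of the C(i−1)→N and Cα→N
directions at 1.01 Å.  Helices follow the minimal-helix rule (two
consecutive i→i+4 turns), strands the parallel/antiparallel bridge
patterns with |i−j| ≥ 3.  Residues with incomplete backbones degrade to
coil by contract.  The full eight-state DSSP alphabet is unnecessary
here: secondary structure enters only as a 30%-weight term in the
alignment score.  The test suite cross-checks the assignment against
mdtraj's DSSP implementation on the toy fold.

## Sequence alignment with a secondary-structure term

Global Needleman–Wunsch with affine gaps (Gotoh recursion), maximising

(1 − w) · BLOSUM62(a, b) + w · M_ss(s_a, s_b),

with w = 0.3 by default.  M_ss scores +6 for identical H/E/C labels, −6
for helix/strand confusion, and 0 against coil — a compact surrogate for
structure-aware alignment tools whose exact blending is not published.
Gap penalties default to open 12 / extend 1 (the first gapped position
costs 12, each extension 1), the common BLOSUM62 convention.  The DP is
hand-rolled rather than delegated to a library aligner because the score
is position-specific (it depends on per-position secondary structure),
which a fixed substitution matrix cannot express; with w = 0 it reduces
exactly to plain BLOSUM62 Needleman–Wunsch, which the tests verify
against Biopython's `PairwiseAligner`.  Traceback ties break match >
gap-in-target > gap-in-reference, making alignments deterministic.

## Superposition and RMSF

Rigid-body fits use the SVD form of the Kabsch solution with the
determinant correction that excludes reflections; inputs with fewer than
three points or (near-)collinear geometry are rejected.  Ensembles are
fitted frame-by-frame on the backbone (N, Cα, C) of the low-fluctuation
core — residues 7–33, 40–47, 50–58, 61–65, 71–81, 88–90, 95–101 for the
reference SH2 domain — and all other atoms ride along rigidly, so
intra-frame geometry is preserved to machine precision.  RMSF is computed
about the ensemble-mean position (not frame 1), the standard fluctuation
definition; for isotropic Gaussian jitter of σ per coordinate it
converges to σ√3, which both the tests and the acceptance script verify
at 10⁴ frames.

## Distance descriptors

The four diagnostic distances (pY loop opening Lys35 Cα–Thr42 Cα,
β-sheet spread Gly39 C–Asn58 N, cleft opening Gly67 Cα–Lys89 Cα, +5 site
opening Tyr66 Cα–Leu88 Cα) are plain Euclidean distances on first-model,
altloc-A coordinates.  A numbering offset argument covers chains numbered
differently from the reference; the survey stage instead maps residues
through the alignment.  Bivariate histograms default to 0.25 Å bins over
[3, 16] Å — fine enough to resolve the ~4 Å (zipped) vs ~12 Å (unzipped)
sheet regimes — and are normalised to unit mass with marginals equal to
the row/column sums by construction.

## PCA, subvectors and state classification

PCA diagonalises the Cα coordinate covariance (population normalisation
1/F) of the core-superposed ensemble over residues 6–101 by default; Cα
atoms suffice because the collective opening/closing motions are
backbone-scale.  The analysis derives its reference mode v from the
supplied ensemble and persists it (NPZ + JSON sidecar) so later runs
reuse a fixed vector rather than refitting.

The two site subvectors are built exactly as defined: the trajectory is
filtered to contain only motion along v (frame → mean + projection·v),
then PCA restricted to the pY-site atoms (Ser34–Phe41) and +5-site atoms
(Gln57–Glu97) is run on the filtered trajectory and each subset's first
mode is kept.  Analytically this is the normalised restriction of v, and
the tests confirm the identity.  Signs are calibrated against a
designated closed-reference structure so that positive projection means a
closed site; without a reference the largest component is made positive
(deterministic but physically uncalibrated).

Classification is by plane quadrant: α (closed/closed), β (open/open),
γ (pY closed/+5 open), δ (pY open/+5 closed).  The boundaries default to
(0, 0) — under the mean-centred construction the midpoint between the
two extreme-projection reconstructions is exactly zero — and exact
boundary ties resolve to the closed side.

Clustering is GROMOS-style neighbor counting: the frame with the most
neighbours within the RMSD cutoff seeds a cluster, its neighbourhood is
removed, and the procedure repeats; ties break to the lowest frame
index.  RMSDs are taken on the already-superposed coordinates without
per-pair refitting — the input contract is a core-fitted ensemble, so a
second fit would only blur the state separation.  The default cutoff is
1 Å Cα RMSD (0.1 nm).  An exhaustive reference implementation in the
tests reproduces the partition exactly.

## Survey screening

Each candidate structure's best chain is chosen by the SS-weighted
alignment score against the reference; aligned pairs define a mapping to
reference numbering.  Entries are excluded when the mapped pY loop is not
exactly the reference's eight residues (insertions and deletions both
break the aligned-run check) or when any mapped descriptor backbone atom
is missing in any model; unalignable inputs get their own reason.  Every
model of an included entry contributes one observation (an N-model NMR
entry adds N points to its stratum), and per-method histograms are
normalised separately.  Survey projections are reported relative to the
reference domain's own position in the essential plane, so a rigid copy
of the reference projects to exactly zero; this shifts the axis by a
constant relative to mean-centred projections and makes the zero point
interpretable without knowing the ensemble mean.  Method labels come from
the coordinate file's EXPDTA record; hybrid methods bucket as "other".

## RDC formalism

Couplings follow D = D_max(type) · uᵀ S u with S the Saupe matrix
parametrised by (S_zz, S_xx − S_yy, S_xy, S_xz, S_yz).  D_max =
−μ₀ħγᵢγⱼ/(8π²r³) (Hz) with gyromagnetic ratios γ_H = 2.6752219×10⁸,
γ_N = −2.7116×10⁷, γ_C = 6.72828×10⁷ rad s⁻¹ T⁻¹ and effective bond
lengths r_NH = 1.041 Å, r_NC′ = 1.329 Å, r_HC′ = 2.085 Å, r_C′Cα =
1.526 Å, r_CαHα = 1.117 Å — common solution-NMR conventions, all exposed
as configuration.  With this sign convention D_max(H–N) ≈ +10.79 kHz;
only internal consistency matters for fitting, and a `flip_sign` flag on
the splitting-difference reader covers the opposite convention
(default: RDC = anisotropic − isotropic splitting).  N–C′ and H–C′
couplings span residue i and the preceding carbonyl.  Missing amide and
α hydrogens are built geometrically (bisector and tetrahedral
constructions); Gly Hα is not built (no Cβ anchor) and such records are
rejected rather than guessed.

The ensemble fit solves the N×5 linear system whose rows are
frame-averaged quadratic-form coefficients scaled by D_max, via
numpy's SVD-based least squares — one tensor for all frames, records
unweighted by default (per-record 1/σ weighting is available but off).
Ensembles larger than `max_structures` (default 100) are subsampled
uniformly without replacement with an explicit seed.  Derived tensor
quantities use principal values ordered by descending magnitude:
magnitude = S_zz′, rhombicity R = (2/3)(S_xx′ − S_yy′)/S_zz′ ∈ [0, 2/3].
Goodness of fit: Pearson r, Q = rms(residual)/rms(observed), RMSD, and
outliers flagged at |residual| > 2 SD (the threshold is a convention;
the underlying labelling rule is not published).  Correlation-vs-size
curves refit the tensor on random subsets per size but always over all
records; the correlation may then be reported on one coupling type only.
Curves are single-draw per size (deterministic given the seed); an
averaged band can be built by varying the seed.

## Synthetic data: what it does and does not emulate

The toy domain is a deterministic fold — three genuinely hydrogen-bonded
antiparallel strands (partner strands are placed by refining a two-fold
screw axis until every designed bridge reaches O···N = 2.95 Å and
O···H = 1.95 Å, and the Kabsch–Sander criterion then accepts the bonds)
plus a 12-residue α-helix, with loops closed by a deterministic
least-squares solve over their dihedrals.  Backbone bonds stay within
1.2–1.6 Å; residue names cycle through 16 amino-acid types (no Gly/Pro,
so every residue has Cβ and amide H).

Two-state ensembles displace the edge strand by 3 Å (sheet spreading,
matching the scale of the ~4 → ~12 Å transition), the pY loop by 1.5 Å
and the +5 segment by 2 Å toward closure for the α-like endpoint; the
β-like endpoint is the fold as built.  Frames mix the endpoints
Bernoulli(fraction_a) and add i.i.d. Gaussian coordinate noise
(default σ = 0.3 Å, n = 200, seed 2024), keeping the endpoint separation
well above 5× the noise SD along both site axes.  These ensembles have
the *statistical* structure the pipeline assumes — two rigid states, one
dominant collective mode, isotropic noise — but none of the physics of a
real protein: no correlated loop dynamics, no anharmonicity, no
force-field dependence.  Passing recovery tests therefore demonstrates
correctness of the machinery, not accuracy of any particular MD ensemble.

Synthetic RDC sets are generated by the package's own forward model plus
Gaussian noise, with the generating tensor (default magnitude ~8×10⁻⁴,
weak-alignment scale giving couplings of a few Hz to tens of Hz) carried
as truth metadata.  The zero-noise round trip is exact by construction
and serves as the oracle for the SVD solver; noisy replicates measure
estimator spread, not experimental realism.

Crystal *stand-ins* place the eight descriptor atoms of a 101-residue toy
fold (numbered 3–103) at prescribed pairwise distances.  They exist
because deposited coordinates are not bundled with the package; they
validate the read → select → measure chain, and only the four descriptor
distances are meaningful geometry.  Stand-in files are labelled
`synthetic_standin` wherever written.

The ten-entry survey fixture plants known defects (a 7-residue loop, an
inserted loop residue, two missing backbone atoms) in jittered, rigidly
moved copies of the toy fold, so inclusion counts and exclusion reasons
have an exact construction-time truth.

## Problem sizes

Default analysis sizes — 200-frame classification ensembles, 10-frame ×
~300-record RDC fits with 50 noise replicates, 10⁴-frame RMSF
calibration, 20-frame clustering oracles — were chosen so each check is
statistically meaningful while the whole suite and the acceptance script
run in well under a minute each; all scale linearly if enlarged.

## Known limitations

* PDB format only (mmCIF would be a thin adapter); binary trajectory
  formats are out of scope — export trajectories as multi-model PDB.
* The survey does not generate biological assemblies (no BIOMT
  expansion) and takes its entry list as input; no PROSITE scanning.
* One alignment tensor per fit; no steric/electrostatic alignment
  prediction from molecular shape.
* The SS-weighted aligner is a compatible reimplementation of
  structure-aware matching, not a clone of any specific tool.
* State boundaries beyond the default (0, 0) midpoint rule, and the atom
  content of the reference mode (Cα vs full backbone), are configuration
  choices exposed to the caller rather than fixed constants.
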