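# Methods

## Scope and model

The package implements the selection core of consensus protein–protein
docking for rigid two-protomer complexes: E engines each contribute a
ranked list of poses of one ligand protomer against one receptor
protomer; the pooled top-k poses are clustered on pairwise heavy-atom
RMSD; the cluster count is chosen at the Kelley penalty minimum; the
most populated cluster's medoid is the final model; its 5 Å interface
is mapped and alanine-scanned.  All structures are reduced to heavy
atoms of standard amino acids at read time — hydrogens, waters, HETATM
records and modified residues never enter the model, because every
downstream quantity (RMSD, contacts, the contact potential) is defined
on a shared heavy-atom topology.

## Structure I/O

PDB parsing and writing go through biotite.  Alternate locations are
resolved to the highest-occupancy conformer (tie → first in file
order), matching common preparation defaults.  Author residue
numbering and insertion codes are preserved so that reported residues
read as deposited.  Coordinates round-trip at the PDB fixed-format
precision of three decimals (stored as float32 by the parser, so
round-trip agreement is ~1e-6 Å, well below any quantity of interest).
mmCIF is not supported.

## Pose RMSD

Docking engines emit poses in unrelated coordinate frames, so a
frame-independent dissimilarity is required.  For each pair, the pose
with the lexicographically larger id is superposed by its receptor
heavy atoms onto the other's (Kabsch via SVD of the 3×3
cross-covariance; the smallest singular direction is sign-corrected so
a reflection is never returned; near-collinear point sets raise an
explicit degeneracy error).  The RMSD is then taken over all heavy
atoms (default) or the ligand only.  With the full-complex choice the
receptor contributes ≈ 0 after superposition, scaling all distances by
√(n_lig/n_total) relative to ligand-only RMSD — a uniform factor that
leaves the clustering invariant.  Fixing the target by pose-id order
makes the matrix symmetric by construction; superposition-based RMSD
is not guaranteed to satisfy the triangle inequality, and the
clustering consumes it as a plain dissimilarity.

## Cluster-number selection (Kelley penalty)

At each dendrogram level with k clusters, the spread of a cluster with
≥ 2 members is its mean within-cluster pairwise dissimilarity;
av_spread(k) is the unweighted mean over such clusters (0 if all
clusters are singletons).  av_spread is computed at every level
k ∈ {1..N−1} and rescaled linearly onto [1, N−1] — one unit per level,
which makes the normalised spread commensurate with the +k term:

    penalty(k) = norm_spread(k) + k

The selected cluster count is the penalty argmin over the non-trivial
levels k ≥ 2 (ties → smallest k).  The k = 1 level (all poses in one
cluster) always carries the maximum spread, so it is never selected,
but its inclusion in the rescaling is essential: it is the only level
whose spread contains the *between*-cluster distances of a two-cluster
structure.  If the rescaling were computed over k ≥ 2 only, the k = 2
level would itself sit at the top of the normalised scale and a
genuine two-mode ensemble could never be selected — a property we
verified empirically (0/20 recovery under every noise level tried)
before fixing the level range.  When every level has equal spread
(e.g. an all-zero matrix) the rescaling is degenerate; norm_spread is
defined as 1 everywhere and selection falls to k = 2.  The
normalisation floor is config-exposed (`kelley_norm_min`).

Operating envelope.  The penalty balances the normalised spread decay
against +1 per extra cluster, so its selection degrades when
within-mode spread keeps decaying appreciably past the true k —
exactly what happens for Gaussian-noise modes in large ensembles,
where splitting off noise outliers keeps reducing the average spread.
In practice: with 70 poses and ~1 Å translational noise against 12 Å
mode separation the argmin systematically overshoots the planted mode
count even though the partition at the true k is perfectly pure; with
35 poses and a separation/noise ratio ≳ 40 recovery exceeds 90%.  The
recovery suite therefore probes the tight-noise regime (below), and
users should read the selected k as an upper bound on well-resolved
structure, inspecting the penalty plot rather than trusting the argmin
blindly — the standard advice for this criterion.

## Final model

"Nearest to the centroid" is realised as the squared-dissimilarity
medoid: the member of the most populated cluster minimising the mean
of squared RMSDs to its cluster mates.  No coordinate-space mean of
poses is defined, and the medoid is the standard surrogate.  All ties
break deterministically: smallest k, then largest cluster → smaller
mean spread → smallest member pose id, then smallest pose id for the
medoid, so identical inputs always yield byte-identical outputs.

## Interface mapping

A receptor/ligand residue pair is a contact iff the minimum over their
heavy-atom pairs of the Euclidean distance is ≤ the cutoff (default
5.0 Å, inclusive).  The production path prunes candidates with a k-d
tree; tests pin exact agreement with an all-pairs scan.  The criterion
is atom–atom, not residue-centroid; both the cutoff and the atom
selection are config-exposed.

## Alanine scanning

Mutation is side-chain truncation past Cβ with no repacking or
minimisation (rigid scanning): backbone and Cβ coordinates are
untouched and the residue is renamed ALA.  GLY targets are logged
no-ops; PRO is truncated like any other residue, ignoring the
backbone–ring coupling, and flagged as geometrically approximate.

The binding score is a 12-6 contact potential over inter-chain
heavy-atom pairs within 10 Å:

    E = Σ 4 ε₀ [(σᵢⱼ/r)¹² − (σᵢⱼ/r)⁶],   σᵢⱼ = (rᵢ + rⱼ)·2^(−1/6)

with element van der Waals radii C 1.70, N 1.55, O 1.52, S 1.80 Å
(default 1.70) and well depth ε₀ = 0.2 (arbitrary energy units), so
each pair's minimum −ε₀ sits exactly at contact distance rᵢ + rⱼ.
This is a deliberately simple, fully specified shape/contact score —
no charges, no solvation, no entropy — chosen so that every number the
package emits is reproducible from the formula above.  Rankings are
contact-driven and should not be compared with MM-GBSA magnitudes.

Δaffinity = E(mutant complex) − E(wild-type complex); positive means
the mutant binds more weakly.  The scan set is exactly the interface
residues at the 5 Å cutoff — a residue outside the interface is never
scanned even if its side chain falls inside the 10 Å energy cutoff.
For this pairwise energy, double mutants are exactly additive whenever
the two truncated side chains share no inter-chain atom pair; the test
suite pins this.  Snapshot averaging over trajectory frames is an
unweighted mean of per-frame values (scan set = union of per-frame
interfaces), mirroring flat 100-snapshot end-point averaging; frames
are subsampled at t = interval, 2·interval, … ≤ duration with
nearest-frame matching (tolerance interval/2, t = 0 excluded).

## Synthetic data generator

`make_toy_complex` builds two clash-free polyalanine-like helices
(N/CA/C/O/Cβ heavy atoms; coarse α-helix geometry: 1.5 Å rise, 100°
twist, 2.3 Å radius) and slides the ligand to the tightest
non-clashing contact placement (≥ 3 inter-chain residue pairs within
5 Å, minimum atom distance ≥ 3 Å).  `make_sidechain_complex` extends a
deterministic 40% of residues into lysine-like pseudo side chains
(1.4 Å steps toward the partner, stopping 3 Å short of it) so that
truncation removes real attractive contacts and scans carry signal.

`generate_ensemble` plants M binding modes: mode 0 is the input
contact placement; modes 1..M−1 are random re-orientations displaced
along the receptor→ligand direction at multiples of `mode_separation`,
so all pairwise mode-centroid distances meet the separation by
construction.  Per-pose noise is a rotation of |N(0, rot_sigma)|
degrees about a uniform random axis through the ligand centroid (so
rot_sigma has an interpretable Å-scale effect ≈ radius·angle) plus an
isotropic N(0, trans_sigma) translation; the mode of each pose is a
categorical draw from `mode_weights`.  Engines are i.i.d. — no
per-engine bias — and ranks are generation order, mirroring a pooling
step that treats engines symmetrically and ignores their scores.  One
seeded generator drives everything; identical (spec, complex) give
bitwise-identical ensembles.

Defaults (the pipeline's study conditions): 7 engines × 10 poses,
M = 3 modes with weights (0.5, 0.3, 0.2), trans_sigma = 1.0 Å,
rot_sigma = 8°, mode_separation = 12 Å (safely above the 6·trans_sigma
resolvability floor).  These emulate a realistically noisy
multi-engine ensemble whose clusters are clean but whose noise is not
token.

What the generator does *not* emulate: engine-specific decoy
statistics or scoring biases, receptor flexibility, binding-mode
overlap, or near-degenerate modes.  Passing tests therefore show that
the selection machinery recovers structure that is genuinely present
in an ensemble; they say nothing about how often real engines place
the native pose in the densest cluster.

## Recovery suite conditions

The planted-mode recovery study (tests and
`analysis/04_mode_recovery.py`) uses 7 engines × 5 poses (N = 35),
mode_separation = 20 Å, trans_sigma = 0.3 Å (ratio 67), rot_sigma =
0.5°, and dominant-heaviest-mode weights (0.7, 0.3) / (0.65, 0.2,
0.15) / (0.6, 0.18, 0.12, 0.1), 20 replicates per M ∈ {2, 3, 4}.  The
scaled-down ensemble keeps the suite fast and stays inside the
penalty's operating envelope (see above); the dominant heaviest weight
keeps multinomial sampling flips (the heaviest-*weight* mode failing
to be the most-*sampled* mode, ~9% at N = 35 for a 0.5-vs-0.3 gap)
from masking what the check targets — the selection machinery, not
sampling luck.

## Numerical choices

- Average linkage by default (single/complete/ward selectable);
  `cut_tree` yields exactly k clusters at every level.
- Kabsch degeneracy: second singular value ≤ 1e-8 × the largest →
  error; rotation invariants checked at 1e-8.
- RMSD matrix symmetry enforced by construction and validated at 1e-9;
  medoid ties at ≤ 1e-12 resolve to the smallest pose id.
- Inter-atom pairs closer than 0.5 Å log a warning but are still
  evaluated (the 12-6 form diverges smoothly; no clamping).
- CSV artefacts are written with fixed float formats so identical runs
  are byte-identical.

## Known limitations

- The contact potential ranks by packing only; polar hot spots driven
  by electrostatics or solvation will be under-called.
- Rigid truncation ignores relaxation; real ΔΔG of mutation includes
  repacking, which always makes the true loss smaller than the rigid
  estimate.
- PRO→ALA is geometrically inconsistent (flagged per-residue).
- Kelley selection over-splits large noisy ensembles (see operating
  envelope); inspect the penalty plot.
- The RMSD is not symmetry-corrected; homodimeric ligands would need
  chain-swap handling the package does not provide.
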