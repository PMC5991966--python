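# Methods

## Ensemble model

The object of study is a set of crystallographic chains of one protein
(here: human Rab11a/Rab11b, with H-Ras and Rab1 as comparators), treated as
samples from its conformational distribution. Each chain is reduced to the
Cα atoms of the residues resolved in *every* member (the common residue
frame, in author numbering), giving an `n × 3m` coordinate matrix. All
analyses assume rigid-body differences have been removed first; nothing
downstream (RMSF, RMSD, DCCM, embeddings) is meaningful on unsuperposed
coordinates, so the pipeline always superposes before measuring.

Crystal structures are not a time series: correlations measured on this
ensemble reflect covariation across deposited states (different nucleotide
states, different bound effectors, different crystal forms), not dynamics
along a trajectory. That is the intended reading — regions that covary
across crystal forms are candidates for conformational coupling.

## Invariant-core superposition

Superposing on all residues lets flexible regions drag the fit. The core
finder instead iterates: superpose all members on the current core (member
0 first, then one refinement pass onto the ensemble mean), compute each
residue's positional scatter ellipsoid (eigendecomposition of its 3×3
positional covariance; the "volume" is the product of the semi-axes, in
Å³), drop the worst residue, repeat. Iteration stops when the largest
remaining volume is ≤ `v_stop` or the core has shrunk to `floor` residues.

Defaults: `v_stop = 1.0 Å³` (scatter of ≈1 Å in each direction — about the
coordinate uncertainty of a moderately flexible surface residue) and
`floor = max(30, 0.4·m)` (a rigid fit needs a broad base; below ~30 residues
the fit becomes sensitive to individual atoms). Both are configurable; no
published convention fixes them, so they are package defaults, not imported
constants.

Superposition itself is the Kabsch SVD solution with a determinant
correction (reflections are never returned). Subsets with fewer than three
points, or whose cross-covariance is rank-deficient (collinear/coincident
points), are rejected.

## Flexibility, deviation, correlation

* RMSF_i = √⟨|r_i − ⟨r_i⟩|²⟩ over members, per residue (Å).
* Pairwise RMSD matrices are computed over any residue subset *after the
  shared superposition* — pairs are not re-fitted, so the matrices of
  different regions are comparable.
* DCCM: C_ij = ⟨Δr_i·Δr_j⟩ / √(⟨|Δr_i|²⟩⟨|Δr_j|²⟩) with displacements about
  the ensemble mean. Residues whose variance is numerically zero (possible
  in synthetic data) are flagged and their rows reported as 0 rather than
  NaN, so rigid fixtures do not abort runs.

## Embeddings and representative selection

* **PCA** by SVD of the column-centered matrix. Variance fractions are
  eigenvalues over total variance; the rank is at most n−1 and requesting
  more components is an error, not a silent truncation.
* **FastICA** (scikit-learn): deflationary fixed-point iteration with the
  log-cosh contrast after PCA whitening; tol 1e-6, max 200 iterations, seed
  mandatory. Non-convergence (e.g. on near-Gaussian inputs, which have no
  preferred independent directions) yields a flagged result, not an
  exception.
* **LLE**: per-sample barycentric reconstruction weights over k nearest
  neighbors (local Gram matrix regularized by `trace · 1e-3`, keeping the
  solve well-posed when k exceeds the local intrinsic rank), then the
  bottom non-trivial eigenvectors of (I−W)ᵀ(I−W). A disconnected k-NN
  graph is an error naming the component count — the bottom eigenvectors of
  a disconnected graph encode membership, not geometry. The neighborhood
  size is chosen from a candidate list by maximizing the Pearson
  correlation between original and embedded pairwise distance matrices
  (ties to the smaller k). This distance-preservation criterion is this
  package's documented choice for k selection; other heuristics exist and
  the candidate list is user-supplied.
* All component signs are fixed (largest-magnitude loading positive) so
  repeated runs write identical files.

Representatives are *clustroids*: after average-linkage hierarchical
clustering (linkage configurable; cut level k is an analysis choice, not
auto-selected), each cluster's representative is the member minimizing
summed within-cluster distance, with ties to the lowest index.

## Residue interaction networks

Nodes are residues; an edge joins Cα pairs within 7.0 Å, weighted by the
Euclidean distance (Å, rounded to 3 decimals so serialized networks
round-trip exactly). Betweenness centrality uses weighted shortest paths,
normalized by (N−1)(N−2)/2. Shortest paths between residue sets are
weighted-minimal; ties are broken by fewer nodes, then lexicographic node
sequence — the tie-break is arbitrary but deterministic, which regression
tests require. Nucleotide-contact residues are those with any heavy atom
within 4.0 Å of a bound nucleotide (GDP/GTP/GNP/GSP). The center of mass is
mass-weighted over all heavy atoms of the polypeptide (ligands excluded);
on Cα-only inputs it degrades to a Cα-weighted center, which for a globular
domain sits within ~1 Å of the all-atom value.

## Interaction profiling and re-scoring

Crystal structures carry no hydrogens, so the profiler is distance-only
(no angle terms): hydrogen bond = protein N/O to ligand N/O ≤ 3.5 Å (per
atom pair); hydrophobic = apolar side-chain carbon to ligand carbon
≤ 4.0 Å (per atom pair); salt bridge = opposite charged-group centers
≤ 5.5 Å (Lys NZ / Arg CZ cations, Asp/Glu carboxylate midpoints; on the
ligand side, carboxylate-like C(O,O) groups and nitrogen atoms); π-cation =
ligand nitrogen to Phe/Tyr/Trp/His ring centroid ≤ 6.0 Å. These are the
widely used geometric defaults. Ligand protonation states and aromaticity
are not perceived (poses arrive as bare HETATM blocks), so ligand cations
are approximated by nitrogens and ligand rings are not used — a known
limitation that only narrows, never inflates, the π-cation count.

Re-scoring: within one hit list, ê = min–max-normalized (−energy) and
î = min–max-normalized interaction count; score = 0.8·ê + 0.2·î. A constant
column normalizes to 1.0 (a single record scores 1.0). The weights encode
that the docking energy is the primary signal and the contact count a
tiebreaker-scale correction; min–max normalization is this package's
choice, since the two quantities have incommensurate units. Ranking is by
descending score, ties by lower energy, then ligand id.

Site assignment counts site-residue heavy atoms within 4.5 Å of any pose
atom; the larger count wins, ties go to site 1 (the site nearer the
nucleotide pocket), no contacts at all is "unassigned".

Lipinski's rule of five: violations counted against donors ≤ 5,
acceptors ≤ 10, mass < 500 g/mol, logP ≤ 5; pass = at most one violation
(the conventional reading). Descriptors are inputs — nothing is computed
from chemical structure.

## Sequence conservation

Needleman–Wunsch global alignment with BLOSUM62, gap open −10, extend −0.5
(the first gap column costs the open penalty, later ones the extend
penalty). Percent identity = identical columns / mutually non-gap columns.
Site identity restricts to the alignment columns of a residue subset of
sequence A under the same denominator rule, so the subset of *all*
positions reproduces the full-sequence identity. Published identity values
computed with other aligners (different gap handling, different
denominators) are reproduced to within a few percentage points, not
exactly; the reproduction tests carry ±3-point tolerances for this reason.

## Synthetic data: what it does and does not emulate

Generators are deterministic per seed and return their ground truth.

* `make_chain`: self-avoiding Cα walk, 3.8 Å virtual bonds, 3.0 Å clash
  floor, plus minimal N/C/O/CB dummy atoms. It reproduces chain-like
  geometry, not secondary structure or packing.
* `make_ensemble`: members = base chain + planted cluster displacement +
  planted mode contributions + isotropic noise, then a random rigid
  placement per member — so no test can accidentally bypass superposition.
  Default study conditions mirror the crystallographic use case: 27
  members, noise σ = 0.5 Å per coordinate, cluster displacements 10× the
  noise confined to the C-terminal 40% of the chain (leaving a rigid core).
* `make_correlated_ensemble`: residue displacements along one common
  direction with scalar amplitudes drawn from a multivariate normal whose
  correlation matrix carries the planted ρ values (semi-definite factor, so
  |ρ| = 1 works). Output is already superposed.
* `make_complex_fixture`: motifs placed 25 Å apart, each realizing exactly
  one planted interaction at a planted distance (including a
  just-over-cutoff salt-bridge variant).
* `make_screen_table`: uniform energies/counts with the ground-truth
  ranking recomputed by the direct formula.

Passing on these fixtures shows the machinery is correct (recovery of
planted structure, agreement with brute-force oracles). It does not show
that real crystallographic ensembles satisfy the planted-model assumptions
— real ensembles have anisotropic, sequence-dependent flexibility,
correlated noise from shared refinement software, and cluster structure
confounded with crystal contacts. Conclusions about a real protein should
rest on the reproduction suite run against cached reference structures.

## Numerical and policy choices

* Alternate locations: highest occupancy wins, ties to the lowest altloc
  letter ('A'). Waters dropped; residues with insertion codes dropped (and
  logged); selenomethionine read as methionine for sequence purposes;
  amino acids lacking a Cα dropped.
* Ensemble chain lists, region ranges and site residue sets are
  configuration with Rab11 defaults.
* Superposition reference: member 0, then one refinement pass onto the
  mean — deterministic, order-dependent only through member 0.
* Degenerate inputs fail loudly (empty frames, empty regions, non-PD
  correlation specs, k ≥ n neighborhoods) rather than returning partial
  results; the two deliberate exceptions are FastICA non-convergence and
  zero-fluctuation DCCM residues, both flagged instead.

## Limitations

* Cα-only network and ensemble geometry; no side-chain contact networks.
* Pairwise sequence comparison only; no multiple alignment.
* The profiler's distance-only rules overcount hydrogen bonds relative to
  profilers that check geometry with explicit hydrogens, and undercount
  π interactions (no ligand ring perception).
* Docking engines are out of scope: score tables are inputs, and only the
  re-scoring layer is implemented.
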