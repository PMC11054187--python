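# Methods

This note documents the models, conventions and numerical choices behind
`mdbind`, and what the synthetic benchmarks do and do not demonstrate.

## Contact-map featurization and classification

A frame of an ensemble becomes an N × N binary residue contact matrix:
M[i][j] = 1 iff the selected atoms of residues i and j are within the cutoff,
**inclusive** (default 4.5 Å between Cα atoms; a `closest-heavy` rule using
the minimum heavy-atom distance is also available — a Cα–Cα cutoff of 4.5 Å
is unusually tight, since consecutive Cα sit at 3.8 Å, so which rule suits a
given protein is the user's call; the Cα rule is the default).  Matrices map
one-to-one to grayscale images with contact = 1.0 and background = 0.0; the
encoding is binary rather than distance-graded because nothing downstream
needs sub-cutoff resolution.

The classifier is deliberately small: two convolutional layers with 1 × 1
kernels (16 then 32 filters), each followed by 2 × 2 max-pooling and ReLU,
then fully connected layers of 512 and 128 units with dropout 0.5 each, and a
K-way softmax.  With 1 × 1 kernels each convolution is a per-pixel linear
map, so the whole network is written in NumPy with explicit forward and
backward passes.  That choice is load-bearing: training and the
vanilla-gradient attribution share one exact gradient implementation, checked
against central finite differences in the tests.  Flattening after the two
pools gives ⌊N/2⌋ then ⌊⌊N/2⌋/2⌋ per side — 26·26·32 = 21 632 inputs to the
first dense layer for N = 104 and 25·25·32 = 20 000 for N = 102.

Training: Adam (lr 1e-3), batch size 64, cross-entropy, stratified 80/20
train/validation split per class, up to 30 epochs with optional early
stopping on validation accuracy (default 0.99 in the pipeline; the epoch
budget is an upper bound).  All randomness (split, initialization, shuffling,
dropout) flows from explicit seeds; runs are deterministic given the seed and
single-threaded BLAS, though not bit-exact across platforms.

## Saliency and domain aggregation

Attribution is the vanilla gradient of the **pre-softmax** class score with
respect to each input pixel, taken in absolute value and symmetrized as
(M + Mᵀ)/2 since contact matrices are symmetric.  The raw map is masked by
the contact map of the most populated structural cluster — frames are
clustered by average-linkage on pairwise best-fit Cα RMSD, cut at 2.0 Å, and
the largest cluster's medoid (minimum summed within-cluster RMSD, ties to the
lower frame index) supplies the representative map.  For tractability the
pairwise RMSD matrix is computed on an evenly strided subset of at most 200
frames.  Masking matters: the gradient of class k is also large (with
opposite sign) at pixels characteristic of *other* classes, and the
representative mask removes exactly those.  Masked attributions are summed
over upper-triangle blocks of structural-domain pairs (domain annotation is a
user input; residues outside every domain pool under `unassigned`), so when
the domains tile the sequence the table total equals the total masked
attribution.

## PCA and free-energy landscapes

The covariance of superposed Cα coordinates is normalized by the number of
frames F (a population average, not F − 1); the SVD oracle in the tests uses
the same convention.  Frames are superposed to their iteratively refined mean
structure (2 rounds) before the covariance is formed, so rigid tumbling does
not masquerade as internal motion.  Eigenvalues are reported as percentage
variance fractions; per-residue magnitudes of an eigenvector give the
porcupine-style displacement pattern.

Projections onto PC1/PC2 are histogrammed (100 × 100 bins by default; the
pipeline uses 60 for its smaller synthetic ensembles) and Boltzmann-inverted:
G = −k_BT ln(P/P_max) with k_B = 0.0019872 kcal mol⁻¹ K⁻¹ and T = 300 K by
default, so the populated minimum is exactly 0; empty bins carry a sentinel
of G_max + 1.  Basin detection floods populated bins in order of increasing
G; a bin with no assigned neighbor seeds a basin, and a bin bridging two
basins merges them when the barrier above the shallower minimum is under the
depth threshold (0.5 kcal/mol default, ties broken by bin index).  Counts are
pre-smoothed with a 3 × 3 box filter and bins below a minimum (smoothed)
occupancy of 2 are ignored — without this, Poisson fluctuations in sparsely
sampled bins each masquerade as a basin.  Each basin's representative frame
is the one nearest its minimum-bin center in PC space.

## Structural metrics

Superposition is the Kabsch least-squares fit (via rotation alignment in
SciPy).  RMSD series are per-frame best fits to a reference on a named
selection; RMSF uses the iterative-mean reference (2 rounds) matching common
trajectory-tool practice, since the choice is otherwise under-determined.
The radius of gyration is mass-weighted (unit masses when no masses are
supplied).  Surface area is the solvent-accessible area by Shrake–Rupley
sampling — 960 quasi-uniform (golden-spiral) points per atom, probe 1.4 Å —
implemented in-package because the energetics stage needs per-atom areas
under user-supplied radii and attributes per-atom differences to residues;
it is cross-checked against an independent implementation in the tests.
"Molecular surface area" throughout means SASA, not the solvent-excluded
surface.

Hydrogen bonds use the geometric criterion: donor···acceptor distance
**strictly** < 3.5 Å and donor–H···acceptor angle (at the hydrogen)
**strictly** > 120°; occupancy is 100 × (frames present)/F, and mean
distance/angle are computed over present frames only.

Frequency distributions are 50-bin histograms; peaks are plateaus of the
3-bin moving average strictly above both flanks, reported at the plateau's
lowest occupied bin (ties resolve toward the lower value).

## Binding free-energy bookkeeping

ΔG_bind = ΔH − TΔS with ΔH = ΔE_ele + ΔE_vdW + ΔG_gb + ΔG_surf, split into a
polar half ΔG_pol = ΔE_ele + ΔG_gb and a hydrophobic half
ΔG_hydro = ΔE_vdW + ΔG_surf.  All deltas follow the single-trajectory
convention — receptor and ligand coordinates are extracted from the complex
frame — so the intra-molecular molecular-mechanics terms cancel identically
and ΔE_ele/ΔE_vdW reduce to receptor–ligand cross sums (asserted to 1e-9 in
the tests).  Coulomb uses k_e = 332.0636 kcal Å mol⁻¹ e⁻², no cutoff;
Lennard-Jones is 12-6 with Lorentz–Berthelot combining.

The polar solvation term is the pairwise Still-form generalized Born model
with user-supplied effective Born radii, including self terms
(f_GB = α at r = 0), which preserves the Born-ion limit and the pairwise
decomposability the per-residue analysis requires; no self-consistent radius
calculation is performed, and OBC-style radii would be a drop-in extension.
Defaults: ε_in = 1, ε_solv = 78.5, no salt screening.  The nonpolar term is
γ·ΔSASA + β with γ = 0.0072 kcal mol⁻¹ Å⁻² and β = 0.

Per-residue decomposition assigns each receptor residue its full Coulomb and
LJ cross terms with the ligand, half of each pairwise GB cross term (the
other half belongs to the ligand), and γ times its atoms' SASA change on
binding; gas-phase shares therefore sum exactly to the complex-level
ΔE_ele + ΔE_vdW.  A residue is *key* when its total is ≤ −0.8 kcal/mol.

The entropy term is pluggable.  `supplied` takes an external −TΔS (used to
reproduce published table arithmetic); `quasiharmonic-schlitter` computes the
Schlitter upper bound S ≤ (k_B/2) ln det(1 + (k_BTe²/ħ²) M^{1/2} C M^{1/2})
from the mass-weighted coordinate covariance, with non-negative eigenvalue
flooring for degenerate covariances.  Normal-mode entropy is out of scope.
Ensemble averages default to an evenly strided subset of frames (400 in the
published setting; the pipeline's toy complex uses 20).

Experimental affinities convert via ΔG = RT ln(IC50) (IC50 in mol/L),
treating the IC50 as a dissociation constant — 10 nM at 300 K gives
−10.98 kcal/mol.

## The synthetic generator

References are self-avoiding Cα chains: starting from a jittered extended
chain (so all non-neighbor pairs begin far apart), an L-BFGS relaxation of a
penalty energy enforces 3.8 Å virtual bonds, pulls each planted pair to
≤ 3.5 Å, and repels every other non-neighbor pair beyond 5.6 Å; hard
verification (planted ≤ 4.0 Å, background > 5.5 Å, bonds within 0.15 Å)
triggers bounded retries and an error when the requested contacts are
geometrically infeasible.  The 3.5 Å planted depth leaves a ≈ 2.4σ margin to
the 4.5 Å cutoff under the default 0.3 Å per-coordinate Gaussian noise, so
planted contacts survive noise about as robustly as the chain-neighbor
contacts do.  Frames are i.i.d. Gaussian displacements about the class
reference: no kinetics, no correlated motion.  The standard benchmark is 3
classes × 300 frames on a 40-residue chain with one unique planted contact
per class bridging distinct non-adjacent domain pairs of a 4-domain tiling.

The toy ligand–receptor complex is a folded 30-bead receptor chain with a
6-bead ligand docked perpendicular to the local chain tangent, one planted
salt bridge (±0.8 e at ~4 Å), and uniform LJ/Born parameters chosen so the
interaction components are O(1–100) kcal/mol.

What passing these benchmarks shows: the pipeline recovers planted
discriminative structure through every stage (featurization, training,
attribution, aggregation) and reproduces all closed-form and published
arithmetic.  What it does not show: performance on real MD ensembles, whose
contact fluctuations are correlated, whose classes overlap, and whose
energetics involve real force fields — the published validation accuracies
for BRD4/BRD9 (88.47%/87.20%) belong to that setting and are not reproduced
here.

## Problem sizes and defaults

The shipped benchmark sizes (40 residues, 300 frames/class, ≤ 30 epochs with
early stopping, 200-frame cap in the RMSD clustering, 20-frame toy-complex
averages) are chosen so a full synthetic pipeline runs in seconds to minutes
on one CPU while every statistical check retains comfortable margins; all are
configuration parameters, and the 104/102-residue, 120 000-image published
setting is reachable by configuration alone.
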