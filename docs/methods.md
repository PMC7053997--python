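# Methods

This note documents the models, conventions and numerical choices behind
`gpcrdyn`, and what the synthetic-data pipeline does and does not establish.

## Generic residue numbering

Labels are assigned per alignment column relative to a per-segment anchor
column (the x.50 position: the most conserved residue of each TM helix, the
conserved Trp for EL1, the disulfide-bonded Cys for EL2). The label index at
a column is 50 plus the signed count of occupied columns (columns that are
non-gap in at least one sequence) between it and the anchor. Consequences:

* receptors with deletions inside a segment skip indices — generic labels of
  shorter sequences need not be consecutive;
* a column that is a gap in *every* sequence carries no index, so inserting
  an all-gap column never shifts labels;
* an anchor falling on a gap for some receptor is a data error, not
  silently repaired.

Segment windows (which columns belong to EL1/EL2/TMn) are part of the
alignment annotation, never inferred. The shipped D2R/D3R loop alignment is
a *reconstructed* stand-in (marked `synthetic` in its filenames): it places
the documented anchor residues (D2R Trp100/Cys182, D3R Trp96/Cys181)
correctly but uses placeholder residue identities away from the anchors.
An `AlignmentBlock` may carry per-sequence start offsets so a block can
cover just a loop window of a full-length receptor.

## Geometry

Coordinates are Å; frame times derive from a constant frame interval in ns.
Dihedrals are signed IUPAC torsions in degrees on (−180, 180] (−180 is
mapped to +180). Centers of mass are weighted by standard atomic masses by
default; an unweighted centroid is available (`weights="geometric"`).

Kabsch superposition uses the SVD of the 3×3 cross-covariance with the
determinant correction that forces a proper rotation (det +1). Fewer than
three atoms, or a centered configuration of rank < 2, is rejected as
degenerate. The pairwise-RMSD matrix performs an *independent optimal
superposition for every frame pair* on the same atom selection used for the
RMSD — there is no common reference frame — and is computed with batched
3×3 SVDs, so thousands of frames remain tractable. Note the minimal-RMSD
value is obtained from the Gram-term identity
msd = (Σ|a|² + Σ|b|² − 2Σσ)/n; for truly identical frames this cancels to
zero only to ~1e−7 Å in double precision, which is the accuracy floor of
exact-zero RMSDs.

Multi-model PDB I/O goes through biotite; models with inconsistent atom
counts raise a format error. Coordinates round-trip at PDB precision
(0.001 Å).

## State classification

* **EL2 helical/extended**: the classifier thresholds the heavy-atom
  distance between the Ile183 backbone carbonyl O and the Asn186 backbone N
  at 4 Å (helical below). This proxies the i→i+3 hydrogen bond that holds
  the loop's C-terminal turn; no hydrogens are placed and no DSSP-style
  assignment is attempted. The heavy-atom N–O reading is consistent with a
  4 Å cut (an H–O criterion would sit nearer 2.5 Å).
* **Rotamers**: gauche− is (−120°, 0°), gauche+ is [0°, 120°), trans is the
  rest; each boundary belongs to exactly one bin (−120° and 120° are trans,
  0° is gauche+).
* **Ile3.40 sub-pocket occupancy**: a ligand probe atom is `occupied` when
  within 4.5 Å of the unweighted centroid of the three Cα atoms of residues
  3.40, 5.47 and 6.44. The 4.5 Å cutoff is a convention of this
  implementation — no published numeric criterion exists for this cavity —
  and is recorded in every result manifest.

## Two-state Markov state model

Transition counting is sliding-window by default (every (t, t+τ) pair;
strided counting by flag) and never crosses trajectory boundaries; series
shorter than the lag are skipped with a warning. For two states the
reversible maximum-likelihood estimator coincides with row normalization of
the count matrix, because every irreducible 2-state chain satisfies detailed
balance; no iterative reversible MLE is needed. Closed forms:
π_h = T_eh/(T_he+T_eh), λ₂ = 1 − T_he − T_eh, implied timescale
t = −τ/ln λ₂ (infinite when λ₂ ≥ 1, undefined in the oscillatory regime
λ₂ ≤ 0). The default analysis lag is 500 frames — 300 ns at the 0.6 ns
frame interval — where the implied timescale has plateaued for the loop
dynamics this targets; the ITS table flags the plateau via a 10% relative-
change tolerance between consecutive lags.

The Bayesian ensemble (default 500 samples) draws each row of *T* from a
Dirichlet posterior with Jeffreys-style prior (1/2 per cell). Two points
matter:

* **Effective counts.** Overlapping sliding-window pairs are strongly
  autocorrelated; using them at face value makes the posterior roughly
  √τ too narrow. Sampling therefore rescales sliding counts by 1/τ (the
  standard effective-count correction, equivalent to non-overlapping
  windows) before forming the Dirichlet parameters; the ML point estimate
  still uses the raw counts. Without this correction the 95% interval's
  coverage of the true π collapses well below nominal.
* **Sampler family.** Per-row Dirichlet is a deliberate simplification
  relative to trajectory-reweighting transition-matrix samplers; only
  summary statistics (posterior means, central intervals) are meant to be
  compared across implementations, not individual samples.

## Binding-site clustering

The protocol: (1) stratified sampling of equal frame counts per
condition × EL2-state stratum, without replacement, erroring (never
silently resampling) if a stratum is too small; (2) k-means (Lloyd, best of
`n_starts` = 20 random initializations by within-cluster sum of squares) on
the *rows of the pairwise-RMSD matrix* used as feature vectors — a
classical-MDS embedding is available behind `embedding="mds"` and recovers
the same planted structures; (3) apRMSD: arithmetic mean of all unordered
within-cluster pairs (diagonal) or all cross pairs (off-diagonal);
(4) compositions as percentages per cluster, normalized separately by
condition and by EL2 state; (5) the whole selection+clustering repeated
`n_repeats` = 20 times, clusters matched across repeats by Hungarian
assignment, then means and standard deviations of compositions reported.

Cluster matching uses the concatenated condition + EL2-state composition
profiles: condition alone is ambiguous precisely in the situation of
interest, where two clusters are pure in the same condition and differ only
in their loop-state composition. Defaults (k = 4, 20 starts, 20 repeats,
1000 frames per stratum) follow the reference protocol sizes. Centroid
frames minimize the mean RMSD to their cluster co-members, ties broken by
lowest frame id.

## Distance-difference maps

A subsegment's position is the unweighted centroid of its Cα atoms (the
residue-range reading of the subsegment definition; a minimum-residue-pair
alternative is noted but not implemented); binding-site residues enter as
single Cα atoms. Profiles are time-averaged pairwise distances over an
explicit frame window (ensembles are typically compared over the final
stretch of a trajectory, e.g. the last 600 ns); the difference map is the
element-wise difference A − B, exactly antisymmetric under argument swap and
invariant under rigid motions of either ensemble. Shipped defaults cover the
D2R extracellular subsegments (TM1e–TM7e residue ranges) and the
D2R/D3R ligand-binding residue sets (34 aligned positions each).

## Pharmacology

Saturation binding fits Y = B_max[A]/([A]+K_A) + NS·[A] *globally*: the
same NS multiplies the nonspecific dataset (NS·[A]) and the total-binding
dataset, sharing information between the two curves. Competition data fit
the four-parameter logistic in X = log₁₀ concentration; K_i follows from
Cheng–Prusoff, K_i = IC₅₀/(1+[L]/K_d). Concentrations are nM on the user
surface. Fits use trust-region least squares with data-driven starts
(Top = max response, Bottom = min, logIC₅₀ = median X, n_H = 1; K_A from
half-maximum interpolation, optimized on a log scale to keep it positive).
Confidence intervals are profile-likelihood: the bound is where the
profiled SSR crosses SSR_min·(1+F(1, n−p; 0.05)/(n−p)); with an essentially
perfect fit the interval collapses to the point estimate. pK↔K conversion
is K(nM) = 10^(9−pK); mutant/WT fold-changes are ratios of K values, so a
fold > 1 means weakened binding. TR-FRET preprocessing is
(acceptor/donor)×10,000 minus nonspecific; BRET maxima are reported as a
percentage of a reference full agonist, negative for inverse agonists.

## Synthetic data

The toy receptor (~70 heavy atoms) carries: four pseudo-Cα beads for each
TM extracellular subsegment on a 12 Å circle; a five-residue EL2 stretch
with full backbone whose Ile183(O)–Asn186(N) distance is pinned to exactly
2.9 Å (helical template) and 8.0 Å (extended template), straddling the 4 Å
threshold; a Trp-analogue sidechain whose χ1/χ2 are set exactly per frame
by Rodrigues rotations; the sub-pocket Cα triad; and a one-atom ligand
probe placed 3.5 Å from the triad centroid in the helical template and 7 Å
away in the extended one.

Switching uses the exact exponential-holding discretization: per frame the
chain leaves its state with probability 1 − exp(−kΔt), so the rates are
recoverable at any frame interval. Default conditions are the reference
study settings: (k_he, k_eh) = (0.01, 0.03)/ns (stationary helical
probability 0.75), Δt = 0.6 ns, 50,000 frames, isotropic Gaussian
coordinate noise of 0.3 Å, χ1 means −65° (helical) / 178° (extended) with
von Mises κ = 50. All randomness flows from one seed through named
substreams (state path / noise / rotamers). Assay datasets are exact model
curves plus Gaussian noise, with each concentration run in triplicate by
default, mirroring assay practice.

What the generator does *not* emulate: force-field energetics, solvent and
membrane, anisotropic or correlated fluctuations, state-dependent
binding-site changes beyond the planted templates, and kinetic (multi-step)
unwinding pathways. Passing tests therefore demonstrate that the
*estimators* are correct and well calibrated under the assumed statistical
structure — not that real trajectories satisfy that structure. One
practical consequence: 0.3 Å isotropic noise on ~1.5 Å bond vectors blurs
measured dihedrals by tens of degrees, so rotamer-recovery statements are
made on the drawn (ground-truth) angles, while the torsion-setting geometry
itself is verified exactly in the noise-free case.

## Problem sizes and determinism

The test suite and the acceptance script size their simulations to run in
minutes on one CPU: MSM recovery uses 20 seeds × 50,000 frames; clustering
recovery uses a 480-frame planted pool with 20 repeated runs; fit-bias
studies use 100 replicates. Every stochastic step is seeded; fixed seeds
give bit-identical Bayesian ensembles and generator output. Known
limitations: the MSM is strictly two-state (no PCCA, no feature learning);
clustering k is fixed, not selected; no periodic-boundary imaging or binary
trajectory formats; the Bayesian sampler's intervals are approximate for
strongly correlated data beyond the 1/τ correction.
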