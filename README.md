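# gpcrdyn

Analysis toolkit for the conformational dynamics and pharmacology of
dopamine-receptor-like GPCRs. Antagonists of different chemical scaffolds can
stabilize *distinct inactive conformations* of the D2 receptor: some occupy a
small sub-pocket below the orthosteric binding site (the Ile3.40 sub-pocket),
and the C-terminal stretch of the second extracellular loop (EL2) switches
between a helical and an extended conformation. This package implements the
quantitative analyses needed to characterize those states from trajectory
data and to test them against binding experiments — for computational
structural biologists and molecular pharmacologists working on aminergic
receptors.

## What it computes

**Generic residue numbering** (`gpcrdyn.numbering`). Ballesteros–Weinstein
style labels extended to the extracellular loops: the conserved EL1 Trp is
EL1.50 and the disulfide-bonded EL2 Cys is EL2.50; labels step by one per
alignment column, so receptors with deletions skip indices.

**Geometry** (`gpcrdyn.geometry`). Multi-model PDB trajectories, distances,
signed IUPAC dihedrals, mass-weighted centers of mass, Kabsch superposition,
and batched all-against-all superposed-RMSD matrices.

**State classification** (`gpcrdyn.states`). EL2 helical/extended from the
Ile183(C=O)–Asn186(N–H) heavy-atom distance at a 4 Å threshold; χ rotamer
bins (gauche−/gauche+/trans); Ile3.40 sub-pocket occupancy of a ligand probe.

**Two-state Markov state model** (`gpcrdyn.msm`). Lagged transition counts,
the maximum-likelihood transition matrix *T*, stationary distribution
π (closed form: π_h = T_eh/(T_he+T_eh)), implied timescale
*t* = −τ/ln λ₂ with λ₂ = 1 − T_he − T_eh, and a 500-sample Bayesian
ensemble (per-row Dirichlet with Jeffreys prior, effective-count corrected
for sliding windows). Detailed balance π_i T_ij = π_j T_ji holds exactly —
every irreducible two-state chain is reversible.

**Binding-site clustering** (`gpcrdyn.cluster`). Stratified frame sampling
(equal numbers per condition × EL2 state), k-means over the rows of the
pairwise-RMSD matrix (k = 4, 20 starts), average pairwise RMSD (apRMSD)
within and between clusters, and cluster compositions averaged over 20
repeated runs with Hungarian cluster matching.

**Distance-difference maps** (`gpcrdyn.pia`). Pairwise-interaction style
comparison of two ensembles at the TM-subsegment and binding-site-residue
level; negative entries mean a pair moved closer in the first ensemble.

**Pharmacology** (`gpcrdyn.pharm`, `gpcrdyn.tables`). Saturation binding
Y = B_max[A]/([A]+K_A) + NS·[A] fitted globally to total and nonspecific
data; the four-parameter logistic competition curve
Y = Bottom + (Top−Bottom)/(1+10^((X−logIC₅₀)·n_H)); Cheng–Prusoff
K_i = IC₅₀/(1+[L]/K_d); pK↔K conversion; mutant/WT fold-changes; TR-FRET
plate preprocessing and BRET E_max normalization. Measured affinity tables
for D2R mutants ship as a worked-example dataset.

**Synthetic data** (`gpcrdyn.synth`). A toy receptor with helical/extended
EL2 templates switching as an exactly discretized continuous-time Markov
process, state-dependent rotamers, coordinate noise, and simulated assay
datasets — every analysis above is testable end-to-end without any download.

## Worked example

```python
from gpcrdyn import msm, states, synth

spec = synth.build_toy_receptor()
ds = synth.simulate_switching_trajectory(spec, synth.SimConfig(n_frames=20_000, seed=42))
series = states.classify_el2(ds.anchor_distance_series())
counts = msm.count_transitions([series], lag_frames=50, frame_interval_ns=0.6)
model = msm.estimate_msm(counts)
ens = msm.bayes_sample(counts, n_samples=500, seed=0)
```

prints (via `python examples/02_loop_state_msm.py`):

```
frames: 20000 | helical fraction: 0.768 (true stationary value: k_eh/(k_he+k_eh) = 0.75)
pi = [0.768, 0.232] | implied timescale: 20.9 ns (true relaxation time 25 ns)
Bayesian 95% CI for pi_helical: [0.709, 0.818]
```

The simulated loop switches helical→extended at 0.01/ns and back at 0.03/ns,
so the true helical occupancy is 0.75; the estimate lands within the
Bayesian interval and the implied timescale approximates the true 25 ns
relaxation time. The other `examples/` scripts cover numbering, clustering
(condition-pure clusters with mixed EL2 states), difference maps (a planted
2 Å TM6e shift appears as a −2 Å entry against TM2e), and the assay fits
(e.g. I122W weakens risperidone 13.2-fold but spiperone only 6.4-fold,
the signature of scaffold-dependent sub-pocket occupation).

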