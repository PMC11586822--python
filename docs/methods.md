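# Methods

This note documents the models, parameters and numerical choices behind
`graphbnc`, and what the synthetic study system does and does not
establish about real nanocluster–protein systems.

## Protein representation

Residues are coarse-grained to their Cα positions; two residues are
connected when their Cα atoms are within **4.5 Å** (unweighted edges).
Each node carries 39 attributes, assembled by a registry of providers in
a fixed order:

| block | dim | definition |
|---|---|---|
| heavy-atom counts N_C, N_N, N_O, N_S | 4 | counted from atom records when present, else from the standard residue composition table |
| molecular mass | 1 | sum of heavy-atom masses (u) |
| side-chain class | 5 | one-hot over hydrophobic / polar / charged-positive / charged-negative / special (CYS, SEC, GLY, PRO) |
| hydrophobicity | 5 | five published scales (Kyte–Doolittle, Hopp–Woods, Eisenberg, Janin, GES), shipped as a replaceable CSV |
| secondary structure | 8 | 8-class one-hot; internal provider assigns H/E/coil from Cα i→i+2/3/4 distances, the remaining classes are reachable through the external-annotation mode |
| rel. ASA, SASA | 2 | Shrake–Rupley with a 1.4 Å probe on heavy atoms (100 golden-spiral points per atom); rel. ASA divides by the residue's theoretical maximum |
| accessible shell | 1 | fraction of free points on spherical shells (radii 3/5/7/9 Å, 30 directions) around the Cα |
| pocketness (+5 clustered) | 6 | fraction of shell points that are free locally but blocked farther out along the same direction (an enclosed void); the five clustered variants re-evaluate at probe radii 1.5–3.5 Å |
| R_inacc | 1 | mean first-blocked shell radius per direction (larger = more open) |
| OPD chirality (5 & 7 n.n.) | 2 | Osipov–Pickup–Dunmur index over the node plus its k nearest Cα; rotation-invariant, sign flips under reflection |
| Ollivier-Ricci | 1 | per-node mean over incident edges of 1 − W₁(μ_u, μ_v), uniform neighbor measures, exact transportation LP |
| Forman-Ricci | 1 | per-node mean of 4 − deg(u) − deg(v) |
| MFD | 1 | box-counting dimension of the graph (greedy ball covering, radii 1..diameter, log–log slope), broadcast to all nodes |
| GNM | 1 | diagonal of the Laplacian pseudoinverse, min–max scaled per protein |

Burial/pocket providers and secondary structure are *internal
approximations* with the same meaning as the external programs a
production workflow would call; both can be replaced by a per-residue
annotation CSV (`chain_id, residue_id, dssp_class, rel_asa, sasa,
acc_shell, pocketness, pocketness_c1..c5, r_inacc`).

Node attributes are expanded by the continuous Weisfeiler–Lehman update
(average of self and neighbor mean, halved), concatenating the initial
attributes with every round: N_WL = 2 gives 117 entries per node.
Isolated nodes take a zero neighbor term. All features are equivariant
under residue input permutation; sequence neighbors for secondary
structure are resolved by residue numbering and the MFD ball covering is
seeded in residue-label order to keep this exact.

## Nanocluster representation

Global (9): heavy-atom fraction, Au fraction, S per ligand, and the
radius/area/volume ratios of the centroid-centred spheres enclosing the
Au subset vs the C subset (radius = max distance from the centre of
mass; only ratios enter the features), plus the sorted principal moments
of inertia normalized to sum to one. Per ligand (7, or 8 when bridge
positions occur): minimum head–head and ring-centre distances, a π–π
stacking flag (ring centres ≤ 5.0 Å and normals within 30° of
(anti)parallel — a declared, configurable criterion), mean burial of
ligand atoms and of ligand oxygens (nearest-surface gap), and the
protecting-unit position one-hot. Single-ligand clusters get a 999 Å
neighbor-distance sentinel, later confined by input min–max scaling.

A pair feature row is `[global(9); ligand(7|8); WL node(117)]` = 133 or
134 entries. Pair rows carry **no geometry of the pose**: the network
estimates the chemical affinity of a contact, and geometry enters only
through which pairs exist (≤ 10 Å head-to-Cα formation distance).

## Interaction model

Five dense networks (hidden 128/64/32, ReLU, two linear outputs for the
Coulomb and vdW channels) are trained on the five folds of a shuffled
K-fold split; the prediction is the fold mean. Inputs are min–max
scaled to [0,1] (constant features map to 0); outputs are scaled by a
symmetric max-abs factor to [−1,1] — a deliberate offset-free scaling,
since an affine offset would break the additivity of per-pair
contributions. The loss is the MAE between the *summed* per-pair
(coulomb + vdw) prediction of a configuration and its label; the
channel split is unidentifiable under this objective and an optional
auxiliary per-channel loss (off by default) restores it. Adam,
lr 10⁻³, minibatches of 32 configurations, 150-epoch cap.

Because an epoch over a desk-scale corpus contains only a handful of
minibatches, training additionally guarantees **15,000 optimiser
updates per fold** (`min_updates`); at corpus scale (≥ 3,200
configurations) the 150-epoch cap alone governs. Without this floor the
ensemble demonstrably underfits (held-out per-pair correlation 0.29 vs
0.74 on identical data).

Predicted pair energies are rescaled to interaction strengths
φ(E) = (median − E)/(median − E_min), so the strongest (most negative)
energy maps to exactly 1 and the median to exactly 0; a degenerate
all-equal table maps to 0 with a warning. φ is computed once over the
full (ligand × residue) table of a protein–cluster combination.

## Placement

Coarse-grained loss over poses (translation + rotation of the rigid
cluster):

* geometric well g(d) = θ/d⁴ − exp(−(d−d₀)²/σ) per ligand, θ = d₀⁴/3,
  with d the minimum head-to-Cα distance; d₀ = 5.0 Å (coarse), σ = 2.0 Å²;
  well depth at d₀ is 2/3.
* steric barrier Σ 1/(t_j − c)⁴ over Cα with (t_j − c) < 5.5 Å, where
  t_j is the Cα distance to the cluster centre and c the minimum
  centre-to-head distance; terms are capped at 10⁶ on penetration so
  the chain stays numerically alive.
* −k Σ φ_j over pairs within 5.5 Å; k = 1.

Metropolis acceptance P = min(1, e^(−ΔL/T)) with k_B = 1 (reduced
units). Proposals translate along a random direction (magnitude
uniform up to the translation step) and rotate about the cluster COM.
Step sizes multiply by 1.1/0.9 when the trailing 50-proposal acceptance
leaves the 40–60% band, evaluated every 10 proposals and clamped to
[10⁻³, 20 Å] and [10⁻³, π]; the fast evaluation cadence is needed for
the controller to keep up when a chain drops into a deep well late in a
run.

Runs start from Fibonacci-sphere directions with random orientations,
brought in until the closest head–Cα distance is d₀ + 2 Å (the loss
gradient is flat farther out). The sampler confines the cluster COM to
a shell of protein bounding radius + cluster radius + 5 Å: the loss
vanishes at large separation, so an unconfined chain at
migration-capable temperatures would simply evaporate. Cooling is
geometric, T = T₀·0.95^(step/100) over 5,000 steps with **T₀ = 1** in
reduced loss units — the loss's own construction pins the barrier scale
(2/3 per engaged ligand), making a fixed default system-independent; a
probe-based calibration (`Schedule(t0=None)`) exists but proved
unstable by orders of magnitude between start poses.

Final COM points of all runs are clustered (complete-linkage
agglomerative, 10 Å threshold, both configurable); sites are ranked by
membership and each site is represented by its member pose with the
lowest raw predicted total interaction energy. Refinement re-anneals
with all atoms: pair membership and well distances switch to any-atom
minima, d₀ tightens to 4.0 Å, proposals are rejected when the COM
leaves an 8 Å restraint sphere or any interatomic distance drops below
1.5 Å, and cooling runs to effectively zero temperature (the final loss
never exceeds that of the best feasible pose found).

## Synthetic study system

The generator emulates the data regime the method is built for:

* **Protein**: a self-avoiding Cα walk (3.8 Å steps, 4.0 Å excluded
  volume, mild centroid bias for globularity) with per-bead charges
  (−1/0/+1, 15% each tail) and hydrophobicities; planted patches are
  the `patch_size` spatially nearest residues around mutually separated
  surface centres, all set to +1 (named LYS/ARG so the featurizer sees
  consistent chemistry); every residue gets a pseudo-all-atom
  decoration matching its residue type's heavy-atom composition.
* **Cluster**: antipodal Fibonacci ligand axes (COM exactly at the
  origin; head centroids exactly at radius r = 8 Å), a symmetric Au
  core, an S anchor, a 6-C ring and a 3-atom carboxylate-like head per
  ligand — Au₂₅(SR)₁₈ scale, 18 ligands.
* **Oracle**: Coulomb + Lennard-Jones (ε = 0.5, σ_LJ = 4 Å) over
  head–Cα pairs in reduced units. The default kernel is a *contact*
  (square-well) model — pairs within 10 Å contribute their energy
  evaluated at a fixed effective distance of 5 Å — so configuration
  labels are exactly decomposable over the pair set the architecture
  models and per-pair energies are determined by the partner
  identities. A Debye-screened distance-weighted kernel (λ = 8 Å, the
  physiological-saline scale) is available for stress tests; with it,
  per-pair energies acquire distance variance that no pose-free feature
  set can explain (the ideal feature-conditional predictor caps at
  r ≈ 0.26), which bounds what sum-supervision can recover. Labels
  carry Gaussian noise of 5% of their standard deviation.

What passing tests show: the 39/9/7-dimensional contracts hold; sum
supervision recovers per-pair energies when pair energies are
feature-determined; the annealer finds a planted unique minimum from
64 directions and the controller holds its acceptance band; the
pipeline emits the configured number of refined, clash-free complexes
deterministically under a seed. What they do not show: accuracy on real
MD-derived labels (distance- and conformation-dependent), transfer
across cluster chemistries, or protein flexibility — the method treats
both partners as rigid.

## Numerical conventions

Coordinates in Å; residue ids 1-based, arrays 0-based. One master seed
drives every stage through spawned `SeedSequence`s; identical seed and
config give byte-identical reports and COM traces. A docked cluster's
COM necessarily sits ≈ cluster radius above the surface, so planted-site
recovery is measured from the patch centroid to the *nearest ligand
head* (threshold 8 Å). Median of an even-length energy list is the mean
of the central pair. Degenerate inputs: isolated graph nodes take zero
curvature and a halving WL update; single-ligand clusters take the
neighbor-distance sentinel; all-equal energy tables scale to φ ≡ 0.

## Problem sizes

Default study conditions: 120-residue protein, 18-ligand cluster,
200 training configurations (+50 held out), 64 annealing runs of 5,000
steps, refinement of 3 sites for 2,000 steps. The full pipeline runs in
a few minutes on one CPU.

## Known limitations

Rigid bodies only; the internal burial/secondary-structure providers
are approximations (external annotations are first-class replacements);
the Coulomb/vdW output split is unidentifiable without the auxiliary
loss; the φ rescaling is relative per protein–cluster pair, so
strengths are not comparable across systems; XYZ/PDB are the only
trajectory formats.
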