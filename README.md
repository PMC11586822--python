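# graphbnc

Prediction of interaction sites between ligand-protected metal
nanoclusters (e.g. Au₂₅(p-MBA)₁₈) and proteins, for computational
chemists and nanobiotechnology researchers who need plausible
nanocluster–protein complexes without crystal structures of the complex
or long unbiased MD.

## The method

The pipeline has four stages:

1. **Featurization.** The protein becomes a residue graph: one node per
   Cα, an (unweighted) edge whenever two Cα are within 4.5 Å. Each node
   carries 39 attributes — heavy-atom counts and mass, a five-class
   side-chain type, five hydrophobicity scales, 8-class secondary
   structure, solvent accessibility and pocket/burial measures, OPD
   chirality, Ollivier-/Forman-Ricci curvature, box-counting dimension
   and a GNM mobility proxy. Attributes are propagated with the
   continuous Weisfeiler–Lehman update

   a⁽ⁱ⁺¹⁾(v) = ½ [ a⁽ⁱ⁾(v) + (1/deg v) Σ_{u∈N(v)} w(v,u) a⁽ⁱ⁾(u) ],

   and the final node representation concatenates all rounds
   (39·(N_WL+1) entries; N_WL = 2 by default). The nanocluster gets a
   9-dim global descriptor (composition ratios, core/shell sphere
   ratios, normalized inertia) and each protecting ligand a 7(8)-dim
   local descriptor (neighbor head/ring distances, π–π stacking,
   burial, protecting-unit position).

2. **Interaction-energy estimation.** Every (ligand head, Cα) pair
   within 10 Å forms a row [global; ligand; WL node]. A five-fold
   ensemble of small dense networks (128/64/32, ReLU, Adam, MAE) maps a
   row to a (Coulomb, vdW) contribution; the training loss compares the
   *sum over a configuration's pairs* with the configuration-level
   energy label, so no per-pair supervision is ever needed. Predictions
   are rescaled so the strongest pair energy is φ = 1 and the median
   φ = 0.

3. **Placement.** Metropolis simulated annealing of the rigid cluster
   over the protein surface minimises

   L = Σ_j g(d_j) + Σ_j 1/(t_j − c)⁴ − k Σ_j φ_j,

   with g(d) = θ/d⁴ − exp(−(d−d₀)²/σ), θ = d₀⁴/3 — a contact well at
   d₀ plus a steric barrier and the learned attraction. Step sizes adapt
   to keep acceptance in the 40–60% band; many independent runs start
   from evenly distributed directions, and final centre-of-mass points
   are clustered (complete linkage) to rank candidate sites.

4. **Refinement.** The best member of each top site is re-annealed with
   all atoms, a steric floor (1.5 Å) and a restraint keeping the COM
   within 8 Å of the site.

A synthetic-complex generator (self-avoiding Cα chains with planted
charged patches, Fibonacci-sphere clusters, an exactly pair-decomposable
Coulomb + Lennard-Jones oracle) supplies training data and ground truth,
so the whole pipeline is trainable and testable at desk scale.

## Worked example

```bash
python examples/place_cluster.py
```

```
32 runs -> 3 candidate sites

site 1: 11 members, closest head   4.4 A from the planted patch
site 2:  4 members, closest head   3.5 A from the planted patch
site 3:  4 members, closest head   3.9 A from the planted patch
```

With a planted high-φ patch the independent annealing runs converge on
it from every approach direction: each ranked site's representative pose
docks a ligand head within a few Å of the patch centroid (the cluster's
COM itself necessarily hovers ≈ cluster radius above the surface). The
other examples cover featurization (`featurize_protein.py`), learning
per-pair energies from configuration sums (`train_interaction_model.py`)
and trajectory residence analytics (`analyze_trajectory.py`).

The same stages are available as a CLI:
`graphbnc synth|featurize|train|run|analyze` (see `graphbnc --help`).

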