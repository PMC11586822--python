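"""Place a nanocluster on a protein by simulated annealing.

Uses a hand-built interaction-strength table (phi = 1 on a planted
charged patch) so the placement stage can be watched in isolation: 32
annealing runs from evenly distributed directions, agglomerative
clustering of the final centre-of-mass points, and a ranked site list.
"""

import numpy as np

import graphbnc as g
from graphbnc.annealing import CoarseLoss

protein = g.make_protein(n_residues=120, n_patches=1, seed=3)
cluster = g.make_cluster(n_ligands=18, seed=3)

phi = np.zeros((cluster.model.n_ligands, len(protein.coarse)))
phi[:, protein.patches[0]] = 1.0  # the planted site is the unique minimum

results = g.anneal(protein.coarse, cluster.model, phi, n_runs=32, seed=1)
evaluator = CoarseLoss(protein.coarse, cluster.model, phi)
ranking = g.select_sites(results, evaluator, -phi, n=3)

patch = protein.patch_centroids[0]
print(f"{len(results)} runs -> {len(ranking.sites)} candidate sites\n")
for rank, site in enumerate(ranking.sites, start=1):
    heads = site.representative_pose.apply(cluster.model.head_centroids)
    d = np.linalg.norm(heads - patch, axis=1).min()
    print(f"site {rank}: {site.member_count:2d} members, "
          f"closest head {d:5.1f} A from the planted patch")
# The ranked sites all dock a ligand head onto the planted patch: runs
# converge there from every approach direction, and the 10 A clustering
# threshold may split the surrounding cloud of COM points into more than
# one candidate when the cluster straddles the patch from different sides.
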