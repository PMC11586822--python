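"""Contact-residence analytics of a cluster trajectory.

Builds a scripted trajectory in which the cluster resides 70% of the
time at one pose and 30% at another, then computes per-residue contact
fractions (4.0 A cutoff), filters at the 40% residence threshold, and
reports the COM displacement summary and the overlap with a 'predicted'
site list.
"""

import numpy as np

import graphbnc as g
from graphbnc.structures import RigidPose

protein = g.make_protein(n_residues=100, n_patches=2, seed=5)
cluster = g.make_cluster(n_ligands=12, seed=5)

site_a, site_b = protein.patch_centroids
center = protein.coarse.ca_coords.mean(axis=0)


def pose_at(site):
    out = site - center
    out /= np.linalg.norm(out)
    return RigidPose(translation=site + 10.0 * out - cluster.model.com,
                     pivot=cluster.model.com)


frames = g.make_trajectory(protein, cluster, pose_at(site_a), n_frames=200,
                           drift=0.3, seed=9,
                           pose_schedule=[(pose_at(site_a), 0.7),
                                          (pose_at(site_b), 0.3)])

report = g.contact_fractions(frames, protein.atoms, cutoff=4.0)
stable = g.filter_report(report, threshold=0.40)
print(f"residues ever in contact: {len(report.table)}; "
      f"above 40% residence: {len(stable.table)}")
print(stable.table.to_string(index=False, float_format=lambda x: f"{x:.2f}"))

disp = g.com_displacement(frames, masses=cluster.model.masses)
print(f"\nCOM RMS displacement from the initial pose: {disp['rmsd']:.1f} A")

predicted = [(c, r) for c, r, _ in
             (protein.coarse.residue_labels[i] for i in protein.patches[0])]
overlap = g.compare_sites(predicted, stable)
print(f"predicted-site residues confirmed by the trajectory: "
      f"{overlap['count']}/{len(predicted)} ({overlap['fraction']:.0%})")
# Residues of the 70% site dominate the residence table; the COM RMSD
# reflects the scripted excursion to the second site.
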