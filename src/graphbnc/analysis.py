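"""Trajectory validation analytics.

Given a trajectory of cluster coordinates over a (rigid) protein, these
routines reproduce the standard post-processing of nanocluster-protein
simulations: per-residue contact residence fractions (a residue counts
as contacting in a frame when any of its heavy atoms is within a cutoff,
default 4.0 A, of any cluster atom), filtering to residues above a
residence threshold (default 40%), centre-of-mass displacement traces,
and overlap of a predicted interaction site with the observed contacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree


@dataclass
class ContactReport:
    """Per-residue contact residence fractions, sorted descending."""

    table: pd.DataFrame  # columns chain_id, residue_id, residue_name, contact_fraction
    n_frames: int
    cutoff: float
    threshold: float = 0.0

    @property
    def residues(self) -> set:
        return set(zip(self.table["chain_id"], self.table["residue_id"]))


def contact_fractions(cluster_frames: np.ndarray, protein_atoms: list,
                      cutoff: float = 4.0,
                      include_hydrogens: bool = False) -> ContactReport:
    """Fraction of frames in which each residue touches the cluster.

    ``cluster_frames`` has shape (n_frames, n_cluster_atoms, 3); the
    protein is held fixed.  Hydrogens are excluded by default.
    """
    frames = np.asarray(cluster_frames, dtype=float)
    if frames.ndim != 3:
        raise ValueError("cluster_frames must have shape (n_frames, n_atoms, 3)")
    atoms = [a for a in protein_atoms
             if include_hydrogens or a.element.upper() != "H"]
    coords = np.array([a.coords for a in atoms])
    keys = [(a.chain_id, a.residue_id, a.residue_name) for a in atoms]
    residues = sorted(set(keys))
    res_index = {k: i for i, k in enumerate(residues)}
    owner = np.array([res_index[k] for k in keys])

    counts = np.zeros(len(residues))
    if cutoff > 0:
        tree = cKDTree(coords)
        for frame in frames:
            hit = tree.query_ball_point(frame, cutoff)
            touched = set()
            for lst in hit:
                touched.update(owner[i] for i in lst)
            for r in touched:
                counts[r] += 1
    fractions = counts / len(frames)
    df = pd.DataFrame({
        "chain_id": [r[0] for r in residues],
        "residue_id": [r[1] for r in residues],
        "residue_name": [r[2] for r in residues],
        "contact_fraction": fractions,
    })
    df = df[df["contact_fraction"] > 0]
    df = df.sort_values("contact_fraction", ascending=False, kind="stable")
    return ContactReport(table=df.reset_index(drop=True),
                         n_frames=len(frames), cutoff=cutoff)


def filter_report(report: ContactReport, threshold: float = 0.40) -> ContactReport:
    """Keep residues with contact fraction strictly above the threshold."""
    kept = report.table[report.table["contact_fraction"] > threshold]
    return ContactReport(table=kept.reset_index(drop=True),
                         n_frames=report.n_frames, cutoff=report.cutoff,
                         threshold=threshold)


def com_displacement(cluster_frames: np.ndarray,
                     masses: np.ndarray | None = None) -> dict:
    """Per-frame COM displacement from frame 0 and its RMS summary."""
    frames = np.asarray(cluster_frames, dtype=float)
    if masses is None:
        masses = np.ones(frames.shape[1])
    m = np.asarray(masses, dtype=float)
    coms = (frames * m[None, :, None]).sum(axis=1) / m.sum()
    d = np.linalg.norm(coms - coms[0], axis=1)
    return {"displacement": d, "rmsd": float(np.sqrt(np.mean(d ** 2)))}


def compare_sites(predicted_residues, report: ContactReport) -> dict:
    """Overlap of predicted site residues with the observed contact list.

    Residues are (chain_id, residue_id) pairs.  Returns the intersection,
    its size and the fraction of predicted residues confirmed by the
    trajectory (the bold-face convention of residence tables).
    """
    predicted = {tuple(r[:2]) for r in predicted_residues}
    observed = report.residues
    overlap = predicted & observed
    fraction = len(overlap) / len(predicted) if predicted else 0.0
    return {"overlap": sorted(overlap), "count": len(overlap),
            "fraction": fraction,
            "predicted": sorted(predicted), "observed": sorted(observed)}
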