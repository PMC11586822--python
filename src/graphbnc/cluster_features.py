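"""Nanocluster descriptors: global shape/composition features and
per-ligand local features.

The global 9-vector characterises the whole cluster (atom-count ratios,
metal-core vs carbon-shell sphere ratios, normalized principal moments of
inertia).  Each protecting ligand gets a 7-vector (8 when bridge-site
ligands occur in the cluster): neighbor head/ring distances, a pi-pi
stacking flag, burial measures and the protecting-unit position class.
All descriptors are invariant under rigid motion of the cluster.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree

from .geometry import normalized_inertia
from .structures import ClusterModel
from .tables import vdw_radius

logger = logging.getLogger(__name__)

NEIGHBOR_SENTINEL = 999.0  # undefined neighbor distance (single-ligand cluster)
PI_PI_MAX_CENTER_DIST = 5.0  # A
PI_PI_MAX_ANGLE = 30.0  # degrees

GLOBAL_DIM = 9


def _subset_sphere_radius(cluster: ClusterModel, elements: set) -> float:
    """Radius of the sphere (centred at the cluster COM) enclosing a subset."""
    mask = np.array([e.upper() in elements for e in cluster.elements])
    if not mask.any():
        raise ValueError(f"cluster has no atoms of {elements}")
    return float(np.linalg.norm(cluster.coords[mask] - cluster.com, axis=1).max())


def global_descriptors(cluster: ClusterModel) -> np.ndarray:
    """[N_nonH/N, N_Au/N, N_S/N_lig, r_Au/r_C, A_Au/A_C, V_Au/V_C, J1^, J2^, J3^]."""
    if cluster.n_ligands == 0:
        raise ValueError("cluster has no ligands")
    els = [e.upper() for e in cluster.elements]
    n = len(els)
    n_nonh = sum(e != "H" for e in els)
    n_au = sum(e == "AU" for e in els)
    n_s = sum(e == "S" for e in els)
    r_au = _subset_sphere_radius(cluster, {"AU"})
    r_c = _subset_sphere_radius(cluster, {"C"})
    ratio = r_au / r_c
    inertia = normalized_inertia(cluster.coords, cluster.masses)
    feats = np.array([n_nonh / n, n_au / n, n_s / cluster.n_ligands,
                      ratio, ratio**2, ratio**3, *inertia])
    cluster.global_features = feats
    return feats


def _ring_normal(coords: np.ndarray) -> np.ndarray:
    """Best-fit plane normal of a ring (smallest principal axis)."""
    x = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(x)
    return vt[-1]


def pi_pi_flags(cluster: ClusterModel,
                max_dist: float = PI_PI_MAX_CENTER_DIST,
                max_angle_deg: float = PI_PI_MAX_ANGLE) -> np.ndarray:
    """Symmetric pi-pi stacking flags per ligand.

    Two ligands stack when their ring centres are within ``max_dist`` and
    their ring normals are within ``max_angle_deg`` of parallel (or
    antiparallel).  Ligands without a ring never stack.
    """
    L = cluster.n_ligands
    centers = cluster.ring_centroids
    normals = np.full((L, 3), np.nan)
    for i, lig in enumerate(cluster.topology.ligands):
        if len(lig.ring_atom_indices) >= 3:
            normals[i] = _ring_normal(cluster.coords[lig.ring_atom_indices])
    flags = np.zeros(L)
    cos_max = np.cos(np.deg2rad(max_angle_deg))
    for i in range(L):
        for j in range(i + 1, L):
            if np.isnan(normals[i]).any() or np.isnan(normals[j]).any():
                continue
            if np.linalg.norm(centers[i] - centers[j]) > max_dist:
                continue
            if abs(float(normals[i] @ normals[j])) >= cos_max:
                flags[i] = flags[j] = 1.0
    return flags


def _min_neighbor_distances(points: np.ndarray) -> np.ndarray:
    """Per-point minimum distance to any other point (sentinel if alone)."""
    valid = ~np.isnan(points).any(axis=1)
    out = np.full(len(points), NEIGHBOR_SENTINEL)
    pts = points[valid]
    if len(pts) >= 2:
        tree = cKDTree(pts)
        d, _ = tree.query(pts, k=2)
        out[valid] = d[:, 1]
    elif len(pts) == 1:
        logger.warning("single ligand: neighbor distances set to sentinel %.1f",
                       NEIGHBOR_SENTINEL)
    return out


def ligand_burial(cluster: ClusterModel) -> tuple:
    """Mean ligand-atom and ligand-oxygen burial, shell-probe style.

    The probe measures, for each ligand atom, the free distance to the
    nearest other cluster atom surface -- a small value marks a buried
    atom.  This mirrors the residue-level R_inacc provider at the cluster
    scale and is rigid-motion invariant.
    """
    coords = cluster.coords
    radii = np.array([vdw_radius(e) for e in cluster.elements])
    tree = cKDTree(coords)
    if len(coords) < 2:
        gaps = np.full(len(coords), 10.0)
    else:
        d, idx = tree.query(coords, k=2)
        gaps = np.minimum(np.maximum(d[:, 1] - radii - radii[idx[:, 1]], 0.0), 10.0)
    lig_mean = np.zeros(cluster.n_ligands)
    oxy_mean = np.zeros(cluster.n_ligands)
    for i, lig in enumerate(cluster.topology.ligands):
        atoms = (list(lig.head_atom_indices) + list(lig.ring_atom_indices)
                 + ([lig.sulfur_index] if lig.sulfur_index is not None else []))
        lig_mean[i] = gaps[atoms].mean()
        oxy = [a for a in atoms if cluster.elements[a].upper() == "O"]
        oxy_mean[i] = gaps[oxy].mean() if oxy else 0.0
    return lig_mean, oxy_mean


def ligand_descriptors(cluster: ClusterModel) -> np.ndarray:
    """Per-ligand feature matrix, 7 columns (8 when bridge sites exist).

    Columns: [min head-head distance, min ring-ring distance, pi-pi flag,
    mean burial (ligand atoms), mean burial (oxygens), unit-position
    one-hot (middle, end[, bridge])].
    """
    min_heads = _min_neighbor_distances(cluster.head_centroids)
    min_rings = _min_neighbor_distances(cluster.ring_centroids)
    flags = pi_pi_flags(cluster)
    burial_all, burial_oxy = ligand_burial(cluster)
    positions = ("middle", "end", "bridge") if cluster.topology.has_bridge \
        else ("middle", "end")
    onehot = np.zeros((cluster.n_ligands, len(positions)))
    for i, lig in enumerate(cluster.topology.ligands):
        onehot[i, positions.index(lig.unit_position)] = 1.0
    feats = np.column_stack([min_heads, min_rings, flags,
                             burial_all, burial_oxy, onehot])
    cluster.ligand_features = feats
    return feats


def featurize_cluster(cluster: ClusterModel) -> ClusterModel:
    global_descriptors(cluster)
    ligand_descriptors(cluster)
    return cluster


def pair_features(protein_graph, cluster: ClusterModel,
                  ligand_index: int, node_index: int) -> np.ndarray:
    """Concatenated [global(9); ligand(7|8); WL node] feature vector."""
    if cluster.global_features is None or cluster.ligand_features is None:
        featurize_cluster(cluster)
    if protein_graph.node_attr_wl is None:
        raise ValueError("protein WL attributes not computed")
    return np.concatenate([cluster.global_features,
                           cluster.ligand_features[ligand_index],
                           protein_graph.node_attr_wl[node_index]])


def pair_feature_matrix(protein_graph, cluster: ClusterModel) -> np.ndarray:
    """(n_ligands * n_residues, D) matrix of all pair feature vectors.

    Row order: ligand-major (ligand 0 with every residue first).
    """
    if cluster.global_features is None or cluster.ligand_features is None:
        featurize_cluster(cluster)
    L, N = cluster.n_ligands, len(protein_graph)
    g = np.tile(cluster.global_features, (L * N, 1))
    lig = np.repeat(cluster.ligand_features, N, axis=0)
    node = np.tile(protein_graph.node_attr_wl, (L, 1))
    return np.hstack([g, lig, node])
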