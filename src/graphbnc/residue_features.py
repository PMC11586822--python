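"""Per-residue chemical and geometric node features.

Each provider returns an (n_residues, dim) block.  Providers that the
original workflow delegates to external programs (secondary structure,
solvent accessibility, pocket measures) run in one of two modes:

* ``internal`` -- self-contained approximations: a CA-geometry secondary
  structure assignment, a Shrake-Rupley SASA with a 1.4 A probe, and a
  spherical-shell probe for accessibility/pocketness/burial.
* ``external`` -- values read from a per-residue annotation CSV with
  columns chain_id, residue_id, dssp_class, rel_asa, sasa, acc_shell,
  pocketness, pocketness_c1..c5, r_inacc.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from .geometry import fibonacci_sphere
from .structures import CoarseProtein, atomic_mass
from .tables import (AA_CLASSES, AA_CLASS_OF, DSSP_CLASSES, MAX_ASA,
                     RESIDUE_COMPOSITION, RESIDUE_MASSES, canonical_residue,
                     hydrophobicity_vector, vdw_radius)

# Shell-probe geometry: sample shells around each CA at these radii (A);
# a sample point is free when no heavy atom lies within the block radius.
SHELL_RADII = (3.0, 5.0, 7.0, 9.0)
SHELL_DIRECTIONS = 30
BLOCK_RADIUS = 2.7
POCKET_PROBE_RADII = (1.5, 2.0, 2.5, 3.0, 3.5)


def _heavy_atoms_by_residue(cp: CoarseProtein, atoms):
    """Group heavy-atom records by residue in coarse-protein node order.

    Falls back to the CA bead itself when no atom list is available.
    """
    order = {(c, r): i for i, (c, r, _) in enumerate(cp.residue_labels)}
    groups = [[] for _ in range(len(cp))]
    if atoms is None:
        for i, xyz in enumerate(cp.ca_coords):
            groups[i].append(("C", xyz))
        return groups
    for a in atoms:
        if a.element.upper() == "H":
            continue
        idx = order.get((a.chain_id, a.residue_id))
        if idx is not None:
            groups[idx].append((a.element, a.coords))
    for i, g in enumerate(groups):
        if not g:
            groups[i].append(("C", cp.ca_coords[i]))
    return groups


# ---------------------------------------------------------------------------
# Composition / identity blocks


def element_counts(cp: CoarseProtein, atoms=None) -> np.ndarray:
    """(N_C, N_N, N_O, N_S) per residue, heavy atoms only.

    Counted from the atom records when available, otherwise taken from the
    standard residue composition table.
    """
    out = np.zeros((len(cp), 4))
    if atoms is not None:
        groups = _heavy_atoms_by_residue(cp, atoms)
        col = {"C": 0, "N": 1, "O": 2, "S": 3}
        for i, g in enumerate(groups):
            for el, _ in g:
                j = col.get(el.upper())
                if j is not None:
                    out[i, j] += 1
    else:
        for i, (_, _, name) in enumerate(cp.residue_labels):
            out[i] = RESIDUE_COMPOSITION.get(canonical_residue(name), (3, 1, 1, 0))
    return out


def molecular_mass(cp: CoarseProtein, atoms=None) -> np.ndarray:
    out = np.zeros((len(cp), 1))
    if atoms is not None:
        groups = _heavy_atoms_by_residue(cp, atoms)
        for i, g in enumerate(groups):
            out[i, 0] = sum(atomic_mass(el) for el, _ in g)
    else:
        for i, (_, _, name) in enumerate(cp.residue_labels):
            out[i, 0] = RESIDUE_MASSES.get(canonical_residue(name), 110.0)
    return out


def amino_type_onehot(cp: CoarseProtein) -> np.ndarray:
    """Five side-chain classes: hydrophobic / polar / positive / negative / special."""
    out = np.zeros((len(cp), 5))
    for i, (_, _, name) in enumerate(cp.residue_labels):
        cls = AA_CLASS_OF.get(canonical_residue(name), "special")
        out[i, AA_CLASSES.index(cls)] = 1.0
    return out


def hydrophobicity(cp: CoarseProtein, table_path=None) -> np.ndarray:
    return np.array([hydrophobicity_vector(name, table_path)
                     for _, _, name in cp.residue_labels])


# ---------------------------------------------------------------------------
# Secondary structure (internal CA-geometry assignment)


def secondary_structure_onehot(cp: CoarseProtein) -> np.ndarray:
    """8-class secondary-structure one-hot from CA i->i+2/3/4 distances.

    The internal assignment only ever populates H (helix), E (strand) and
    '-' (coil); the remaining DSSP classes are available through the
    external annotation mode.
    """
    n = len(cp)
    classes = ["-"] * n
    xyz = cp.ca_coords
    # sequence neighbors by residue numbering, not by array position
    by_id = {(c, r): i for i, (c, r, _) in enumerate(cp.residue_labels)}

    def d(i, k):
        chain, resid, _ = cp.residue_labels[i]
        j = by_id.get((chain, resid + k))
        if j is None:
            return np.inf
        return float(np.linalg.norm(xyz[i] - xyz[j]))

    for i in range(n):
        d2, d3, d4 = d(i, 2), d(i, 3), d(i, 4)
        if 4.8 <= d2 <= 6.4 and d3 <= 6.0 and d4 <= 7.3:
            classes[i] = "H"
        elif d2 >= 6.3 and d3 >= 8.0 and d4 >= 10.0:
            classes[i] = "E"
    out = np.zeros((n, 8))
    for i, c in enumerate(classes):
        out[i, DSSP_CLASSES.index(c)] = 1.0
    return out


# ---------------------------------------------------------------------------
# Solvent accessibility (internal Shrake-Rupley)


def shrake_rupley_sasa(elements, coords, probe: float = 1.4,
                       n_points: int = 100) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), golden-spiral points."""
    coords = np.asarray(coords, dtype=float)
    radii = np.array([vdw_radius(e) for e in elements]) + probe
    sphere = fibonacci_sphere(n_points)
    tree = cKDTree(coords)
    out = np.zeros(len(coords))
    rmax = radii.max()
    for i in range(len(coords)):
        pts = coords[i] + radii[i] * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], radii[i] + rmax)
                     if j != i]
        if neighbors:
            d = np.linalg.norm(pts[:, None, :] - coords[neighbors][None, :, :], axis=2)
            exposed = np.all(d >= radii[neighbors][None, :], axis=1)
        else:
            exposed = np.ones(n_points, dtype=bool)
        out[i] = exposed.mean() * 4 * np.pi * radii[i] ** 2
    return out


def sasa_features(cp: CoarseProtein, atoms=None, probe: float = 1.4) -> np.ndarray:
    """Columns [rel_asa, sasa] per residue."""
    groups = _heavy_atoms_by_residue(cp, atoms)
    elements = [el for g in groups for el, _ in g]
    coords = np.array([xyz for g in groups for _, xyz in g])
    owner = np.concatenate([[i] * len(g) for i, g in enumerate(groups)])
    per_atom = shrake_rupley_sasa(elements, coords, probe=probe)
    sasa = np.bincount(owner, weights=per_atom, minlength=len(cp))
    rel = np.array([sasa[i] / MAX_ASA.get(canonical_residue(name), 200.0)
                    for i, (_, _, name) in enumerate(cp.residue_labels)])
    return np.column_stack([rel, sasa])


# ---------------------------------------------------------------------------
# Shell-probe burial / pocketness


def shell_probe_features(cp: CoarseProtein, atoms=None) -> dict:
    """Grid-probe burial descriptors from spherical shells around each CA.

    Returns a dict with keys ``acc_shell`` (N,), ``pocketness`` (N,),
    ``pocketness_clust`` (N, 5) and ``r_inacc`` (N,).

    A shell sample point is *free* when its nearest heavy atom is farther
    than the block radius.  Pocketness is the fraction of directions that
    are free close to the residue but blocked farther out (an enclosed
    void); the five clustered variants re-evaluate this at five probe
    radii.  ``r_inacc`` is the mean, over directions, of the first blocked
    shell radius -- larger values mean a more open environment.
    """
    groups = _heavy_atoms_by_residue(cp, atoms)
    all_coords = np.array([xyz for g in groups for _, xyz in g])
    tree = cKDTree(all_coords)
    dirs = fibonacci_sphere(SHELL_DIRECTIONS)
    radii = np.array(SHELL_RADII)
    # points: (N, n_dirs, n_shells, 3)
    pts = (cp.ca_coords[:, None, None, :]
           + dirs[None, :, None, :] * radii[None, None, :, None])
    dmin, _ = tree.query(pts.reshape(-1, 3))
    dmin = dmin.reshape(len(cp), SHELL_DIRECTIONS, len(radii))

    free = dmin > BLOCK_RADIUS
    acc_shell = free.mean(axis=(1, 2))

    def pocketness_at(block):
        fr = dmin > block  # (N, dirs, shells)
        # free at some shell with a blocked shell farther out in the same direction
        blocked_farther = np.zeros_like(fr)
        blocked_farther[:, :, :-1] = np.cumsum((~fr)[:, :, ::-1], axis=2)[:, :, ::-1][:, :, 1:] > 0
        return (fr & blocked_farther).mean(axis=(1, 2))

    pocketness = pocketness_at(BLOCK_RADIUS)
    pocket_clust = np.column_stack([pocketness_at(b) for b in POCKET_PROBE_RADII])

    # first blocked shell radius per direction (beyond last shell -> r_max + 2)
    blocked = ~free
    first_blocked = np.where(blocked.any(axis=2),
                             radii[np.argmax(blocked, axis=2)],
                             radii[-1] + 2.0)
    r_inacc = first_blocked.mean(axis=1)
    return {"acc_shell": acc_shell, "pocketness": pocketness,
            "pocketness_clust": pocket_clust, "r_inacc": r_inacc}


# ---------------------------------------------------------------------------
# OPD chirality


def opd_chirality(cp: CoarseProtein, k: int) -> np.ndarray:
    """Osipov-Pickup-Dunmur chirality index over the k nearest CA neighbors.

    Rotation invariant and antisymmetric under mirror reflection; computed
    from the node plus its k nearest CA neighbors, summing the scaled OPD
    integrand over all ordered quadruples of distinct points.
    """
    from itertools import permutations

    n = len(cp)
    if n < k + 1:
        return np.zeros(n)
    tree = cKDTree(cp.ca_coords)
    _, nn = tree.query(cp.ca_coords, k=k + 1)  # includes self at column 0
    quads = np.array(list(permutations(range(k + 1), 4)))
    out = np.zeros(n)
    for i in range(n):
        pts = cp.ca_coords[nn[i]]
        A, B, C, D = (pts[quads[:, j]] for j in range(4))
        r12, r23, r34, r14 = B - A, C - B, D - C, D - A
        num = (np.einsum("ij,ij->i", np.cross(r12, r34), r14)
               * np.einsum("ij,ij->i", r12, r23)
               * np.einsum("ij,ij->i", r23, r34))
        den = ((np.linalg.norm(r12, axis=1) * np.linalg.norm(r23, axis=1)
                * np.linalg.norm(r34, axis=1)) ** 2 * np.linalg.norm(r14, axis=1))
        ok = den > 1e-12
        out[i] = (num[ok] / den[ok]).sum() / (3 * len(quads))
    return out
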