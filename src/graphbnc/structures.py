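"""Molecular structure I/O and coarse-grained representations.

Proteins are read from PDB files (via Biopython) and reduced to their
alpha-carbon trace; nanoclusters are read from XYZ or PDB files together
with a ligand-topology sidecar (JSON) that maps atom indices to ligands,
their charged head groups, phenyl rings and protecting-unit positions.

Conventions: coordinates are in Angstrom throughout; residue numbering is
1-based as in the PDB; all in-memory atom indices are 0-based.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.PDB import PDBParser
from scipy.spatial.distance import pdist

logger = logging.getLogger(__name__)

# Heavy-atom masses (u) for the elements that occur in proteins and
# thiolate-protected metal clusters; unknown elements fall back to 12.0.
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "SE": 78.971, "AU": 196.967, "AG": 107.868, "NA": 22.990,
    "CL": 35.45, "FE": 55.845, "ZN": 65.38,
}

_WATER_NAMES = {"HOH", "WAT", "SOL", "TIP", "TIP3"}
_ION_NAMES = {"NA", "CL", "K", "MG", "ZN", "FE", "MN", "CU", "IOD", "BR"}


def atomic_mass(element: str) -> float:
    return ATOMIC_MASSES.get(element.upper(), 12.0)


@dataclass
class AtomRecord:
    """One atom of a molecular structure."""

    element: str
    coords: np.ndarray  # (3,) Angstrom
    residue_id: int
    residue_name: str
    chain_id: str
    atom_name: str
    icode: str = ""
    occupancy: float = 1.0
    hetatm: bool = False

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be a finite 3-vector")
        if not self.element:
            raise ValueError("element symbol must be non-empty")


@dataclass
class CoarseProtein:
    """Alpha-carbon trace of a protein: one bead per residue."""

    ca_coords: np.ndarray  # (N, 3)
    residue_labels: list  # [(chain_id, residue_id, residue_name), ...]

    def __post_init__(self):
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        if len(self.ca_coords) != len(self.residue_labels):
            raise ValueError("coordinate/label length mismatch")
        if len(self.ca_coords) >= 2 and pdist(self.ca_coords).min() < 0.1:
            raise ValueError("two alpha-carbons closer than 0.1 A")

    def __len__(self):
        return len(self.residue_labels)

    @property
    def bounding_radius(self) -> float:
        """Max distance of any CA from the CA centroid."""
        c = self.ca_coords.mean(axis=0)
        return float(np.linalg.norm(self.ca_coords - c, axis=1).max())


@dataclass
class Ligand:
    """Topology of one protecting ligand of a nanocluster."""

    head_atom_indices: list
    ring_atom_indices: list
    sulfur_index: int | None = None
    ligand_type: str = ""
    unit_position: str = "middle"

    def __post_init__(self):
        if not self.head_atom_indices:
            raise ValueError("ligand must have at least one head atom")
        if self.unit_position not in ("middle", "end", "bridge"):
            raise ValueError(f"unknown unit position {self.unit_position!r}")
        if set(self.head_atom_indices) & set(self.ring_atom_indices):
            raise ValueError("head and ring atom sets overlap")


@dataclass
class LigandTopology:
    ligands: list  # list[Ligand]

    def __len__(self):
        return len(self.ligands)

    @property
    def has_bridge(self) -> bool:
        return any(l.unit_position == "bridge" for l in self.ligands)


@dataclass
class RigidPose:
    """Rigid-body transform: rotation about a pivot followed by a translation.

    ``apply`` maps x -> R (x - pivot) + pivot + t.  The pivot is normally the
    cluster centre of mass in its reference frame.
    """

    rotation: np.ndarray = field(default_factory=lambda: np.eye(3))
    translation: np.ndarray = field(default_factory=lambda: np.zeros(3))
    pivot: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        self.pivot = np.asarray(self.pivot, dtype=float)

    def check_valid(self, tol: float = 1e-6) -> None:
        R = self.rotation
        if not np.allclose(R @ R.T, np.eye(3), atol=tol) or abs(np.linalg.det(R) - 1) > tol:
            raise ValueError("rotation must be orthonormal with determinant +1")

    def apply(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        return (coords - self.pivot) @ self.rotation.T + self.pivot + self.translation


@dataclass
class ClusterModel:
    """Rigid nanocluster: all-atom geometry plus ligand topology.

    Feature vectors (``global_features``, ``ligand_features``) are attached by
    :mod:`graphbnc.cluster_features`.
    """

    elements: list
    coords: np.ndarray  # (N, 3)
    topology: LigandTopology
    global_features: np.ndarray | None = None
    ligand_features: np.ndarray | None = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        n = len(self.coords)
        for lig in self.topology.ligands:
            idx = list(lig.head_atom_indices) + list(lig.ring_atom_indices)
            if lig.sulfur_index is not None:
                idx.append(lig.sulfur_index)
            if idx and (max(idx) >= n or min(idx) < 0):
                raise IndexError("topology references an atom index outside the structure")

    @property
    def n_ligands(self) -> int:
        return len(self.topology)

    @property
    def masses(self) -> np.ndarray:
        return np.array([atomic_mass(e) for e in self.elements])

    @property
    def com(self) -> np.ndarray:
        m = self.masses
        return (self.coords * m[:, None]).sum(axis=0) / m.sum()

    @property
    def head_centroids(self) -> np.ndarray:
        return np.array([self.coords[l.head_atom_indices].mean(axis=0)
                         for l in self.topology.ligands])

    @property
    def ring_centroids(self) -> np.ndarray:
        out = np.full((self.n_ligands, 3), np.nan)
        for i, l in enumerate(self.topology.ligands):
            if l.ring_atom_indices:
                out[i] = self.coords[l.ring_atom_indices].mean(axis=0)
        return out

    @property
    def radius(self) -> float:
        return float(np.linalg.norm(self.coords - self.com, axis=1).max())

    def transformed(self, pose: RigidPose) -> "ClusterModel":
        return ClusterModel(list(self.elements), pose.apply(self.coords), self.topology,
                            self.global_features, self.ligand_features)


# ---------------------------------------------------------------------------
# PDB reading


def read_protein(path, model_index: int = 0) -> list:
    """Read all ATOM/HETATM records of one model of a PDB file.

    Waters and common monoatomic ions are dropped; for altloc duplicates the
    highest-occupancy copy is kept (ties: first encountered).  Insertion
    codes are preserved on the returned records.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        structure = parser.get_structure("s", str(path))
    models = list(structure)
    if model_index >= len(models):
        raise IndexError(f"model {model_index} not in file ({len(models)} models)")
    records = []
    for chain in models[model_index]:
        for residue in chain:
            hetflag, resseq, icode = residue.get_id()
            resname = residue.get_resname().strip()
            if resname in _WATER_NAMES or resname in _ION_NAMES:
                continue
            best = {}
            for atom in residue.get_unpacked_list():
                name = atom.get_name()
                if name not in best or (atom.get_occupancy() or 1.0) > best[name][0]:
                    best[name] = ((atom.get_occupancy() or 1.0), atom)
            for name, (occ, atom) in best.items():
                el = (atom.element or name[:1]).strip()
                records.append(AtomRecord(
                    element=el, coords=atom.get_coord(), residue_id=int(resseq),
                    residue_name=resname, chain_id=chain.get_id(),
                    atom_name=name, icode=icode.strip(), occupancy=occ,
                    hetatm=bool(hetflag.strip()),
                ))
    return records


def extract_coarse_protein(atoms: list) -> CoarseProtein:
    """Collapse an atom list to one alpha-carbon bead per residue.

    Residues lacking a CA atom are excluded with a warning.  Ordering is by
    chain then residue number (insertion codes break ties).
    """
    by_res = {}
    for a in atoms:
        key = (a.chain_id, a.residue_id, a.icode)
        by_res.setdefault(key, {"name": a.residue_name, "ca": None, "occ": -1.0})
        if a.atom_name == "CA" and a.element.upper() == "C":
            if a.occupancy > by_res[key]["occ"]:
                by_res[key]["ca"] = a.coords
                by_res[key]["occ"] = a.occupancy
    coords, labels = [], []
    for key in sorted(by_res, key=lambda k: (k[0], k[1], k[2])):
        entry = by_res[key]
        if entry["ca"] is None:
            logger.warning("residue %s%d%s has no CA atom; excluded from the trace",
                           key[0], key[1], key[2])
            continue
        coords.append(entry["ca"])
        labels.append((key[0], key[1], entry["name"]))
    if not coords:
        raise ValueError("no alpha-carbons found in structure")
    return CoarseProtein(np.array(coords), labels)


# ---------------------------------------------------------------------------
# XYZ reading (single- and multi-frame)


def read_xyz(path) -> list:
    """Read an (optionally multi-frame) XYZ file.

    Returns a list of frames, each ``(elements, coords)`` with coords of
    shape (N, 3).
    """
    frames = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i].strip())
        block = lines[i + 2:i + 2 + n]
        elements, coords = [], []
        for ln in block:
            parts = ln.split()
            elements.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        frames.append((elements, np.array(coords)))
        i += 2 + n
    if not frames:
        raise ValueError(f"no frames found in {path}")
    return frames


def write_xyz(path, elements, frames, comments=None) -> None:
    """Write one or more coordinate frames as an XYZ file."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    if frames.ndim != 3 or frames.shape[2] != 3:
        raise ValueError("frames must have shape (n_atoms, 3) or (n_frames, n_atoms, 3)")
    with open(path, "w") as fh:
        for t, coords in enumerate(frames):
            fh.write(f"{len(elements)}\n")
            fh.write((comments[t] if comments else f"frame {t}") + "\n")
            for el, (x, y, z) in zip(elements, coords):
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


# ---------------------------------------------------------------------------
# Cluster + topology sidecar

TOPOLOGY_SCHEMA = """\
Ligand-topology sidecar (JSON):
{
  "ligands": [
    {"head": [i, ...],          # 0-based atom indices of the charged head group
     "ring": [i, ...],          # atom indices of the phenyl ring (may be empty)
     "sulfur": i or null,       # anchoring sulfur atom
     "type": "p-MBA",           # free-text ligand tag
     "unit_position": "middle"} # middle | end | bridge
  ]
}
Indices refer to the atom order of the accompanying structure file.
"""


def read_topology(path) -> LigandTopology:
    with open(path) as fh:
        data = json.load(fh)
    ligands = [
        Ligand(head_atom_indices=list(l["head"]),
               ring_atom_indices=list(l.get("ring", [])),
               sulfur_index=l.get("sulfur"),
               ligand_type=l.get("type", ""),
               unit_position=l.get("unit_position", "middle"))
        for l in data["ligands"]
    ]
    return LigandTopology(ligands)


def write_topology(path, topology: LigandTopology) -> None:
    data = {"ligands": [
        {"head": list(l.head_atom_indices), "ring": list(l.ring_atom_indices),
         "sulfur": l.sulfur_index, "type": l.ligand_type,
         "unit_position": l.unit_position}
        for l in topology.ligands]}
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1)


def read_cluster(structure_path, topology_path) -> ClusterModel:
    """Read a nanocluster structure (XYZ or PDB) plus its topology sidecar."""
    structure_path = Path(structure_path)
    if structure_path.suffix.lower() == ".xyz":
        elements, coords = read_xyz(structure_path)[0]
    else:
        atoms = read_protein(structure_path)
        elements = [a.element for a in atoms]
        coords = np.array([a.coords for a in atoms])
    topology = read_topology(topology_path)
    return ClusterModel(elements, coords, topology)


# ---------------------------------------------------------------------------
# PDB writing


def _pdb_line(serial, name, resname, chain, resseq, xyz, element, hetatm=False):
    rec = "HETATM" if hetatm else "ATOM  "
    name_f = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (f"{rec}{serial:>5d} {name_f}{'':1s}{resname:>3s} {chain:1s}"
            f"{resseq:>4d}    {xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
            f"{1.00:6.2f}{0.00:6.2f}          {element.upper():>2s}\n")


def write_pdb(path, atoms: list) -> None:
    """Write a list of AtomRecord to a PDB file."""
    with open(path, "w") as fh:
        for i, a in enumerate(atoms, start=1):
            fh.write(_pdb_line(i % 100000, a.atom_name, a.residue_name, a.chain_id,
                               a.residue_id, a.coords, a.element, a.hetatm))
        fh.write("END\n")


def write_complex(protein_atoms, cluster: ClusterModel, pose: RigidPose, path) -> None:
    """Write a protein + posed cluster as a single PDB file.

    Protein chains come first as ATOM records, the transformed cluster
    follows as HETATM records (chain X; residue number = ligand index + 1,
    core atoms as residue 0 -> written as resid 999).
    """
    pose.check_valid()
    moved = pose.apply(cluster.coords)
    lig_of_atom = {}
    for li, lig in enumerate(cluster.topology.ligands):
        for idx in list(lig.head_atom_indices) + list(lig.ring_atom_indices) + (
                [lig.sulfur_index] if lig.sulfur_index is not None else []):
            lig_of_atom[idx] = li
    with open(path, "w") as fh:
        serial = 1
        for a in protein_atoms:
            fh.write(_pdb_line(serial % 100000, a.atom_name, a.residue_name,
                               a.chain_id, a.residue_id, a.coords, a.element))
            serial += 1
        fh.write("TER\n")
        for i, (el, xyz) in enumerate(zip(cluster.elements, moved)):
            resid = lig_of_atom.get(i, 998) + 1
            fh.write(_pdb_line(serial % 100000, f"{el.upper()}{i % 100}", "CLS",
                               "X", resid, xyz, el, hetatm=True))
            serial += 1
        fh.write("END\n")
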