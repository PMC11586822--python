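"""Static per-residue reference tables.

Heavy-atom compositions and residue masses follow standard PDB content
(no hydrogens, no OXT).  The five hydrophobicity scales live in a
packaged CSV (``data/hydrophobicity.csv``) and can be overridden.
"""

from __future__ import annotations

import functools
from importlib import resources

import numpy as np
import pandas as pd

# Canonicalize common protonation/derivative variants.
RESIDUE_ALIASES = {
    "HID": "HIS", "HIE": "HIS", "HIP": "HIS", "HSD": "HIS", "HSE": "HIS",
    "HSP": "HIS", "CYX": "CYS", "CYM": "CYS", "ASH": "ASP", "GLH": "GLU",
    "LYN": "LYS", "ARN": "ARG", "MSE": "MET",
}

# Heavy-atom counts (C, N, O, S) per residue, backbone included.
RESIDUE_COMPOSITION = {
    "GLY": (2, 1, 1, 0), "ALA": (3, 1, 1, 0), "SER": (3, 1, 2, 0),
    "CYS": (3, 1, 1, 1), "SEC": (3, 1, 1, 0), "THR": (4, 1, 2, 0),
    "VAL": (5, 1, 1, 0), "PRO": (5, 1, 1, 0), "LEU": (6, 1, 1, 0),
    "ILE": (6, 1, 1, 0), "MET": (5, 1, 1, 1), "PHE": (9, 1, 1, 0),
    "TYR": (9, 1, 2, 0), "TRP": (11, 2, 1, 0), "ASP": (4, 1, 3, 0),
    "GLU": (5, 1, 3, 0), "ASN": (4, 2, 2, 0), "GLN": (5, 2, 2, 0),
    "HIS": (6, 3, 1, 0), "LYS": (6, 2, 1, 0), "ARG": (6, 4, 1, 0),
}

# Residue (monomer) masses in u.
RESIDUE_MASSES = {
    "GLY": 57.05, "ALA": 71.08, "SER": 87.08, "CYS": 103.14, "SEC": 150.04,
    "THR": 101.10, "VAL": 99.13, "PRO": 97.12, "LEU": 113.16, "ILE": 113.16,
    "MET": 131.19, "PHE": 147.18, "TYR": 163.18, "TRP": 186.21, "ASP": 115.09,
    "GLU": 129.12, "ASN": 114.10, "GLN": 128.13, "HIS": 137.14, "LYS": 128.17,
    "ARG": 156.19,
}

# Five side-chain classes used for the amino-acid-type one-hot block.
AA_CLASSES = ("hydrophobic", "polar", "positive", "negative", "special")
AA_CLASS_OF = {}
for _r in ("ALA", "VAL", "LEU", "ILE", "MET", "PHE", "TYR", "TRP"):
    AA_CLASS_OF[_r] = "hydrophobic"
for _r in ("SER", "THR", "ASN", "GLN"):
    AA_CLASS_OF[_r] = "polar"
for _r in ("ARG", "HIS", "LYS"):
    AA_CLASS_OF[_r] = "positive"
for _r in ("ASP", "GLU"):
    AA_CLASS_OF[_r] = "negative"
for _r in ("CYS", "SEC", "GLY", "PRO"):
    AA_CLASS_OF[_r] = "special"

# Theoretical maximum accessible surface areas (A^2), Tien et al. convention.
MAX_ASA = {
    "ALA": 129.0, "ARG": 274.0, "ASN": 195.0, "ASP": 193.0, "CYS": 167.0,
    "GLU": 223.0, "GLN": 225.0, "GLY": 104.0, "HIS": 224.0, "ILE": 197.0,
    "LEU": 201.0, "LYS": 236.0, "MET": 224.0, "PHE": 240.0, "PRO": 159.0,
    "SER": 155.0, "THR": 172.0, "TRP": 285.0, "TYR": 263.0, "VAL": 174.0,
    "SEC": 167.0,
}

# Van der Waals radii (A) for SASA / probe calculations.
VDW_RADII = {"H": 1.2, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80,
             "P": 1.80, "SE": 1.90, "AU": 1.66, "AG": 1.72}
DEFAULT_VDW = 1.70

DSSP_CLASSES = ("H", "B", "E", "G", "I", "T", "S", "-")


def canonical_residue(name: str) -> str:
    name = name.strip().upper()
    return RESIDUE_ALIASES.get(name, name)


@functools.lru_cache(maxsize=4)
def hydrophobicity_table(path: str | None = None) -> pd.DataFrame:
    """Five hydrophobicity scales per residue, indexed by 3-letter code."""
    if path is None:
        with resources.files("graphbnc.data").joinpath("hydrophobicity.csv").open() as fh:
            df = pd.read_csv(fh)
    else:
        df = pd.read_csv(path)
    return df.set_index("residue")


def hydrophobicity_vector(resname: str, path: str | None = None) -> np.ndarray:
    table = hydrophobicity_table(path)
    resname = canonical_residue(resname)
    if resname in table.index:
        return table.loc[resname].to_numpy(dtype=float)
    return np.zeros(table.shape[1])


def vdw_radius(element: str) -> float:
    return VDW_RADII.get(element.upper(), DEFAULT_VDW)
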