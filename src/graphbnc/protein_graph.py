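"""Residue contact graph, 39-dimensional node featurization and
continuous Weisfeiler-Lehman propagation.

Residues are nodes (one per alpha-carbon); two residues are connected
when their CA atoms are within the contact cutoff (default 4.5 A); edges
are unweighted.  Each node carries a 39-dimensional attribute vector
assembled from pluggable providers, then expanded by iterative
neighbor-averaging (continuous WL updates), concatenating each round so
that N_WL updates yield a 39*(N_WL+1)-dimensional representation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree

from . import graph_features as gf
from . import residue_features as rf
from .structures import CoarseProtein

N_FEATURES = 39
DEFAULT_CUTOFF = 4.5
DEFAULT_N_WL = 2


@dataclass
class ProteinGraph:
    """Residue graph with raw and WL-expanded node attributes."""

    coarse: CoarseProtein
    graph: nx.Graph
    node_attr_raw: np.ndarray | None = None  # (N, 39)
    node_attr_wl: np.ndarray | None = None   # (N, 39*(N_WL+1))

    def __len__(self):
        return len(self.coarse)

    @property
    def adjacency(self) -> np.ndarray:
        return nx.to_numpy_array(self.graph, nodelist=range(len(self)))


def build_graph(cp: CoarseProtein, cutoff: float = DEFAULT_CUTOFF) -> ProteinGraph:
    """Connect residues whose CA atoms are within ``cutoff`` Angstrom."""
    if len(cp) < 2:
        raise ValueError("need at least two residues to build a graph")
    G = nx.Graph()
    G.add_nodes_from(range(len(cp)))
    tree = cKDTree(cp.ca_coords)
    for i, j in tree.query_pairs(cutoff):
        G.add_edge(int(i), int(j))
    return ProteinGraph(coarse=cp, graph=G)


# ---------------------------------------------------------------------------
# Feature provider registry


@dataclass
class FeatureProvider:
    name: str
    dim: int
    func: object  # (pg, atoms, annotations) -> (N, dim)
    external_columns: tuple = ()  # annotation CSV columns for external mode


def _ann_lookup(pg, annotations, columns):
    """Pull per-residue values from the annotation table."""
    idx = annotations.set_index(["chain_id", "residue_id"])
    out = np.zeros((len(pg), len(columns)))
    for i, (chain, resid, _) in enumerate(pg.coarse.residue_labels):
        try:
            row = idx.loc[(chain, resid)]
        except KeyError:
            raise KeyError(f"annotation table is missing residue {chain}{resid}")
        out[i] = [row[c] for c in columns]
    return out


def _label_order(pg):
    """Node indices sorted by residue label -- invariant to input order."""
    return sorted(range(len(pg)), key=lambda i: pg.coarse.residue_labels[i])


def _dssp_external(pg, annotations):
    from .tables import DSSP_CLASSES
    idx = annotations.set_index(["chain_id", "residue_id"])
    out = np.zeros((len(pg), 8))
    for i, (chain, resid, _) in enumerate(pg.coarse.residue_labels):
        cls = str(idx.loc[(chain, resid)]["dssp_class"])
        out[i, DSSP_CLASSES.index(cls if cls in DSSP_CLASSES else "-")] = 1.0
    return out


def default_registry(mode: str = "internal") -> list:
    """The 39-dimensional default feature stack, in canonical order.

    ``mode`` selects internal computation or external annotation lookup for
    the providers that the original workflow delegated to external tools.
    """
    ext = mode == "external"

    def shell(key, dim):
        cache = {}

        def fn(pg, atoms, annotations):
            if ext:
                cols = ([f"pocketness_c{i}" for i in range(1, 6)]
                        if key == "pocketness_clust" else [key])
                return _ann_lookup(pg, annotations, cols)
            if id(pg) not in cache:
                cache.clear()
                cache[id(pg)] = rf.shell_probe_features(pg.coarse, atoms)
            val = cache[id(pg)][key]
            return val.reshape(len(pg), dim)
        return fn

    providers = [
        FeatureProvider("element_counts", 4,
                        lambda pg, a, an: rf.element_counts(pg.coarse, a)),
        FeatureProvider("molecular_mass", 1,
                        lambda pg, a, an: rf.molecular_mass(pg.coarse, a)),
        FeatureProvider("amino_type", 5,
                        lambda pg, a, an: rf.amino_type_onehot(pg.coarse)),
        FeatureProvider("hydrophobicity", 5,
                        lambda pg, a, an: rf.hydrophobicity(pg.coarse)),
        FeatureProvider("dssp", 8,
                        (lambda pg, a, an: _dssp_external(pg, an)) if ext else
                        (lambda pg, a, an: rf.secondary_structure_onehot(pg.coarse))),
        FeatureProvider("rel_asa_sasa", 2,
                        (lambda pg, a, an: _ann_lookup(pg, an, ["rel_asa", "sasa"]))
                        if ext else
                        (lambda pg, a, an: rf.sasa_features(pg.coarse, a))),
        FeatureProvider("acc_shell", 1, shell("acc_shell", 1)),
        FeatureProvider("pocketness", 1, shell("pocketness", 1)),
        FeatureProvider("pocketness_clust", 5, shell("pocketness_clust", 5)),
        FeatureProvider("r_inacc", 1, shell("r_inacc", 1)),
        FeatureProvider("opd_chirality", 2,
                        lambda pg, a, an: np.column_stack(
                            [rf.opd_chirality(pg.coarse, 5),
                             rf.opd_chirality(pg.coarse, 7)])),
        FeatureProvider("ollivier_ricci", 1,
                        lambda pg, a, an: gf.ollivier_ricci_nodes(pg.graph)[:, None]),
        FeatureProvider("forman_ricci", 1,
                        lambda pg, a, an: gf.forman_ricci_nodes(pg.graph)[:, None]),
        FeatureProvider("mfd", 1,
                        lambda pg, a, an: np.full(
                            (len(pg), 1), gf.box_counting_dimension(
                                pg.graph, node_order=_label_order(pg)))),
        FeatureProvider("gnm", 1,
                        lambda pg, a, an: gf.gnm_mobility(pg.graph)[:, None]),
    ]
    assert sum(p.dim for p in providers) == N_FEATURES
    return providers


def compute_node_features(pg: ProteinGraph, atoms=None, annotations=None,
                          registry=None) -> np.ndarray:
    """Assemble the raw (N, 39) node attribute matrix and attach it."""
    if registry is None:
        registry = default_registry("external" if annotations is not None
                                    else "internal")
    blocks = []
    for p in registry:
        block = np.asarray(p.func(pg, atoms, annotations), dtype=float)
        if block.shape != (len(pg), p.dim):
            raise ValueError(f"provider {p.name} returned shape {block.shape}, "
                             f"expected {(len(pg), p.dim)}")
        if not np.all(np.isfinite(block)):
            raise ValueError(f"provider {p.name} produced non-finite values")
        blocks.append(block)
    pg.node_attr_raw = np.hstack(blocks)
    return pg.node_attr_raw


# ---------------------------------------------------------------------------
# Continuous Weisfeiler-Lehman updates


def wl_update(pg: ProteinGraph, n_updates: int = DEFAULT_N_WL) -> np.ndarray:
    """Iterative neighbor-average update of node attributes.

    a^{i+1}(v) = 1/2 [ a^i(v) + (1/deg v) sum_{u in N(v)} a^i(u) ],
    with the neighbor term taken as zero for isolated nodes.  Returns the
    concatenation [a^0; a^1; ...; a^{n_updates}] and attaches it.
    """
    if pg.node_attr_raw is None:
        raise ValueError("raw node attributes not computed yet")
    A = pg.adjacency
    deg = A.sum(axis=1)
    inv_deg = np.where(deg > 0, 1.0 / np.maximum(deg, 1e-300), 0.0)
    reps = [pg.node_attr_raw]
    a = pg.node_attr_raw
    for _ in range(n_updates):
        a = 0.5 * (a + inv_deg[:, None] * (A @ a))
        reps.append(a)
    pg.node_attr_wl = np.hstack(reps)
    return pg.node_attr_wl


def featurize_protein(cp: CoarseProtein, atoms=None, annotations=None,
                      cutoff: float = DEFAULT_CUTOFF,
                      n_wl: int = DEFAULT_N_WL) -> ProteinGraph:
    """Build graph, compute raw features and WL-expand them, in one call."""
    pg = build_graph(cp, cutoff=cutoff)
    compute_node_features(pg, atoms=atoms, annotations=annotations)
    wl_update(pg, n_updates=n_wl)
    return pg
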