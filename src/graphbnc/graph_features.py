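"""Graph-theoretic node descriptors of the residue contact graph.

All quantities are computed on the unweighted 4.5 A CA contact graph:
Ollivier-Ricci and Forman-Ricci curvatures (averaged per node over
incident edges), the box-counting (multifractal) dimension of the graph,
and a Gaussian-network-model mobility proxy from the Laplacian
pseudoinverse.  They depend on connectivity only, never on absolute
coordinates.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
from scipy.optimize import linprog

logger = logging.getLogger(__name__)


def _wasserstein_uniform(G: nx.Graph, u, v) -> float:
    """W1 between uniform measures on the neighborhoods of u and v.

    Ground metric: shortest-path distance in G.  Solved exactly as a small
    transportation linear program.
    """
    Nu, Nv = list(G.neighbors(u)), list(G.neighbors(v))
    nu, nv = len(Nu), len(Nv)
    cost = np.array([[_pair_dist(G, a, b) for b in Nv] for a in Nu], dtype=float)
    c = cost.ravel()
    A_eq, b_eq = [], []
    for i in range(nu):
        row = np.zeros(nu * nv)
        row[i * nv:(i + 1) * nv] = 1
        A_eq.append(row)
        b_eq.append(1 / nu)
    for j in range(nv):
        row = np.zeros(nu * nv)
        row[j::nv] = 1
        A_eq.append(row)
        b_eq.append(1 / nv)
    res = linprog(c, A_eq=np.array(A_eq), b_eq=np.array(b_eq),
                  bounds=(0, None), method="highs")
    return float(res.fun)


_DIST_CACHE: dict = {}


def _pair_dist(G, a, b):
    cache = _DIST_CACHE.setdefault(id(G), {})
    if a not in cache:
        cache[a] = nx.single_source_shortest_path_length(G, a)
    return cache[a].get(b, 1e6)


def ollivier_ricci_edges(G: nx.Graph) -> dict:
    """Exact Ollivier-Ricci curvature per edge with uniform neighbor measures.

    kappa(u,v) = 1 - W1(mu_u, mu_v) / d(u,v), with d(u,v) = 1 on an edge.
    """
    _DIST_CACHE.pop(id(G), None)
    out = {}
    for u, v in G.edges():
        out[(u, v)] = 1.0 - _wasserstein_uniform(G, u, v)
    _DIST_CACHE.pop(id(G), None)
    return out


def ollivier_ricci_nodes(G: nx.Graph) -> np.ndarray:
    """Mean Ollivier-Ricci curvature of incident edges, per node."""
    edge_k = ollivier_ricci_edges(G)
    out = np.zeros(G.number_of_nodes())
    nodes = list(G.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    sums = np.zeros(len(nodes))
    counts = np.zeros(len(nodes))
    for (u, v), k in edge_k.items():
        sums[index[u]] += k
        sums[index[v]] += k
        counts[index[u]] += 1
        counts[index[v]] += 1
    mask = counts > 0
    out[mask] = sums[mask] / counts[mask]
    if not mask.all():
        logger.warning("isolated nodes present; their curvature is set to 0")
    return out


def forman_ricci_nodes(G: nx.Graph) -> np.ndarray:
    """Mean unweighted Forman-Ricci curvature of incident edges, per node.

    For a unit-weight graph the Forman curvature of edge (u,v) is
    4 - deg(u) - deg(v).
    """
    nodes = list(G.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    deg = dict(G.degree())
    sums = np.zeros(len(nodes))
    counts = np.zeros(len(nodes))
    for u, v in G.edges():
        f = 4.0 - deg[u] - deg[v]
        sums[index[u]] += f
        sums[index[v]] += f
        counts[index[u]] += 1
        counts[index[v]] += 1
    out = np.zeros(len(nodes))
    mask = counts > 0
    out[mask] = sums[mask] / counts[mask]
    return out


def box_counting_dimension(G: nx.Graph, max_radius: int | None = None,
                           node_order=None) -> float:
    """Box-counting (multifractal) dimension of the graph.

    Greedy covering with shortest-path balls of radius r for r = 1..diam;
    the dimension is minus the least-squares slope of log N(r) against
    log(2r + 1).  Graphs too small to fit a slope return 1.0.

    ``node_order`` fixes the greedy ball-seeding order (default: sorted
    node ids); pass a label-derived order to make the value invariant to
    node relabelling.
    """
    nodes = list(node_order) if node_order is not None else sorted(G.nodes())
    if len(nodes) < 2:
        return 1.0
    # true diameter of the largest-diameter component
    diam = 0
    for comp in nx.connected_components(G):
        if len(comp) >= 2:
            diam = max(diam, nx.diameter(G.subgraph(comp)))
    if max_radius is not None:
        diam = min(diam, max_radius)
    if diam < 2:
        return 1.0
    radii = np.arange(1, diam + 1)
    counts = []
    for r in radii:
        covered = set()
        n_boxes = 0
        for n in nodes:
            if n in covered:
                continue
            ball = nx.single_source_shortest_path_length(G, n, cutoff=r)
            covered.update(ball)
            n_boxes += 1
        counts.append(n_boxes)
    x = np.log(2 * radii + 1.0)
    y = np.log(np.array(counts, dtype=float))
    slope = np.polyfit(x, y, 1)[0]
    return float(-slope)


def gnm_mobility(G: nx.Graph) -> np.ndarray:
    """Diagonal of the Laplacian pseudoinverse, min-max scaled per graph.

    The GNM mean-square-fluctuation profile of the contact network: large
    values mark mobile, weakly constrained residues.
    """
    nodes = list(G.nodes())
    L = nx.laplacian_matrix(G, nodelist=nodes).toarray().astype(float)
    diag = np.diag(np.linalg.pinv(L, hermitian=True)).copy()
    lo, hi = diag.min(), diag.max()
    if hi - lo < 1e-12:
        return np.zeros(len(nodes))
    return (diag - lo) / (hi - lo)
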