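"""Weighted nodal and global network metrics.

Conventions, fixed once and used everywhere:

* Edge weights are density-like (larger = stronger), so the weight-to-length
  map for shortest paths is ``length = 1/weight``; absent edges have
  infinite length. The map is isolated in :func:`weight_to_length` so an
  alternative (e.g. -log w) could be plugged in.
* Clustering is the Onnela weighted coefficient: weights rescaled by the
  per-network maximum, triangle intensity via cube-root products. Nodes
  with degree < 2 get clustering 0.
* Betweenness is left unnormalized — the sum over unordered node pairs of
  the fraction of their shortest paths through the node. Group comparisons
  and rank-based hub criteria are invariant to the constant normalization
  factor.
* Disconnected pairs contribute 0 to efficiency sums (1/inf = 0), keeping
  global efficiency monotone under edge addition and bounded in [0, 1] for
  weights <= 1.
* The characteristic path length is defined as the inverse of global
  efficiency (a harmonic-mean convention), even when some pairs are
  disconnected; it is +inf for an empty network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

from .core import ConnectivityMatrix


@dataclass
class NodalMetrics:
    """Per-node metric vectors, all of length n (atlas order)."""

    strength: np.ndarray
    clustering: np.ndarray
    betweenness: np.ndarray
    regional_efficiency: np.ndarray
    vulnerability: np.ndarray
    degree: np.ndarray

    #: names of the float-valued metrics, in reporting order
    METRIC_NAMES = (
        "strength",
        "clustering",
        "betweenness",
        "regional_efficiency",
        "vulnerability",
    )

    def as_dict(self) -> dict[str, np.ndarray]:
        return {name: getattr(self, name) for name in self.METRIC_NAMES}


@dataclass
class GlobalMetrics:
    """Whole-network summary scalars."""

    global_strength: float
    global_clustering: float
    char_path_length: float
    global_betweenness: float
    global_vulnerability: float
    global_efficiency: float

    METRIC_NAMES = (
        "global_strength",
        "global_clustering",
        "char_path_length",
        "global_betweenness",
        "global_vulnerability",
        "global_efficiency",
    )

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self.METRIC_NAMES}


# ---------------------------------------------------------------------------
# nodal metrics


def strength(m: ConnectivityMatrix) -> np.ndarray:
    """Connection strength: the sum of each node's edge weights."""
    return m.weights.sum(axis=1)


def degrees(m: ConnectivityMatrix) -> np.ndarray:
    return (m.weights > 0).sum(axis=1)


def local_clustering(m: ConnectivityMatrix) -> np.ndarray:
    """Onnela weighted clustering coefficient per node.

    Weights are rescaled by the network-wide maximum (per subject, so each
    subject's coefficients live in [0, 1] independently), and triangle
    intensity is the geometric mean of the three rescaled weights:

        C_i = (1 / (k_i (k_i - 1))) * sum_{j,h} (w'_ij w'_ih w'_jh)^(1/3)

    Nodes with fewer than two connections get 0.
    """
    w = m.weights
    wmax = w.max()
    if wmax == 0:
        return np.zeros(m.n)
    cube = np.cbrt(w / wmax)
    # diag of cube^3 counts each ordered (j, h) pair once
    tri = np.einsum("ij,jh,hi->i", cube, cube, cube)
    k = degrees(m)
    denom = k * (k - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        c = np.where(denom > 0, tri / np.where(denom > 0, denom, 1), 0.0)
    return c


def weight_to_length(m: ConnectivityMatrix) -> np.ndarray:
    """Map weights to path lengths: 1/w for w > 0, +inf otherwise, 0 diagonal."""
    w = m.weights
    with np.errstate(divide="ignore"):
        length = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), np.inf)
    np.fill_diagonal(length, 0.0)
    return length


def shortest_path_lengths(m: ConnectivityMatrix) -> np.ndarray:
    """All-pairs shortest weighted path lengths d_ij (Dijkstra).

    d_ii = 0; +inf for pairs in different components.
    """
    w = m.weights
    with np.errstate(divide="ignore"):
        lengths = np.where(w > 0, 1.0 / np.where(w > 0, w, 1.0), 0.0)
    return dijkstra(csr_array(lengths), directed=False)


def betweenness(m: ConnectivityMatrix) -> np.ndarray:
    """Betweenness centrality on shortest weighted paths, unnormalized.

    B_i = sum over unordered pairs {h, j} (h, j != i) of the fraction of
    shortest h-j paths passing through i; tied shortest paths contribute
    fractionally via exact multiplicity counting (Brandes accumulation).
    """
    g = nx.Graph()
    g.add_nodes_from(range(m.n))
    ii, jj = np.nonzero(np.triu(m.weights, k=1))
    g.add_weighted_edges_from(
        ((int(i), int(j), 1.0 / m.weights[i, j]) for i, j in zip(ii, jj)),
        weight="length",
    )
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(m.n)])


def _efficiency_from_distances(d: np.ndarray) -> float:
    n = d.shape[0]
    if n < 2:
        return 0.0
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return float(inv.sum() / (n * (n - 1)))


def regional_efficiency(
    m: ConnectivityMatrix, distances: np.ndarray | None = None
) -> np.ndarray:
    """Nodal efficiency: mean inverse shortest path length to all other nodes.

    E_i = (1/(n-1)) * sum_{j != i} 1/d_ij, with 1/inf = 0.
    """
    d = shortest_path_lengths(m) if distances is None else distances
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (m.n - 1)


def global_efficiency(
    m: ConnectivityMatrix, distances: np.ndarray | None = None
) -> float:
    """Mean of 1/d_ij over all ordered pairs i != j (1/inf = 0)."""
    d = shortest_path_lengths(m) if distances is None else distances
    return _efficiency_from_distances(d)


def vulnerability(m: ConnectivityMatrix, eglob: float | None = None) -> np.ndarray:
    """Drop in global efficiency when a node and its edges are removed.

    Vul_i = E_glob(G) - E_glob(G \\ i), with the reduced efficiency computed
    over the remaining n-1 nodes. Removing a peripheral node can *raise*
    efficiency, so values may be negative.
    """
    if m.n < 3:
        raise ValueError("vulnerability requires at least 3 nodes")
    if eglob is None:
        eglob = global_efficiency(m)
    w = m.weights
    out = np.empty(m.n)
    keep = np.ones(m.n, dtype=bool)
    for i in range(m.n):
        keep[i] = False
        sub = w[np.ix_(keep, keep)]
        with np.errstate(divide="ignore"):
            lengths = np.where(sub > 0, 1.0 / np.where(sub > 0, sub, 1.0), 0.0)
        d = dijkstra(csr_array(lengths), directed=False)
        out[i] = eglob - _efficiency_from_distances(d)
        keep[i] = True
    return out


def nodal_metrics(m: ConnectivityMatrix) -> NodalMetrics:
    """Compute all per-node metrics, sharing one distance matrix."""
    d = shortest_path_lengths(m)
    eglob = _efficiency_from_distances(d)
    return NodalMetrics(
        strength=strength(m),
        clustering=local_clustering(m),
        betweenness=betweenness(m),
        regional_efficiency=regional_efficiency(m, distances=d),
        vulnerability=vulnerability(m, eglob=eglob),
        degree=degrees(m),
    )


# ---------------------------------------------------------------------------
# global summary


def global_summary(nm: NodalMetrics, m: ConnectivityMatrix) -> GlobalMetrics:
    """Summarize nodal metrics into whole-network scalars.

    Global strength/clustering/betweenness are nodal means; global
    vulnerability is the nodal maximum; the characteristic path length is
    1/E_glob (reported as +inf with a warning when E_glob = 0).
    """
    eglob = global_efficiency(m)
    if eglob > 0:
        cpl = 1.0 / eglob
    else:
        warnings.warn("global efficiency is 0; characteristic path length is +inf")
        cpl = np.inf
    return GlobalMetrics(
        global_strength=float(nm.strength.mean()),
        global_clustering=float(nm.clustering.mean()),
        char_path_length=cpl,
        global_betweenness=float(nm.betweenness.mean()),
        global_vulnerability=float(nm.vulnerability.max()),
        global_efficiency=eglob,
    )


def global_metrics(m: ConnectivityMatrix) -> GlobalMetrics:
    """Convenience: nodal metrics then global summary."""
    return global_summary(nodal_metrics(m), m)
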