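"""Weighted segregation and integration measures on thresholded SL networks.

Segregation: mean clustering coefficient C (weighted geometric-mean
triangles) and local efficiency E_loc (efficiency of each node's
neighborhood subgraph).  Integration: characteristic path length L and
global efficiency E_glob, both on shortest paths with edge length = 1/w.

Convention used throughout the pipeline: C and E_loc are computed on
max-normalized weights (the standard weighted-clustering convention, and
exactly scale invariant), while L and E_glob are computed on the raw SL_MAD
weights, whose magnitude is itself meaningful (SL <= 1 implies every edge
length >= 1, so E_glob stays in [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .errors import DisconnectedGraphError, EmptyNetworkError
from .threshold import ThresholdedSL, sl_mean

__all__ = [
    "WeightedGraph",
    "NetworkMetrics",
    "normalize_weights",
    "weighted_graph",
    "clustering_coefficient",
    "shortest_path_matrix",
    "char_path_length",
    "global_efficiency",
    "local_efficiency",
    "compute_all",
]


@dataclass
class WeightedGraph:
    """Symmetric nonnegative weight matrix with zero diagonal."""

    W: np.ndarray
    degrees: np.ndarray     # per-node count of nonzero edges

    @property
    def n(self) -> int:
        return self.W.shape[0]


def weighted_graph(values: np.ndarray) -> WeightedGraph:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError("weight matrix must be square")
    if np.any(values < 0):
        raise ValueError("weights must be nonnegative")
    W = values.copy()
    np.fill_diagonal(W, 0.0)
    return WeightedGraph(W=W, degrees=(W > 0).sum(axis=1))


def normalize_weights(t: ThresholdedSL | np.ndarray) -> WeightedGraph:
    """Graph with weights divided by the maximum weight (max edge -> 1)."""
    values = t.values if isinstance(t, ThresholdedSL) else np.asarray(t, float)
    g = weighted_graph(values)
    wmax = g.W.max()
    if wmax == 0:
        raise EmptyNetworkError("cannot normalize an empty network")
    g.W /= wmax
    return g


def clustering_coefficient(g: WeightedGraph) -> float:
    """Mean weighted clustering coefficient C.

    c_i = 2 t_i / (k_i (k_i - 1)) with t_i the geometric-mean triangle
    intensity around i; nodes with fewer than two edges contribute 0.
    """
    if g.n < 3:
        raise ValueError("clustering needs at least 3 nodes")
    W3 = np.cbrt(g.W)
    t = np.diag(W3 @ W3 @ W3) / 2.0
    k = g.degrees.astype(float)
    denom = k * (k - 1.0)
    c = np.where(denom > 0, 2.0 * t / np.where(denom > 0, denom, 1.0), 0.0)
    return float(c.mean())


def shortest_path_matrix(g: WeightedGraph) -> np.ndarray:
    """All-pairs weighted distances with edge length = 1/weight.

    Unreachable pairs get +inf; the diagonal is 0.
    """
    rows, cols = np.nonzero(g.W)
    lengths = csr_matrix((1.0 / g.W[rows, cols], (rows, cols)),
                         shape=g.W.shape)
    return shortest_path(lengths, method="D", directed=False)


def char_path_length(d: np.ndarray) -> tuple[float, float]:
    """Characteristic path length L and the fraction of unreachable pairs.

    L averages the finite off-diagonal distances; the disconnected-pair
    fraction is reported alongside rather than folded into the mean.
    """
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    n_off = int(off.sum())
    n_fin = int(finite.sum())
    if n_fin == 0:
        raise DisconnectedGraphError("no finite path between any node pair")
    return float(d[finite].mean()), float((n_off - n_fin) / n_off)


def global_efficiency(d: np.ndarray) -> float:
    """Average inverse shortest path length (1/inf counted as 0)."""
    n = d.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d > 0, d, np.inf),
                       0.0)
    return float(inv[off].mean())


def local_efficiency(g: WeightedGraph) -> float:
    """Mean nodal local efficiency E_loc.

    For node i with degree >= 2, paths between its neighbors are restricted
    to the neighborhood subgraph; e_i averages the cube-root intensity
    (w_ij * w_ih / d_jh(N_i))^(1/3) over ordered neighbor pairs.
    """
    if g.n < 3:
        raise ValueError("local efficiency needs at least 3 nodes")
    e = np.zeros(g.n)
    for i in range(g.n):
        nbrs = np.nonzero(g.W[i])[0]
        k = nbrs.size
        if k < 2:
            continue
        sub = weighted_graph(g.W[np.ix_(nbrs, nbrs)])
        d_sub = shortest_path_matrix(sub)
        with np.errstate(divide="ignore"):
            inv_d = np.where(np.isfinite(d_sub) & (d_sub > 0), 1.0 / d_sub, 0.0)
        w_i = g.W[i, nbrs]
        intensity = np.cbrt(np.outer(w_i, w_i) * inv_d)
        np.fill_diagonal(intensity, 0.0)
        e[i] = intensity.sum() / (k * (k - 1))
    return float(e.mean())


@dataclass
class NetworkMetrics:
    """Per-subject, per-condition scalar network summaries."""

    sl_mean: float
    C: float
    E_loc: float
    L: float
    E_glob: float
    edge_count: int
    disconnected_pair_fraction: float

    def as_dict(self) -> dict:
        return {"SL_MEAN": self.sl_mean, "C": self.C, "E_loc": self.E_loc,
                "L": self.L, "E_glob": self.E_glob,
                "edge_count": self.edge_count,
                "disconnected_pair_fraction": self.disconnected_pair_fraction}


def metrics_from_thresholded(t: ThresholdedSL) -> NetworkMetrics:
    """All five scalar measures of one thresholded SL network."""
    g_norm = normalize_weights(t)
    g_raw = weighted_graph(t.values)
    d = shortest_path_matrix(g_raw)
    L, frac = char_path_length(d)
    return NetworkMetrics(
        sl_mean=sl_mean(t),
        C=clustering_coefficient(g_norm),
        E_loc=local_efficiency(g_norm),
        L=L,
        E_glob=global_efficiency(d),
        edge_count=t.edge_count,
        disconnected_pair_fraction=frac,
    )


def compute_all(t_rest: ThresholdedSL,
                t_preh: ThresholdedSL) -> tuple[NetworkMetrics, NetworkMetrics]:
    """Metric records for the rest and prehension networks of one subject."""
    if t_rest.values.shape != t_preh.values.shape:
        raise ValueError("condition matrices differ in shape")
    return metrics_from_thresholded(t_rest), metrics_from_thresholded(t_preh)
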