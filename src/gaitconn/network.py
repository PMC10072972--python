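"""Weighted brain-graph construction and metrics.

Graphs are dense symmetric weight matrices (PLI values in [0, 1]) with a
zero diagonal.  Metric conventions follow the Brain Connectivity Toolbox:

* edge distance = 1 / weight (no edge → infinite distance);
* global efficiency = mean over ordered node pairs of 1 / shortest-path
  distance, with disconnected pairs contributing 0;
* characteristic path length = mean shortest-path distance over
  *connected* ordered pairs;
* weighted clustering / transitivity use Onnela triangle intensities,
  the geometric means of the triangle's weights after normalizing the
  matrix by its maximum weight;
* eigenvector centrality is the non-negative unit-norm leading
  eigenvector of the weight matrix (power iteration, tol 1e-10).

Metrics are computed on the *full* weighted matrix; the 50 %-of-strongest
edge threshold is a display convention applied only to exported or
plotted graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sstats
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra

from .connectivity import ConnectivityTensor

__all__ = [
    "WeightedGraph",
    "GlobalMetrics",
    "LocalMetrics",
    "threshold_edges",
    "global_metrics",
    "local_metrics",
    "region_means",
    "timecourse_global",
    "plot_network",
]

GLOBAL_METRIC_NAMES = ("global_efficiency", "transitivity", "char_path_length")
LOCAL_METRIC_NAMES = ("local_efficiency", "strength", "clustering_coeff",
                      "eigenvector_centrality")


def _check_weights(w: np.ndarray) -> np.ndarray:
    w = np.asarray(w, dtype=float)
    if w.ndim != 2 or w.shape[0] != w.shape[1]:
        raise ValueError("weight matrix must be square")
    if np.any(w < 0):
        raise ValueError("negative weights are not allowed")
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("weight matrix must be symmetric")
    w = 0.5 * (w + w.T)
    np.fill_diagonal(w, 0.0)
    return w


@dataclass
class WeightedGraph:
    """Symmetric weighted graph over the electrode grid."""

    weights: np.ndarray
    node_labels: list[str] = field(default_factory=list)
    region_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = _check_weights(self.weights)
        if not self.node_labels:
            self.node_labels = [f"ch{i:02d}" for i in range(self.n_nodes)]

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]


@dataclass
class GlobalMetrics:
    global_efficiency: float
    transitivity: float
    char_path_length: float
    n_disconnected_pairs: int = 0

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.global_efficiency, self.transitivity, self.char_path_length)


@dataclass
class LocalMetrics:
    local_efficiency: np.ndarray
    strength: np.ndarray
    clustering_coeff: np.ndarray
    eigenvector_centrality: np.ndarray

    def by_name(self, name: str) -> np.ndarray:
        if name not in LOCAL_METRIC_NAMES:
            raise ValueError(f"unknown local metric {name!r}")
        return getattr(self, name)


def threshold_edges(g: WeightedGraph, fraction: float = 0.5) -> WeightedGraph:
    """Keep only edges stronger than ``fraction`` of the strongest edge.

    Surviving edges keep their original weight.  Used for display and
    export; metrics are computed on the unthresholded matrix.
    """
    if not (0.0 <= fraction < 1.0):
        raise ValueError("fraction must lie in [0, 1)")
    w = g.weights.copy()
    cut = fraction * w.max()
    w[w <= cut] = 0.0
    return WeightedGraph(w, list(g.node_labels), dict(g.region_map))


def _shortest_distances(w: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path distances with edge length 1/weight."""
    n = w.shape[0]
    ii, jj = np.nonzero(w)
    d = csr_matrix((1.0 / w[ii, jj], (ii, jj)), shape=(n, n))
    return dijkstra(d, directed=False)


def _triangle_terms(w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Onnela triangle intensity t_i and binary degree k_i per node."""
    wmax = w.max()
    if wmax == 0:
        return np.zeros(w.shape[0]), np.zeros(w.shape[0])
    cube = np.cbrt(w / wmax)
    t = np.diagonal(cube @ cube @ cube) / 2.0
    k = (w > 0).sum(axis=1).astype(float)
    return t, k


def global_metrics(g: WeightedGraph) -> GlobalMetrics:
    """Global efficiency, weighted transitivity, characteristic path length."""
    w = g.weights
    n = g.n_nodes
    if n < 2:
        raise ValueError("need at least 2 nodes")
    d = _shortest_distances(w)
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(d) & off
    inv = np.zeros_like(d)
    inv[finite] = 1.0 / d[finite]
    eglob = float(inv[off].mean())
    n_disc = int(np.sum(off & ~finite))
    if n_disc:
        warnings.warn(f"{n_disc} disconnected ordered pairs excluded from L")
    L = float(d[finite].mean()) if finite.any() else np.inf
    t, k = _triangle_terms(w)
    denom = float(np.sum(k * (k - 1)))
    trans = float(2.0 * t.sum() / denom) if denom > 0 else 0.0
    return GlobalMetrics(eglob, trans, L, n_disc)


def _eigenvector_centrality(w: np.ndarray, tol: float = 1e-10,
                            max_iter: int = 100000) -> np.ndarray:
    """Leading eigenvector by power iteration, non-negative, unit norm."""
    n = w.shape[0]
    if w.max() == 0:
        return np.zeros(n)
    v = np.full(n, 1.0 / np.sqrt(n))
    for _ in range(max_iter):
        nv = w @ v
        norm = np.linalg.norm(nv)
        if norm == 0:
            return np.zeros(n)
        nv /= norm
        if np.linalg.norm(nv - v) < tol:
            v = nv
            break
        v = nv
    v = np.abs(v)
    return v / np.linalg.norm(v)


def local_metrics(g: WeightedGraph) -> LocalMetrics:
    """Per-node local efficiency, strength, clustering, eigenvector centrality.

    Local efficiency of node i is the global efficiency of the subgraph
    induced by i's neighbors (with original weights).  Isolated nodes get
    0 for strength, clustering and local efficiency.
    """
    w = g.weights
    n = g.n_nodes
    strength = w.sum(axis=1)
    t, k = _triangle_terms(w)
    cc = np.zeros(n)
    mask = k > 1
    cc[mask] = 2.0 * t[mask] / (k[mask] * (k[mask] - 1.0))
    eloc = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(w[i])
        if len(nbrs) < 2:
            continue
        sub = w[np.ix_(nbrs, nbrs)]
        d = _shortest_distances(sub)
        m = len(nbrs)
        off = ~np.eye(m, dtype=bool)
        finite = np.isfinite(d) & off
        inv = np.zeros_like(d)
        inv[finite] = 1.0 / d[finite]
        eloc[i] = float(inv[off].mean())
    ec = _eigenvector_centrality(w)
    return LocalMetrics(eloc, strength, cc, ec)


def region_means(values: np.ndarray, node_labels: list[str],
                 region_map: dict[str, str]) -> dict[str, float]:
    """Average a per-node metric within each brain region."""
    out: dict[str, list[float]] = {}
    for v, label in zip(values, node_labels):
        region = region_map.get(label)
        if region is None:
            continue
        out.setdefault(region, []).append(float(v))
    return {r: float(np.mean(vals)) for r, vals in out.items()}


def timecourse_global(
    tensor: ConnectivityTensor, ci_level: float = 0.95
) -> "pd.DataFrame":
    """Per-window global metrics averaged within condition, with CIs.

    Metrics are computed per epoch per window on the full weighted PLI
    matrix, then averaged over the epochs of each condition.  The CI is
    the t-based confidence interval of the mean; for single-epoch
    conditions it is undefined and flagged as NaN.
    """
    import pandas as pd

    if tensor.values.shape[0] == 0:
        raise ValueError("empty connectivity tensor")
    n_ep, n_win = tensor.values.shape[:2]
    vals = np.zeros((n_ep, n_win, 3))
    for e in range(n_ep):
        for wdx in range(n_win):
            gm = global_metrics(WeightedGraph(tensor.values[e, wdx]))
            vals[e, wdx] = gm.as_tuple()
    labels = np.asarray(tensor.conditions, dtype=str)
    rows = []
    for cond in dict.fromkeys(labels):
        sub = vals[labels == cond]
        m = sub.shape[0]
        mean = sub.mean(axis=0)
        if m > 1:
            sem = sub.std(axis=0, ddof=1) / np.sqrt(m)
            half = sem * sstats.t.ppf(0.5 + ci_level / 2.0, df=m - 1)
        else:
            half = np.full_like(mean, np.nan)
        for wdx in range(n_win):
            for mi, name in enumerate(GLOBAL_METRIC_NAMES):
                rows.append(
                    {
                        "condition": cond,
                        "window": wdx,
                        "t_start_s": tensor.grid.start_offsets_s[wdx],
                        "metric": name,
                        "value": mean[wdx, mi],
                        "ci_half_width": half[wdx, mi],
                        "n_epochs": m,
                    }
                )
    return pd.DataFrame(rows)


def plot_network(g: WeightedGraph, threshold_fraction: float = 0.5, ax=None):
    """Simple 2-D rendering: nodes grouped by region, edges above threshold.

    Node size tracks the thresholded degree, edge width/color the weight.
    Requires matplotlib.
    """
    import matplotlib.pyplot as plt

    gt = threshold_edges(g, threshold_fraction)
    n = g.n_nodes
    ang = 2 * np.pi * np.arange(n) / n
    xy = np.c_[np.cos(ang), np.sin(ang)]
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    wmax = gt.weights.max() or 1.0
    for i in range(n):
        for j in range(i + 1, n):
            wij = gt.weights[i, j]
            if wij > 0:
                ax.plot(
                    xy[[i, j], 0], xy[[i, j], 1],
                    color=plt.cm.viridis(wij / wmax),
                    lw=0.5 + 2.5 * wij / wmax, zorder=1,
                )
    deg = (gt.weights > 0).sum(axis=1)
    ax.scatter(xy[:, 0], xy[:, 1], s=20 + 15 * deg, c="tab:red", zorder=2)
    for i, label in enumerate(g.node_labels):
        ax.annotate(label, xy[i] * 1.08, ha="center", va="center", fontsize=6)
    ax.set_aspect("equal")
    ax.axis("off")
    return ax
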