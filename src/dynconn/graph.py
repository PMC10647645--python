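"""Ten binary undirected graph measures, from first principles.

Families: segregation (clustering coefficient, transitivity), integration
(global efficiency, characteristic path length), centrality (degree,
betweenness, eccentricity, diameter), resilience (degree assortativity,
k-core coreness).

Low binarization thresholds on small networks frequently disconnect
graphs, so the disconnected-graph conventions are explicit and follow the
Brain Connectivity Toolbox style:

* characteristic path length averages *finite* distances only (NaN when no
  pair of distinct nodes is reachable);
* global efficiency treats unreachable pairs as efficiency 0 (1/inf);
* eccentricity is the maximum *finite* distance from a node (0 for an
  isolated node); diameter is the maximum eccentricity;
* assortativity is NaN when the end-node degree variance is zero (e.g. any
  regular graph, or no edges at all);
* nodes with degree < 2 contribute clustering 0 and are kept in the mean;
* betweenness is unnormalized (raw pair-dependency counts).
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .fc import DEFAULT_THRESHOLDS, BinaryGraph, FcWindowSeries, binarize
from .networks import NetworkDefinition

METRIC_NAMES = (
    "clustering",
    "transitivity",
    "efficiency",
    "char_path_length",
    "degree",
    "betweenness",
    "eccentricity",
    "diameter",
    "assortativity",
    "kcore",
)

#: metrics that are nodal quantities reduced over nodes (the reduction is
#: configurable); the rest are inherently global
NODAL_METRICS = ("clustering", "degree", "betweenness", "eccentricity", "kcore")

_DISTANCE_METRICS = frozenset(
    {"efficiency", "char_path_length", "eccentricity", "diameter"}
)


def _as_adjacency(adj) -> np.ndarray:
    a = adj.adjacency if isinstance(adj, BinaryGraph) else np.asarray(adj)
    a = a.astype(np.int8, copy=False)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("adjacency must be square")
    return a


def bfs_distances(adj) -> np.ndarray:
    """All-pairs shortest-path lengths (np.inf across components)."""
    a = _as_adjacency(adj).astype(bool)
    n = a.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0.0)
    frontier = np.eye(n, dtype=bool)
    visited = frontier.copy()
    d = 0
    while frontier.any():
        d += 1
        frontier = (frontier @ a) & ~visited
        dist[frontier] = d
        visited |= frontier
    return dist


def clustering_and_transitivity(adj) -> tuple[float, float, np.ndarray]:
    """(mean nodal clustering, transitivity, nodal clustering values)."""
    a = _as_adjacency(adj).astype(np.int64)
    k = a.sum(axis=1)
    # t_i = number of triangles through node i
    t = np.einsum("ij,jk,ki->i", a, a, a) / 2.0
    denom = k * (k - 1)
    nodal = np.where(denom > 0, 2.0 * t / np.maximum(denom, 1), 0.0)
    total = denom.sum()
    transitivity = float(2.0 * t.sum() / total) if total > 0 else 0.0
    return float(nodal.mean()), transitivity, nodal


def integration_metrics(distances: np.ndarray) -> tuple[float, float]:
    """(characteristic path length, global efficiency) from a distance
    matrix; see the module docstring for disconnection conventions."""
    d = np.asarray(distances, dtype=float)
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    vals = d[off]
    finite = np.isfinite(vals)
    cpl = float(vals[finite].mean()) if finite.any() else float("nan")
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(vals), 1.0 / vals, 0.0)
    eff = float(inv.mean()) if n > 1 else 0.0
    return cpl, eff


def betweenness_nodal(adj) -> np.ndarray:
    """Unnormalized undirected betweenness (Brandes accumulation).

    Pair dependencies exclude endpoints; each unordered pair is counted
    once; unreachable pairs contribute nothing.
    """
    a = _as_adjacency(adj)
    n = a.shape[0]
    nbrs = [np.flatnonzero(a[i]).tolist() for i in range(n)]
    bc = np.zeros(n)
    for s in range(n):
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in nbrs[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0  # each unordered pair visited from both endpoints


def eccentricity_and_diameter(distances: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(mean eccentricity, diameter, nodal eccentricities) over finite
    distances; isolated nodes have eccentricity 0."""
    d = np.asarray(distances, dtype=float)
    masked = np.where(np.isfinite(d), d, 0.0)
    nodal = masked.max(axis=1)
    return float(nodal.mean()), float(nodal.max()), nodal


def assortativity(adj) -> float:
    """Newman degree assortativity: Pearson correlation of end-node
    degrees over all edges counted in both directions; NaN when the graph
    has no edges or zero end-degree variance (regular graphs)."""
    a = _as_adjacency(adj)
    i, j = np.nonzero(np.triu(a, 1))
    if i.size == 0:
        return float("nan")
    k = a.sum(axis=1).astype(float)
    x = np.concatenate([k[i], k[j]])
    y = np.concatenate([k[j], k[i]])
    vx = x.var()
    if vx < 1e-15:
        return float("nan")
    return float(((x - x.mean()) * (y - y.mean())).mean() / vx)


def kcore_nodal(adj) -> np.ndarray:
    """Coreness of each node via iterative minimum-degree peeling."""
    a = _as_adjacency(adj).astype(np.int64)
    n = a.shape[0]
    deg = a.sum(axis=1)
    alive = np.ones(n, dtype=bool)
    core = np.zeros(n, dtype=np.int64)
    k = 0
    remaining = n
    while remaining:
        candidates = np.flatnonzero(alive & (deg <= k))
        if candidates.size == 0:
            k += 1
            continue
        for v in candidates.tolist():
            if not alive[v]:
                continue
            stack = [v]
            while stack:
                u = stack.pop()
                if not alive[u] or deg[u] > k:
                    continue
                alive[u] = False
                core[u] = k
                remaining -= 1
                for w in np.flatnonzero(a[u]).tolist():
                    if alive[w]:
                        deg[w] -= 1
                        if deg[w] <= k:
                            stack.append(w)
    return core


@dataclass(frozen=True)
class MetricVector:
    """The ten graph measures for one binary network graph."""

    clustering: float
    transitivity: float
    efficiency: float
    char_path_length: float
    degree: float
    betweenness: float
    eccentricity: float
    diameter: float
    assortativity: float
    kcore: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


def metric_vector(
    adj,
    metrics: Sequence[str] | None = None,
    reduction: str = "mean",
) -> MetricVector:
    """Compute the ten graph measures (or a subset) for one adjacency.

    Parameters
    ----------
    adj
        Symmetric 0/1 adjacency with zero diagonal, or a BinaryGraph.
    metrics
        Optional subset of :data:`METRIC_NAMES` to compute; the remaining
        fields are NaN.  Useful when only a few measures are needed on
        many windows.
    reduction
        Nodal-to-network reduction for nodal metrics: ``"mean"`` (default),
        ``"max"`` or ``"sum"``.
    """
    a = _as_adjacency(adj)
    n = a.shape[0]
    if n < 2:
        raise ValueError(f"network with {n} node(s) is too small for graph metrics")
    wanted = set(METRIC_NAMES if metrics is None else metrics)
    unknown = wanted - set(METRIC_NAMES)
    if unknown:
        raise ValueError(f"unknown metric(s): {sorted(unknown)}")
    if reduction not in ("mean", "max", "sum"):
        raise ValueError("reduction must be one of: mean, max, sum")
    red = {"mean": np.mean, "max": np.max, "sum": np.sum}[reduction]

    out: dict[str, float] = {name: float("nan") for name in METRIC_NAMES}
    if wanted & {"clustering", "transitivity"}:
        c_mean, trans, c_nodal = clustering_and_transitivity(a)
        out["clustering"] = float(red(c_nodal))
        out["transitivity"] = trans
    if wanted & _DISTANCE_METRICS:
        d = bfs_distances(a)
        if wanted & {"char_path_length", "efficiency"}:
            out["char_path_length"], out["efficiency"] = integration_metrics(d)
        if wanted & {"eccentricity", "diameter"}:
            _, out["diameter"], ecc_nodal = eccentricity_and_diameter(d)
            out["eccentricity"] = float(red(ecc_nodal))
    if "degree" in wanted:
        out["degree"] = float(red(a.sum(axis=1).astype(float)))
    if "betweenness" in wanted:
        out["betweenness"] = float(red(betweenness_nodal(a)))
    if "assortativity" in wanted:
        out["assortativity"] = assortativity(a)
    if "kcore" in wanted:
        out["kcore"] = float(red(kcore_nodal(a).astype(float)))
    return MetricVector(**out)


class GraphMetricsExtractor(BaseEstimator, TransformerMixin):
    """Transformer from FC window series to a long-format metric table.

    For every (window, threshold, network) cell, the FC matrix is
    restricted to the network's ROIs, binarized (strict ``>`` threshold;
    negative/NaN correlations excluded) and measured.

    Parameters
    ----------
    network_map
        ROI-to-network mapping; metrics are computed per named network and
        for the all-ROI ``"brain"`` network.
    thresholds
        Increasing binarization thresholds in (0, 1).
    networks
        Optional subset of network names (``"brain"`` allowed).
    metrics
        Optional subset of metric names.
    reduction
        Nodal-to-network reduction (see :func:`metric_vector`).
    """

    def __init__(
        self,
        network_map: NetworkDefinition,
        thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
        networks: Sequence[str] | None = None,
        metrics: Sequence[str] | None = None,
        reduction: str = "mean",
    ):
        self.network_map = network_map
        self.thresholds = thresholds
        self.networks = networks
        self.metrics = metrics
        self.reduction = reduction

    def _check_params(self):
        thr = [float(t) for t in self.thresholds]
        if any(not 0 < t < 1 for t in thr):
            raise ValueError("thresholds must lie in (0, 1)")
        if any(b <= a for a, b in zip(thr, thr[1:])):
            raise ValueError("thresholds must be strictly increasing")
        nets = (
            list(self.networks)
            if self.networks is not None
            else list(self.network_map.names_with_brain)
        )
        return thr, nets

    def fit(self, X=None, y=None):
        self._check_params()
        return self

    def transform(self, X: Iterable[FcWindowSeries] | FcWindowSeries) -> pd.DataFrame:
        thr, nets = self._check_params()
        series_list = [X] if isinstance(X, FcWindowSeries) else list(X)
        metric_cols = list(METRIC_NAMES if self.metrics is None else self.metrics)
        rows = []
        for fcs in series_list:
            net_idx = {
                net: self.network_map.indices(net, fcs.roi_labels) for net in nets
            }
            for w in range(fcs.n_windows):
                mat = fcs.windows[w]
                for net in nets:
                    idx = net_idx[net]
                    sub = mat[np.ix_(idx, idx)]
                    for t in thr:
                        g = binarize(sub, t, window_index=w)
                        mv = metric_vector(
                            g.adjacency, metrics=metric_cols, reduction=self.reduction
                        )
                        for m in metric_cols:
                            rows.append(
                                (
                                    fcs.participant_id,
                                    fcs.group,
                                    fcs.condition,
                                    fcs.epoch_index,
                                    net,
                                    t,
                                    w,
                                    m,
                                    getattr(mv, m),
                                )
                            )
        return pd.DataFrame(
            rows,
            columns=[
                "participant_id",
                "group",
                "condition",
                "epoch_index",
                "network",
                "threshold",
                "window",
                "metric",
                "value",
            ],
        )
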