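"""Independent brute-force oracles for the graph measures.

Deliberately naive implementations (Floyd–Warshall, exhaustive triangle
and shortest-path enumeration, repeated k-pruning) kept separate from the
package so oracle and implementation share no code path.
"""

import itertools

import numpy as np


def floyd_warshall(adj):
    a = np.asarray(adj)
    n = a.shape[0]
    d = np.where(a > 0, 1.0, np.inf)
    np.fill_diagonal(d, 0.0)
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def triangle_clustering(adj):
    """Nodal clustering by enumerating all node triples."""
    a = np.asarray(adj)
    n = a.shape[0]
    tri = np.zeros(n)
    for i, j, k in itertools.combinations(range(n), 3):
        if a[i, j] and a[j, k] and a[i, k]:
            tri[i] += 1
            tri[j] += 1
            tri[k] += 1
    deg = a.sum(axis=1)
    denom = deg * (deg - 1) / 2
    nodal = np.where(denom > 0, tri / np.maximum(denom, 1), 0.0)
    total = denom.sum()
    transitivity = tri.sum() / total if total > 0 else 0.0
    return nodal, float(transitivity)


def all_shortest_paths(adj, s, t):
    """Every shortest s->t path, by breadth-limited DFS enumeration."""
    a = np.asarray(adj)
    d = floyd_warshall(a)
    if not np.isfinite(d[s, t]) or s == t:
        return []
    target_len = int(d[s, t])
    paths = []

    def extend(path):
        v = path[-1]
        if v == t:
            paths.append(list(path))
            return
        if len(path) - 1 == target_len:
            return
        for w in np.flatnonzero(a[v]):
            # only steps that stay on some shortest path
            if d[s, w] == len(path) and d[w, t] == target_len - len(path):
                extend(path + [int(w)])

    extend([s])
    return paths


def betweenness_by_enumeration(adj):
    """Unnormalized betweenness from an explicit list of all shortest
    paths of every unordered pair (endpoints excluded)."""
    a = np.asarray(adj)
    n = a.shape[0]
    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = all_shortest_paths(a, s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                bc[v] += 1.0 / len(paths)
    return bc


def coreness_by_pruning(adj):
    """Coreness via, for each k, repeatedly deleting nodes of degree < k."""
    a = np.asarray(adj).astype(int)
    n = a.shape[0]
    core = np.zeros(n, dtype=int)
    for k in range(1, n):
        alive = np.ones(n, dtype=bool)
        changed = True
        while changed:
            changed = False
            deg = (a * alive).sum(axis=1)
            kill = alive & (deg < k)
            if kill.any():
                alive[kill] = False
                changed = True
        core[alive] = k
        if not alive.any():
            break
    return core


def assortativity_by_edge_list(adj):
    a = np.asarray(adj)
    deg = a.sum(axis=1).astype(float)
    xs, ys = [], []
    n = a.shape[0]
    for i in range(n):
        for j in range(n):
            if i != j and a[i, j]:
                xs.append(deg[i])
                ys.append(deg[j])
    if not xs:
        return float("nan")
    x = np.array(xs)
    y = np.array(ys)
    if x.var() < 1e-15:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def rank_then_pearson(data):
    """Independent Spearman oracle: explicit midranks, then the Pearson
    product-moment formula."""
    x = np.asarray(data, dtype=float)
    n_roi, n_s = x.shape
    ranks = np.empty_like(x)
    for i in range(n_roi):
        order = np.argsort(x[i], kind="stable")
        r = np.empty(n_s)
        r[order] = np.arange(1, n_s + 1, dtype=float)
        # midranks for ties
        vals, inv, counts = np.unique(x[i], return_inverse=True, return_counts=True)
        for v_idx in np.flatnonzero(counts > 1):
            sel = inv == v_idx
            r[sel] = r[sel].mean()
        ranks[i] = r
    out = np.eye(n_roi)
    for i in range(n_roi):
        for j in range(i + 1, n_roi):
            xi = ranks[i] - ranks[i].mean()
            xj = ranks[j] - ranks[j].mean()
            denom = np.sqrt((xi**2).sum() * (xj**2).sum())
            out[i, j] = out[j, i] = (xi * xj).sum() / denom if denom > 0 else np.nan
    return out
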