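"""Independent brute-force oracles used to validate the feature code.

Everything here is deliberately naive (Floyd-Warshall, exhaustive subset
enumeration, explicit pair counting) and shares no code path with the
package implementation it checks.
"""

from __future__ import annotations

import itertools

import numpy as np


def floyd_warshall(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest hop distances from a boolean adjacency matrix."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    d[adj.astype(bool)] = 1.0
    for k in range(n):
        d = np.minimum(d, d[:, k:k + 1] + d[k:k + 1, :])
    return d


def shortest_path_counts(adj: np.ndarray, dist: np.ndarray) -> np.ndarray:
    """sigma[s, t] = number of shortest s-t paths (DP over distance layers)."""
    n = adj.shape[0]
    sigma = np.zeros((n, n))
    np.fill_diagonal(sigma, 1.0)
    for s in range(n):
        order = np.argsort(dist[s], kind="stable")
        for t in order:
            if t == s or not np.isfinite(dist[s, t]):
                continue
            preds = [u for u in range(n) if adj[u, t] and dist[s, u] == dist[s, t] - 1]
            sigma[s, t] = sum(sigma[s, u] for u in preds)
    return sigma


def total_betweenness_sum(adj: np.ndarray) -> float:
    """Sum over v of sum over unordered pairs {s,t}, s != v != t, of
    sigma_st(v)/sigma_st."""
    n = adj.shape[0]
    dist = floyd_warshall(adj)
    sigma = shortest_path_counts(adj, dist)
    total = 0.0
    for v in range(n):
        for s in range(n):
            for t in range(s + 1, n):
                if v in (s, t) or not np.isfinite(dist[s, t]) or sigma[s, t] == 0:
                    continue
                if dist[s, v] + dist[v, t] == dist[s, t]:
                    total += sigma[s, v] * sigma[v, t] / sigma[s, t]
    return total


def total_harmonic_sum(adj: np.ndarray) -> float:
    dist = floyd_warshall(adj)
    n = adj.shape[0]
    total = 0.0
    for v in range(n):
        for u in range(n):
            if u != v and np.isfinite(dist[v, u]) and dist[v, u] > 0:
                total += 1.0 / dist[v, u]
    return total


def maximal_cliques_exhaustive(adj: np.ndarray) -> int:
    """Count maximal cliques by enumerating every vertex subset (n <= ~14)."""
    n = adj.shape[0]
    cliques = []
    for r in range(1, n + 1):
        for sub in itertools.combinations(range(n), r):
            if all(adj[a, b] for a, b in itertools.combinations(sub, 2)):
                cliques.append(set(sub))
    count = 0
    for c in cliques:
        if not any(c < other for other in cliques):
            count += 1
    return count


def average_clustering_cube(adj: np.ndarray) -> float:
    """Mean local clustering via the diagonal of A^3 (twice the triangle
    count at each vertex)."""
    a = adj.astype(float)
    n = a.shape[0]
    if n == 0:
        return 0.0
    deg = a.sum(axis=1)
    tri2 = np.diagonal(a @ a @ a)  # 2 * triangles through v
    cv = np.zeros(n)
    mask = deg >= 2
    cv[mask] = tri2[mask] / (deg[mask] * (deg[mask] - 1))
    return float(cv.mean())


def largest_component_indices(adj: np.ndarray) -> list[int]:
    comps = union_find_components(adj)
    best = max(set(comps), key=lambda c: (comps == c).sum())
    return [i for i in range(adj.shape[0]) if comps[i] == best]


def union_find_components(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if adj[i, j]:
                parent[find(i)] = find(j)
    return np.array([find(i) for i in range(n)])


def diameter_radius_apl(adj: np.ndarray) -> tuple[float, float, float]:
    """(diameter, radius, mean ordered-pair distance) on the largest
    connected component."""
    idx = largest_component_indices(adj)
    if len(idx) <= 1:
        return 0.0, 0.0, 0.0
    sub = adj[np.ix_(idx, idx)]
    d = floyd_warshall(sub)
    ecc = d.max(axis=1)
    m = len(idx)
    return float(ecc.max()), float(ecc.min()), float(d.sum() / (m * (m - 1)))


def lambda2_dense(weights: np.ndarray) -> float:
    """Second-smallest eigenvalue of L = D - W on the largest component."""
    idx = largest_component_indices(weights > 0)
    if len(idx) <= 1:
        return 0.0
    w = weights[np.ix_(idx, idx)].astype(float)
    lap = np.diag(w.sum(axis=1)) - w
    return float(np.sort(np.linalg.eigvalsh(lap))[1])


def density_simple(adj: np.ndarray) -> float:
    n = adj.shape[0]
    if n <= 1:
        return 0.0
    e = int(np.triu(adj, k=1).sum())
    return 2.0 * e / (n * (n - 1))


def cliffs_delta_pairs(x, y) -> float:
    gt = lt = 0
    for xi in x:
        for yj in y:
            if xi > yj:
                gt += 1
            elif xi < yj:
                lt += 1
    return (gt - lt) / (len(x) * len(y))


def visibility_edges_cubic(x: np.ndarray) -> set[tuple[int, int]]:
    """Natural-visibility edge set by the O(N^3) definition."""
    n = len(x)
    edges = set()
    for a in range(n):
        for b in range(a + 1, n):
            visible = True
            for c in range(a + 1, b):
                if x[c] >= x[a] + (x[b] - x[a]) * (c - a) / (b - a):
                    visible = False
                    break
            if visible:
                edges.add((a, b))
    return edges


def balanced_accuracy_confusion(y_true, y_pred) -> float:
    """Mean per-class recall from an explicit confusion matrix, averaged
    over classes present in y_true."""
    classes = sorted(set(y_true))
    recalls = []
    for c in classes:
        tp = sum(1 for t, p in zip(y_true, y_pred) if t == c and p == c)
        n = sum(1 for t in y_true if t == c)
        recalls.append(tp / n)
    return float(np.mean(recalls))
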