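"""Independent brute-force oracles used to validate the implementation.

These are deliberately naive (exhaustive enumeration, term-by-term series,
counting-based ranks) and share no code path with the package.
"""

from __future__ import annotations

import numpy as np


def enumerate_simple_paths(adj: np.ndarray, src: int, dst: int):
    """All simple paths src -> dst by exhaustive DFS (tiny graphs only)."""
    n = adj.shape[0]
    paths = []

    def walk(node, visited, path):
        if node == dst:
            paths.append(list(path))
            return
        for nxt in range(n):
            if adj[node, nxt] and nxt not in visited:
                visited.add(nxt)
                path.append(nxt)
                walk(nxt, visited, path)
                path.pop()
                visited.remove(nxt)

    walk(src, {src}, [src])
    return paths


def oracle_standard_measures(adj: np.ndarray, unreachable_cap: float | None = None):
    """Standard topological measures by exhaustive path enumeration.

    Returns dict with s, jaccard (matrices) and closeness, betweenness,
    clustering, degree (vectors). Conventions: shortest paths in edges,
    unreachable pairs capped at N, isolated nodes closeness 0, open
    neighborhoods, all-geodesic betweenness with endpoints excluded
    (unordered pairs), standard clustering coefficient.
    """
    n = adj.shape[0]
    cap = float(n) if unreachable_cap is None else unreachable_cap
    deg = adj.sum(axis=1).astype(float)
    s = np.full((n, n), cap)
    np.fill_diagonal(s, 0.0)
    geod = {}  # (i, j) i<j -> list of geodesic paths
    for i in range(n):
        for j in range(i + 1, n):
            paths = enumerate_simple_paths(adj, i, j)
            if paths:
                d = min(len(p) - 1 for p in paths)
                s[i, j] = s[j, i] = d
                geod[(i, j)] = [p for p in paths if len(p) - 1 == d]
    btw = np.zeros(n)
    for (i, j), paths in geod.items():
        q = len(paths)
        for x in range(n):
            if x in (i, j):
                continue
            qx = sum(1 for p in paths if x in p)
            btw[x] += qx / q
    closeness = np.zeros(n)
    for x in range(n):
        if deg[x] > 0:
            closeness[x] = 1.0 / sum(s[x, i] for i in range(n) if i != x)
    cc = np.zeros(n)
    for x in range(n):
        nbrs = [i for i in range(n) if adj[x, i]]
        k = len(nbrs)
        if k >= 2:
            e = sum(adj[a, b] for ai, a in enumerate(nbrs) for b in nbrs[ai + 1 :])
            cc[x] = 2.0 * e / (k * (k - 1))
    jac = np.zeros((n, n))
    for x in range(n):
        for y in range(n):
            nx_ = {i for i in range(n) if adj[x, i]}
            ny_ = {i for i in range(n) if adj[y, i]}
            u = nx_ | ny_
            jac[x, y] = len(nx_ & ny_) / len(u) if u else 0.0
    return dict(s=s, jaccard=jac, closeness=closeness, betweenness=btw,
                clustering=cc, degree=deg)


def taylor_kernel(adj: np.ndarray, beta: float, terms: int = 50) -> np.ndarray:
    """exp(beta (A - D)) by a term-by-term truncated Taylor series."""
    lap = adj.astype(float) - np.diag(adj.sum(axis=1).astype(float))
    n = lap.shape[0]
    out = np.eye(n)
    term = np.eye(n)
    for k in range(1, terms + 1):
        term = term @ (beta * lap) / k
        out = out + term
    return out


def oracle_scale_aware(adj: np.ndarray, beta: float, eps: float = 1e-12):
    """All five scale-aware measures from a Taylor-series kernel, computed
    with explicit python loops from the printed formulas."""
    K = taylor_kernel(adj, beta)
    n = K.shape[0]
    S = np.empty((n, n))
    for x in range(n):
        for y in range(n):
            S[x, y] = -np.log(max(K[x, y], eps))
    c = np.array([1.0 - K[x, x] for x in range(n)])
    J = np.empty((n, n))
    for x in range(n):
        for y in range(n):
            num = sum(min(K[x, i], K[i, y]) for i in range(n))
            den = sum(max(K[x, i], K[i, y]) for i in range(n))
            J[x, y] = num / den if den > 0 else 0.0
    b = np.array(
        [
            sum(S[x, y] - (S[x, z] + S[z, y]) for x in range(n) for y in range(n)) / n**2
            for z in range(n)
        ]
    )
    cc = np.array([sum(K[x, i] * J[x, i] for i in range(n) if i != x) for x in range(n)])
    return dict(s=S, jaccard=J, centrality=c, betweenness=b, clustering=cc)


def counting_rank(pool: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Average rank of each value within pool, by counting comparisons."""
    out = np.empty(len(values))
    for i, v in enumerate(values):
        less = int((pool < v).sum())
        equal = int((pool == v).sum())
        out[i] = less + (equal + 1) / 2.0
    return out


def block_sum(mat: np.ndarray, factor: int) -> np.ndarray:
    """Per-cell brute-force block summation for coarsening."""
    n = mat.shape[0]
    nn = -(-n // factor)
    out = np.zeros((nn, nn))
    for i in range(n):
        for j in range(n):
            out[i // factor, j // factor] += mat[i, j]
    return out


def threshold_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by exhaustive threshold sweep over all cut points (trapezoid),
    equivalent to pairwise win counting; used to certify separability."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
    return wins / (len(pos) * len(neg))
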