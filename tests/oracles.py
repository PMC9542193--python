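"""Independent brute-force implementations used only as test oracles.

Everything here trades efficiency for obviousness: explicit loops,
exhaustive path enumeration, textbook formulas.  These functions must stay
independent of the package's own metric code paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def bf_degrees(adj: np.ndarray) -> np.ndarray:
    return (adj > 0).sum(axis=1)


def bf_clustering(adj: np.ndarray, binary: bool = False) -> float:
    n = len(adj)
    w = (adj > 0).astype(float) if binary else adj
    total = 0.0
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        k = len(nb)
        if k < 2:
            continue
        t = 0.0
        for j, h in itertools.combinations(nb, 2):
            if adj[j, h] > 0:
                t += (w[i, j] * w[i, h] * w[j, h]) ** (1.0 / 3.0)
        total += 2.0 * t / (k * (k - 1))
    return total / n


def bf_assortativity(adj: np.ndarray) -> float:
    """Pearson correlation over the doubled edge end-degree list."""
    deg = bf_degrees(adj).astype(float)
    xs, ys = [], []
    for i, j in zip(*np.where(np.triu(adj, 1) > 0)):
        xs += [deg[i], deg[j]]
        ys += [deg[j], deg[i]]
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(xs, ys)[0, 1]
    return float(r)


def bf_shortest_paths(adj: np.ndarray) -> np.ndarray:
    """Floyd-Warshall on 1/weight edge lengths."""
    n = len(adj)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if adj[i, j] > 0:
                d[i, j] = 1.0 / adj[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def bf_global_efficiency(adj: np.ndarray) -> float:
    d = bf_shortest_paths(adj)
    n = len(adj)
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(d[i, j]):
                total += 1.0 / d[i, j]
    return total / (n * (n - 1))


def bf_betweenness(adj: np.ndarray) -> np.ndarray:
    """Exhaustive simple-path enumeration betweenness (pairs counted once)."""
    n = len(adj)
    d = bf_shortest_paths(adj)
    bc = np.zeros(n)

    def all_simple_paths(s, t):
        out = []

        def dfs(node, visited, length, path):
            if node == t:
                out.append((length, list(path)))
                return
            for nxt in np.flatnonzero(adj[node]):
                if nxt not in visited:
                    dfs(nxt, visited | {int(nxt)}, length + 1.0 / adj[node, nxt],
                        path + [int(nxt)])

        dfs(s, {s}, 0.0, [s])
        return out

    for s in range(n):
        for t in range(s + 1, n):
            if not np.isfinite(d[s, t]) or d[s, t] == 0:
                continue
            shortest = [p for length, p in all_simple_paths(s, t)
                        if abs(length - d[s, t]) < 1e-9]
            g = len(shortest)
            for p in shortest:
                for v in p[1:-1]:
                    bc[v] += 1.0 / g
    return bc


def bf_paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Closed-form paired t + two-tailed p via the regularized beta."""
    from scipy.special import betainc

    d = np.asarray(a, float) - np.asarray(b, float)
    n = len(d)
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    df = n - 1
    p = betainc(df / 2.0, 0.5, df / (df + t**2))
    return float(t), float(p)


def bf_kmo(x: np.ndarray) -> float:
    """KMO with anti-image partial correlations obtained by regression
    residuals (pairwise, no matrix inversion)."""
    n, p = x.shape
    r = np.corrcoef(x, rowvar=False)
    q = np.zeros((p, p))
    for i in range(p):
        for j in range(i + 1, p):
            others = [k for k in range(p) if k not in (i, j)]
            z = np.column_stack([np.ones(n), x[:, others]])
            beta_i, *_ = np.linalg.lstsq(z, x[:, i], rcond=None)
            beta_j, *_ = np.linalg.lstsq(z, x[:, j], rcond=None)
            ri = x[:, i] - z @ beta_i
            rj = x[:, j] - z @ beta_j
            q[i, j] = q[j, i] = np.corrcoef(ri, rj)[0, 1]
    off = ~np.eye(p, dtype=bool)
    return float(np.sum(r[off] ** 2) / (np.sum(r[off] ** 2) + np.sum(q[off] ** 2)))
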