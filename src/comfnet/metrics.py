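"""Graph-theoretical indices of sparse weighted brain networks.

Global indices: weighted clustering coefficient (CC, Onnela geometric-mean
triangles), degree assortativity (AC, Newman), global efficiency (GE) and
characteristic path length on inverse-weight path lengths, and
small-worldness σ against degree-preserving randomized surrogates.  Local
indices: binary node degree (Deg) and unnormalized weighted betweenness
centrality (BC).  A trapezoidal AUC across the sparsity sweep summarizes
each index free of the threshold choice.

Path lengths use ``1/weight`` throughout, so stronger connections are
shorter.  Degrees are binary edge counts even on weighted graphs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import dijkstra

from .network import SparseNetwork, SparsityGrid


def _adjacency(net: SparseNetwork | np.ndarray) -> np.ndarray:
    adj = net.adjacency if isinstance(net, SparseNetwork) else np.asarray(net, float)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.allclose(adj, adj.T, atol=1e-9):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(adj) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if np.any(adj < 0):
        raise ValueError("weights must be non-negative")
    return adj


def clustering_coefficient(net: SparseNetwork | np.ndarray, binary: bool = False) -> float:
    """Mean weighted clustering coefficient.

    Per node: ``CC_i = 2 t_i / (k_i (k_i − 1))`` with the geometric-mean
    triangle intensity ``t_i = ½ Σ_{jh} (w_ij w_ih w_jh)^{1/3}``; nodes with
    fewer than two neighbours contribute 0.
    """
    adj = _adjacency(net)
    if binary:
        adj = (adj > 0).astype(float)
    k = np.count_nonzero(adj, axis=1)
    w3 = np.cbrt(adj)
    t = np.einsum("ij,jh,hi->i", w3, w3, w3) / 2.0
    cc = np.zeros(adj.shape[0])
    mask = k >= 2
    cc[mask] = 2.0 * t[mask] / (k[mask] * (k[mask] - 1.0))
    return float(cc.mean())


def assortativity(net: SparseNetwork | np.ndarray) -> float:
    """Newman degree assortativity over edge end-degrees.

    With (j_e, k_e) the binary degrees of the endpoints of edge e and M the
    edge count::

        AC = [M⁻¹ Σ j k − (M⁻¹ Σ ½(j+k))²] /
             [M⁻¹ Σ ½(j²+k²) − (M⁻¹ Σ ½(j+k))²]

    Undefined (NaN, with a warning) when all end-degrees are equal.
    """
    adj = _adjacency(net)
    deg = np.count_nonzero(adj, axis=1).astype(float)
    rows, cols = np.where(np.triu(adj, k=1) > 0)
    m = len(rows)
    if m < 2:
        raise ValueError("assortativity needs at least 2 edges")
    j, k = deg[rows], deg[cols]
    mean_prod = np.mean(j * k)
    mean_sum = np.mean(0.5 * (j + k))
    mean_sq = np.mean(0.5 * (j**2 + k**2))
    denom = mean_sq - mean_sum**2
    if abs(denom) < 1e-15:
        warnings.warn("assortativity undefined: zero end-degree variance",
                      stacklevel=2)
        return float("nan")
    return float((mean_prod - mean_sum**2) / denom)


def shortest_path_lengths(net: SparseNetwork | np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths with edge length = 1/weight.

    Disconnected pairs are infinite.
    """
    adj = _adjacency(net)
    with np.errstate(divide="ignore"):
        lengths = np.where(adj > 0, 1.0 / np.where(adj > 0, adj, 1.0), 0.0)
    return dijkstra(lengths, directed=False, unweighted=False)


def global_efficiency(net: SparseNetwork | np.ndarray) -> float:
    """GE = (1/n) Σ_i [Σ_{j≠i} 1/d_ij] / (n−1); infinite distances count 0."""
    d = shortest_path_lengths(net)
    n = d.shape[0]
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / np.where(d > 0, d, 1.0), 0.0)
    return float(inv.sum() / (n * (n - 1)))


def characteristic_path_length(net: SparseNetwork | np.ndarray) -> float:
    """Mean finite off-diagonal shortest path length."""
    d = shortest_path_lengths(net)
    off = ~np.eye(d.shape[0], dtype=bool)
    finite = off & np.isfinite(d)
    if not finite.any():
        raise ValueError("graph has no connected pairs")
    return float(d[finite].mean())


def node_degree(net: SparseNetwork | np.ndarray) -> np.ndarray:
    """Binary edge count per node (weights ignored)."""
    return np.count_nonzero(_adjacency(net), axis=1)


def betweenness(net: SparseNetwork | np.ndarray) -> np.ndarray:
    """Unnormalized weighted betweenness, each unordered pair counted once."""
    adj = _adjacency(net)
    g = nx.from_numpy_array(adj)
    g.remove_edges_from([(u, v) for u, v, w in g.edges(data="weight") if w == 0])
    for _, _, attrs in g.edges(data=True):
        attrs["length"] = 1.0 / attrs["weight"]
    bc = nx.betweenness_centrality(g, weight="length", normalized=False)
    return np.array([bc[i] for i in range(adj.shape[0])])


@dataclass(frozen=True)
class SmallWorldResult:
    sigma: float
    cc: float
    cpl: float
    cc_random: float
    cpl_random: float
    n_surrogates: int


def small_worldness(
    net: SparseNetwork | np.ndarray,
    n_surrogates: int = 100,
    seed: int = 0,
    n_rewires: int | None = None,
) -> SmallWorldResult:
    """σ = (CC/CC_random) / (CPL/CPL_random) against a degree-preserving null.

    Surrogates are Maslov-Sneppen double-edge-swap randomizations (default
    ``10 × edges`` swap attempts, enough to mix) with the original weight
    multiset shuffled onto the rewired edges.
    """
    adj = _adjacency(net)
    if n_surrogates < 10:
        raise ValueError("need at least 10 surrogates")
    n = adj.shape[0]
    comp = max(nx.connected_components(nx.from_numpy_array((adj > 0).astype(int))),
               key=len)
    if len(comp) < 0.9 * n:
        raise ValueError("giant component covers < 90% of nodes")

    cc_real = clustering_coefficient(adj)
    cpl_real = characteristic_path_length(adj)
    rows, cols = np.where(np.triu(adj, k=1) > 0)
    weights = adj[rows, cols]
    m = len(weights)
    n_rewires = n_rewires if n_rewires is not None else 10 * m

    rng = np.random.default_rng(seed)
    cc_r, cpl_r = [], []
    for _ in range(n_surrogates):
        g = nx.from_edgelist(zip(rows.tolist(), cols.tolist()))
        g.add_nodes_from(range(n))
        try:
            nx.double_edge_swap(g, nswap=n_rewires, max_tries=n_rewires * 100,
                                seed=int(rng.integers(2**31)))
        except nx.NetworkXError as exc:  # rewiring starved of swappable pairs
            raise RuntimeError(
                f"surrogate rewiring failed after {n_rewires * 100} tries"
            ) from exc
        surr = np.zeros_like(adj)
        perm = rng.permutation(m)
        for (u, v), w in zip(g.edges(), weights[perm]):
            surr[u, v] = surr[v, u] = w
        cc_r.append(clustering_coefficient(surr))
        cpl_r.append(characteristic_path_length(surr))
    cc_random = float(np.mean(cc_r))
    cpl_random = float(np.mean(cpl_r))
    sigma = (cc_real / cc_random) / (cpl_real / cpl_random)
    return SmallWorldResult(
        sigma=float(sigma), cc=cc_real, cpl=cpl_real,
        cc_random=cc_random, cpl_random=cpl_random, n_surrogates=n_surrogates,
    )


def metric_auc(sparsities: np.ndarray, values: np.ndarray) -> float:
    """Trapezoidal area under a metric-vs-density curve."""
    s = np.asarray(sparsities, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(s) < 2:
        raise ValueError("AUC needs at least 2 sparsity levels")
    if not (np.all(np.isfinite(s)) and np.all(np.isfinite(v))):
        raise ValueError("AUC inputs must be finite")
    if np.any(np.diff(s) <= 0):
        raise ValueError("sparsity levels must be strictly increasing")
    return float(np.trapezoid(v, s))


# ---------------------------------------------------------------------------
# Sweep tables
# ---------------------------------------------------------------------------

def global_metrics_table(
    ensemble: list[SparseNetwork],
    n_surrogates: int = 0,
    seed: int = 0,
) -> pd.DataFrame:
    """One row per sparsity level: cc, ac, ge, cpl (and sigma if requested)."""
    rows = []
    for net in ensemble:
        row = {
            "sparsity": net.sparsity,
            "cc": clustering_coefficient(net),
            "ac": assortativity(net),
            "ge": global_efficiency(net),
            "cpl": characteristic_path_length(net),
        }
        if n_surrogates:
            row["sigma"] = small_worldness(net, n_surrogates=n_surrogates,
                                           seed=seed).sigma
        rows.append(row)
    return pd.DataFrame(rows)


def nodal_metrics_table(
    ensemble: list[SparseNetwork], region_codes: np.ndarray
) -> pd.DataFrame:
    """Tidy per-level nodal metrics: sparsity, region code, deg, bc."""
    frames = []
    for net in ensemble:
        frames.append(pd.DataFrame({
            "sparsity": net.sparsity,
            "region": region_codes,
            "deg": node_degree(net),
            "bc": betweenness(net),
        }))
    return pd.concat(frames, ignore_index=True)


def global_auc(table: pd.DataFrame) -> dict[str, float]:
    """AUC of each global metric over the sweep; NaN levels are excluded
    with a warning (e.g. undefined assortativity on degenerate graphs)."""
    out = {}
    s = table["sparsity"].to_numpy()
    for col in table.columns:
        if col == "sparsity":
            continue
        v = table[col].to_numpy(dtype=float)
        ok = np.isfinite(v)
        if not ok.all():
            warnings.warn(f"{col}: {np.sum(~ok)} undefined level(s) excluded "
                          "from AUC", stacklevel=2)
        if ok.sum() < 2:
            out[col] = float("nan")
            continue
        out[col] = metric_auc(s[ok], v[ok])
    return out


def nodal_auc(table: pd.DataFrame) -> pd.DataFrame:
    """Per-region AUC of deg and bc; index = region code."""
    def _auc(g: pd.DataFrame) -> pd.Series:
        g = g.sort_values("sparsity")
        return pd.Series({
            "deg": metric_auc(g["sparsity"], g["deg"]),
            "bc": metric_auc(g["sparsity"], g["bc"]),
        })

    return table.groupby("region").apply(_auc, include_groups=False)
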