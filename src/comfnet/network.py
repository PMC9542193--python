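"""Proportional-threshold sparse network construction.

A fully connected connectivity matrix is reduced to a weighted graph by
keeping the ``round(s · n(n−1)/2)`` strongest off-diagonal weights at each
sparse density ``s`` of a sweep (default 10–38 % in 4 % steps, i.e. eight
levels).  Weights are preserved, not binarized.  Ties at the cut are broken
deterministically by lexicographic (row, col) order, which also makes the
edge sets nested across densities.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np

from .connectivity import ConnectivityMatrix

DEFAULT_SPARSITY = (0.10, 0.38, 0.04)


@dataclass(frozen=True)
class SparsityGrid:
    low: float
    high: float
    step: float
    levels: tuple[float, ...]

    def __len__(self) -> int:
        return len(self.levels)


@dataclass(frozen=True)
class SparseNetwork:
    adjacency: np.ndarray
    sparsity: float
    n_edges: int

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def graph(self) -> nx.Graph:
        g = nx.from_numpy_array(self.adjacency)
        g.remove_edges_from([(u, v) for u, v, w in g.edges(data="weight") if w == 0])
        return g


def sparsity_levels(
    low: float = DEFAULT_SPARSITY[0],
    high: float = DEFAULT_SPARSITY[1],
    step: float = DEFAULT_SPARSITY[2],
) -> SparsityGrid:
    """Ascending density levels ``low, low+step, ...`` not exceeding ``high``."""
    if not 0 < low <= high < 1:
        raise ValueError("require 0 < low <= high < 1")
    if step <= 0:
        raise ValueError("step must be positive")
    levels = []
    k = 0
    while (lvl := low + k * step) <= high + 1e-9:
        levels.append(round(lvl, 10))
        k += 1
    return SparsityGrid(low=low, high=high, step=step, levels=tuple(levels))


def threshold_network(
    cm: ConnectivityMatrix | np.ndarray, sparsity: float
) -> SparseNetwork:
    """Keep the strongest ``round(s · n(n−1)/2)`` edges of a square matrix.

    Ties are resolved in favour of the lexicographically smaller (row, col)
    pair so the retained edge count is always exact and runs are
    reproducible across platforms.
    """
    if not 0 < sparsity <= 1:
        raise ValueError("sparsity must lie in (0, 1]")
    w = cm.plv if isinstance(cm, ConnectivityMatrix) else np.asarray(cm, dtype=float)
    n = w.shape[0]
    if w.shape != (n, n) or not np.allclose(w, w.T, atol=1e-9):
        raise ValueError("input must be a symmetric square matrix")
    n_possible = n * (n - 1) // 2
    n_keep = int(round(sparsity * n_possible))
    if n_keep == 0:
        raise ValueError(f"sparsity {sparsity} keeps zero edges for n={n}")

    rows, cols = np.triu_indices(n, k=1)
    weights = w[rows, cols]
    order = np.lexsort((cols, rows, -weights))
    keep = order[:n_keep]
    adj = np.zeros_like(w)
    adj[rows[keep], cols[keep]] = weights[keep]
    adj = adj + adj.T
    return SparseNetwork(adjacency=adj, sparsity=float(sparsity), n_edges=n_keep)


def build_ensemble(
    cm: ConnectivityMatrix | np.ndarray, grid: SparsityGrid | None = None
) -> list[SparseNetwork]:
    """Threshold one matrix at every level of the sparsity sweep."""
    grid = grid or sparsity_levels()
    return [threshold_network(cm, s) for s in grid.levels]


def write_edgelist(net: SparseNetwork, path: str | Path,
                   node_codes: np.ndarray | None = None) -> None:
    """Weighted edge list TSV: node_a, node_b, weight."""
    codes = node_codes if node_codes is not None else np.arange(net.n_nodes)
    rows, cols = np.triu_indices(net.n_nodes, k=1)
    mask = net.adjacency[rows, cols] > 0
    with open(path, "w") as f:
        f.write("node_a\tnode_b\tweight\n")
        for i, j in zip(rows[mask], cols[mask]):
            f.write(f"{codes[i]}\t{codes[j]}\t{net.adjacency[i, j]:.10g}\n")


def write_graphml(net: SparseNetwork, path: str | Path,
                  node_codes: np.ndarray | None = None) -> None:
    g = net.graph()
    if node_codes is not None:
        g = nx.relabel_nodes(g, {i: int(c) for i, c in enumerate(node_codes)})
    nx.write_graphml(g, path)
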