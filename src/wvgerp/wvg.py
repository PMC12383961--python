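"""Weighted visibility graph (WVG) construction.

A series x(t_1..t_N) maps to a graph with one node per time point.  Nodes
i < j are connected when the straight line between (t_i, x_i) and
(t_j, x_j) passes strictly above every intermediate sample — equivalently,
when the slope from i to j strictly exceeds the slope from i to every
intermediate point.  Each visible pair carries the weight

    w_ij = |arctan((x_i - x_j) / (t_i - t_j))|,

the slope angle magnitude, in [0, pi/2).  Time is measured in node-index
units, making the weights dimensionless and invariant to the sampling
step.  Flat segments (equal consecutive values) remain adjacent with
weight 0, so binary features see the edge while strength-based features
ignore it.  Visibility of consecutive points guarantees connectivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numba
import numpy as np


@numba.njit(cache=True)
def _adjacency_and_weights(x):  # pragma: no cover - exercised via build_wvg
    n = x.size
    a = np.zeros((n, n), dtype=np.uint8)
    w = np.zeros((n, n), dtype=np.float64)
    for i in range(n):
        max_slope = -np.inf
        for j in range(i + 1, n):
            slope = (x[j] - x[i]) / (j - i)
            if slope > max_slope or j == i + 1:
                a[i, j] = 1
                a[j, i] = 1
                wij = abs(np.arctan(slope))
                w[i, j] = wij
                w[j, i] = wij
            if slope > max_slope:
                max_slope = slope
    return a, w


@dataclass
class WeightedGraph:
    """Dense adjacency (binary) and weight matrices of a WVG."""

    adjacency: np.ndarray   # uint8, symmetric, zero diagonal
    weights: np.ndarray     # float64, nonzero only where adjacency is 1

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(np.int64)

    @property
    def strengths(self) -> np.ndarray:
        """Node strengths s_i = sum_j w_ij."""
        return self.weights.sum(axis=1)

    def edge_list(self) -> list[tuple[int, int, float]]:
        """(i, j, w) triples with i < j, for inspection or export."""
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        return [(int(i), int(j), float(self.weights[i, j]))
                for i, j in zip(ii, jj)]

    def to_igraph(self):
        import igraph as ig

        edges = self.edge_list()
        g = ig.Graph(n=self.n_nodes, edges=[(i, j) for i, j, _ in edges])
        g.es["weight"] = [w for _, _, w in edges]
        return g


def is_visible(x: np.ndarray, i: int, j: int) -> bool:
    """Whether nodes i < j (0-based) see each other.

    True iff the slope from i to j strictly exceeds the slope from i to
    every intermediate point; adjacent points are always visible.
    Collinear intermediates block visibility (strict inequality).
    """
    x = np.asarray(x, dtype=float)
    if not 0 <= i < j < x.size:
        raise IndexError(f"need 0 <= i < j < N, got i={i}, j={j}, N={x.size}")
    slope_ij = (x[j] - x[i]) / (j - i)
    for k in range(i + 1, j):
        if (x[k] - x[i]) / (k - i) >= slope_ij:
            return False
    return True


def edge_weight(x: np.ndarray, i: int, j: int) -> float:
    """|arctan(slope)| between visible nodes i < j, in radians."""
    x = np.asarray(x, dtype=float)
    if not is_visible(x, i, j):
        raise ValueError(f"nodes {i} and {j} are not mutually visible")
    return float(abs(np.arctan((x[i] - x[j]) / (i - j))))


def build_wvg(x: np.ndarray) -> WeightedGraph:
    """Weighted visibility graph of a series (N >= 2, finite values)."""
    x = np.ascontiguousarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("series must be one-dimensional with N >= 2")
    if not np.all(np.isfinite(x)):
        raise ValueError("series contains non-finite values")
    a, w = _adjacency_and_weights(x)
    return WeightedGraph(adjacency=a, weights=w)


def write_edge_list(graph: WeightedGraph, path) -> None:
    """Write ``i<TAB>j<TAB>w`` lines (0-based node ids)."""
    with open(path, "w") as fh:
        fh.write("i\tj\tweight\n")
        for i, j, w in graph.edge_list():
            fh.write(f"{i}\t{j}\t{w:.10g}\n")
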