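"""Topological features of weighted visibility graphs.

Sixteen per-graph features are computed for every (channel, band,
condition) cell, plus one cross-channel feature (CCSS) per (band,
condition):

==========  =============================================================
AWD         average weighted degree: mean node strength (1/N) sum_i s_i
DD          degree distribution index: lambda of a Poisson fit to the
            binary degree distribution (maximum likelihood = mean degree)
NE          network entropy: Shannon entropy (natural log) of the
            empirical binary-degree distribution
M           modularity Q of the Louvain partition of the weighted graph
APL         average path length: mean hop count over ordered node pairs
CC          mean local clustering coefficient (triangles over triples)
GIC         graph index complexity 4c(1-c) from the largest adjacency
            eigenvalue
LE          local efficiency: mean over nodes of the global efficiency of
            the neighbour-induced subgraph
GE          global efficiency: mean of 1/l_ij over ordered pairs
SW          small-worldness (C/C_rand)/(L/L_rand) against an analytic
            Erdos-Renyi reference (C_rand = density,
            L_rand = ln N / ln mean-degree)
SMaC        size of the maximum clique (exact)
CTSP        cost of a closed travelling-salesman tour on hop-count
            distances: nearest-neighbour start from node 0 refined by
            2-opt to a local optimum (deterministic)
GD          graph density 2E / N(N-1)
IN          independence number (exact)
SMiC        size of the global minimum cut (unit capacities, exact)
VCN         vertex coloring number: chromatic number by clique/DSATUR
            bounds plus budgeted exact backtracking
CCSS        clustering-coefficient sequence similarity: mean pairwise
            Pearson correlation of node-wise clustering sequences across
            channels
==========  =============================================================

AWD and M use the weighted adjacency; all other features use the binary
visibility adjacency.
"""

from __future__ import annotations

import logging
import random as _random
from dataclasses import dataclass

import numba
import numpy as np
import pandas as pd

from .config import CCSS_KEY, SINGLE_CHANNEL_FEATURES
from .preprocessing import BandSeriesGrid
from .wvg import WeightedGraph, build_wvg

logger = logging.getLogger(__name__)

_BIG = 1 << 20  # "unreachable" marker for integer hop distances


@numba.njit(cache=True)
def _floyd_warshall(a):  # pragma: no cover - exercised via hop_distances
    n = a.shape[0]
    d = np.empty((n, n), dtype=np.int64)
    for i in range(n):
        for j in range(n):
            if i == j:
                d[i, j] = 0
            elif a[i, j]:
                d[i, j] = 1
            else:
                d[i, j] = _BIG
    for k in range(n):
        for i in range(n):
            dik = d[i, k]
            if dik == _BIG:
                continue
            for j in range(n):
                alt = dik + d[k, j]
                if alt < d[i, j]:
                    d[i, j] = alt
    return d


@numba.njit(cache=True)
def _local_efficiency(a):  # pragma: no cover
    n = a.shape[0]
    total = 0.0
    for v in range(n):
        nbrs = np.flatnonzero(a[v])
        k = nbrs.size
        if k < 2:
            continue
        sub = np.empty((k, k), dtype=np.uint8)
        for p in range(k):
            for q in range(k):
                sub[p, q] = a[nbrs[p], nbrs[q]]
        d = _floyd_warshall(sub)
        eff = 0.0
        for p in range(k):
            for q in range(k):
                if p != q and d[p, q] < _BIG:
                    eff += 1.0 / d[p, q]
        total += eff / (k * (k - 1))
    return total / n


@numba.njit(cache=True)
def _tsp_nn_two_opt(d):  # pragma: no cover
    n = d.shape[0]
    visited = np.zeros(n, dtype=np.uint8)
    tour = np.empty(n, dtype=np.int64)
    tour[0] = 0
    visited[0] = 1
    for step in range(1, n):
        prev = tour[step - 1]
        best, best_cost = -1, np.inf
        for j in range(n):
            if not visited[j] and d[prev, j] < best_cost:
                best, best_cost = j, d[prev, j]
        tour[step] = best
        visited[best] = 1
    improved = True
    while improved:
        improved = False
        best_delta = 0.0
        best_i, best_j = -1, -1
        for i in range(n - 1):
            a_, b_ = tour[i], tour[(i + 1) % n]
            for j in range(i + 2, n):
                if i == 0 and j == n - 1:
                    continue
                c_, e_ = tour[j], tour[(j + 1) % n]
                delta = (d[a_, c_] + d[b_, e_]) - (d[a_, b_] + d[c_, e_])
                if delta < best_delta - 1e-12:
                    best_delta = delta
                    best_i, best_j = i, j
        if best_i >= 0:
            lo, hi = best_i + 1, best_j
            while lo < hi:
                tour[lo], tour[hi] = tour[hi], tour[lo]
                lo += 1
                hi -= 1
            improved = True
    cost = 0.0
    for i in range(n):
        cost += d[tour[i], tour[(i + 1) % n]]
    return cost


@numba.njit(cache=True)
def _popcount64(x):  # pragma: no cover
    c = 0
    while x:
        x &= x - numba.uint64(1)
        c += 1
    return c


@numba.njit(cache=True)
def _ctz64(x):  # pragma: no cover
    v = 0
    while not (x & numba.uint64(1)):
        x >>= numba.uint64(1)
        v += 1
    return v


@numba.njit(cache=True)
def _color_sort(nbr, cand, verts_row, bnds_row):  # pragma: no cover
    # Greedy coloring of the candidate set; vertices come out grouped by
    # color class, with bnds_row[i] an upper bound on any clique using
    # verts_row[i] and the vertices before it.
    one = numba.uint64(1)
    idx = 0
    c = 0
    rest = cand
    while rest:
        c += 1
        avail = rest
        while avail:
            v = _ctz64(avail)
            bit = one << numba.uint64(v)
            avail &= ~bit
            avail &= ~nbr[v]
            rest &= ~bit
            verts_row[idx] = v
            bnds_row[idx] = c
            idx += 1
    return idx


@numba.njit(cache=True)
def _max_clique_masks(nbr, n):  # pragma: no cover
    # Branch and bound with a greedy-coloring bound (Tomita-style MCQ),
    # iterative with explicit per-level stacks.  Exact for n <= 64.
    # Returns (size, member bitmask) of one maximum clique.
    one = numba.uint64(1)
    best = 0
    best_mask = numba.uint64(0)
    levels = n + 2
    cand = np.zeros(levels, dtype=np.uint64)
    size = np.zeros(levels, dtype=np.int64)
    take = np.zeros(levels, dtype=np.int64)
    verts = np.zeros((levels, n), dtype=np.int64)
    bnds = np.zeros((levels, n), dtype=np.int64)
    ptr = np.zeros(levels, dtype=np.int64)
    cand[0] = (one << numba.uint64(n)) - one
    ptr[0] = _color_sort(nbr, cand[0], verts[0], bnds[0]) - 1
    lv = 0
    while lv >= 0:
        if ptr[lv] < 0 or size[lv] + bnds[lv, ptr[lv]] <= best:
            lv -= 1
            continue
        v = verts[lv, ptr[lv]]
        ptr[lv] -= 1
        cand[lv] &= ~(one << numba.uint64(v))
        take[lv] = v
        if size[lv] + 1 > best:
            best = size[lv] + 1
            mask = numba.uint64(0)
            for j in range(lv + 1):
                mask |= one << numba.uint64(take[j])
            best_mask = mask
        child = cand[lv] & nbr[v]
        if child:
            lv += 1
            cand[lv] = child
            size[lv] = size[lv - 1] + 1
            ptr[lv] = _color_sort(nbr, child, verts[lv], bnds[lv]) - 1
    return best, best_mask


def _neighbor_masks(a: np.ndarray) -> np.ndarray:
    """Row-wise adjacency bitmasks (uint64; requires N <= 64)."""
    n = a.shape[0]
    if n > 64:
        raise ValueError("bitmask clique search supports at most 64 nodes")
    bits = (np.uint64(1) << np.arange(n, dtype=np.uint64))
    return (a.astype(np.uint64) * bits[None, :]).sum(axis=1, dtype=np.uint64)


@numba.njit(cache=True)
def _dsatur_greedy(a):  # pragma: no cover
    """DSATUR greedy coloring; returns number of colors used."""
    n = a.shape[0]
    colors = np.full(n, -1, dtype=np.int64)
    degrees = a.sum(axis=1).astype(np.int64)
    for _ in range(n):
        best, best_sat, best_deg = -1, -1, -1
        for v in range(n):
            if colors[v] >= 0:
                continue
            seen = np.zeros(n + 1, dtype=np.uint8)
            sat = 0
            for u in range(n):
                if a[v, u] and colors[u] >= 0 and not seen[colors[u]]:
                    seen[colors[u]] = 1
                    sat += 1
            if sat > best_sat or (sat == best_sat and degrees[v] > best_deg):
                best, best_sat, best_deg = v, sat, degrees[v]
        used = np.zeros(n + 1, dtype=np.uint8)
        for u in range(n):
            if a[best, u] and colors[u] >= 0:
                used[colors[u]] = 1
        c = 0
        while used[c]:
            c += 1
        colors[best] = c
    return colors.max() + 1


def hop_distances(graph: WeightedGraph) -> np.ndarray:
    """All-pairs shortest hop counts of the binary graph."""
    return _floyd_warshall(np.ascontiguousarray(graph.adjacency))


# --- features with explicit formulas ---------------------------------------

def average_weighted_degree(graph: WeightedGraph) -> float:
    """Mean node strength wd = (1/N) sum_i s_i."""
    return float(graph.strengths.mean())


def degree_distribution_index(graph: WeightedGraph,
                              method: str = "mle") -> float:
    """Poisson rate fitted to the binary degree distribution.

    ``mle`` (default) gives the closed-form maximum-likelihood estimate,
    the mean degree.  ``lsq`` minimises the squared distance between the
    Poisson pmf and the empirical degree histogram.
    """
    degrees = graph.degrees
    if method == "mle":
        return float(degrees.mean())
    if method == "lsq":
        from scipy.optimize import minimize_scalar
        from scipy.stats import poisson

        ks, counts = np.unique(degrees, return_counts=True)
        emp = np.zeros(int(degrees.max()) + 1)
        emp[ks] = counts / degrees.size
        support = np.arange(emp.size)

        def sse(lam: float) -> float:
            return float(np.sum((poisson.pmf(support, lam) - emp) ** 2))

        res = minimize_scalar(sse, bounds=(1e-9, float(degrees.max()) + 1.0),
                              method="bounded")
        return float(res.x)
    raise ValueError(f"unknown method {method!r}")


def network_entropy(graph: WeightedGraph) -> float:
    """Shannon entropy (nats) of the empirical degree distribution."""
    _, counts = np.unique(graph.degrees, return_counts=True)
    p = counts / counts.sum()
    return float(-(p * np.log(p)).sum())


@dataclass
class CommunityPartition:
    """Louvain community assignment and its modularity."""

    membership: np.ndarray
    q: float

    @property
    def n_communities(self) -> int:
        return int(self.membership.max()) + 1


def modularity(weights: np.ndarray, membership: np.ndarray) -> float:
    """Weighted modularity Q = (1/2m) sum_ij (w_ij - k_i k_j / 2m) d(C_i,C_j)."""
    two_m = weights.sum()
    if two_m <= 0:
        raise ValueError("modularity undefined for total weight m = 0")
    k = weights.sum(axis=1)
    same = membership[:, None] == membership[None, :]
    return float(((weights - np.outer(k, k) / two_m) * same).sum() / two_m)


def louvain_modularity(graph: WeightedGraph, seed: int = 0,
                       _ig=None) -> CommunityPartition:
    """Louvain partition of the weighted graph and its modularity.

    Local moving plus aggregation iterated until no positive modularity
    gain remains; Q is recomputed from the definition on the returned
    partition, not taken from the incremental updates.  ``seed`` pins the
    random state consulted by the community backend; the multilevel
    routine is deterministic for a fixed graph, so results are
    reproducible across runs.
    """
    if graph.weights.sum() <= 0:
        raise ValueError("Louvain modularity requires total edge weight m > 0")
    g = graph.to_igraph() if _ig is None else _ig
    state = _random.getstate()
    _random.seed(seed)
    try:
        part = g.community_multilevel(weights=g.es["weight"])
    finally:
        _random.setstate(state)
    membership = np.asarray(part.membership, dtype=np.int64)
    return CommunityPartition(membership=membership,
                              q=modularity(graph.weights, membership))


def average_path_length(graph: WeightedGraph,
                        hops: np.ndarray | None = None) -> float:
    """Mean shortest-path hop count over ordered node pairs."""
    d = hop_distances(graph) if hops is None else hops
    n = d.shape[0]
    assert d.max() < _BIG, "visibility graphs are connected"
    return float(d.sum() / (n * (n - 1)))


# --- pinned standard graph-theory features ---------------------------------

def clustering_sequence(graph: WeightedGraph) -> np.ndarray:
    """Node-wise local clustering coefficients (binary graph)."""
    a = graph.adjacency.astype(np.float64)
    triangles = ((a @ a) * a).sum(axis=1) / 2.0
    k = graph.degrees.astype(np.float64)
    triples = k * (k - 1) / 2.0
    out = np.zeros(graph.n_nodes)
    mask = triples > 0
    out[mask] = triangles[mask] / triples[mask]
    return out


def clustering_coefficient(graph: WeightedGraph) -> float:
    """Mean local clustering coefficient."""
    return float(clustering_sequence(graph).mean())


def graph_index_complexity(graph: WeightedGraph) -> float:
    """4c(1-c) with c locating the largest adjacency eigenvalue between
    the path-graph minimum 2cos(pi/(N+1)) and the complete-graph maximum
    N-1."""
    n = graph.n_nodes
    lam_max = float(np.linalg.eigvalsh(graph.adjacency.astype(float))[-1])
    ref = 2.0 * np.cos(np.pi / (n + 1))
    c = (lam_max - ref) / (n - 1 - ref)
    return float(4.0 * c * (1.0 - c))


def local_efficiency(graph: WeightedGraph) -> float:
    """Mean over nodes of the efficiency of the neighbour subgraph."""
    return float(_local_efficiency(np.ascontiguousarray(graph.adjacency)))


def global_efficiency(graph: WeightedGraph,
                      hops: np.ndarray | None = None) -> float:
    """Mean inverse hop distance over ordered node pairs."""
    d = hop_distances(graph) if hops is None else hops
    n = d.shape[0]
    off = ~np.eye(n, dtype=bool)
    return float((1.0 / d[off]).sum() / (n * (n - 1)))


def graph_density(graph: WeightedGraph) -> float:
    """2E / N(N-1)."""
    n = graph.n_nodes
    return float(2.0 * graph.n_edges / (n * (n - 1)))


def small_worldness(graph: WeightedGraph,
                    hops: np.ndarray | None = None,
                    _c: float | None = None) -> float:
    """(C/C_rand)/(L/L_rand) with the analytic random-graph reference
    C_rand = density and L_rand = ln N / ln(mean degree)."""
    n = graph.n_nodes
    c = clustering_coefficient(graph) if _c is None else _c
    lpath = average_path_length(graph, hops)
    c_rand = graph_density(graph)
    kbar = float(graph.degrees.mean())
    if kbar <= 1.0 or c_rand <= 0.0:
        raise ValueError("small-worldness reference undefined (mean degree <= 1)")
    l_rand = np.log(n) / np.log(kbar)
    return float((c / c_rand) / (lpath / l_rand))


def max_clique(graph: WeightedGraph) -> tuple[int, list[int]]:
    """Size and members of one maximum clique (bitmask branch and bound)."""
    a = graph.adjacency
    size, mask = _max_clique_masks(_neighbor_masks(a), a.shape[0])
    members = [v for v in range(a.shape[0]) if (int(mask) >> v) & 1]
    return int(size), members


def max_clique_size(graph: WeightedGraph) -> int:
    """Exact maximum clique size (bitmask branch and bound)."""
    a = graph.adjacency
    return int(_max_clique_masks(_neighbor_masks(a), a.shape[0])[0])


def independence_number(graph: WeightedGraph) -> int:
    """Exact maximum independent set size.

    Computed as the maximum clique of the complement graph with the same
    branch-and-bound search.
    """
    a = graph.adjacency
    comp = 1 - a - np.eye(a.shape[0], dtype=a.dtype)
    return int(_max_clique_masks(_neighbor_masks(comp), a.shape[0])[0])


def min_cut_size(graph: WeightedGraph, _ig=None) -> int:
    """Global minimum cut with unit capacities (exact)."""
    g = graph.to_igraph() if _ig is None else _ig
    return int(round(g.mincut().value))


#: Node budget per k-colorability search; exceeding it is inconclusive.
_COLORING_BUDGET = 200_000


def _k_colorable(nbr_masks: list[int], k: int,
                 clique: list[int]) -> bool | None:
    """Exact k-colorability by backtracking with bitmask color domains.

    A maximum clique is pre-colored with distinct colors (symmetry
    breaking); vertices are assigned most-constrained-first with domain
    propagation.  Returns True/False, or None if the node budget is
    exhausted (inconclusive).
    """
    n = len(nbr_masks)
    full = (1 << k) - 1
    colors = [-1] * n
    domains = [full] * n
    budget = _COLORING_BUDGET

    def assign(v: int, c: int, undo: list[int]) -> bool:
        colors[v] = c
        bit = 1 << c
        rest = nbr_masks[v]
        while rest:
            u = (rest & -rest).bit_length() - 1
            rest &= rest - 1
            if colors[u] < 0 and domains[u] & bit:
                domains[u] &= ~bit
                undo.append(u)
                if domains[u] == 0:
                    return False
        return True

    def undo_all(v: int, c: int, undo: list[int]) -> None:
        bit = 1 << c
        for u in undo:
            domains[u] |= bit
        colors[v] = -1

    for c, v in enumerate(clique):
        ok = assign(v, c, [])
        if not ok:
            return False

    def backtrack(remaining: int):
        nonlocal budget
        if remaining == 0:
            return True
        budget -= 1
        if budget <= 0:
            return None
        # most-constrained vertex: smallest domain, then highest degree
        v, best_key = -1, (k + 1, -1)
        for u in range(n):
            if colors[u] >= 0:
                continue
            key = (bin(domains[u]).count("1"), -bin(nbr_masks[u]).count("1"))
            if key < best_key:
                v, best_key = u, key
        dom = domains[v]
        while dom:
            c = (dom & -dom).bit_length() - 1
            dom &= dom - 1
            undo: list[int] = []
            if assign(v, c, undo):
                res = backtrack(remaining - 1)
                if res is not False:
                    return res
            undo_all(v, c, undo)
        return False

    return backtrack(n - len(clique))


def chromatic_number(graph: WeightedGraph, _clique: int | None = None) -> int:
    """Chromatic number: exact unless the search budget is exhausted.

    Lower bound from the exact clique number, upper bound from a DSATUR
    greedy coloring; when they disagree, a budgeted backtracking search
    (maximum-clique pre-coloring, domain propagation) closes the gap.
    If the budget runs out the greedy upper bound is returned — a
    deterministic, documented fallback that in practice is hit only on
    adversarial instances, not on visibility graphs of block-averaged
    series.
    """
    lb, clique_members = max_clique(graph)
    if _clique is not None:
        lb = _clique
    ub = int(_dsatur_greedy(np.ascontiguousarray(graph.adjacency)))
    if ub == lb:
        return lb
    masks = [int(m) for m in _neighbor_masks(graph.adjacency)]
    for k in range(lb, ub):
        res = _k_colorable(masks, k, clique_members)
        if res is True:
            return k
        if res is None:
            logger.warning("coloring search budget exhausted; returning the "
                           "greedy bound %d", ub)
            return ub
    return ub


def tsp_cost(graph: WeightedGraph, hops: np.ndarray | None = None) -> float:
    """Closed-tour cost on hop-count distances.

    Deterministic heuristic: nearest-neighbour construction from node 0
    followed by best-improvement 2-opt to a local optimum.
    """
    d = hop_distances(graph) if hops is None else hops
    return float(_tsp_nn_two_opt(d.astype(np.float64)))


_LEGACY = {
    "CC": clustering_coefficient,
    "GIC": graph_index_complexity,
    "LE": local_efficiency,
    "GE": global_efficiency,
    "SW": small_worldness,
    "SMaC": max_clique_size,
    "CTSP": tsp_cost,
    "GD": graph_density,
    "IN": independence_number,
    "SMiC": min_cut_size,
    "VCN": chromatic_number,
}


def legacy_feature(graph: WeightedGraph, name: str) -> float:
    """One of the pinned standard graph features by short name."""
    try:
        fn = _LEGACY[name]
    except KeyError:
        raise ValueError(f"unknown feature {name!r}") from None
    return float(fn(graph))


def ccss(cc_sequences: list[np.ndarray]) -> float:
    """Mean pairwise Pearson correlation of clustering sequences.

    Pairs involving a constant sequence (undefined correlation)
    contribute 0 and are logged.
    """
    if len(cc_sequences) < 2:
        raise ValueError("CCSS needs at least two channels")
    lengths = {len(s) for s in cc_sequences}
    if len(lengths) != 1:
        raise ValueError("clustering sequences differ in length")
    mat = np.asarray(cc_sequences, dtype=float)
    sd = mat.std(axis=1)
    centred = mat - mat.mean(axis=1, keepdims=True)
    total, n_pairs = 0.0, 0
    for i in range(mat.shape[0]):
        for j in range(i + 1, mat.shape[0]):
            n_pairs += 1
            if sd[i] == 0.0 or sd[j] == 0.0:
                logger.debug("constant clustering sequence in CCSS pair "
                             "(%d, %d); contributing 0", i, j)
                continue
            total += float((centred[i] * centred[j]).mean() / (sd[i] * sd[j]))
    return total / n_pairs


# --- per-subject feature vector --------------------------------------------

def single_channel_features(graph: WeightedGraph, seed: int = 0,
                            _cc_seq: np.ndarray | None = None) -> dict[str, float]:
    """All 16 per-graph features, reusing the hop-distance matrix."""
    hops = hop_distances(graph)
    g_ig = graph.to_igraph()
    cc_seq = clustering_sequence(graph) if _cc_seq is None else _cc_seq
    cc_mean = float(cc_seq.mean())
    values = {
        "AWD": average_weighted_degree(graph),
        "DD": degree_distribution_index(graph),
        "NE": network_entropy(graph),
        "M": louvain_modularity(graph, seed=seed, _ig=g_ig).q,
        "APL": average_path_length(graph, hops),
        "CC": cc_mean,
        "GIC": graph_index_complexity(graph),
        "LE": local_efficiency(graph),
        "GE": global_efficiency(graph, hops),
        "SW": small_worldness(graph, hops, _c=cc_mean),
        "SMaC": 0.0,
        "CTSP": tsp_cost(graph, hops),
        "GD": graph_density(graph),
        "IN": float(independence_number(graph)),
        "SMiC": float(min_cut_size(graph, g_ig)),
    }
    smac = max_clique_size(graph)
    values["SMaC"] = float(smac)
    values["VCN"] = float(chromatic_number(graph, _clique=smac))
    assert set(values) == set(SINGLE_CHANNEL_FEATURES)
    return values


def feature_key(channel: str, band: str, condition: str, feature: str) -> str:
    return f"{channel}|{band}|{condition}|{feature}"


def feature_names(channels, bands, conditions) -> list[str]:
    """Canonical feature-vector key order for a configuration."""
    names = [feature_key(ch, b, c, f)
             for ch in channels for b in bands for c in conditions
             for f in SINGLE_CHANNEL_FEATURES]
    names += [feature_key(CCSS_KEY, b, c, "CCSS")
              for b in bands for c in conditions]
    return names


def extract_features(grid: BandSeriesGrid, seed: int = 0) -> pd.Series:
    """Named feature vector for one subject's band-series grid.

    Raises if any grid cell is missing or non-finite; nothing is imputed.
    """
    if not np.all(np.isfinite(grid.values)):
        bad = [
            feature_key(ch, b, c, "*")
            for chi, ch in enumerate(grid.channels)
            for bi, b in enumerate(grid.bands)
            for ci, c in enumerate(grid.conditions)
            if not np.all(np.isfinite(grid.values[chi, bi, ci]))
        ]
        raise ValueError(f"non-finite band series for cells: {bad}")
    out: dict[str, float] = {}
    for bi, band in enumerate(grid.bands):
        for ci, cond in enumerate(grid.conditions):
            sequences = []
            for chi, ch in enumerate(grid.channels):
                graph = build_wvg(grid.values[chi, bi, ci])
                cc_seq = clustering_sequence(graph)
                feats = single_channel_features(graph, seed=seed,
                                                _cc_seq=cc_seq)
                for name, v in feats.items():
                    out[feature_key(ch, band, cond, name)] = v
                sequences.append(cc_seq)
            out[feature_key(CCSS_KEY, band, cond, "CCSS")] = ccss(sequences)
    names = feature_names(grid.channels, grid.bands, grid.conditions)
    missing = set(names) - set(out)
    if missing:
        raise ValueError(f"incomplete feature vector; missing {sorted(missing)}")
    return pd.Series(out).reindex(names)
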