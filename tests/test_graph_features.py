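"""Graph features: hand-computed toys, exhaustive oracles, library cross-checks."""

import itertools

import networkx as nx
import numpy as np
import pytest

import wvgerp.graph_features as gf
from wvgerp.config import SINGLE_CHANNEL_FEATURES
from wvgerp.preprocessing import BandSeriesGrid
from wvgerp.wvg import WeightedGraph, build_wvg


def graph_from_edges(n, edges, weights=None):
    """WeightedGraph from an explicit (i, j[, w]) edge list."""
    a = np.zeros((n, n), dtype=np.uint8)
    w = np.zeros((n, n))
    for k, (i, j) in enumerate(edges):
        a[i, j] = a[j, i] = 1
        wij = 1.0 if weights is None else weights[k]
        w[i, j] = w[j, i] = wij
    return WeightedGraph(adjacency=a, weights=w)


def complete_graph(n):
    return graph_from_edges(n, list(itertools.combinations(range(n), 2)))


def path_graph(n):
    return graph_from_edges(n, [(i, i + 1) for i in range(n - 1)])


def random_vg(rng, n_min=4, n_max=40):
    return build_wvg(rng.standard_normal(rng.integers(n_min, n_max + 1)))


class TestAverageWeightedDegree:
    def test_single_edge(self):
        g = graph_from_edges(2, [(0, 1)], [0.5])
        assert gf.average_weighted_degree(g) == pytest.approx(0.5)

    def test_flat_series_graph_has_zero(self):
        g = build_wvg(np.ones(5))
        assert gf.average_weighted_degree(g) == 0.0

    def test_triangle_hand_value(self):
        g = graph_from_edges(3, [(0, 1), (1, 2), (2, 0)], [0.1, 0.2, 0.3])
        # strengths 0.4, 0.3, 0.5
        assert gf.average_weighted_degree(g) == pytest.approx(0.4)


class TestDegreeDistributionIndex:
    def test_cycle_graph(self):
        g = graph_from_edges(5, [(i, (i + 1) % 5) for i in range(5)])
        assert gf.degree_distribution_index(g) == pytest.approx(2.0)

    def test_path_graph(self):
        assert gf.degree_distribution_index(path_graph(4)) == pytest.approx(1.5)

    def test_star_graph(self):
        g = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        assert gf.degree_distribution_index(g) == pytest.approx(1.6)

    def test_lsq_variant_close_to_mle_on_poissonish_degrees(self, rng):
        g = random_vg(rng, 30, 40)
        mle = gf.degree_distribution_index(g, "mle")
        lsq = gf.degree_distribution_index(g, "lsq")
        assert lsq > 0
        assert abs(lsq - mle) < max(2.0, 0.5 * mle)


class TestNetworkEntropy:
    def test_regular_graph_zero(self):
        g = graph_from_edges(4, [(i, (i + 1) % 4) for i in range(4)])
        assert gf.network_entropy(g) == 0.0

    def test_two_equal_degree_classes(self):
        assert gf.network_entropy(path_graph(4)) == pytest.approx(np.log(2))


class TestModularity:
    def test_two_cliques_with_bridge_matches_exhaustive_search(self):
        edges = list(itertools.combinations(range(4), 2)) \
            + list(itertools.combinations(range(4, 8), 2)) + [(3, 4)]
        g = graph_from_edges(8, edges)

        def partitions(nodes):
            if not nodes:
                yield []
                return
            first, rest = nodes[0], nodes[1:]
            for p in partitions(rest):
                for i in range(len(p)):
                    yield p[:i] + [[first] + p[i]] + p[i + 1:]
                yield [[first]] + p

        best_q = -1.0
        for part in partitions(list(range(8))):
            mem = np.empty(8, dtype=int)
            for ci, block in enumerate(part):
                for v in block:
                    mem[v] = ci
            best_q = max(best_q, gf.modularity(g.weights, mem))
        louvain = gf.louvain_modularity(g)
        assert louvain.q == pytest.approx(best_q, abs=0.02)

    def test_complete_graph_single_community(self):
        g = complete_graph(6)
        part = gf.louvain_modularity(g)
        assert part.n_communities == 1
        assert part.q == pytest.approx(0.0, abs=1e-12)

    def test_single_edge(self):
        g = graph_from_edges(2, [(0, 1)], [0.7])
        part = gf.louvain_modularity(g)
        assert part.q == pytest.approx(gf.modularity(g.weights,
                                                     part.membership))

    def test_zero_weight_graph_rejected(self):
        g = build_wvg(np.ones(4))
        with pytest.raises(ValueError, match="m > 0"):
            gf.louvain_modularity(g)

    def test_determinism(self, rng):
        g = random_vg(rng)
        p1 = gf.louvain_modularity(g, seed=3)
        p2 = gf.louvain_modularity(g, seed=3)
        assert np.array_equal(p1.membership, p2.membership)
        assert p1.q == p2.q

    def test_q_range(self, rng):
        for _ in range(20):
            q = gf.louvain_modularity(random_vg(rng)).q
            assert -0.5 <= q <= 1.0


class TestAveragePathLength:
    def test_complete(self):
        assert gf.average_path_length(complete_graph(5)) == 1.0

    def test_path_of_three(self):
        assert gf.average_path_length(path_graph(3)) == pytest.approx(4 / 3)

    def test_two_nodes(self):
        assert gf.average_path_length(path_graph(2)) == 1.0


class TestLegacyToys:
    def test_density_of_complete_graph(self):
        assert gf.legacy_feature(complete_graph(6), "GD") == 1.0

    def test_clustering_extremes(self):
        assert gf.legacy_feature(complete_graph(3), "CC") == 1.0
        star = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        assert gf.legacy_feature(star, "CC") == 0.0

    def test_max_clique_with_pendant(self):
        edges = list(itertools.combinations(range(4), 2)) + [(3, 4)]
        assert gf.legacy_feature(graph_from_edges(5, edges), "SMaC") == 4

    def test_unknown_feature_name(self):
        with pytest.raises(ValueError, match="unknown feature"):
            gf.legacy_feature(complete_graph(3), "XYZ")


class TestAgainstNetworkx:
    """Independent library cross-checks on random visibility graphs."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_clustering_efficiency_paths(self, seed):
        g = random_vg(np.random.default_rng(seed))
        gx = nx.from_numpy_array(g.adjacency)
        assert gf.clustering_coefficient(g) == pytest.approx(
            nx.average_clustering(gx))
        assert gf.local_efficiency(g) == pytest.approx(
            nx.local_efficiency(gx))
        assert gf.global_efficiency(g) == pytest.approx(
            nx.global_efficiency(gx))
        assert gf.average_path_length(g) == pytest.approx(
            nx.average_shortest_path_length(gx))
        seq = gf.clustering_sequence(g)
        nx_seq = nx.clustering(gx)
        np.testing.assert_allclose(seq, [nx_seq[i] for i in range(g.n_nodes)])

    @pytest.mark.parametrize("seed", [5, 6, 7])
    def test_gic_uses_largest_adjacency_eigenvalue(self, seed):
        g = random_vg(np.random.default_rng(seed))
        lam = max(np.real(np.linalg.eigvals(g.adjacency.astype(float))))
        n = g.n_nodes
        ref = 2 * np.cos(np.pi / (n + 1))
        c = (lam - ref) / (n - 1 - ref)
        assert gf.graph_index_complexity(g) == pytest.approx(4 * c * (1 - c))


class TestExhaustiveOracles:
    """SMaC, IN, VCN, SMiC and CTSP equal exhaustive search for N <= 7."""

    @pytest.mark.parametrize("seed", range(40))
    def test_combinatorial_features(self, seed):
        rng = np.random.default_rng(seed)
        g = random_vg(rng, 4, 7)
        n = g.n_nodes
        a = g.adjacency

        def is_clique(nodes):
            return all(a[i, j] for i, j in itertools.combinations(nodes, 2))

        smac = max(k for k in range(1, n + 1)
                   for c in itertools.combinations(range(n), k)
                   if is_clique(c))
        indep = max(k for k in range(1, n + 1)
                    for c in itertools.combinations(range(n), k)
                    if not any(a[i, j] for i, j in
                               itertools.combinations(c, 2)))
        vcn = next(k for k in range(1, n + 1)
                   for coloring in itertools.product(range(k), repeat=n)
                   if all(coloring[i] != coloring[j]
                          for i in range(n) for j in range(i + 1, n)
                          if a[i, j]))
        cuts = []
        for r in range(1, n // 2 + 1):
            for side in itertools.combinations(range(n), r):
                other = [v for v in range(n) if v not in side]
                cuts.append(sum(a[i, j] for i in side for j in other))
        smic = min(cuts)
        d = gf.hop_distances(g)
        ctsp = min(sum(d[p[i], p[(i + 1) % n]] for i in range(n))
                   for p in ([0] + list(q)
                             for q in itertools.permutations(range(1, n))))

        assert gf.max_clique_size(g) == smac
        assert gf.independence_number(g) == indep
        assert gf.chromatic_number(g) == vcn
        assert gf.min_cut_size(g) == smic
        assert gf.tsp_cost(g) == ctsp


class TestCCSS:
    def test_identical_sequences(self, rng):
        s = rng.standard_normal(10)
        assert gf.ccss([s, s.copy(), s.copy()]) == pytest.approx(1.0)

    def test_anticorrelated_pair(self, rng):
        s = rng.standard_normal(10)
        assert gf.ccss([s, -s]) == pytest.approx(-1.0)

    def test_mean_of_pairwise_correlations(self, rng):
        seqs = [rng.standard_normal(12) for _ in range(3)]

        def pearson(u, v):
            u = u - u.mean()
            v = v - v.mean()
            return float((u @ v) / np.sqrt((u @ u) * (v @ v)))

        expected = np.mean([pearson(seqs[0], seqs[1]),
                            pearson(seqs[0], seqs[2]),
                            pearson(seqs[1], seqs[2])])
        assert gf.ccss(seqs) == pytest.approx(expected)

    def test_constant_sequence_contributes_zero(self, rng):
        s = rng.standard_normal(8)
        assert gf.ccss([s, -s, np.ones(8)]) == pytest.approx(-1.0 / 3)

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            gf.ccss([rng.standard_normal(5)])
        with pytest.raises(ValueError):
            gf.ccss([rng.standard_normal(5), rng.standard_normal(6)])


class TestFeatureProperties:
    def test_bounded_and_typed_values(self, rng):
        for _ in range(10):
            g = random_vg(rng, 10, 40)
            f = gf.single_channel_features(g)
            for name in ("GD", "CC", "LE", "GE"):
                assert 0.0 <= f[name] <= 1.0
            assert f["SW"] > 0
            for name in ("SMaC", "IN", "SMiC", "VCN"):
                assert f[name] == int(f[name]) and f[name] >= 1
            assert f["DD"] >= 0 and f["NE"] >= 0 and f["APL"] >= 1

    def test_determinism(self, rng):
        g = random_vg(rng)
        f1 = gf.single_channel_features(g, seed=0)
        f2 = gf.single_channel_features(g, seed=0)
        assert f1 == f2

    def test_node_relabelling_invariance(self, rng):
        """Graph-level features are invariant under consistent node
        permutation.  CTSP (fixed start node) and the Louvain partition
        depend on node order by construction and are exempt."""
        invariant = [n for n in SINGLE_CHANNEL_FEATURES
                     if n not in ("CTSP", "M")]
        g = random_vg(rng, 8, 20)
        perm = rng.permutation(g.n_nodes)
        gp = WeightedGraph(adjacency=g.adjacency[np.ix_(perm, perm)],
                           weights=g.weights[np.ix_(perm, perm)])
        f1 = gf.single_channel_features(g)
        f2 = gf.single_channel_features(gp)
        for name in invariant:
            assert f1[name] == pytest.approx(f2[name]), name


class TestExtractFeatures:
    def _grid(self, channels, bands, conditions, rng):
        values = rng.standard_normal((len(channels), len(bands),
                                      len(conditions), 37))
        return BandSeriesGrid(channels=channels, bands=bands,
                              conditions=conditions, values=values, step=0.08)

    def test_reduced_grid_counts(self, rng):
        grid = self._grid(("Fz", "Pz"), ("raw", "delta"), ("NA", "OC"), rng)
        vec = gf.extract_features(grid)
        assert len(vec) == 2 * 2 * 16 * 2 + 2 * 2
        assert vec.notna().all()

    def test_key_set_is_canonical_and_ordered(self, rng):
        grid = self._grid(("Fz", "Pz"), ("raw",), ("NA",), rng)
        vec = gf.extract_features(grid)
        assert list(vec.index) == gf.feature_names(("Fz", "Pz"), ("raw",),
                                                  ("NA",))
        assert vec.index[0] == "Fz|raw|NA|AWD"
        assert vec.index[-1] == "ALL|raw|NA|CCSS"

    def test_non_finite_cell_is_an_error(self, rng):
        grid = self._grid(("Fz", "Pz"), ("raw",), ("NA",), rng)
        grid.values[1, 0, 0, 5] = np.nan
        with pytest.raises(ValueError, match=r"Pz\|raw\|NA"):
            gf.extract_features(grid)
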