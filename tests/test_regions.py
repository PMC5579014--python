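"""Stepping-stone matrix, percolation, community detection, barriers."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from seapan import (
    ConnectivityMatrix,
    RegionPartition,
    barrier_strength,
    detect_regions,
    modularity_significance,
    percolate,
    stepping_stone_matrix,
    weighted_modularity,
)
from seapan.regions import RegionError, _strength_matrix


def conn_from_edges(n, edges):
    """ConnectivityMatrix from {(i, j): T_days}."""
    T = np.full((n, n), np.nan)
    for (i, j), t in edges.items():
        T[i, j] = t
    return ConnectivityMatrix.from_dense(T)


def enumerate_shortest_paths(W):
    """Oracle: minimal path sum by enumerating all simple paths."""
    n = W.shape[0]
    S = np.full((n, n), np.inf)
    np.fill_diagonal(S, 0.0)
    nodes = range(n)
    for i in nodes:
        for j in nodes:
            if i == j:
                continue
            best = np.inf
            for r in range(n):
                for mid in itertools.permutations(
                        [k for k in nodes if k not in (i, j)], r):
                    path = (i, *mid, j)
                    total = sum(W[a, b] for a, b in zip(path, path[1:]))
                    best = min(best, total)
            S[i, j] = best
    return S


def exhaustive_max_modularity(A):
    """Oracle: maximum weighted modularity over all partitions."""
    n = A.shape[0]
    best = -np.inf
    # iterate set partitions via restricted growth strings
    def rec(k, labels, m):
        nonlocal best
        if k == n:
            best = max(best, weighted_modularity(A, np.array(labels)))
            return
        for lab in range(m + 1):
            rec(k + 1, labels + [lab], max(m, lab + 1))
    rec(1, [0], 1)
    return best


def two_cliques(n1, n2, bridge_weight=1.0):
    G = nx.Graph()
    for base, size in ((0, n1), (n1, n2)):
        for i in range(size):
            for j in range(i + 1, size):
                G.add_edge(base + i, base + j, weight=1.0)
    G.add_edge(n1 - 1, n1, weight=bridge_weight)
    return G


class TestSteppingStone:
    def test_two_leg_path_beats_direct_edge(self):
        C = conn_from_edges(3, {(0, 1): 2.0, (1, 2): 3.0, (0, 2): 10.0})
        S = stepping_stone_matrix(C)
        assert S.S[0, 2] == pytest.approx(5.0)

    def test_single_edge_graph(self):
        C = conn_from_edges(3, {(0, 1): 4.0})
        S = stepping_stone_matrix(C)
        assert S.S[0, 1] == pytest.approx(4.0)
        assert np.isinf(S.S[1, 0]) and np.isinf(S.S[0, 2])

    def test_diagonal_is_zero(self):
        C = conn_from_edges(4, {(0, 1): 1.0, (1, 0): 2.0, (0, 0): 3.0})
        S = stepping_stone_matrix(C)
        assert (np.diag(S.S) == 0).all()

    def test_negative_weight_rejected(self):
        C = conn_from_edges(2, {(0, 1): -1.0})
        with pytest.raises(RegionError):
            stepping_stone_matrix(C)

    def test_matches_path_enumeration_on_random_digraphs(self):
        """Floyd–Warshall equals brute-force path enumeration and obeys the
        triangle inequality on random small directed graphs."""
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(3, 7))
            W = np.full((n, n), np.nan)
            for i in range(n):
                for j in range(n):
                    if i != j and rng.random() < 0.45:
                        W[i, j] = float(rng.uniform(0.5, 9.5))
            C = ConnectivityMatrix.from_dense(W)
            if not (C.N > 0).any():
                continue
            S = stepping_stone_matrix(C).S
            oracle = enumerate_shortest_paths(
                np.where(np.isnan(W), np.inf, W))
            assert np.allclose(S, oracle)
            # S_ik <= S_ij + S_jk wherever defined
            for i, j, k in itertools.product(range(n), repeat=3):
                if np.isfinite(S[i, j]) and np.isfinite(S[j, k]):
                    assert S[i, k] <= S[i, j] + S[j, k] + 1e-9


class TestPercolate:
    def test_chain_keeps_every_edge(self):
        C = conn_from_edges(4, {(0, 1): 1.0, (1, 2): 2.0, (2, 3): 3.0})
        G = percolate(C)
        assert G.number_of_edges() == 3  # every edge is a bridge
        assert G.graph["percolation_threshold"] == pytest.approx(1 / 3)

    def test_clique_with_pendant_weak_edge(self):
        # strong 4-clique (T=1) plus a pendant attached by T=10; the
        # pendant's bridge survives and sets the threshold, so no clique
        # edge (strength 1 >= 0.1) is removed either
        edges = {(i, j): 1.0 for i in range(4) for j in range(4) if i != j}
        edges[(0, 4)] = 10.0
        C = conn_from_edges(5, edges)
        G = percolate(C)
        assert G.has_edge(0, 4)
        assert G.graph["percolation_threshold"] == pytest.approx(0.1)
        # removing edges below a higher threshold would disconnect node 4
        assert G.number_of_edges() == 7

    def test_weak_internal_edges_removed(self):
        # two strong 3-cliques joined by a strong bridge, plus one weak
        # internal shortcut that the percolation threshold removes
        edges = {}
        for base in (0, 3):
            for i in range(3):
                for j in range(i + 1, 3):
                    edges[(base + i, base + j)] = 1.0
        edges[(2, 3)] = 1.0       # bridge
        edges[(0, 5)] = 50.0      # weak long-range shortcut
        C = conn_from_edges(6, edges)
        G = percolate(C)
        assert not G.has_edge(0, 5)
        assert G.has_edge(2, 3)

    def test_bridge_between_cliques_survives(self):
        G = percolate(conn_from_edges(6, {
            **{(i, j): 1.0 for i in range(3) for j in range(3) if i != j},
            **{(i, j): 1.0 for i in range(3, 6) for j in range(3, 6) if i != j},
            (2, 3): 7.0,
        }))
        assert G.has_edge(2, 3)

    def test_disconnected_support_names_components(self):
        C = conn_from_edges(4, {(0, 1): 1.0, (2, 3): 1.0})
        with pytest.raises(RegionError, match="components"):
            percolate(C)

    def test_min_symmetrization_takes_strongest_direction(self):
        C = conn_from_edges(2, {(0, 1): 2.0, (1, 0): 8.0})
        s = _strength_matrix(C, "min")
        assert s[0, 1] == pytest.approx(0.5)
        s_mean = _strength_matrix(C, "mean")
        assert s_mean[0, 1] == pytest.approx(0.2)


class TestDetectRegions:
    @pytest.mark.parametrize("n1,n2", [(3, 3), (4, 3), (5, 5)])
    def test_two_cliques_reach_exhaustive_maximum(self, n1, n2):
        G = two_cliques(n1, n2)
        part = detect_regions(G)
        A = nx.to_numpy_array(G, nodelist=sorted(G), weight="weight")
        assert part.n_regions == 2
        memb = part.membership_array(sorted(G))
        assert len(set(memb[:n1])) == 1 and len(set(memb[n1:])) == 1
        assert part.modularity == pytest.approx(exhaustive_max_modularity(A))

    def test_never_exceeds_exhaustive_maximum(self):
        rng = np.random.default_rng(7)
        for _ in range(6):
            n = int(rng.integers(4, 8))
            A = np.triu((rng.random((n, n)) < 0.5).astype(float), 1)
            A = A + A.T
            if A.sum() == 0:
                continue
            G = nx.from_numpy_array(A)
            if not nx.is_connected(G):
                continue
            part = detect_regions(G)
            assert part.modularity <= exhaustive_max_modularity(A) + 1e-12

    def test_complete_graph_single_community(self):
        G = nx.complete_graph(6)
        nx.set_edge_attributes(G, 1.0, "weight")
        part = detect_regions(G)
        assert part.n_regions == 1
        assert part.modularity == pytest.approx(0.0, abs=1e-12)

    def test_matches_igraph_on_random_graphs(self):
        igraph = pytest.importorskip("igraph")
        rng = np.random.default_rng(3)
        for _ in range(5):
            n = 12
            A = np.triu((rng.random((n, n)) < 0.3).astype(float), 1)
            A = A + A.T
            G = nx.from_numpy_array(A)
            if not nx.is_connected(G):
                continue
            part = detect_regions(G)
            g = igraph.Graph.Adjacency((A > 0).tolist(), mode="undirected")
            cl = g.community_leading_eigenvector()
            # both are greedy spectral heuristics; Q should agree closely
            assert part.modularity == pytest.approx(cl.modularity, abs=0.05)

    def test_two_gyre_regions_split_at_the_jet(self, two_gyre_chain):
        ch = two_gyre_chain
        part = ch["partition"]
        assert part.n_regions >= 2
        nodes = sorted(part.membership)
        memb = part.membership_array(nodes)
        sides = (np.array(nodes) >= ch["break_cell"]).astype(int)
        # purity: map each detected region to its majority shore
        correct = 0
        for r in set(memb):
            in_r = memb == r
            correct += max((sides[in_r] == 0).sum(), (sides[in_r] == 1).sum())
        assert correct / len(nodes) >= 0.95


class TestModularitySignificance:
    def test_strong_two_clique_partition_is_significant(self):
        G = two_cliques(5, 5)
        part = detect_regions(G)
        p = modularity_significance(G, part, n_rand=999, seed=0)
        assert p <= 0.01

    def test_single_community_partition_p_is_one(self):
        G = two_cliques(4, 4)
        part = RegionPartition({v: 0 for v in G}, 1, 0.0)
        assert modularity_significance(G, part, n_rand=99, seed=0) == 1.0

    def test_random_partition_p_is_uniform(self):
        G = two_cliques(5, 5)
        rng = np.random.default_rng(0)
        ps = []
        for s in range(40):
            labels = rng.permutation([0] * 5 + [1] * 5)
            part = RegionPartition({v: int(labels[v]) for v in G}, 2, 0.0)
            ps.append(modularity_significance(G, part, n_rand=199, seed=s))
        assert 0.2 < np.median(ps) < 0.8

    def test_invalid_n_rand(self):
        G = two_cliques(3, 3)
        part = detect_regions(G)
        with pytest.raises(RegionError):
            modularity_significance(G, part, n_rand=0, seed=0)


class TestBarrierStrength:
    def make_partition(self, mapping):
        return RegionPartition(mapping, len(set(mapping.values())), 0.0)

    def test_one_of_five_connecting_cells_gives_80pct(self):
        N = np.zeros((8, 8), int)
        for i in range(5):
            N[i, (i + 1) % 5] = 1        # region 0 internally connected
        N[0, 5] = 1                       # one cell connects to region 1
        N[5, 6] = N[6, 5] = N[7, 5] = 1   # region 1 internal
        C = ConnectivityMatrix.from_dense(np.where(N > 0, 1.0, np.nan), N)
        part = self.make_partition({i: (0 if i < 5 else 1) for i in range(8)})
        b = barrier_strength(C, part)
        assert b.reduction.loc[0, 1] == pytest.approx(80.0)
        assert np.isnan(b.reduction.loc[0, 0])

    def test_no_connection_is_100_and_full_connection_is_0(self):
        N = np.zeros((4, 4), int)
        N[0, 1] = N[1, 0] = 1            # region 0 = {0,1} internal
        N[2, 3] = N[3, 2] = 1            # region 1 = {2,3} internal
        N[0, 2] = N[1, 3] = 1            # every region-0 cell reaches region 1
        C = ConnectivityMatrix.from_dense(np.where(N > 0, 2.0, np.nan), N)
        part = self.make_partition({0: 0, 1: 0, 2: 1, 3: 1})
        b = barrier_strength(C, part)
        assert b.reduction.loc[0, 1] == pytest.approx(0.0)
        assert b.reduction.loc[1, 0] == pytest.approx(100.0)

    def test_relabelling_equivariance(self):
        rng = np.random.default_rng(5)
        N = (rng.random((9, 9)) < 0.3).astype(int)
        C = ConnectivityMatrix.from_dense(np.where(N > 0, 1.0, np.nan), N)
        memb = {i: i % 3 for i in range(9)}
        b1 = barrier_strength(C, self.make_partition(memb))
        relabel = {0: 2, 1: 0, 2: 1}
        b2 = barrier_strength(
            C, self.make_partition({i: relabel[m] for i, m in memb.items()}))
        for ri in range(3):
            for rj in range(3):
                if ri == rj:
                    continue
                a = b1.reduction.loc[ri, rj]
                b = b2.reduction.loc[relabel[ri], relabel[rj]]
                assert a == pytest.approx(b, nan_ok=True)

    def test_cross_jet_barriers_exceed_within_shore(self, two_gyre_chain):
        ch = two_gyre_chain
        part = ch["partition"]
        red = ch["barriers"].reduction
        nodes = sorted(part.membership)
        memb = part.membership_array(nodes)
        sides = (np.array(nodes) >= ch["break_cell"]).astype(int)
        region_side = {}
        for r in set(memb):
            in_r = memb == r
            region_side[r] = int((sides[in_r] == 1).sum() > (sides[in_r] == 0).sum())
        cross, within = [], []
        for ri in red.index:
            for rj in red.columns:
                if ri == rj or np.isnan(red.loc[ri, rj]):
                    continue
                (cross if region_side[ri] != region_side[rj]
                 else within).append(red.loc[ri, rj])
        assert np.mean(cross) > np.mean(within)
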