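"""Oceanographic region detection and barrier strength.

The averaged connectivity matrix is turned into a stepping-stone matrix
(all-pairs minimal summed transport time, Floyd–Warshall), percolated
(weakest edges removed up to the maximal threshold that keeps one connected
component), and partitioned into regions with Newman's leading-eigenvector
community detection on the weighted, symmetrized graph.  Partition quality
is the weighted modularity Q; its significance comes from random membership
assignments preserving region sizes; barrier strength between regions is
the percentage reduction in connectivity computed from counts of cells
with at least one direct dispersal event.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse.csgraph import floyd_warshall

from .connectivity import ConnectivityMatrix

__all__ = [
    "SteppingStoneMatrix",
    "RegionPartition",
    "BarrierMatrix",
    "stepping_stone_matrix",
    "percolate",
    "detect_regions",
    "modularity_significance",
    "barrier_strength",
    "weighted_modularity",
]

_DQ_TOL = 1e-10  # recursion stops when the best split gains no more than this


class RegionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Stepping-stone matrix
# ---------------------------------------------------------------------------

@dataclass
class SteppingStoneMatrix:
    """Minimal summed transport time over multi-leg paths; inf = unreachable."""

    S: np.ndarray

    @property
    def n(self) -> int:
        return self.S.shape[0]


def stepping_stone_matrix(C: ConnectivityMatrix) -> SteppingStoneMatrix:
    """All-pairs shortest paths with the directed transport times as weights."""
    if not (C.N > 0).any():
        raise RegionError("connectivity matrix has no defined entries")
    W = np.where(C.N > 0, C.T, np.inf)
    if np.nanmin(np.where(C.N > 0, C.T, np.nan)) < 0:
        raise RegionError("negative transport times")
    np.fill_diagonal(W, 0.0)
    S = floyd_warshall(W, directed=True)
    return SteppingStoneMatrix(S=S)


# ---------------------------------------------------------------------------
# Symmetrization and percolation
# ---------------------------------------------------------------------------

def _strength_matrix(M, symmetrize: str = "min") -> np.ndarray:
    """Edge strengths 1/T on the symmetrized transport-time matrix.

    ``symmetrize="min"`` takes, per unordered pair, the minimum transport
    time over the two directions (the strongest link); ``"mean"`` averages
    the directions that are defined.
    """
    if isinstance(M, ConnectivityMatrix):
        T = np.where(M.N > 0, M.T, np.nan)
    elif isinstance(M, SteppingStoneMatrix):
        T = np.where(np.isfinite(M.S), M.S, np.nan)
    else:
        T = np.asarray(M, dtype=float)
    if symmetrize == "min":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sym = np.fmin(T, T.T)
    elif symmetrize == "mean":
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            sym = np.nanmean(np.stack([T, T.T]), axis=0)
    else:
        raise RegionError(f"unknown symmetrization {symmetrize!r}")
    np.fill_diagonal(sym, np.nan)  # self-loops carry no community information
    with np.errstate(divide="ignore", invalid="ignore"):
        strength = np.where(np.isnan(sym), 0.0,
                            np.where(sym <= 0, np.inf, 1.0 / sym))
    # a 0-day symmetrized time would be an infinite strength; transport
    # times are strictly positive so this only guards degenerate input
    return strength


def percolate(M, symmetrize: str = "min") -> nx.Graph:
    """Remove the weakest edges up to the maximal strength threshold that
    keeps all retained cells in one connected component.

    The threshold equals the bottleneck (minimum) edge strength of the
    maximum spanning tree, so bridges can never be removed and the result
    is deterministic and order-independent.  Cells with no connection at
    all are dropped ("retained cells" are those with >= 1 edge).  The
    graph's ``percolation_threshold`` attribute records the threshold.
    """
    strength = _strength_matrix(M, symmetrize)
    n = strength.shape[0]
    G = nx.Graph()
    ij = np.argwhere(strength > 0)
    for i, j in ij:
        if i < j:
            G.add_edge(int(i), int(j), weight=float(strength[i, j]))
    if G.number_of_nodes() == 0:
        raise RegionError("no connected cells")
    if not nx.is_connected(G):
        comps = [sorted(c) for c in nx.connected_components(G)]
        raise RegionError(
            f"support graph is disconnected; components: {comps}"
        )
    mst = nx.maximum_spanning_tree(G, weight="weight")
    threshold = min(d["weight"] for _, _, d in mst.edges(data=True))
    out = nx.Graph()
    out.add_nodes_from(G.nodes)
    out.add_edges_from(
        (u, v, d) for u, v, d in G.edges(data=True)
        if d["weight"] >= threshold
    )
    out.graph["percolation_threshold"] = threshold
    out.graph["n_cells_total"] = n
    return out


# ---------------------------------------------------------------------------
# Leading-eigenvector community detection
# ---------------------------------------------------------------------------

def _adjacency(graph: nx.Graph) -> tuple[np.ndarray, list]:
    nodes = sorted(graph.nodes)
    A = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    return A, nodes


def weighted_modularity(A: np.ndarray, membership: np.ndarray) -> float:
    """Weighted Newman modularity Q of a partition given adjacency A."""
    k = A.sum(axis=1)
    two_m = k.sum()
    if two_m == 0:
        return 0.0
    B = A - np.outer(k, k) / two_m
    same = membership[:, None] == membership[None, :]
    return float((B * same).sum() / two_m)


@dataclass
class RegionPartition:
    membership: dict[int, int]     # cell id -> region id (0..r-1)
    n_regions: int
    modularity: float
    percolation_threshold: float | None = None
    p_value: float | None = None
    n_rand: int | None = None
    seed: int | None = None

    def membership_array(self, nodes: list[int] | None = None) -> np.ndarray:
        nodes = nodes if nodes is not None else sorted(self.membership)
        return np.array([self.membership[v] for v in nodes])

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {"cell_id": sorted(self.membership),
             "region_id": [self.membership[c] for c in sorted(self.membership)]}
        ).to_csv(path, index=False)


def detect_regions(graph: nx.Graph, seed: int | None = None,
                   max_regions: int | None = None) -> RegionPartition:
    """Newman leading-eigenvector communities on the weighted graph.

    The modularity matrix of each candidate group is split by the sign of
    its dominant eigenvector; splitting recurses while the modularity gain
    exceeds a small tolerance.  Near-zero eigenvector entries join the side
    of the group's lowest node id.  The algorithm is deterministic; ``seed``
    is accepted for interface symmetry only.  ``max_regions`` optionally
    caps the number of communities (off by default: the region count is
    emergent).
    """
    if graph.number_of_nodes() < 2:
        raise RegionError("need >= 2 nodes")
    A, nodes = _adjacency(graph)
    n = len(nodes)
    k = A.sum(axis=1)
    two_m = k.sum()
    membership = np.zeros(n, dtype=int)
    if two_m == 0:
        part = {v: 0 for v in nodes}
        return RegionPartition(part, 1, 0.0,
                               graph.graph.get("percolation_threshold"))
    B = A - np.outer(k, k) / two_m

    groups = [np.arange(n)]
    final: list[np.ndarray] = []
    while groups:
        g = groups.pop()
        if g.size == 1:
            final.append(g)
            continue
        if max_regions is not None and \
                len(final) + len(groups) + 1 >= max_regions:
            final.append(g)
            continue
        Bg = B[np.ix_(g, g)].copy()
        Bg[np.diag_indices_from(Bg)] -= Bg.sum(axis=1)
        w, V = np.linalg.eigh(Bg)
        lead = V[:, -1]
        if w[-1] <= _DQ_TOL:
            final.append(g)
            continue
        s = np.where(lead > 1e-12, 1.0, -1.0)
        ties = np.abs(lead) <= 1e-12
        # near-zero entries join the side of the lowest node id in the group
        s[ties] = s[0] if not ties[0] else 1.0
        if np.all(s == s[0]):
            final.append(g)
            continue
        dq = float(s @ Bg @ s) / (2.0 * two_m)
        if dq <= _DQ_TOL:
            final.append(g)
            continue
        groups.append(g[s > 0])
        groups.append(g[s < 0])

    for rid, g in enumerate(sorted(final, key=lambda a: a.min())):
        membership[g] = rid
    q = weighted_modularity(A, membership)
    part = {nodes[i]: int(membership[i]) for i in range(n)}
    return RegionPartition(
        membership=part, n_regions=len(final), modularity=q,
        percolation_threshold=graph.graph.get("percolation_threshold"),
        seed=seed,
    )


def modularity_significance(graph: nx.Graph, partition: RegionPartition,
                            n_rand: int = 10000, seed: int = 0) -> float:
    """Permutation p-value for Q: random memberships preserving region
    sizes; ``p = (#{Q_rand >= Q_obs} + 1)/(n_rand + 1)``."""
    if n_rand < 1:
        raise RegionError("n_rand must be >= 1")
    A, nodes = _adjacency(graph)
    memb = partition.membership_array(nodes)
    q_obs = weighted_modularity(A, memb)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x0D]))
    count = 0
    for _ in range(n_rand):
        if weighted_modularity(A, memb[rng.permutation(memb.size)]) \
                >= q_obs - 1e-12:
            count += 1
    return (count + 1) / (n_rand + 1)


# ---------------------------------------------------------------------------
# Barrier strength
# ---------------------------------------------------------------------------

@dataclass
class BarrierMatrix:
    """Region x region percentage reduction in connectivity (diagonal NaN)."""

    reduction: pd.DataFrame

    def to_csv(self, path) -> None:
        long = self.reduction.stack().rename("reduction_pct").reset_index()
        long.columns = ["region_i", "region_j", "reduction_pct"]
        long.to_csv(path, index=False)


def barrier_strength(C: ConnectivityMatrix, partition: RegionPartition
                     ) -> BarrierMatrix:
    """Percentage reduction in connectivity between detected regions.

    ``connect_ij`` counts cells of region i with at least one particle
    beaching in region j (one dispersal event suffices); ``within_i``
    counts cells of region i connected to at least one cell of region i
    (self-recruitment included).  The reduction is
    ``100 * (1 - connect_ij / within_i)`` clipped to [0, 100]; rows with
    ``within_i = 0`` are undefined with a logged warning.  Relabelling the
    regions permutes rows and columns but changes no value.
    """
    cells = sorted(partition.membership)
    if max(cells) >= C.n:
        raise RegionError("partition references cells beyond the matrix")
    regions = sorted(set(partition.membership.values()))
    members = {r: [c for c in cells if partition.membership[c] == r]
               for r in regions}
    connected = C.N > 0
    out = pd.DataFrame(np.nan, index=regions, columns=regions, dtype=float)
    for ri in regions:
        rows = np.array(members[ri])
        within = int(connected[np.ix_(rows, rows)].any(axis=1).sum())
        if within == 0:
            warnings.warn(f"region {ri} has no internally connected cells; "
                          "its barrier row is undefined", stacklevel=2)
            continue
        for rj in regions:
            if rj == ri:
                continue
            cols = np.array(members[rj])
            connect = int(connected[np.ix_(rows, cols)].any(axis=1).sum())
            out.loc[ri, rj] = float(np.clip(100.0 * (1 - connect / within),
                                            0.0, 100.0))
    return BarrierMatrix(reduction=out)
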