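"""Weighted-network metrics on the thresholded group matrix W.

Link weights W in [0, 1) are converted to travel costs D = 1 - W for
shortest-path-based measures (path length, betweenness, global
efficiency); strength, clustering, assortativity and modularity operate on
W directly.  Modularity uses the weighted Newman-Girvan objective with a
resolution parameter and is maximized by restarted Louvain runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.sparse import csr_array
from scipy.sparse.csgraph import dijkstra

__all__ = [
    "Partition",
    "SmallWorldResult",
    "complete_edge_count",
    "strength",
    "distance_matrix",
    "shortest_paths",
    "betweenness",
    "global_efficiency",
    "modularity_q",
    "louvain_partition",
    "assortativity",
    "small_world_indices",
]


@dataclass(frozen=True)
class Partition:
    """Module assignment per node plus its modularity score.

    Module ids are contiguous from 0, numbered by order of each module's
    lowest node index.
    """

    assignment: np.ndarray
    q_value: float

    def __post_init__(self) -> None:
        a = np.asarray(self.assignment, dtype=int)
        object.__setattr__(self, "assignment", a)
        ids = np.unique(a)
        if not np.array_equal(ids, np.arange(len(ids))):
            raise ValueError("module ids must be contiguous from 0")

    @property
    def n_modules(self) -> int:
        return int(self.assignment.max()) + 1

    def members(self, m: int) -> np.ndarray:
        return np.flatnonzero(self.assignment == m)


@dataclass(frozen=True)
class SmallWorldResult:
    clustering: float
    path_length: float
    clustering_random: float
    path_length_random: float
    sigma: float
    flags: dict = field(default_factory=dict)


def _check_weight_matrix(W: np.ndarray, name: str = "W") -> np.ndarray:
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError(f"{name} must be square")
    if not np.allclose(W, W.T, atol=1e-10):
        raise ValueError(f"{name} must be symmetric")
    if np.any(W < 0):
        raise ValueError(f"{name} must be non-negative")
    if np.any(np.diag(W) != 0):
        raise ValueError(f"{name} must have a zero diagonal")
    return W


def complete_edge_count(n: int) -> int:
    """Number of connections in a fully connected n-region network: n(n-1)/2."""
    if n < 1:
        raise ValueError(f"node count must be >= 1, got {n}")
    return n * (n - 1) // 2


def strength(W: np.ndarray) -> np.ndarray:
    """Per-node strength: the sum of the weights of all incident links."""
    W = _check_weight_matrix(W)
    return W.sum(axis=1)


def distance_matrix(W: np.ndarray) -> np.ndarray:
    """Convert weights to travel costs: D = 1 - W on edges, +inf off edges."""
    W = _check_weight_matrix(W)
    if np.any(W >= 1):
        raise ValueError("weights must be < 1 to map onto distances D = 1 - W")
    D = np.where(W > 0, 1.0 - W, np.inf)
    np.fill_diagonal(D, 0.0)
    return D


def _as_graph(D: np.ndarray) -> nx.Graph:
    n = D.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    iu = np.triu_indices(n, k=1)
    for i, j in zip(*iu):
        if np.isfinite(D[i, j]):
            G.add_edge(int(i), int(j), distance=float(D[i, j]), weight=1.0 - float(D[i, j]))
    return G


def _weight_graph(W: np.ndarray) -> nx.Graph:
    """Graph keyed by weights only (no distance mapping; weights may be 1)."""
    n = W.shape[0]
    G = nx.Graph()
    G.add_nodes_from(range(n))
    iu = np.triu_indices(n, k=1)
    for i, j in zip(*iu):
        if W[i, j] > 0:
            G.add_edge(int(i), int(j), weight=float(W[i, j]))
    return G


def shortest_paths(D: np.ndarray) -> np.ndarray:
    """All-pairs weighted shortest path lengths (Dijkstra over costs D);
    unreachable pairs stay +inf."""
    D = np.asarray(D, dtype=float)
    finite = np.where(np.isfinite(D), D, 0.0)
    mask = np.isfinite(D) & (~np.eye(D.shape[0], dtype=bool))
    graph = csr_array(np.where(mask, finite, 0.0))
    return dijkstra(graph, directed=False)


def betweenness(D: np.ndarray) -> np.ndarray:
    """Weighted betweenness centrality on costs D (fractional shortest-path
    shares, normalized by the number of ordered non-incident pairs)."""
    G = _as_graph(np.asarray(D, dtype=float))
    bc = nx.betweenness_centrality(G, weight="distance", normalized=True)
    return np.array([bc[i] for i in range(D.shape[0])])


def global_efficiency(D: np.ndarray) -> float:
    """Mean inverse shortest path length over ordered node pairs;
    unreachable pairs contribute zero."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if n < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    sp = shortest_paths(D)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(sp) & (sp > 0), 1.0 / sp, 0.0)
    return float(inv[off].mean())


def modularity_q(W: np.ndarray, assignment: np.ndarray, gamma: float = 1.0) -> float:
    """Weighted Newman-Girvan modularity of a module assignment.

    Q = sum_c [ e_c / m  -  gamma * (a_c / 2m)^2 ], where m is the total
    edge weight, e_c the weight inside module c and a_c the summed strength
    of its members.
    """
    W = _check_weight_matrix(W)
    assignment = np.asarray(assignment, dtype=int)
    two_m = W.sum()
    if two_m <= 0:
        raise ValueError("network has no edges")
    s = W.sum(axis=1)
    q = 0.0
    for c in np.unique(assignment):
        idx = assignment == c
        e_c = W[np.ix_(idx, idx)].sum() / 2.0
        a_c = s[idx].sum()
        q += e_c / (two_m / 2.0) - gamma * (a_c / two_m) ** 2
    return float(q)


def _canonical_assignment(communities, n: int) -> np.ndarray:
    a = np.empty(n, dtype=int)
    ordered = sorted((min(c), c) for c in communities)
    for mid, (_, c) in enumerate(ordered):
        for node in c:
            a[node] = mid
    return a


def louvain_partition(
    W: np.ndarray,
    gamma: float = 1.0,
    seed: int = 0,
    restarts: int = 100,
) -> Partition:
    """Best-of-restarts Louvain modularity partition of W.

    Each restart runs Louvain with a distinct seed derived from ``seed``;
    the assignment with the highest directly evaluated Q is returned (ties
    broken by lexicographically smallest assignment, so a fixed seed is
    fully reproducible).
    """
    W = _check_weight_matrix(W)
    if W.sum() <= 0:
        raise ValueError("network has no edges")
    n = W.shape[0]
    G = _weight_graph(W)
    best: tuple[float, tuple[int, ...]] | None = None
    seeds = np.random.SeedSequence(seed).generate_state(restarts) % (2**31)
    for s in seeds:
        comms = nx.community.louvain_communities(
            G, weight="weight", resolution=gamma, seed=int(s)
        )
        a = _canonical_assignment(comms, n)
        q = modularity_q(W, a, gamma=gamma)
        key = (q, tuple(-x for x in a))
        if best is None or key > best:
            best = key
    assert best is not None
    q, neg_a = best
    return Partition(assignment=np.array([-x for x in neg_a]), q_value=q)


def assortativity(W: np.ndarray) -> float:
    """Strength-strength Pearson correlation over edge endpoints (both
    orientations).  Returns NaN with a warning when endpoint strengths have
    no variance."""
    W = _check_weight_matrix(W)
    s = W.sum(axis=1)
    iu = np.triu_indices(W.shape[0], k=1)
    present = W[iu] > 0
    if present.sum() < 2:
        raise ValueError("assortativity needs at least 2 edges")
    si = s[iu[0][present]]
    sj = s[iu[1][present]]
    x = np.concatenate([si, sj])
    y = np.concatenate([sj, si])
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn(
            "endpoint strengths have zero variance; assortativity undefined",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


def _mean_path_length(D: np.ndarray) -> tuple[float, bool]:
    sp = shortest_paths(D)
    n = sp.shape[0]
    off = ~np.eye(n, dtype=bool)
    finite = np.isfinite(sp) & off
    disconnected = not finite.all(where=off, axis=None)
    if not finite.any():
        return float("inf"), True
    return float(sp[finite].mean()), disconnected


def small_world_indices(
    W: np.ndarray,
    n_random: int = 20,
    seed: int = 0,
) -> SmallWorldResult:
    """Small-world indices against degree-preserving random references.

    C is the mean weighted clustering coefficient (geometric-mean triangle
    rule, weights scaled by the maximum weight); L the mean shortest path
    length on D = 1 - W over reachable pairs.  References preserve the
    degree sequence by edge rewiring (10 swaps per edge) and reshuffle the
    original weights over the rewired edges.  sigma = (C/C_rand)/(L/L_rand).
    On a disconnected network the measures cover reachable pairs only and
    the result is flagged.
    """
    W = _check_weight_matrix(W)
    if n_random < 10:
        raise ValueError("need at least 10 random reference networks")
    G = _as_graph(distance_matrix(W))
    m = G.number_of_edges()
    if m < 2:
        raise ValueError("small-world indices need at least 2 edges")
    C = float(np.mean(list(nx.clustering(G, weight="weight").values())))
    L, disconnected = _mean_path_length(distance_matrix(W))

    rng = np.random.default_rng(seed)
    weights = np.array([d["weight"] for _, _, d in G.edges(data=True)])
    c_rand, l_rand = [], []
    for _ in range(n_random):
        H = G.copy()
        if m > 2:
            nx.double_edge_swap(
                H, nswap=10 * m, max_tries=200 * m, seed=int(rng.integers(2**31))
            )
        perm = rng.permutation(len(weights))
        for (u, v), w in zip(H.edges(), weights[perm]):
            H[u][v]["weight"] = float(w)
            H[u][v]["distance"] = float(1.0 - w)
        c_rand.append(float(np.mean(list(nx.clustering(H, weight="weight").values()))))
        Dh = np.full_like(W, np.inf)
        np.fill_diagonal(Dh, 0.0)
        for u, v, d in H.edges(data=True):
            Dh[u, v] = Dh[v, u] = d["distance"]
        lr, _ = _mean_path_length(Dh)
        l_rand.append(lr)
    C_rand = float(np.mean(c_rand))
    L_rand = float(np.mean(l_rand))
    sigma = (C / C_rand) / (L / L_rand) if C_rand > 0 and L_rand > 0 else float("nan")
    return SmallWorldResult(
        clustering=C,
        path_length=L,
        clustering_random=C_rand,
        path_length_random=L_rand,
        sigma=float(sigma),
        flags={"disconnected": disconnected},
    )
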