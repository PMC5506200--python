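"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (direct formulas, exhaustive
enumeration) and shares no code path with the package implementation.
"""

from __future__ import annotations

import itertools
from collections import Counter

import numpy as np


def weighted_pearson_direct(x, y, w) -> float:
    """Weighted Pearson by literal weighted-moment computation."""
    x, y, w = (np.asarray(a, dtype=float) for a in (x, y, w))
    p = w / w.sum()
    mx = sum(pi * xi for pi, xi in zip(p, x))
    my = sum(pi * yi for pi, yi in zip(p, y))
    cov = sum(pi * (xi - mx) * (yi - my) for pi, xi, yi in zip(p, x, y))
    vx = sum(pi * (xi - mx) ** 2 for pi, xi in zip(p, x))
    vy = sum(pi * (yi - my) ** 2 for pi, yi in zip(p, y))
    return cov / np.sqrt(vx * vy)


def bh_stepup(p_values, q) -> np.ndarray:
    """Benjamini-Hochberg by the literal sorted step-up rule."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_max = rank
    mask = np.zeros(m, dtype=bool)
    mask[order[:k_max]] = True
    return mask


def enumerate_simple_paths(D: np.ndarray, src: int, dst: int):
    """All simple paths src -> dst over finite entries of cost matrix D,
    yielding (cost, path) tuples."""
    n = D.shape[0]

    def rec(node, visited, cost, path):
        if node == dst:
            yield cost, tuple(path)
            return
        for nxt in range(n):
            if nxt not in visited and np.isfinite(D[node, nxt]) and nxt != node:
                yield from rec(nxt, visited | {nxt}, cost + D[node, nxt], path + [nxt])

    yield from rec(src, {src}, 0.0, [src])


def shortest_paths_brute(D: np.ndarray) -> np.ndarray:
    """All-pairs shortest path cost by exhaustive simple-path enumeration."""
    n = D.shape[0]
    out = np.full((n, n), np.inf)
    np.fill_diagonal(out, 0.0)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            costs = [c for c, _ in enumerate_simple_paths(D, i, j)]
            if costs:
                out[i, j] = min(costs)
    return out


def betweenness_brute(D: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """Normalized weighted betweenness by enumerating every shortest path.

    For each unordered pair (s, t) the fraction of minimal-cost simple
    paths through node v accrues to v; totals are divided by
    (n-1)(n-2)/2, the number of pairs a node can intermediate.
    """
    n = D.shape[0]
    acc = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            paths = list(enumerate_simple_paths(D, s, t))
            if not paths:
                continue
            best = min(c for c, _ in paths)
            geodesics = [p for c, p in paths if c <= best + tol]
            for v in range(n):
                if v in (s, t):
                    continue
                through = sum(1 for p in geodesics if v in p)
                acc[v] += through / len(geodesics)
    denom = (n - 1) * (n - 2) / 2
    return acc / denom


def global_efficiency_brute(D: np.ndarray) -> float:
    sp = shortest_paths_brute(D)
    n = D.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i != j and np.isfinite(sp[i, j]) and sp[i, j] > 0:
                total += 1.0 / sp[i, j]
    return total / (n * (n - 1))


def set_partitions(items):
    """Every partition of ``items`` into non-empty unlabeled blocks."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for k in range(len(part)):
            yield part[:k] + [part[k] + [first]] + part[k + 1 :]
        yield part + [[first]]


def modularity_direct(W: np.ndarray, blocks, gamma: float = 1.0) -> float:
    """Weighted modularity evaluated straight from its definition."""
    two_m = W.sum()
    q = 0.0
    for block in blocks:
        idx = np.array(block)
        e_c = W[np.ix_(idx, idx)].sum() / 2.0
        a_c = W[idx].sum()
        q += e_c / (two_m / 2.0) - gamma * (a_c / two_m) ** 2
    return q


def best_partition_exhaustive(W: np.ndarray, gamma: float = 1.0) -> float:
    """Maximum modularity over every partition (Bell-number enumeration)."""
    return max(
        modularity_direct(W, part, gamma)
        for part in set_partitions(range(W.shape[0]))
    )


def anchoring_pmf_enumeration(n: int, homolog: dict[int, int]) -> dict[int, float]:
    """Exact anchoring-count law by enumerating all m! edge-weight
    orderings of the complete graph (feasible only for tiny n)."""
    edges = list(itertools.combinations(range(n), 2))
    cnt: Counter[int] = Counter()
    total = 0
    for perm in itertools.permutations(range(len(edges))):
        partner: dict[int, int] = {}
        for e in sorted(range(len(edges)), key=lambda e: perm[e]):
            u, v = edges[e]
            partner.setdefault(u, v)
            partner.setdefault(v, u)
        cnt[sum(1 for i, h in homolog.items() if partner[i] == h)] += 1
        total += 1
    return {k: v / total for k, v in cnt.items()}


def colocation_pmf_enumeration(sizes, pair_map) -> dict[int, float]:
    """Exact co-location law by enumerating node permutations over the
    fixed module-size template."""
    n = sum(sizes)
    template = []
    for m, s in enumerate(sizes):
        template.extend([m] * s)
    cnt: Counter[int] = Counter()
    total = 0
    for perm in itertools.permutations(range(n)):
        assign = [0] * n
        for pos, node in enumerate(perm):
            assign[node] = template[pos]
        cnt[sum(1 for i, j in pair_map if assign[i] == assign[j])] += 1
        total += 1
    return {k: v / total for k, v in cnt.items()}


def random_weight_matrix(rng: np.random.Generator, n: int, density: float = 0.7):
    """Random symmetric weight matrix in (0, 1), zero diagonal, connected
    not guaranteed."""
    W = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < density:
                W[i, j] = W[j, i] = rng.uniform(0.05, 0.95)
    return W
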