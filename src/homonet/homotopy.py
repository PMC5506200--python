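"""Homotopy statistics: strongest-link anchoring and module symmetry.

Two bespoke statistics quantify how strongly interhemispheric homotopy
organizes a weighted brain network:

* strongest-link anchoring — for each region select the incident link of
  maximal weight (one selection per region); count the paired regions whose
  selection is their contralateral homolog;
* module pairing / symmetry ratios — how many homotopic pairs fall jointly
  inside one module of a partition, and per module the fraction of members
  whose homolog is a fellow member.

Both are compared against chance with label-exchangeable nulls: Monte
Carlo permutation by default, exact computation for small networks (full
distribution of the argmax structure of i.i.d. edge weights for anchoring,
enumeration of equal-size module assignments for co-location).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .graph import Partition
from .nodes import NodeSet

__all__ = [
    "StrongestLinks",
    "NullResult",
    "HomotopyReport",
    "strongest_link_per_node",
    "anchoring_count",
    "module_pairing",
    "symmetry_ratios",
    "null_anchoring",
    "null_colocation",
    "homotopy_report",
]

_EXACT_MAX_NODES = 10


@dataclass(frozen=True)
class StrongestLinks:
    """Per-node strongest-link selection.

    ``partners[i]`` is the argmax-weight neighbor of node i, or -1 for an
    isolated node.  Ties are broken toward the lowest partner index and
    recorded in ``tied``.
    """

    partners: np.ndarray
    isolated: np.ndarray  # bool per node
    tied: np.ndarray  # bool per node

    @property
    def unique_links(self) -> set[tuple[int, int]]:
        """The selected links deduplicated as undirected (i, j) pairs."""
        out = set()
        for i, j in enumerate(self.partners):
            if j >= 0:
                out.add((min(i, int(j)), max(i, int(j))))
        return out


@dataclass(frozen=True)
class NullResult:
    """A null comparison: observed statistic, p-value and the null law."""

    observed: int
    p_value: float
    mode: str
    null_counts: np.ndarray | None = None  # permutation draws
    null_pmf: dict[int, float] | None = None  # exact distribution
    n_perm: int = 0


@dataclass(frozen=True)
class HomotopyReport:
    strongest: StrongestLinks
    anchored_nodes: int
    anchored_total: int
    pairs_colocated: int
    colocated_pairs: tuple[tuple[int, int], ...]
    symmetry_per_module: tuple[tuple[int, int], ...]  # (k_m, n_m) per module
    symmetry_total: tuple[int, int]  # (K, N)
    p_anchoring: float
    p_colocation: float
    flags: dict = field(default_factory=dict)


def strongest_link_per_node(W: np.ndarray) -> StrongestLinks:
    """For each node, the incident edge of maximal weight.

    A link may be selected by both of its endpoints; selections are counted
    per node (n selections for n non-isolated nodes).  Isolated nodes
    (all-zero rows, possible after FDR thresholding) get partner -1 and a
    warning.
    """
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("W must be square")
    n = W.shape[0]
    A = W.copy()
    np.fill_diagonal(A, -np.inf)
    partners = np.argmax(A, axis=1)
    best = A[np.arange(n), partners]
    isolated = ~(A > 0).any(axis=1)
    tied = ((A == best[:, None]).sum(axis=1) > 1) & ~isolated
    partners = partners.astype(int)
    partners[isolated] = -1
    if isolated.any():
        warnings.warn(
            f"{int(isolated.sum())} isolated node(s) excluded from "
            "strongest-link selection",
            RuntimeWarning,
            stacklevel=2,
        )
    return StrongestLinks(partners=partners, isolated=isolated, tied=tied)


def anchoring_count(
    links: StrongestLinks | np.ndarray, nodes: NodeSet
) -> tuple[int, int]:
    """(anchored, total_paired): paired nodes whose strongest link connects
    to their homolog, over all non-isolated paired nodes."""
    if isinstance(links, StrongestLinks):
        partners = links.partners
    else:
        partners = np.asarray(links, dtype=int)
    anchored = 0
    total = 0
    for i in nodes.paired_indices:
        if partners[i] < 0:
            continue  # isolated after thresholding; excluded from denominator
        total += 1
        if partners[i] == nodes.homolog(i):
            anchored += 1
    return anchored, total


def module_pairing(
    partition: Partition, nodes: NodeSet
) -> tuple[int, tuple[tuple[int, int], ...]]:
    """Homotopic pairs whose two members share a module."""
    a = partition.assignment
    if len(a) != nodes.n_nodes:
        raise ValueError("partition does not cover the node set")
    colocated = tuple((i, j) for i, j in nodes.pair_map if a[i] == a[j])
    return len(colocated), colocated


def symmetry_ratios(
    partition: Partition, nodes: NodeSet
) -> tuple[tuple[tuple[int, int], ...], tuple[int, int]]:
    """Per-module (symmetric members k_m, size n_m) and totals (K, N).

    A member is symmetric when its homotopic homolog sits in the same
    module; K = sum of k_m = 2 x pairs co-located, N = node count.
    """
    a = partition.assignment
    if len(a) != nodes.n_nodes:
        raise ValueError("partition does not cover the node set")
    per_module = []
    for m in range(partition.n_modules):
        members = partition.members(m)
        k = sum(
            1
            for i in members
            if (h := nodes.homolog(int(i))) is not None and a[h] == m
        )
        per_module.append((k, len(members)))
    K = sum(k for k, _ in per_module)
    N = sum(n for _, n in per_module)
    return tuple(per_module), (K, N)


# --- nulls ------------------------------------------------------------------


def _pair_lookup(nodes: NodeSet) -> np.ndarray:
    homolog = np.full(nodes.n_nodes, -1, dtype=int)
    for i, j in nodes.pair_map:
        homolog[i], homolog[j] = j, i
    return homolog


def _anchoring_null_draws(
    nodes: NodeSet, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Anchoring counts under i.i.d. exchangeable weights on the complete
    graph, vectorized over permutations."""
    n = nodes.n_nodes
    homolog = _pair_lookup(nodes)
    paired = homolog >= 0
    counts = np.empty(n_perm, dtype=int)
    batch = max(1, min(n_perm, 4_000_000 // (n * n)))
    done = 0
    while done < n_perm:
        b = min(batch, n_perm - done)
        U = rng.random((b, n, n))
        U = np.triu(U, 1)
        U = U + np.transpose(U, (0, 2, 1))
        idx = np.arange(n)
        U[:, idx, idx] = -1.0
        partners = np.argmax(U, axis=2)
        counts[done : done + b] = (partners[:, paired] == homolog[paired]).sum(axis=1)
        done += b
    return counts


def _exact_anchoring_pmf(nodes: NodeSet) -> dict[int, float]:
    """Exact distribution of the anchoring count under i.i.d. edge weights.

    Edges processed in descending weight order form an exchangeable
    sequence; the first edge incident to a node is that node's strongest
    link.  Conditional on the set of still-unfixed nodes, the next edge
    touching an unfixed node is uniform over such edges, which yields a
    subset-indexed recursion over at most 2^n states.
    """
    n = nodes.n_nodes
    if n > _EXACT_MAX_NODES:
        raise ValueError(
            f"exact anchoring null limited to n <= {_EXACT_MAX_NODES}, got {n}"
        )
    homolog = _pair_lookup(nodes)
    edges = list(itertools.combinations(range(n), 2))
    memo: dict[int, dict[int, float]] = {}

    def solve(mask: int) -> dict[int, float]:
        # mask: bit set = node still unfixed
        if mask == 0:
            return {0: 1.0}
        if mask in memo:
            return memo[mask]
        relevant = [(u, v) for u, v in edges if (mask >> u) & 1 or (mask >> v) & 1]
        out: dict[int, float] = {}
        p_edge = 1.0 / len(relevant)
        for u, v in relevant:
            inc = 0
            new_mask = mask
            for w, other in ((u, v), (v, u)):
                if (mask >> w) & 1:
                    new_mask &= ~(1 << w)
                    if homolog[w] == other:
                        inc += 1
            for k, p in solve(new_mask).items():
                out[k + inc] = out.get(k + inc, 0.0) + p_edge * p
        memo[mask] = out
        return out

    return solve((1 << n) - 1)


def null_anchoring(
    nodes: NodeSet,
    observed: int,
    n_perm: int = 999,
    seed: int = 0,
    mode: str = "permute",
) -> NullResult:
    """Chance null for the anchoring count.

    Under the null, all edge weights of the complete network are
    exchangeable (i.i.d. ranks); each node's strongest partner is then
    uniform over the other nodes marginally, with the dependence between
    nodes handled exactly (``mode="exact"``, n <= 10) or by Monte Carlo
    redraws (``mode="permute"``); p = (1 + #{null >= obs}) / (1 + n_perm)
    in permutation mode.
    """
    if mode == "permute":
        if n_perm < 100:
            raise ValueError("permutation null needs n_perm >= 100")
        rng = np.random.default_rng(seed)
        counts = _anchoring_null_draws(nodes, n_perm, rng)
        p = (1 + int((counts >= observed).sum())) / (1 + n_perm)
        return NullResult(
            observed=observed, p_value=p, mode=mode, null_counts=counts, n_perm=n_perm
        )
    if mode == "exact":
        pmf = _exact_anchoring_pmf(nodes)
        p = sum(prob for k, prob in pmf.items() if k >= observed)
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        return NullResult(observed=observed, p_value=p, mode=mode, null_pmf=pmf)
    raise ValueError(f"unknown null mode {mode!r}")


def _colocation_count(assign: np.ndarray, pair_map) -> int:
    return sum(1 for i, j in pair_map if assign[i] == assign[j])


def _exact_colocation_pmf(
    module_sizes: list[int], nodes: NodeSet
) -> dict[int, float]:
    n = nodes.n_nodes
    if n > _EXACT_MAX_NODES:
        raise ValueError(
            f"exact co-location null limited to n <= {_EXACT_MAX_NODES}, got {n}"
        )
    pmf: dict[int, float] = {}
    total = 0

    def recurse(remaining: frozenset[int], sizes: list[int], assign: dict[int, int]):
        nonlocal total
        if not sizes:
            a = np.array([assign[i] for i in range(n)])
            k = _colocation_count(a, nodes.pair_map)
            pmf[k] = pmf.get(k, 0.0) + 1.0
            total += 1
            return
        size = sizes[0]
        rest = sorted(remaining)
        anchor = rest[0]  # anchor the smallest label to kill module-label symmetry
        for combo in itertools.combinations(rest[1:], size - 1):
            members = (anchor,) + combo
            for mbr in members:
                assign[mbr] = len(sizes)
            recurse(remaining - set(members), sizes[1:], assign)

    recurse(frozenset(range(n)), sorted(module_sizes, reverse=True), {})
    return {k: v / total for k, v in pmf.items()}


def null_colocation(
    module_sizes: list[int],
    nodes: NodeSet,
    observed: int,
    n_perm: int = 999,
    seed: int = 0,
    mode: str = "permute",
) -> NullResult:
    """Chance null for the number of co-located homotopic pairs.

    Node labels are randomly reassigned over the fixed module-size vector;
    exact mode enumerates every assignment (n <= 10).
    """
    sizes = [int(s) for s in module_sizes]
    if sum(sizes) != nodes.n_nodes:
        raise ValueError(
            f"module sizes sum to {sum(sizes)}, node count is {nodes.n_nodes}"
        )
    if mode == "permute":
        if n_perm < 100:
            raise ValueError("permutation null needs n_perm >= 100")
        rng = np.random.default_rng(seed)
        template = np.repeat(np.arange(len(sizes)), sizes)
        counts = np.empty(n_perm, dtype=int)
        for t in range(n_perm):
            assign = np.empty(nodes.n_nodes, dtype=int)
            assign[rng.permutation(nodes.n_nodes)] = template
            counts[t] = _colocation_count(assign, nodes.pair_map)
        p = (1 + int((counts >= observed).sum())) / (1 + n_perm)
        return NullResult(
            observed=observed, p_value=p, mode=mode, null_counts=counts, n_perm=n_perm
        )
    if mode == "exact":
        pmf = _exact_colocation_pmf(sizes, nodes)
        p = sum(prob for k, prob in pmf.items() if k >= observed)
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        return NullResult(observed=observed, p_value=p, mode=mode, null_pmf=pmf)
    raise ValueError(f"unknown null mode {mode!r}")


def homotopy_report(
    W: np.ndarray,
    partition: Partition,
    nodes: NodeSet,
    n_perm: int = 999,
    seed: int = 0,
) -> HomotopyReport:
    """Assemble the full homotopy analysis of a weighted network and its
    module partition, with permutation nulls for both statistics."""
    links = strongest_link_per_node(W)
    anchored, total = anchoring_count(links, nodes)
    n_coloc, coloc_pairs = module_pairing(partition, nodes)
    per_module, totals = symmetry_ratios(partition, nodes)
    sizes = [len(partition.members(m)) for m in range(partition.n_modules)]
    seeds = np.random.SeedSequence(seed).generate_state(2) % (2**31)
    p_anchor = null_anchoring(
        nodes, anchored, n_perm=n_perm, seed=int(seeds[0])
    ).p_value
    p_coloc = null_colocation(
        sizes, nodes, n_coloc, n_perm=n_perm, seed=int(seeds[1])
    ).p_value
    unique = links.unique_links
    homolog = _pair_lookup(nodes)
    n_unique_homotopic = sum(1 for i, j in unique if homolog[i] == j)
    return HomotopyReport(
        strongest=links,
        anchored_nodes=anchored,
        anchored_total=total,
        pairs_colocated=n_coloc,
        colocated_pairs=coloc_pairs,
        symmetry_per_module=per_module,
        symmetry_total=totals,
        p_anchoring=p_anchor,
        p_colocation=p_coloc,
        flags={
            "n_unique_strongest_links": len(unique),
            "n_unique_homotopic_strongest_links": n_unique_homotopic,
            "n_isolated": int(links.isolated.sum()),
            "n_ties": int(links.tied.sum()),
            "n_perm": n_perm,
        },
    )
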