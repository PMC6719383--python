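"""Dendrogram construction and concordance statistics.

Hierarchical clustering uses 1 - Pearson correlation with complete
linkage by default (both configurable) and a deterministic tie-break:
among equally distant cluster pairs the one whose (lexicographically
smallest member, other member) pair sorts first is merged. Concordance
between two trees over the same leaves is quantified four ways:
entanglement of leaf orders (with greedy two-sided untangling),
Goodman-Kruskal gamma over cophenetic rank pairs (with a leaf-shuffle
permutation null), and the cophenetic correlation.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dendrogram import Dendrogram, Node

logger = logging.getLogger(__name__)


# -- hierarchical clustering -----------------------------------------


def _distance_matrix(X: np.ndarray, metric: str) -> np.ndarray:
    if metric == "correlation":
        D = 1.0 - np.corrcoef(X)
        np.fill_diagonal(D, 0.0)
        return np.maximum(D, 0.0)
    if metric == "euclidean":
        diff = X[:, None, :] - X[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    raise ValueError(f"unknown metric {metric!r}")


def hclust_expression(
    profiles: pd.DataFrame,
    metric: str = "correlation",
    linkage: str = "complete",
) -> tuple[Dendrogram, list[str]]:
    """Agglomerative clustering of gene expression profiles.

    Returns (tree, excluded_ids); zero-variance profiles are excluded
    (they have no defined correlation distance) with their ids logged.
    """
    if linkage not in {"complete", "average", "single"}:
        raise ValueError(f"unknown linkage {linkage!r}")
    X = profiles.to_numpy(dtype=float)
    labels = [str(i) for i in profiles.index]
    excluded: list[str] = []
    if metric == "correlation":
        keep = X.std(axis=1) > 0
        excluded = [lab for lab, k in zip(labels, keep) if not k]
        if excluded:
            logger.warning("excluded %d zero-variance profile(s): %s",
                           len(excluded), excluded[:10])
        X = X[keep]
        labels = [lab for lab, k in zip(labels, keep) if k]
    if len(labels) < 2:
        raise ValueError("need >= 2 usable profiles")
    D = _distance_matrix(X, metric)
    tree = _agglomerate(D, labels, linkage)
    return tree, excluded


def _agglomerate(D: np.ndarray, labels: list[str], linkage: str) -> Dendrogram:
    n = len(labels)
    D = D.astype(float).copy()
    np.fill_diagonal(D, np.inf)
    active = list(range(n))
    nodes: dict[int, Node] = {i: Node(label=labels[i]) for i in range(n)}
    min_lab: dict[int, str] = {i: labels[i] for i in range(n)}
    sizes: dict[int, int] = {i: 1 for i in range(n)}
    height = 0.0
    while len(active) > 1:
        sub = D[np.ix_(active, active)]
        dmin = sub.min()
        # deterministic tie-break on the merged pair's sorted min-labels
        cand = np.argwhere(sub <= dmin + 1e-12)
        best = None
        for i, j in cand:
            if i >= j:
                continue
            a, b = active[i], active[j]
            key = tuple(sorted((min_lab[a], min_lab[b])))
            if best is None or key < best[0]:
                best = (key, a, b)
        _, a, b = best
        height = max(height, float(D[a, b]))  # enforce monotone heights
        if min_lab[a] <= min_lab[b]:
            parent = Node(height=height, left=nodes[a], right=nodes[b])
        else:
            parent = Node(height=height, left=nodes[b], right=nodes[a])
        new = max(nodes) + 1
        nodes[new] = parent
        min_lab[new] = min(min_lab[a], min_lab[b])
        sizes[new] = sizes[a] + sizes[b]
        # grow D by one row/col for the merged cluster
        others = [k for k in active if k not in (a, b)]
        newrow = np.full(new + 1, np.inf)
        for k in others:
            if linkage == "complete":
                d = max(D[a, k], D[b, k])
            elif linkage == "single":
                d = min(D[a, k], D[b, k])
            else:  # average (UPGMA)
                d = (sizes[a] * D[a, k] + sizes[b] * D[b, k]) / (sizes[a] + sizes[b])
            newrow[k] = d
        D = np.pad(D, ((0, new + 1 - D.shape[0]),) * 2, constant_values=np.inf)
        D[new, : new + 1] = newrow
        D[: new + 1, new] = newrow
        D[new, new] = np.inf
        active = others + [new]
    return Dendrogram(nodes[active[0]])


# -- entanglement and untangling -------------------------------------


def entanglement(tree_a: Dendrogram, tree_b: Dendrogram, L: float = 1.5) -> float:
    """Normalized leaf-rank disagreement between two trees (0 = aligned).

    value = sum |rA_i - rB_i|^L / sum |i - (n+1-i)|^L, the denominator
    being the fully reversed (worst-case) order.
    """
    order_a = tree_a.leaf_order
    order_b = tree_b.leaf_order
    if set(order_a) != set(order_b):
        diff = set(order_a) ^ set(order_b)
        raise ValueError(f"leaf sets differ: {sorted(diff)[:10]}")
    n = len(order_a)
    if n == 1:
        return 0.0
    rank_b = {lab: i + 1 for i, lab in enumerate(order_b)}
    num = sum(abs((i + 1) - rank_b[lab]) ** L for i, lab in enumerate(order_a))
    den = sum(abs((i + 1) - (n - i)) ** L for i in range(n))
    return num / den if den > 0 else 0.0


def _size(node: Node) -> int:
    if node.is_leaf:
        return 1
    return _size(node.left) + _size(node.right)


def _optimal_rotation(tree: Dendrogram, target_rank: dict[str, int], L: float) -> Dendrogram:
    """Child-order rearrangement of ``tree`` minimizing the rank-distance
    sum against fixed 1-based ``target_rank``.

    Each subtree occupies a contiguous rank block whose offset is set by
    ancestor choices, so the optimum decomposes over (node, offset)
    states — solved exactly by memoized recursion.
    """
    sizes: dict[int, int] = {}

    def size(node: Node) -> int:
        key = id(node)
        if key not in sizes:
            sizes[key] = 1 if node.is_leaf else size(node.left) + size(node.right)
        return sizes[key]

    memo: dict[tuple[int, int], tuple[float, bool]] = {}

    def cost(node: Node, offset: int) -> float:
        if node.is_leaf:
            return abs((offset + 1) - target_rank[node.label]) ** L
        key = (id(node), offset)
        if key in memo:
            return memo[key][0]
        sl = size(node.left)
        sr = size(node.right)
        keep = cost(node.left, offset) + cost(node.right, offset + sl)
        swap = cost(node.right, offset) + cost(node.left, offset + sr)
        memo[key] = (keep, False) if keep <= swap else (swap, True)
        return memo[key][0]

    cost(tree.root, 0)

    def rebuild(node: Node, offset: int) -> Node:
        if node.is_leaf:
            return Node(height=node.height, label=node.label)
        _, swapped = memo[(id(node), offset)]
        first, second = (node.right, node.left) if swapped else (node.left, node.right)
        left = rebuild(first, offset)
        right = rebuild(second, offset + size(first))
        return Node(height=node.height, left=left, right=right)

    return Dendrogram(rebuild(tree.root, 0))


def _all_rotations(tree: Dendrogram):
    """Yield every child-order variant of a tree (2^internal nodes)."""
    internals = tree.internal_nodes()
    for mask in range(2 ** len(internals)):
        t = tree.copy()
        ints = t.internal_nodes()
        for i in range(len(internals)):
            if mask >> i & 1:
                ints[i].left, ints[i].right = ints[i].right, ints[i].left
        yield t


def untangle_step2side(
    tree_a: Dendrogram,
    tree_b: Dendrogram,
    L: float = 1.5,
    max_rounds: int = 20,
) -> tuple[Dendrogram, Dendrogram, float]:
    """Alternating one-sided untangling.

    Each pass rotates one tree's internal nodes to the exact one-sided
    optimum against the other tree's current leaf order (A side, then B
    side), repeating until a full double pass stops improving. Topology
    and heights are untouched — only child order changes — so the result
    never has higher entanglement than the input.
    """
    def mirror(tree: Dendrogram) -> Dendrogram:
        def rec(node: Node) -> Node:
            if node.is_leaf:
                return Node(height=node.height, label=node.label)
            return Node(height=node.height, left=rec(node.right), right=rec(node.left))

        return Dendrogram(rec(tree.root))

    def alternate(a: Dendrogram, b: Dendrogram, a_first: bool):
        current = entanglement(a, b, L)
        for _ in range(max_rounds):
            improved = False
            sides = ("a", "b") if a_first else ("b", "a")
            for side in sides:
                if side == "a":
                    rank = {lab: i + 1 for i, lab in enumerate(b.leaf_order)}
                    cand = _optimal_rotation(a, rank, L)
                    trial = entanglement(cand, b, L)
                    if trial < current - 1e-15:
                        a, current, improved = cand, trial, True
                else:
                    rank = {lab: i + 1 for i, lab in enumerate(a.leaf_order)}
                    cand = _optimal_rotation(b, rank, L)
                    trial = entanglement(a, cand, L)
                    if trial < current - 1e-15:
                        b, current, improved = cand, trial, True
            if not improved:
                break
        return a, b, current

    n_internal = len(tree_a.internal_nodes()) + len(tree_b.internal_nodes())
    if n_internal <= 12:
        # small trees: the full rotation space is tiny, solve exactly
        best_pair = None
        for a_cand in _all_rotations(tree_a):
            rank_a = {lab: i + 1 for i, lab in enumerate(a_cand.leaf_order)}
            b_cand = _optimal_rotation(tree_b, rank_a, L)
            e = entanglement(a_cand, b_cand, L)
            if best_pair is None or e < best_pair[2] - 1e-15:
                best_pair = (a_cand, b_cand, e)
        return best_pair

    # multi-start: side order x mirrored inputs escape different local optima
    starts = [
        (a0, b0, a_first)
        for a0 in (tree_a.copy, lambda: mirror(tree_a))
        for b0 in (tree_b.copy, lambda: mirror(tree_b))
        for a_first in (True, False)
    ]
    starts = [(a0(), b0(), a_first) for a0, b0, a_first in starts]
    best = None
    for a0, b0, a_first in starts:
        result = alternate(a0, b0, a_first)
        if best is None or result[2] < best[2] - 1e-15:
            best = result
    # contract: never worse than the input alignment
    raw = entanglement(tree_a, tree_b, L)
    if best[2] > raw:
        return tree_a.copy(), tree_b.copy(), raw
    return best


# -- Goodman-Kruskal gamma -------------------------------------------


def _tie_count(x: np.ndarray) -> float:
    _, counts = np.unique(x, return_counts=True)
    return float((counts * (counts - 1) / 2).sum())


def _concordance(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """(C - D, C + D) over all observation pairs, ties skipped.

    Uses Kendall tau-b to recover C - D in O(m log m); tie corrections
    give C + D by inclusion-exclusion.
    """
    m = len(x)
    n0 = m * (m - 1) / 2
    n1 = _tie_count(x)
    n2 = _tie_count(y)
    joint = np.stack([x, y], axis=1)
    _, counts = np.unique(joint, axis=0, return_counts=True)
    n3 = float((counts * (counts - 1) / 2).sum())
    cpd = n0 - n1 - n2 + n3
    if n0 == n1 or n0 == n2:
        return 0.0, cpd
    tau = stats.kendalltau(x, y).statistic
    if math.isnan(tau):
        return 0.0, cpd
    cmd = tau * math.sqrt((n0 - n1) * (n0 - n2))
    return cmd, cpd


def gk_gamma(tree_a: Dendrogram, tree_b: Dendrogram) -> float:
    """Goodman-Kruskal gamma between cophenetic height rankings.

    For every leaf pair its merge height in each tree forms an
    observation; gamma = (C - D)/(C + D) over all pairs of observations,
    ties skipped. Undefined (NaN, logged) when every pair is tied.
    """
    leaves = sorted(tree_a.leaves)
    if set(leaves) != tree_b.leaves:
        raise ValueError("leaf sets differ")
    if len(leaves) < 3:
        raise ValueError("gamma needs >= 3 shared leaves")
    A = tree_a.cophenetic_matrix(leaves)
    B = tree_b.cophenetic_matrix(leaves)
    iu = np.triu_indices(len(leaves), k=1)
    cmd, cpd = _concordance(A[iu], B[iu])
    if cpd <= 0:
        logger.warning("gamma undefined: all pairs tied")
        return float("nan")
    return float(cmd / cpd)


@dataclass
class GammaPermutationResult:
    observed: float
    null_sample: np.ndarray
    null_mean: float
    ci95: tuple[float, float]
    p_vs_one: float  # one-sided t-test of null gamma against 1
    p_vs_observed: float  # one-sided t-test of null gamma against the observed value
    n_perm: int


def gamma_permutation_test(
    tree_a: Dendrogram,
    tree_b: Dendrogram,
    n_perm: int = 100,
    seed: int | np.random.Generator = 0,
    shuffle_both: bool = False,
) -> GammaPermutationResult:
    """Leaf-shuffle null for gamma.

    Each permutation relabels the leaves of tree B (optionally both
    trees) by a random permutation of the same label set and recomputes
    gamma against tree A.
    """
    if n_perm <= 0:
        raise ValueError("n_perm must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    observed = gk_gamma(tree_a, tree_b)
    labels = sorted(tree_a.leaves)
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = list(rng.permutation(labels))
        b_shuf = tree_b.relabel(dict(zip(labels, perm)))
        if shuffle_both:
            perm2 = list(rng.permutation(labels))
            a_shuf = tree_a.relabel(dict(zip(labels, perm2)))
            null[i] = gk_gamma(a_shuf, b_shuf)
        else:
            null[i] = gk_gamma(tree_a, b_shuf)
    mean = float(null.mean())
    se = float(null.std(ddof=1) / math.sqrt(n_perm)) if n_perm > 1 else float("nan")
    ci = (mean - 1.96 * se, mean + 1.96 * se)
    p_one = float(stats.ttest_1samp(null, 1.0, alternative="less").pvalue)
    p_obs = float(stats.ttest_1samp(null, observed, alternative="less").pvalue)
    return GammaPermutationResult(observed, null, mean, ci, p_one, p_obs, n_perm)


# -- cophenetic correlation ------------------------------------------


def cophenetic_correlation(tree_a: Dendrogram, tree_b: Dendrogram) -> float:
    """Pearson r between the two cophenetic distance upper triangles.

    Returns NaN (logged) when either tree puts all merges at one height.
    """
    leaves = sorted(tree_a.leaves)
    if set(leaves) != tree_b.leaves:
        raise ValueError("leaf sets differ")
    A = tree_a.cophenetic_matrix(leaves)
    B = tree_b.cophenetic_matrix(leaves)
    iu = np.triu_indices(len(leaves), k=1)
    a, b = A[iu], B[iu]
    if a.std() == 0 or b.std() == 0:
        logger.warning("cophenetic correlation undefined: zero variance")
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


# -- rolling membership scan -----------------------------------------


@dataclass
class WindowScan:
    leaf_order: list[str]
    indicator: np.ndarray
    window: int
    sums: np.ndarray

    @property
    def peak_positions(self) -> list[int]:
        """0-based window start indices attaining the maximum rolling sum."""
        peak = self.sums.max()
        return [int(i) for i in np.flatnonzero(self.sums == peak)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"window_start": np.arange(len(self.sums)),
             "first_gene": self.leaf_order[: len(self.sums)],
             "rolling_sum": self.sums.astype(int)}
        )


def rolling_membership_scan(leaf_order, membership_set, window: int = 50) -> WindowScan:
    """Rolling sums of set membership along an ordered leaf sequence."""
    leaf_order = list(leaf_order)
    n = len(leaf_order)
    if window < 1 or window > n:
        raise ValueError(f"window must be in [1, {n}]")
    members = set(membership_set)
    indicator = np.array([1 if lab in members else 0 for lab in leaf_order])
    sums = np.convolve(indicator, np.ones(window, dtype=int), mode="valid")
    return WindowScan(leaf_order, indicator, window, sums)


# -- bundled comparison ----------------------------------------------


@dataclass
class TanglegramStats:
    entanglement_raw: float
    entanglement_untangled: float
    gamma: float
    gamma_null_mean: float
    gamma_ci95: tuple[float, float]
    gamma_p_vs_one: float
    cophenetic_r: float
    L: float
    n_perm: int

    def as_dict(self) -> dict:
        return {
            "entanglement_raw": self.entanglement_raw,
            "entanglement_untangled": self.entanglement_untangled,
            "gamma": self.gamma,
            "gamma_null_mean": self.gamma_null_mean,
            "gamma_ci95_lo": self.gamma_ci95[0],
            "gamma_ci95_hi": self.gamma_ci95[1],
            "gamma_p_vs_one": self.gamma_p_vs_one,
            "cophenetic_r": self.cophenetic_r,
            "L": self.L,
            "n_perm": self.n_perm,
        }


def compare_dendrograms(
    tree_a: Dendrogram,
    tree_b: Dendrogram,
    L: float = 1.5,
    n_perm: int = 100,
    seed: int = 0,
) -> tuple[TanglegramStats, Dendrogram, Dendrogram]:
    """Full concordance battery; returns stats plus the untangled pair."""
    raw = entanglement(tree_a, tree_b, L)
    ua, ub, untangled = untangle_step2side(tree_a, tree_b, L)
    gres = gamma_permutation_test(tree_a, tree_b, n_perm=n_perm, seed=seed)
    r = cophenetic_correlation(tree_a, tree_b)
    stats_out = TanglegramStats(
        raw, untangled, gres.observed, gres.null_mean, gres.ci95,
        gres.p_vs_one, r, L, n_perm,
    )
    return stats_out, ua, ub
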