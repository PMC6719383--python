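import itertools

import numpy as np
import pandas as pd
import pytest

from conftest import random_tree
from mitosense import concordance
from mitosense.concordance import (
    cophenetic_correlation,
    entanglement,
    gamma_permutation_test,
    gk_gamma,
    hclust_expression,
    rolling_membership_scan,
    untangle_step2side,
)
from mitosense.dendrogram import Dendrogram, Node


def mirror(tree: Dendrogram) -> Dendrogram:
    """Flip every internal node -> exactly reversed leaf order."""

    def rec(node: Node) -> Node:
        if node.is_leaf:
            return Node(height=node.height, label=node.label)
        return Node(height=node.height, left=rec(node.right), right=rec(node.left))

    return Dendrogram(rec(tree.root))


def brute_gamma(tree_a, tree_b):
    """Oracle: O(m^2) pair-of-pairs enumeration of (C - D)/(C + D)."""
    leaves = sorted(tree_a.leaves)
    A = tree_a.cophenetic_matrix(leaves)
    B = tree_b.cophenetic_matrix(leaves)
    pairs = list(itertools.combinations(range(len(leaves)), 2))
    x = [A[i, j] for i, j in pairs]
    y = [B[i, j] for i, j in pairs]
    C = D = 0
    for u in range(len(x)):
        for v in range(u + 1, len(x)):
            dx = np.sign(x[u] - x[v])
            dy = np.sign(y[u] - y[v])
            if dx == 0 or dy == 0:
                continue
            if dx == dy:
                C += 1
            else:
                D += 1
    return (C - D) / (C + D) if C + D else float("nan")


class TestHclust:
    def test_identical_profiles_merge_first(self):
        df = pd.DataFrame(
            [[1.0, 2.0, 3.0, 1.5], [1.0, 2.0, 3.0, 1.5], [3.0, 1.0, 0.5, 4.0]],
            index=["a", "b", "c"],
        )
        tree, _ = hclust_expression(df)
        first = tree.root.left if not tree.root.left.is_leaf else tree.root.right
        assert {first.left.label, first.right.label} == {"a", "b"}

    def test_manual_complete_linkage_trace(self):
        # hand-built distance structure via profiles with known correlations
        df = pd.DataFrame(
            [[0.0, 1.0, 2.0], [0.1, 1.0, 2.1], [2.0, 1.0, 0.0]],
            index=["a", "b", "c"],
        )
        X = df.to_numpy()
        D = 1 - np.corrcoef(X)
        tree, _ = hclust_expression(df)
        # a,b nearly perfectly correlated -> merge first at 1 - r_ab
        inner = tree.root.left if not tree.root.left.is_leaf else tree.root.right
        assert {inner.left.label, inner.right.label} == {"a", "b"}
        assert inner.height == pytest.approx(D[0, 1], abs=1e-12)
        # complete linkage: root height = max(d(a,c), d(b,c))
        assert tree.root.height == pytest.approx(max(D[0, 2], D[1, 2]), abs=1e-12)

    def test_zero_variance_profile_excluded(self):
        df = pd.DataFrame(
            [[1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [2.0, 1.0, 0.0]],
            index=["flat", "a", "b"],
        )
        tree, excluded = hclust_expression(df)
        assert excluded == ["flat"]
        assert tree.leaves == {"a", "b"}

    def test_deterministic(self, rng):
        df = pd.DataFrame(rng.normal(size=(12, 6)), index=[f"g{i}" for i in range(12)])
        t1, _ = hclust_expression(df)
        t2, _ = hclust_expression(df)
        assert t1.leaf_order == t2.leaf_order


class TestEntanglement:
    def test_identity_zero(self, rng):
        t = random_tree(list("ABCDEFG"), rng)
        assert entanglement(t, t) == 0.0

    def test_reversed_is_one(self, rng):
        t = random_tree(list("ABCDEF"), rng)
        assert entanglement(t, mirror(t)) == pytest.approx(1.0)

    def test_three_leaf_worked_example(self):
        # orders (A,B,C) vs (A,C,B) at L=1.5: 2 / (2*2^1.5) = 0.35355
        ab = Node(height=1, left=Node(label="A"), right=Node(label="B"))
        t1 = Dendrogram(Node(height=2, left=ab, right=Node(label="C")))
        ac = Node(height=1, left=Node(label="A"), right=Node(label="C"))
        t2 = Dendrogram(Node(height=2, left=ac, right=Node(label="B")))
        assert entanglement(t1, t2, L=1.5) == pytest.approx(2 / (2 * 2**1.5), rel=1e-9)

    def test_leaf_mismatch_errors(self, rng):
        t1 = random_tree(list("ABC"), rng)
        t2 = random_tree(list("ABD"), rng)
        with pytest.raises(ValueError, match="leaf sets"):
            entanglement(t1, t2)


class TestUntangle:
    def test_already_aligned_unchanged(self, rng):
        t = random_tree(list("ABCDE"), rng)
        a, b, e = untangle_step2side(t, t.copy())
        assert e == 0.0
        assert a.leaf_order == t.leaf_order

    def test_never_increases(self, rng):
        for _ in range(20):
            labels = [f"L{i}" for i in range(int(rng.integers(3, 10)))]
            t1 = random_tree(labels, rng)
            t2 = random_tree(labels, rng)
            before = entanglement(t1, t2)
            _, _, after = untangle_step2side(t1, t2)
            assert after <= before + 1e-12

    def test_topology_preserved(self, rng):
        labels = list("ABCDEF")
        t1 = random_tree(labels, rng)
        t2 = random_tree(labels, rng)
        a, b, _ = untangle_step2side(t1, t2)
        order = sorted(labels)
        assert np.allclose(a.cophenetic_matrix(order), t1.cophenetic_matrix(order))
        assert np.allclose(b.cophenetic_matrix(order), t2.cophenetic_matrix(order))

    def test_four_leaf_reaches_exhaustive_optimum(self, rng):
        labels = list("ABCD")
        for _ in range(10):
            t1 = random_tree(labels, rng)
            t2 = random_tree(labels, rng)
            _, _, got = untangle_step2side(t1, t2)
            best = exhaustive_min_entanglement(t1, t2)
            assert got <= best + 0.05


def all_rotations(tree: Dendrogram):
    internals = tree.internal_nodes()
    k = len(internals)
    for mask in range(2**k):
        t = tree.copy()
        ints = t.internal_nodes()
        for i in range(k):
            if mask >> i & 1:
                ints[i].left, ints[i].right = ints[i].right, ints[i].left
        yield t


def exhaustive_min_entanglement(t1, t2, L=1.5):
    return min(
        entanglement(a, b, L) for a in all_rotations(t1) for b in all_rotations(t2)
    )


class TestGamma:
    def test_identical_trees(self, rng):
        t = random_tree(list("ABCDE"), rng)
        assert gk_gamma(t, t) == pytest.approx(1.0)

    def test_brute_force_oracle_small_trees(self, rng):
        for _ in range(30):
            n = int(rng.integers(3, 6))
            labels = [f"L{i}" for i in range(n)]
            t1 = random_tree(labels, rng)
            t2 = random_tree(labels, rng)
            want = brute_gamma(t1, t2)
            got = gk_gamma(t1, t2)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-9)

    def test_random_relabeling_near_zero_on_average(self, rng):
        labels = [f"L{i}" for i in range(20)]
        t = random_tree(labels, rng)
        vals = []
        for _ in range(30):
            perm = list(rng.permutation(labels))
            vals.append(gk_gamma(t, t.relabel(dict(zip(labels, perm)))))
        assert abs(np.mean(vals)) < 0.15

    def test_too_few_leaves(self, rng):
        t = random_tree(["A", "B"], rng)
        with pytest.raises(ValueError):
            gk_gamma(t, t)


class TestGammaPermutation:
    def test_deterministic_under_seed(self, rng):
        labels = [f"L{i}" for i in range(12)]
        t1 = random_tree(labels, rng)
        t2 = random_tree(labels, rng)
        r1 = gamma_permutation_test(t1, t2, n_perm=15, seed=7)
        r2 = gamma_permutation_test(t1, t2, n_perm=15, seed=7)
        assert np.array_equal(r1.null_sample, r2.null_sample)

    def test_null_mean_near_zero(self, rng):
        labels = [f"L{i}" for i in range(50)]
        t1 = random_tree(labels, rng)
        t2 = random_tree(labels, rng)
        res = gamma_permutation_test(t1, t2, n_perm=60, seed=3)
        se = res.null_sample.std(ddof=1) / np.sqrt(len(res.null_sample))
        assert abs(res.null_mean) <= 3 * se + 0.02

    def test_rejects_perfect_alignment_null(self, rng):
        labels = [f"L{i}" for i in range(30)]
        t = random_tree(labels, rng)
        res = gamma_permutation_test(t, t.copy(), n_perm=30, seed=1)
        assert res.observed == pytest.approx(1.0)
        assert res.p_vs_one < 0.01  # null gammas are far below 1

    def test_bad_n_perm(self, rng):
        t = random_tree(list("ABC"), rng)
        with pytest.raises(ValueError):
            gamma_permutation_test(t, t, n_perm=0)


class TestCophenetic:
    def test_identical_trees(self, rng):
        t = random_tree(list("ABCDEFGH"), rng)
        assert cophenetic_correlation(t, t) == pytest.approx(1.0)

    def test_hand_computed_four_leaf(self):
        # T1: ((A,B):1,(C,D):2):3 ; T2: ((A,C):1,(B,D):2):3
        t1 = Dendrogram(Node(height=3,
                             left=Node(height=1, left=Node(label="A"), right=Node(label="B")),
                             right=Node(height=2, left=Node(label="C"), right=Node(label="D"))))
        t2 = Dendrogram(Node(height=3,
                             left=Node(height=1, left=Node(label="A"), right=Node(label="C")),
                             right=Node(height=2, left=Node(label="B"), right=Node(label="D"))))
        # upper triangles in order A,B,C,D:
        x = np.array([1, 3, 3, 3, 3, 2], dtype=float)  # T1: AB,AC,AD,BC,BD,CD
        y = np.array([3, 1, 3, 3, 2, 3], dtype=float)
        want = np.corrcoef(x, y)[0, 1]
        assert cophenetic_correlation(t1, t2) == pytest.approx(want, rel=1e-12)

    def test_single_height_flagged(self):
        # all merges at height 1 -> zero variance in cophenetic distances
        t = Dendrogram(Node(height=1.0,
                            left=Node(height=1.0, left=Node(label="A"), right=Node(label="B")),
                            right=Node(label="C")))
        assert np.isnan(cophenetic_correlation(t, t))


class TestRollingScan:
    def test_worked_example(self):
        scan = rolling_membership_scan(list("abcde"), {"a", "c", "d"}, window=2)
        assert scan.sums.tolist() == [1, 1, 2, 1]

    def test_all_members(self):
        scan = rolling_membership_scan([f"g{i}" for i in range(60)],
                                       {f"g{i}" for i in range(60)}, window=50)
        assert np.all(scan.sums == 50)

    def test_empty_membership(self):
        scan = rolling_membership_scan(list("abc"), set(), window=2)
        assert np.all(scan.sums == 0)

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            rolling_membership_scan(list("ab"), set(), window=3)

    def test_total_conservation(self, rng):
        n, w = 40, 7
        order = [f"g{i}" for i in range(n)]
        members = {g for g in order if rng.random() < 0.3}
        scan = rolling_membership_scan(order, members, window=w)
        # each position i is covered by min(i+1, w, n-w+1, n-i) windows
        cover = [min(i + 1, w, n - w + 1, n - i) for i in range(n)]
        want = sum(c * m for c, m in zip(cover, scan.indicator))
        assert scan.sums.sum() == want

    def test_peak_positions(self):
        scan = rolling_membership_scan(list("abcdef"), {"c", "d"}, window=2)
        assert scan.peak_positions == [2]


def test_compare_dendrograms_bundle(rng):
    labels = [f"L{i}" for i in range(15)]
    t1 = random_tree(labels, rng)
    t2 = random_tree(labels, rng)
    stats, ua, ub = concordance.compare_dendrograms(t1, t2, n_perm=10, seed=0)
    assert 0 <= stats.entanglement_untangled <= stats.entanglement_raw <= 1
    assert -1 <= stats.gamma <= 1
    assert len(stats.__dict__) > 0
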