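"""Rooted binary merge trees (dendrograms) with heights and leaf order.

The tree is the unit of currency for the concordance stage: entanglement
and untangling act on the left-to-right leaf order, Goodman-Kruskal
gamma and the cophenetic correlation act on cophenetic (merge-height)
distances. Newick I/O encodes each branch length as the height drop from
parent to child, so ultrametric trees round-trip exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np


class NewickParseError(ValueError):
    pass


@dataclass
class Node:
    """A dendrogram node; a leaf iff ``label`` is set."""

    height: float = 0.0
    label: str | None = None
    left: "Node | None" = None
    right: "Node | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.label is not None

    def copy(self) -> "Node":
        if self.is_leaf:
            return Node(height=self.height, label=self.label)
        return Node(height=self.height, left=self.left.copy(), right=self.right.copy())


class Dendrogram:
    def __init__(self, root: Node):
        self.root = root
        self._validate()

    # -- construction -------------------------------------------------

    @classmethod
    def from_linkage(cls, Z: np.ndarray, labels: Sequence[str]) -> "Dendrogram":
        """Build from a scipy-style linkage matrix.

        Child order is canonicalized: the subtree whose lexicographically
        smallest leaf label is smaller goes left, so leaf order is
        deterministic across platforms.
        """
        n = len(labels)
        nodes: dict[int, Node] = {i: Node(label=str(labels[i])) for i in range(n)}
        min_label: dict[int, str] = {i: str(labels[i]) for i in range(n)}
        for k, row in enumerate(np.asarray(Z)):
            a, b, h = int(row[0]), int(row[1]), float(row[2])
            la, lb = nodes[a], nodes[b]
            if min_label[a] <= min_label[b]:
                node = Node(height=h, left=la, right=lb)
            else:
                node = Node(height=h, left=lb, right=la)
            nodes[n + k] = node
            min_label[n + k] = min(min_label[a], min_label[b])
        return cls(nodes[n + len(Z) - 1])

    # -- invariants ---------------------------------------------------

    def _validate(self) -> None:
        labels = self.leaf_order
        if len(set(labels)) != len(labels):
            raise ValueError("leaf labels must be unique")

        def check(node: Node) -> None:
            if node.is_leaf:
                return
            if node.left is None or node.right is None:
                raise ValueError("internal node must have two children")
            for c in (node.left, node.right):
                if node.height < c.height - 1e-12:
                    raise ValueError("merge heights must be monotone to the root")
                check(c)

        check(self.root)

    # -- accessors ----------------------------------------------------

    @property
    def leaf_order(self) -> list[str]:
        out: list[str] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node.label)  # type: ignore[arg-type]
            else:
                stack.append(node.right)  # right pushed first -> left visited first
                stack.append(node.left)
        return out

    @property
    def leaves(self) -> set[str]:
        return set(self.leaf_order)

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_order)

    def internal_nodes(self) -> list[Node]:
        """All internal nodes in pre-order."""
        out: list[Node] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if not node.is_leaf:
                out.append(node)
                stack.append(node.right)
                stack.append(node.left)
        return out

    def copy(self) -> "Dendrogram":
        return Dendrogram(self.root.copy())

    def cophenetic_matrix(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Pairwise merge heights (n x n, zero diagonal) in the given label order."""
        order = list(order) if order is not None else self.leaf_order
        idx = {lab: i for i, lab in enumerate(order)}
        n = len(order)
        D = np.zeros((n, n))

        def fill(node: Node) -> list[int]:
            if node.is_leaf:
                return [idx[node.label]]
            li = fill(node.left)
            ri = fill(node.right)
            for i in li:
                for j in ri:
                    D[i, j] = D[j, i] = node.height
            return li + ri

        fill(self.root)
        return D

    def relabel(self, mapping: dict[str, str]) -> "Dendrogram":
        """New tree with leaf labels replaced via ``mapping``."""

        def rec(node: Node) -> Node:
            if node.is_leaf:
                return Node(height=node.height, label=mapping[node.label])
            return Node(height=node.height, left=rec(node.left), right=rec(node.right))

        return Dendrogram(rec(self.root))


# -- Newick I/O (dendropy-backed parsing) -----------------------------


def _quote(label: str) -> str:
    if any(c in label for c in "(),:;'[] \t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def to_newick(tree: Dendrogram) -> str:
    def rec(node: Node, parent_height: float) -> str:
        bl = parent_height - node.height
        if node.is_leaf:
            return f"{_quote(node.label)}:{bl:.12g}"
        inner = f"({rec(node.left, node.height)},{rec(node.right, node.height)})"
        return f"{inner}:{bl:.12g}"

    root = tree.root
    if root.is_leaf:
        return f"{_quote(root.label)}:0;"
    return f"({rec(root.left, root.height)},{rec(root.right, root.height)});"


def write_newick(tree: Dendrogram, path) -> None:
    with open(path, "w") as fh:
        fh.write(to_newick(tree) + "\n")


def from_newick(text: str) -> Dendrogram:
    """Parse a Newick string with branch lengths into a Dendrogram.

    Node heights are reconstructed as the maximum path length to any
    descendant leaf, so ultrametric trees recover their merge heights
    exactly and non-ultrametric input still yields monotone heights.
    Multifurcations are collapsed left-to-right at the parent's height.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error classes
        raise NewickParseError(f"invalid Newick: {exc}") from exc

    def height_of(dnode) -> float:
        if dnode.is_leaf():
            return 0.0
        return max(
            (c.edge.length or 0.0) + height_of(c) for c in dnode.child_nodes()
        )

    def convert(dnode) -> Node:
        if dnode.is_leaf():
            if dnode.taxon is None or not dnode.taxon.label:
                raise NewickParseError("leaf without a label")
            return Node(label=str(dnode.taxon.label))
        h = height_of(dnode)
        kids = [convert(c) for c in dnode.child_nodes()]
        if len(kids) < 2:
            # unifurcation: collapse onto the single child
            kids[0].height = max(kids[0].height, h)
            return kids[0]
        while len(kids) > 2:
            right = kids.pop()
            left = kids.pop()
            kids.append(Node(height=h, left=left, right=right))
        return Node(height=h, left=kids[0], right=kids[1])

    return Dendrogram(convert(dtree.seed_node))


def read_newick(path) -> Dendrogram:
    with open(path) as fh:
        return from_newick(fh.read())
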