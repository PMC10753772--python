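"""Distance-based tree building (neighbor joining) and grouping checks.

The classic Saitou-Nei agglomeration with the Studier-Keppler Q-criterion.
Ties in Q break deterministically toward the pair whose clusters carry the
lexicographically smallest leaf labels.  Negative branch-length estimates
(a known NJ artifact on near-ultrametric matrices) are clamped to zero and
flagged.  The tree is unrooted; it is stored rooted at the last internal
node purely for traversal.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .diversity import DistanceMatrix


class PhyloError(ValueError):
    pass


@dataclasses.dataclass
class Node:
    name: str | None = None  # leaf label, None for internal nodes
    children: list = dataclasses.field(default_factory=list)  # (Node, length)

    def leaves(self) -> frozenset[str]:
        if self.name is not None:
            return frozenset([self.name])
        out: set[str] = set()
        for child, _ in self.children:
            out |= child.leaves()
        return frozenset(out)


_SAFE = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_.-")


def _quote(label: str) -> str:
    if set(label) <= _SAFE:
        return label
    return "'" + label.replace("'", "''") + "'"


class Tree:
    """Unrooted binary tree over the leaf set of a distance matrix."""

    def __init__(self, root: Node, negative_clamped: bool = False):
        self.root = root
        self.negative_clamped = negative_clamped

    def leaf_names(self) -> frozenset[str]:
        return self.root.leaves()

    def bipartitions(self) -> set[frozenset[str]]:
        """Leaf set on one side of every edge (pendant edges included)."""
        out: set[frozenset[str]] = set()

        def walk(node: Node) -> None:
            for child, _ in node.children:
                out.add(child.leaves())
                walk(child)

        walk(self.root)
        return out

    def splits(self) -> set[frozenset[str]]:
        """Canonical unrooted splits: each edge's leaf side that does not
        contain the lexicographically smallest leaf (so the same split is
        never represented twice from opposite sides)."""
        leaves = self.leaf_names()
        anchor = min(leaves)
        return {
            b if anchor not in b else leaves - b
            for b in self.bipartitions()
        }

    def newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.name is not None:
                return _quote(node.name)
            inner = ",".join(
                f"{fmt(child)}:{length:.17g}" for child, length in node.children
            )
            return f"({inner})"

        return fmt(self.root) + ";"

    def n_edges(self) -> int:
        count = 0

        def walk(node: Node) -> None:
            nonlocal count
            for child, _ in node.children:
                count += 1
                walk(child)

        walk(self.root)
        return count


def neighbor_joining(matrix: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining on a symmetric distance matrix."""
    n = len(matrix.labels)
    if n < 3:
        raise PhyloError(f"neighbor joining needs >= 3 taxa, got {n}")
    d = matrix.values.astype(float).copy()
    nodes = [Node(name=lab) for lab in matrix.labels]
    # representative label per cluster, for deterministic tie-breaks
    reps = list(matrix.labels)
    active = list(range(n))
    clamped = False

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0:
            clamped = True
            return 0.0
        return x

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * d[i, j] - sums[i] - sums[j]
                key = (q, min(reps[i], reps[j]), max(reps[i], reps[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = clamp(0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2)))
        lj = clamp(d[i, j] - (0.5 * d[i, j] + (sums[i] - sums[j]) / (2 * (r - 2))))
        parent = Node(children=[(nodes[i], li), (nodes[j], lj)])
        # distances from the new node (classic reduction)
        new_row = np.zeros(d.shape[0] + 1)
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, :] = new_row
        d[:, -1] = new_row
        nodes.append(parent)
        reps.append(min(reps[i], reps[j]))
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    li = clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    lj = clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    lk = clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    root = Node(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])
    return Tree(root, negative_clamped=clamped)


def is_reciprocally_monophyletic(tree: Tree, partition: dict[str, str]) -> bool:
    """True iff one edge of the unrooted tree splits the leaves exactly
    into the two groups of ``partition``."""
    leaves = tree.leaf_names()
    missing = leaves - set(partition)
    if missing:
        raise PhyloError(f"partition does not cover leaves: {sorted(missing)}")
    groups = sorted({partition[lab] for lab in leaves})
    if len(groups) != 2:
        raise PhyloError(f"need exactly two groups, got {len(groups)}")
    side = frozenset(lab for lab in leaves if partition[lab] == groups[0])
    bips = tree.bipartitions()
    return side in bips or (leaves - side) in bips
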