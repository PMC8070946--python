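"""p-distance matrices and neighbor-joining trees.

p-distances are computed with pairwise deletion (positions with a gap or
ambiguity in either sequence of a pair are excluded).  The NJ
agglomeration follows Saitou & Nei with a deterministic tie-break: among
pairs minimizing Q, the pair whose clusters carry the lexicographically
smallest (minimum leaf label) labels is joined.  Negative branch lengths
are clamped to zero (recorded on the tree object).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

AMBIGUOUS = set("-.NnXx ")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        self.values = v

    def of(self, a: str, b: str) -> float:
        i, j = self.labels.index(a), self.labels.index(b)
        return float(self.values[i, j])


def p_distance(
    aligned_seqs: dict[str, str], pairwise_deletion: bool = True
) -> DistanceMatrix:
    """Proportion of differing sites per pair over comparable columns."""
    labels = list(aligned_seqs)
    seqs = [aligned_seqs[k].upper() for k in labels]
    if len({len(s) for s in seqs}) > 1:
        raise ValueError("sequences must be aligned to equal length")
    n = len(labels)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            diffs = sites = 0
            for a, b in zip(seqs[i], seqs[j]):
                if a in AMBIGUOUS or b in AMBIGUOUS:
                    if pairwise_deletion:
                        continue
                sites += 1
                diffs += a != b
            if sites == 0:
                raise ValueError(
                    f"no comparable sites between {labels[i]} and {labels[j]}"
                )
            vals[i, j] = vals[j, i] = diffs / sites
    return DistanceMatrix(labels, vals)


@dataclass
class TreeNode:
    name: Optional[str] = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def newick(self) -> str:
        return self._nwk() + ";"

    def _nwk(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c._nwk()}:{bl:.6f}" for c, bl in self.children)
        return f"({inner})"


@dataclass
class PhyloTree:
    root: TreeNode
    clamped_branches: list[str] = field(default_factory=list)

    def newick(self) -> str:
        return self.root.newick()

    def leaves(self) -> list[str]:
        return self.root.leaves()

    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial leaf bipartitions (one side each) induced by
        internal edges of the unrooted tree."""
        all_leaves = frozenset(self.leaves())
        parts: set[frozenset[str]] = set()

        def walk(node: TreeNode) -> frozenset[str]:
            if not node.children:
                return frozenset([node.name])
            below = frozenset()
            for child, _ in node.children:
                sub = walk(child)
                if 1 < len(sub) < len(all_leaves) - 1:
                    parts.add(min(sub, all_leaves - sub, key=sorted))
                below |= sub
            return below

        walk(self.root)
        return parts


def nj_tree(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou-Nei neighbor joining; deterministic lowest-label
    tie-break; >=3 labels required."""
    labels = list(matrix.labels)
    if len(labels) < 3:
        raise ValueError("neighbor joining requires at least 3 taxa")
    d = {
        (a, b): matrix.values[i, j]
        for i, a in enumerate(labels)
        for j, b in enumerate(labels)
    }
    nodes: dict[str, TreeNode] = {l: TreeNode(l) for l in labels}
    # cluster key for the tie-break: smallest leaf label inside
    keys: dict[str, str] = {l: l for l in labels}
    active = list(labels)
    clamped: list[str] = []

    def clamp(x: float, where: str) -> float:
        if x < 0:
            clamped.append(where)
            return 0.0
        return x

    while len(active) > 2:
        r = len(active)
        net = {a: sum(d[(a, b)] for b in active if b != a) for a in active}
        best = None
        for i, a in enumerate(active):
            for b in active[i + 1 :]:
                q = (r - 2) * d[(a, b)] - net[a] - net[b]
                pair_key = tuple(sorted((keys[a], keys[b])))
                cand = (q, pair_key, a, b)
                if best is None or cand < best:
                    best = cand
        _, _, a, b = best
        dab = d[(a, b)]
        la = 0.5 * dab + (net[a] - net[b]) / (2 * (r - 2))
        lb = dab - la
        la = clamp(la, f"{keys[a]}")
        lb = clamp(lb, f"{keys[b]}")
        new = f"__{keys[a]}+{keys[b]}"
        nodes[new] = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        keys[new] = min(keys[a], keys[b])
        for c in active:
            if c in (a, b):
                continue
            d[(new, c)] = d[(c, new)] = 0.5 * (d[(a, c)] + d[(b, c)] - dab)
        active = [c for c in active if c not in (a, b)] + [new]
    a, b = active
    root = TreeNode(children=[(nodes[a], 0.0), (nodes[b], clamp(d[(a, b)], "root"))])
    return PhyloTree(root, clamped)


def is_monophyletic(tree: PhyloTree, label_subset) -> bool:
    """True iff some edge bipartition isolates exactly the subset (all
    leaves and singletons are trivially monophyletic)."""
    subset = frozenset(label_subset)
    leaves = frozenset(tree.leaves())
    if not subset <= leaves:
        raise ValueError("subset contains labels not in the tree")
    if len(subset) <= 1 or subset == leaves or len(subset) == len(leaves) - 1:
        return True
    parts = tree.bipartitions()
    return subset in parts or (leaves - subset) in parts
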