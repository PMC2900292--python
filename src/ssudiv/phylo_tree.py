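"""Neighbor-joining trees, newick I/O, and phylogenetic diversity.

Trees are held as :class:`skbio.TreeNode` objects. Neighbor joining is the
canonical Saitou-Nei agglomeration with the Studier-Keppler Q criterion;
negative branch-length estimates, which NJ can produce on non-additive
matrices, are clamped to zero so that phylogenetic diversity and UniFrac
remain well defined.
"""

from __future__ import annotations

import io
from pathlib import Path

import numpy as np
from skbio import TreeNode

from ssudiv.distances import DistanceMatrix

PhyloTree = TreeNode


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Canonical neighbor joining; deterministic lexicographic tie-breaking.

    Returns an unrooted tree (trifurcation at the last join) whose path
    lengths exactly reproduce any additive distance matrix. Requires n >= 3;
    n = 2 returns a single edge of length d.
    """
    n = dm.n
    if n < 2:
        raise ValueError("neighbor joining requires at least 2 taxa")
    if n == 2:
        root = TreeNode()
        a = TreeNode(name=dm.ids[0], length=dm.get(dm.ids[0], dm.ids[1]))
        b = TreeNode(name=dm.ids[1], length=0.0)
        root.extend([a, b])
        return root

    d = dm.as_square().astype(float)
    nodes: list[TreeNode] = [TreeNode(name=sid) for sid in dm.ids]
    labels: list[str] = list(dm.ids)  # lexicographic tie-break keys
    active = list(range(n))

    while len(active) > 3:
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        m = len(active)
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = tuple(sorted((labels[i], labels[j])))
                if best is None or q < best[0] - 1e-12 or (abs(q - best[0]) <= 1e-12 and key < best[1]):
                    best = (q, key, i, j)
        _, _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = TreeNode()
        nodes[i].length = li
        nodes[j].length = lj
        parent.extend([nodes[i], nodes[j]])
        # distances from the new node to every other active node
        new_row = np.zeros(d.shape[0])
        for k in active:
            if k in (i, j):
                continue
            new_row[k] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        d[i, :] = new_row
        d[:, i] = new_row
        nodes[i] = parent
        labels[i] = min(labels[i], labels[j])
        active.remove(j)

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    root = TreeNode()
    for idx, length in ((i, li), (j, lj), (k, lk)):
        nodes[idx].length = max(length, 0.0)
        root.append(nodes[idx])
    return root


def phylogenetic_diversity(tree: TreeNode) -> float:
    """Total branch length of the tree (Faith's PD over the full leaf set)."""
    return float(sum(node.length or 0.0 for node in tree.traverse() if not node.is_root()))


def tree_path_distance(tree: TreeNode, a: str, b: str) -> float:
    """Patristic distance between two named leaves."""
    return float(tree.find(a).distance(tree.find(b)))


def read_newick(path: str | Path) -> TreeNode:
    """Parse a newick file; duplicate leaf labels are rejected."""
    tree = TreeNode.read(str(path), format="newick")
    names = [t.name for t in tree.tips()]
    dupes = {nm for nm in names if names.count(nm) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def parse_newick(text: str) -> TreeNode:
    tree = TreeNode.read(io.StringIO(text), format="newick")
    names = [t.name for t in tree.tips()]
    dupes = {nm for nm in names if names.count(nm) > 1}
    if dupes:
        raise ValueError(f"duplicate leaf labels: {sorted(dupes)}")
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")
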