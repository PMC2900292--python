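"""Jaccard, Morisita-Horn, and UniFrac similarity between two communities.

All four metrics are reported as similarities in [0, 1] (UniFrac as
1 - distance) so that larger always means more alike. Jaccard uses OTU
membership only; Morisita-Horn weights by relative abundance and is
scale-invariant per community; the UniFrac pair measures overlap of the
communities on the branches of a shared phylogeny.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from skbio import TreeNode


@dataclass(frozen=True)
class CommunityAssignment:
    """Sequence id -> community label (1 or 2)."""

    assignment: Mapping[str, int]
    seed: int = 0

    def __post_init__(self) -> None:
        labels = set(self.assignment.values())
        if not labels <= {1, 2}:
            raise ValueError("community labels must be 1 or 2")
        if labels != {1, 2}:
            raise ValueError("both communities must be non-empty")

    def members(self, community: int) -> frozenset[str]:
        return frozenset(s for s, c in self.assignment.items() if c == community)


@dataclass(frozen=True)
class SharedTable:
    """OTU label -> (count in community 1, count in community 2)."""

    rows: Mapping[str, tuple[int, int]]

    def __post_init__(self) -> None:
        for label, (x, y) in self.rows.items():
            if x < 0 or y < 0:
                raise ValueError(f"negative count in OTU {label!r}")
            if x + y == 0:
                raise ValueError(f"OTU {label!r} has zero total count")

    @classmethod
    def from_partition(cls, partition, comm: CommunityAssignment) -> "SharedTable":
        rows: dict[str, list[int]] = {}
        for sid, otu in partition.assignment.items():
            c = comm.assignment[sid]
            rows.setdefault(otu, [0, 0])[c - 1] += 1
        return cls({k: (v[0], v[1]) for k, v in rows.items()})

    def vectors(self) -> tuple[np.ndarray, np.ndarray]:
        x = np.array([v[0] for v in self.rows.values()], dtype=float)
        y = np.array([v[1] for v in self.rows.values()], dtype=float)
        return x, y


def jaccard_similarity(table: SharedTable) -> float:
    """Shared OTUs over total observed OTUs (membership only)."""
    x, y = table.vectors()
    if len(x) == 0:
        raise ValueError("empty shared table")
    both = np.sum((x > 0) & (y > 0))
    either = np.sum((x > 0) | (y > 0))
    return float(both / either)


def morisita_horn(table: SharedTable) -> float:
    """Abundance-weighted overlap: 2*sum(x*y) / ((sum(x^2)/X^2 + sum(y^2)/Y^2) * X * Y)."""
    x, y = table.vectors()
    X, Y = x.sum(), y.sum()
    if X == 0 or Y == 0:
        raise ValueError("both community totals must be positive")
    lam = x @ x / X**2 + y @ y / Y**2
    return float(2.0 * (x @ y) / (lam * X * Y))


def _branch_weights(tree: TreeNode, comm: CommunityAssignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-branch (length, community-1 leaf count, community-2 leaf count).

    The tree is midpoint rooted before the edge walk so both UniFrac variants
    see the same rooted branch set.
    """
    leaves = {t.name for t in tree.tips()}
    unlabeled = leaves - set(comm.assignment)
    if unlabeled:
        raise ValueError(f"leaves without community label: {sorted(unlabeled)}")
    rooted = tree.root_at_midpoint() if len(tree.children) != 2 else tree
    lengths, c1, c2 = [], [], []
    for node in rooted.postorder():
        if node.is_root():
            continue
        tips = [t.name for t in node.tips()] if not node.is_tip() else [node.name]
        lengths.append(node.length or 0.0)
        c1.append(sum(1 for t in tips if comm.assignment[t] == 1))
        c2.append(sum(1 for t in tips if comm.assignment[t] == 2))
    return np.asarray(lengths), np.asarray(c1, dtype=float), np.asarray(c2, dtype=float)


def unweighted_unifrac(tree: TreeNode, comm: CommunityAssignment) -> float:
    """Fraction of total branch length on paths leading to both communities.

    Equal to 1 minus the unweighted UniFrac distance: a branch is shared when
    its subtree contains leaves of both communities, unique when it contains
    leaves of only one.
    """
    lengths, c1, c2 = _branch_weights(tree, comm)
    occupied = (c1 > 0) | (c2 > 0)
    total = lengths[occupied].sum()
    if total == 0:
        raise ValueError("tree has zero total branch length")
    shared = lengths[(c1 > 0) & (c2 > 0)].sum()
    return float(shared / total)


def weighted_unifrac(tree: TreeNode, comm: CommunityAssignment, normalized: bool = True) -> float:
    """1 minus the normalized weighted UniFrac distance.

    Raw distance is sum_b l_b * |a_b - b_b| over branches, with a_b and b_b
    the fractions of each community's sequences below branch b; normalization
    divides by sum_b l_b * (a_b + b_b), bounding the distance in [0, 1].
    """
    lengths, c1, c2 = _branch_weights(tree, comm)
    n1 = sum(1 for v in comm.assignment.values() if v == 1)
    n2 = sum(1 for v in comm.assignment.values() if v == 2)
    a = c1 / n1
    b = c2 / n2
    raw = float(np.sum(lengths * np.abs(a - b)))
    if not normalized:
        return 1.0 - raw
    scale = float(np.sum(lengths * (a + b)))
    if scale == 0:
        raise ValueError("tree has zero total branch length")
    return 1.0 - raw / scale


def write_shared_table(table: SharedTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("otu\tcount1\tcount2\n")
        for otu in sorted(table.rows):
            x, y = table.rows[otu]
            fh.write(f"{otu}\t{x}\t{y}\n")


def read_shared_table(path: str | Path) -> SharedTable:
    rows: dict[str, tuple[int, int]] = {}
    lines = Path(path).read_text().splitlines()
    for ln in lines[1:]:
        if not ln.strip():
            continue
        otu, x, y = ln.split("\t")
        rows[otu] = (int(x), int(y))
    return SharedTable(rows)
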