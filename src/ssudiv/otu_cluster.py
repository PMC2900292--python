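"""Agglomerative OTU clustering and richness-vs-cutoff curves.

Furthest neighbor is complete linkage (cluster distance = maximum pairwise
distance), nearest neighbor is single linkage, and average neighbor is UPGMA
(arithmetic mean weighted by cluster sizes). Merge heights are the raw
4-decimal distances, so the richness curve reports every cutoff the data can
actually describe rather than a fixed grid.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np

from ssudiv.distances import DistanceMatrix

Linkage = Literal["furthest", "nearest", "average"]


@dataclass(frozen=True)
class ClusterSchedule:
    """Ordered merge history: (height, frozenset of member ids merged so far)."""

    ids: tuple[str, ...]
    merges: tuple[tuple[float, frozenset[str]], ...]
    linkage: Linkage

    def __post_init__(self) -> None:
        heights = [h for h, _ in self.merges]
        if any(b < a for a, b in zip(heights, heights[1:])):
            raise ValueError("merge heights must be non-decreasing")


@dataclass(frozen=True)
class OTUPartition:
    """Flat OTU assignment at a distance cutoff."""

    cutoff: float
    assignment: dict[str, str]  # sequence id -> OTU label

    @property
    def otus(self) -> dict[str, frozenset[str]]:
        groups: dict[str, set[str]] = {}
        for sid, label in self.assignment.items():
            groups.setdefault(label, set()).add(sid)
        return {k: frozenset(v) for k, v in groups.items()}

    @property
    def n_otus(self) -> int:
        return len(set(self.assignment.values()))


def _linkage_distance(linkage: Linkage, dists: list[float]) -> float:
    if linkage == "furthest":
        return max(dists)
    if linkage == "nearest":
        return min(dists)
    return float(np.mean(dists))  # UPGMA: mean over all cross pairs = size-weighted


def cluster(dm: DistanceMatrix, linkage: Linkage = "furthest") -> ClusterSchedule:
    """Agglomerative clustering over the full matrix.

    At each step the pair of clusters with the smallest linkage distance
    merges; ties break on the smallest lexicographic pair of cluster labels,
    a cluster's label being its lexicographically smallest member id.
    """
    ids = dm.ids
    if len(ids) < 2:
        return ClusterSchedule(ids, (), linkage)
    sq = dm.as_square()
    index = {sid: i for i, sid in enumerate(ids)}
    clusters: dict[str, frozenset[str]] = {sid: frozenset([sid]) for sid in ids}
    merges: list[tuple[float, frozenset[str]]] = []
    while len(clusters) > 1:
        best: tuple[float, str, str] | None = None
        labels = sorted(clusters)
        for i, la in enumerate(labels):
            for lb in labels[i + 1 :]:
                dists = [sq[index[x], index[y]] for x in clusters[la] for y in clusters[lb]]
                d = _linkage_distance(linkage, dists)
                if best is None or d < best[0] or (d == best[0] and (la, lb) < (best[1], best[2])):
                    best = (d, la, lb)
        d, la, lb = best
        merged = clusters.pop(la) | clusters.pop(lb)
        clusters[min(merged)] = merged
        merges.append((d, merged))
    return ClusterSchedule(ids, tuple(merges), linkage)


def partition_at(sched: ClusterSchedule, cutoff: float) -> OTUPartition:
    """Flat clusters after applying every merge with height <= cutoff."""
    if cutoff < 0:
        raise ValueError("cutoff must be non-negative")
    clusters: dict[str, set[str]] = {sid: {sid} for sid in sched.ids}
    member_of: dict[str, str] = {sid: sid for sid in sched.ids}
    for height, merged in sched.merges:
        if height > cutoff:
            break
        labels = {member_of[m] for m in merged}
        new_label = min(labels)
        new_members: set[str] = set()
        for lab in labels:
            new_members |= clusters.pop(lab)
        clusters[new_label] = new_members
        for m in new_members:
            member_of[m] = new_label
    assignment = {sid: lab for lab, members in clusters.items() for sid in members}
    return OTUPartition(cutoff, assignment)


def richness_curve(sched: ClusterSchedule) -> list[tuple[float, int]]:
    """(cutoff, OTU count) at zero and at every distinct merge height."""
    n = len(sched.ids)
    points: list[tuple[float, int]] = []
    remaining = n
    zero_merges = sum(1 for h, _ in sched.merges if h == 0.0)
    points.append((0.0, n - zero_merges))
    for height, _ in sched.merges:
        remaining -= 1
        if height == 0.0:
            continue
        count_at = remaining
        # collapse duplicate heights to the final count at that height
        if points and points[-1][0] == height:
            points[-1] = (height, count_at)
        else:
            points.append((height, count_at))
    return points


def replicate_richness(
    dm: DistanceMatrix,
    linkage: Linkage = "furthest",
    n_replicates: int = 50,
    seed: int = 0,
) -> list[list[tuple[float, int]]]:
    """Richness curves over resampled sequence orderings.

    Re-running the agglomeration on shuffled input orderings probes how much
    tie-breaking and input order move the richness curve; defaults to the
    50-replicate design used for the alpha-diversity analyses.
    """
    rng = np.random.default_rng(seed)
    curves = []
    for _ in range(n_replicates):
        order = rng.permutation(dm.n)
        ids = tuple(dm.ids[i] for i in order)
        sq = dm.as_square()[np.ix_(order, order)]
        cond = np.array([sq[i, j] for i in range(len(ids)) for j in range(i)])
        curves.append(richness_curve(cluster(DistanceMatrix(ids, cond), linkage)))
    return curves


def write_list_file(sched: ClusterSchedule, path: str | Path) -> None:
    """One line per observable cutoff: cutoff, #OTUs, comma-joined OTU members."""
    heights = sorted({0.0} | {h for h, _ in sched.merges})
    with open(path, "w") as fh:
        for h in heights:
            part = partition_at(sched, h)
            groups = sorted(",".join(sorted(m)) for m in part.otus.values())
            fh.write(f"{h:.4f}\t{part.n_otus}\t" + "\t".join(groups) + "\n")


def write_richness_tsv(curve: list[tuple[float, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cutoff\tn_otus\n")
        for h, n in curve:
            fh.write(f"{h:.4f}\t{n}\n")
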