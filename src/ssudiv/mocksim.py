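"""Mock-community construction for beta-diversity benchmarking.

Sequences already clustered into OTUs are segregated into two communities
that share 80% of their membership but differ in structure: OTUs are randomly
ordered, 10% go exclusively to each community, and the remaining shared OTUs
split per sequence with probability 0.375 of landing in community 1 for half
of them and 0.625 for the other half. Under deep sampling this design has a
Jaccard similarity of 0.80 and a Morisita-Horn similarity of 0.60; shallow
sampling biases both downward. The partitioning is replicated (100 times by
default) with replicate seeds derived deterministically from the design seed,
so the same replicate assignments can be reused across every distance
calculator, alignment, region, and metric being compared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from ssudiv.beta_metrics import (
    CommunityAssignment,
    SharedTable,
    jaccard_similarity,
    morisita_horn,
    unweighted_unifrac,
    weighted_unifrac,
)
from ssudiv.otu_cluster import ClusterSchedule, OTUPartition, partition_at


@dataclass(frozen=True)
class MockDesign:
    otu_cutoff: float = 0.05
    frac_exclusive_each: float = 0.10
    shared_split_p: tuple[float, float] = (0.375, 0.625)
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < 2 * self.frac_exclusive_each < 1:
            raise ValueError("exclusive fractions must leave shared OTUs")
        p1, p2 = self.shared_split_p
        if not (0 < p1 < 1 and 0 < p2 < 1):
            raise ValueError("split probabilities must lie in (0, 1)")


def build_mock_pair(partition: OTUPartition, design: MockDesign, replicate_seed: int) -> CommunityAssignment:
    """One replicate: sequence -> community (1 or 2) labels.

    OTU ordering is a seeded uniform shuffle; exclusive OTU counts are
    floor(frac * n), at least 1; the extra OTU of an odd shared count goes to
    the p=0.625 half. Sequences of exclusive OTUs are assigned
    deterministically; shared-OTU sequences are independent Bernoulli draws.
    """
    rng = np.random.default_rng(replicate_seed)
    otus = partition.otus
    labels = sorted(otus)
    if len(labels) < 10:
        raise ValueError("design underdetermined: fewer than 10 OTUs")
    order = rng.permutation(len(labels))
    shuffled = [labels[i] for i in order]
    n_excl = max(1, int(design.frac_exclusive_each * len(labels)))
    excl1 = shuffled[:n_excl]
    excl2 = shuffled[n_excl : 2 * n_excl]
    shared = shuffled[2 * n_excl :]
    half = len(shared) // 2
    lo_half, hi_half = shared[:half], shared[half:]  # extra OTU lands in the high-p half
    p_lo, p_hi = sorted(design.shared_split_p)

    assignment: dict[str, int] = {}
    for otu in excl1:
        for sid in otus[otu]:
            assignment[sid] = 1
    for otu in excl2:
        for sid in otus[otu]:
            assignment[sid] = 2
    for group, p1 in ((lo_half, p_lo), (hi_half, p_hi)):
        for otu in group:
            members = sorted(otus[otu])
            draws = rng.random(len(members)) < p1
            for sid, in_first in zip(members, draws):
                assignment[sid] = 1 if in_first else 2
    if 1 not in assignment.values() or 2 not in assignment.values():
        # pathological tiny input; force both communities non-empty
        raise ValueError("a community came out empty; increase sequences per OTU")
    return CommunityAssignment(assignment, seed=replicate_seed)


_OTU_METRICS: dict[str, Callable[[SharedTable], float]] = {
    "jaccard": jaccard_similarity,
    "morisita_horn": morisita_horn,
}


def replicate_seeds(design: MockDesign) -> list[int]:
    """Deterministic per-replicate seeds below 2^31, derived from design.seed."""
    ss = np.random.SeedSequence(design.seed)
    return [int(s) % (2**31) for s in ss.generate_state(design.n_replicates)]


def run_replicates(
    partition: OTUPartition,
    design: MockDesign,
    metrics: Sequence[str] = ("jaccard", "morisita_horn"),
    tree=None,
    sched: ClusterSchedule | None = None,
    cutoffs: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Tidy table of (replicate, metric, cutoff, value) over all replicates.

    ``partition`` is the furthest-neighbor partition at the design cutoff
    that defines the mock communities. When a schedule and extra cutoffs are
    given, OTU-based metrics are re-evaluated on partitions at each cutoff
    using the same community labels. UniFrac metrics ('unweighted_unifrac',
    'weighted_unifrac') need ``tree`` and ignore the cutoff axis.
    """
    cutoffs = list(cutoffs) if cutoffs is not None else [design.otu_cutoff]
    partitions = {c: (partition_at(sched, c) if sched is not None else partition) for c in cutoffs}
    rows = []
    for rep, rep_seed in enumerate(replicate_seeds(design)):
        comm = build_mock_pair(partition, design, rep_seed)
        for metric in metrics:
            if metric in _OTU_METRICS:
                for c, part in partitions.items():
                    table = SharedTable.from_partition(part, comm)
                    rows.append((rep, metric, c, _OTU_METRICS[metric](table)))
            elif metric == "unweighted_unifrac":
                rows.append((rep, metric, np.nan, unweighted_unifrac(tree, comm)))
            elif metric == "weighted_unifrac":
                rows.append((rep, metric, np.nan, weighted_unifrac(tree, comm)))
            else:
                raise ValueError(f"unknown metric: {metric!r}")
    return pd.DataFrame(rows, columns=["replicate", "metric", "cutoff", "value"])


def uniform_partition(n_otus: int, seqs_per_otu: int, cutoff: float = 0.05) -> OTUPartition:
    """Idealized deeply sampled partition: n_otus equal-sized OTUs.

    Stands in for a furthest-neighbor clustering of a large collection when
    only the community-partitioning behaviour is under study.
    """
    assignment = {
        f"s{o:04d}_{s:04d}": f"otu{o:04d}" for o in range(n_otus) for s in range(seqs_per_otu)
    }
    return OTUPartition(cutoff, assignment)
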