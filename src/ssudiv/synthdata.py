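"""Synthetic gapped alignments with known truth for pipeline testing.

The generator emulates the structure of curated full-length 16S rRNA
collections: sequences evolve along a random pure-birth (Yule) tree under a
Jukes-Cantor substitution process, slow conserved blocks alternate with fast
hypervariable blocks, and indels concentrate in the variable blocks. Because
downstream distances are uncorrected mismatch fractions, a richer
substitution model would add nothing testable.

Indels are realized as lineage-specific loss of residues against a fixed
truth-alignment column universe: a deletion on one lineage is observationally
indistinguishable from an insertion on the complementary lineages, and this
keeps positional homology exact in the truth alignment. The first leaf is the
coordinate reference; it is exempt from indels, so its row is gap-free and
anchors a total reference-position-to-column map, playing the role E. coli
numbering plays for real 16S alignments.

Perturbation modes mimic the alignment-quality gradient between curated
reference alignments and aligners that fail on hypervariable regions:
``shuffle_variable`` scrambles residue placement within each variable region
(degraded homology), ``unalign_variable`` left-justifies residues there (no
homology attempted).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from skbio import TreeNode

from ssudiv.seqio_regions import AlignmentSet, ColumnMask, CoordinateMap

RegionKind = Literal["conserved", "variable"]
PerturbMode = Literal["faithful", "shuffle_variable", "unalign_variable"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticWorldConfig:
    """Parameters of the synthetic sequence world.

    tree_depth is the expected number of substitutions per site from root to
    tip in conserved regions; variable regions evolve ``rate_multiplier``
    times faster and receive indels at ``indel_rate`` per column per branch
    of unit depth (geometric run length, mean 2).
    """

    n_taxa: int = 20
    tree_depth: float = 0.10
    region_layout: tuple[tuple[RegionKind, int], ...] = (
        ("conserved", 120),
        ("variable", 60),
        ("conserved", 120),
        ("variable", 60),
        ("conserved", 120),
    )
    rate_multiplier: float = 4.0
    indel_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_taxa < 4:
            raise ValueError("too few taxa")
        if any(n <= 0 for _, n in self.region_layout):
            raise ValueError("region column counts must be positive")
        if self.rate_multiplier < 1:
            raise ValueError("rate_multiplier must be >= 1")

    @property
    def width(self) -> int:
        return sum(n for _, n in self.region_layout)

    @property
    def region_kinds(self) -> tuple[RegionKind, ...]:
        kinds: list[RegionKind] = []
        for kind, n in self.region_layout:
            kinds.extend([kind] * n)
        return tuple(kinds)


@dataclass(frozen=True)
class SyntheticWorld:
    config: SyntheticWorldConfig
    truth_alignment: AlignmentSet
    true_tree: TreeNode
    coordinate_map: CoordinateMap
    region_kinds: tuple[RegionKind, ...]


def _yule_tree(n_taxa: int, depth: float, rng: np.random.Generator) -> TreeNode:
    """Ultrametric pure-birth tree with root-to-tip depth scaled to ``depth``."""
    root = TreeNode()
    a, b = TreeNode(length=0.0), TreeNode(length=0.0)
    root.extend([a, b])
    active = [a, b]
    elapsed = 0.0
    birth_times = {id(a): 0.0, id(b): 0.0}
    while len(active) < n_taxa:
        elapsed += rng.exponential(1.0 / len(active))
        parent = active.pop(rng.integers(len(active)))
        parent.length = elapsed - birth_times[id(parent)]
        c1, c2 = TreeNode(length=0.0), TreeNode(length=0.0)
        parent.extend([c1, c2])
        birth_times[id(c1)] = birth_times[id(c2)] = elapsed
        active.extend([c1, c2])
    elapsed += rng.exponential(1.0 / len(active))
    for leaf in active:
        leaf.length = elapsed - birth_times[id(leaf)]
    scale = depth / elapsed
    for node in root.traverse():
        if node.length is not None:
            node.length *= scale
    for i, leaf in enumerate(root.tips()):
        leaf.name = f"t{i:04d}"
    return root


def _evolve(root: TreeNode, rates: np.ndarray, indel_rate: np.ndarray, span_end: np.ndarray,
            rng: np.random.Generator, ref_name: str) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Simulate sequences and presence masks down the tree.

    Substitution follows Jukes-Cantor: on a branch of length t a site of rate
    r changes to a uniformly chosen different base with probability
    (3/4)(1 - exp(-4 r t / 3)). Deleted columns stay deleted in descendants.
    """
    width = len(rates)
    root_seq = rng.integers(0, 4, size=width)
    out: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    ref_clade = {id(n) for n in _path_to_ref(root, ref_name)}

    def descend(node: TreeNode, seq: np.ndarray, present: np.ndarray) -> None:
        if node.length:
            t = node.length
            p_change = 0.75 * (1.0 - np.exp(-4.0 * rates * t / 3.0))
            hit = rng.random(width) < p_change
            if hit.any():
                seq = seq.copy()
                shifts = rng.integers(1, 4, size=int(hit.sum()))
                seq[hit] = (seq[hit] + shifts) % 4
            if id(node) not in ref_clade:
                starts = np.flatnonzero(rng.random(width) < indel_rate * t)
                if starts.size:
                    present = present.copy()
                    for s in starts:
                        run = int(rng.geometric(0.5))  # mean length 2
                        present[s : min(s + run, span_end[s])] = False
        if node.is_tip():
            out[node.name] = (seq, present)
        else:
            for child in node.children:
                descend(child, seq, present)

    descend(root, root_seq, np.ones(width, dtype=bool))
    return out


def _path_to_ref(root: TreeNode, ref_name: str) -> list[TreeNode]:
    ref = root.find(ref_name)
    path = []
    node = ref
    while node is not None:
        path.append(node)
        node = node.parent
    return path


def generate_world(config: SyntheticWorldConfig) -> SyntheticWorld:
    """Simulate a gapped truth alignment along a random Yule tree."""
    rng = np.random.default_rng(config.seed)
    tree = _yule_tree(config.n_taxa, config.tree_depth, rng)
    kinds = np.array(config.region_kinds)
    variable = kinds == "variable"
    rates = np.where(variable, config.rate_multiplier, 1.0)
    indel = np.where(variable, config.indel_rate, 0.0)
    # indel runs may not spill out of the variable span they start in
    span_end = np.zeros(config.width, dtype=int)
    for lo, hi in _variable_spans(config.region_kinds):
        span_end[lo:hi] = hi
    ref_name = next(tree.tips()).name
    sim = _evolve(tree, rates, indel, span_end, rng, ref_name)
    records = []
    for name in sorted(sim, key=lambda s: (s != ref_name, s)):
        seq, present = sim[name]
        row = np.where(present, _BASES[seq], "-")
        records.append((name, "".join(row)))
    aln = AlignmentSet(tuple(records))
    cmap = CoordinateMap.from_gapped_reference(aln[ref_name])
    return SyntheticWorld(config, aln, tree, cmap, config.region_kinds)


def _variable_spans(kinds: Sequence[RegionKind]) -> list[tuple[int, int]]:
    spans = []
    start = None
    for i, k in enumerate(kinds):
        if k == "variable" and start is None:
            start = i
        elif k != "variable" and start is not None:
            spans.append((start, i))
            start = None
    if start is not None:
        spans.append((start, len(kinds)))
    return spans


def perturb_alignment(world: SyntheticWorld, mode: PerturbMode, seed: int = 0) -> AlignmentSet:
    """Degrade positional homology inside variable regions, gaps-only moves.

    The per-row ungapped residue string is always preserved; conserved
    columns are untouched in every mode.
    """
    if mode == "faithful":
        return world.truth_alignment
    if mode not in ("shuffle_variable", "unalign_variable"):
        raise ValueError(f"unknown perturbation mode: {mode!r}")
    rng = np.random.default_rng(seed)
    spans = _variable_spans(world.region_kinds)
    records = []
    for sid, seq in world.truth_alignment.records:
        row = list(seq)
        for lo, hi in spans:
            chunk = row[lo:hi]
            residues = [c for c in chunk if c != "-"]
            n = hi - lo
            if mode == "unalign_variable":
                new = residues + ["-"] * (n - len(residues))
            else:
                slots = rng.choice(n, size=len(residues), replace=False)
                new = ["-"] * n
                for slot, res in zip(sorted(slots), residues):
                    new[slot] = res
            row[lo:hi] = new
        records.append((sid, "".join(row)))
    return AlignmentSet(tuple(records))


def generate_mask(world: SyntheticWorld, keep_kind: RegionKind = "conserved") -> ColumnMask:
    """Mask retaining exactly the columns of the requested region kind."""
    return ColumnMask(tuple(k == keep_kind for k in world.region_kinds))
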