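"""Alignment I/O, sequence screening, region extraction, masking, and pairwise alignment.

Coordinates follow E. coli 16S rRNA numbering: 1-based and inclusive on both
ends, the convention used when hypervariable regions are quoted as position
pairs (V3 = 357-514 and so on). The input gap glyphs '.' and '-' are
semantically identical; '-' is written on output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP_CHARS = frozenset(".-")
ALPHABET = frozenset("ACGTN-.")
AMBIGUOUS = frozenset("N")


@dataclass(frozen=True)
class AlignmentSet:
    """An ordered gapped multiple sequence alignment of uniform width."""

    records: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        seen: set[str] = set()
        width = None
        for sid, seq in self.records:
            if not sid:
                raise ValueError("empty sequence id")
            if sid in seen:
                raise ValueError(f"duplicate sequence id: {sid!r}")
            seen.add(sid)
            if width is None:
                width = len(seq)
            elif len(seq) != width:
                raise ValueError(f"ragged alignment: record {sid!r} has length {len(seq)}, expected {width}")
            for pos, ch in enumerate(seq):
                if ch not in ALPHABET:
                    raise ValueError(f"illegal character {ch!r} in record {sid!r} at column {pos + 1}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "AlignmentSet":
        return cls(tuple((sid, seq.upper().replace(".", "-")) for sid, seq in pairs))

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(sid for sid, _ in self.records)

    @property
    def width(self) -> int:
        return len(self.records[0][1]) if self.records else 0

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, sid: str) -> str:
        for rid, seq in self.records:
            if rid == sid:
                return seq
        raise KeyError(sid)

    def ungapped(self, sid: str) -> str:
        return self[sid].replace("-", "")


@dataclass(frozen=True)
class CoordinateMap:
    """1-based reference position -> 1-based alignment column, strictly increasing."""

    ref_to_column: Mapping[int, int]

    def __post_init__(self) -> None:
        items = sorted(self.ref_to_column.items())
        cols = [c for _, c in items]
        if any(b <= a for a, b in zip(cols, cols[1:])):
            raise ValueError("coordinate map columns must strictly increase with position")

    def column(self, ref_position: int) -> int:
        try:
            return self.ref_to_column[ref_position]
        except KeyError:
            raise KeyError(f"reference position {ref_position} is not mapped") from None

    @classmethod
    def from_gapped_reference(cls, gapped_reference: str) -> "CoordinateMap":
        """Build the map from the reference taxon's gapped alignment row."""
        mapping: dict[int, int] = {}
        pos = 0
        for col, ch in enumerate(gapped_reference, start=1):
            if ch not in GAP_CHARS:
                pos += 1
                mapping[pos] = col
        return cls(mapping)


@dataclass(frozen=True)
class RegionDef:
    """A 16S sub-region as an inclusive E. coli coordinate pair."""

    name: str
    ecoli_start: int
    ecoli_end: int

    def __post_init__(self) -> None:
        if self.ecoli_start >= self.ecoli_end:
            raise ValueError(f"region {self.name!r}: start must precede end")


#: The thirteen study regions with their E. coli coordinates.
TABLE1_REGIONS: tuple[RegionDef, ...] = (
    RegionDef("V19", 2, 1491),
    RegionDef("V12", 28, 337),
    RegionDef("V13", 28, 514),
    RegionDef("V14", 28, 784),
    RegionDef("V2", 100, 337),
    RegionDef("V23", 100, 514),
    RegionDef("V3", 357, 514),
    RegionDef("V35", 357, 906),
    RegionDef("V4", 578, 784),
    RegionDef("V6", 986, 1045),
    RegionDef("V69", 986, 1491),
    RegionDef("V89", 1100, 1491),
    RegionDef("V9", 1300, 1491),
)


@dataclass(frozen=True)
class ColumnMask:
    """Per-column keep flags; length must equal alignment width when applied."""

    keep: tuple[bool, ...]

    @property
    def n_kept(self) -> int:
        return sum(self.keep)

    def __len__(self) -> int:
        return len(self.keep)


@dataclass(frozen=True)
class ScreenPolicy:
    """Sequence quality screen: length, ambiguity, span, and uniqueness rules.

    Defaults follow the curation of full-length reference collections: at
    least 1,200 ungapped bases, at most 5 ambiguous bases, coverage from
    E. coli position 28 through 1491, and sequence-level deduplication.
    """

    min_ungapped_length: int = 1200
    max_ambiguous: int = 5
    must_start_by: int = 28
    must_end_after: int = 1491
    deduplicate: bool = True

    def __post_init__(self) -> None:
        if self.min_ungapped_length < 0 or self.max_ambiguous < 0:
            raise ValueError("screen thresholds must be non-negative")


def read_fasta(path: str | Path) -> AlignmentSet:
    """Read an aligned multi-FASTA file; '.' and '-' both parse as gaps."""
    records = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return AlignmentSet.from_pairs(records)


def write_fasta(aln: AlignmentSet, path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=sid, description="") for sid, seq in aln.records]
    SeqIO.write(recs, str(path), "fasta-2line")


def read_mask(path: str | Path) -> ColumnMask:
    """Read a mask file: one line of 0/1 characters; '#' lines are comments."""
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if set(line) - {"0", "1"}:
            raise ValueError("mask line may contain only 0 and 1")
        return ColumnMask(tuple(ch == "1" for ch in line))
    return ColumnMask(())


def write_mask(mask: ColumnMask, path: str | Path) -> None:
    Path(path).write_text("".join("1" if k else "0" for k in mask.keep) + "\n")


def read_coordinate_map(path: str | Path) -> CoordinateMap:
    """Read a two-column TSV of (reference_position, alignment_column), 1-based."""
    mapping: dict[int, int] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        pos, col = line.split("\t")
        mapping[int(pos)] = int(col)
    return CoordinateMap(mapping)


def write_coordinate_map(cmap: CoordinateMap, path: str | Path) -> None:
    lines = [f"{pos}\t{col}" for pos, col in sorted(cmap.ref_to_column.items())]
    Path(path).write_text("\n".join(lines) + "\n")


def screen_sequences(aln: AlignmentSet, cmap: CoordinateMap, policy: ScreenPolicy | None = None) -> AlignmentSet:
    """Apply the quality screen, returning the surviving records in input order.

    A record survives when its ungapped length meets the minimum, its count of
    ambiguous bases does not exceed the maximum, its first residue lies at or
    before the column mapped from ``must_start_by``, and its last residue lies
    at or after the column mapped from ``must_end_after``. With deduplication,
    only the first record of each identical ungapped sequence is kept.
    """
    policy = policy or ScreenPolicy()
    start_col = cmap.column(policy.must_start_by)
    end_col = cmap.column(policy.must_end_after)
    kept: list[tuple[str, str]] = []
    seen_ungapped: set[str] = set()
    for sid, seq in aln.records:
        ungapped = seq.replace("-", "")
        if len(ungapped) < policy.min_ungapped_length:
            continue
        if sum(seq.count(ch) for ch in AMBIGUOUS) > policy.max_ambiguous:
            continue
        first = next((i for i, ch in enumerate(seq, start=1) if ch != "-"), None)
        if first is None or first > start_col:
            continue
        last = max(i for i, ch in enumerate(seq, start=1) if ch != "-")
        if last < end_col:
            continue
        if policy.deduplicate:
            if ungapped in seen_ungapped:
                continue
            seen_ungapped.add(ungapped)
        kept.append((sid, seq))
    return AlignmentSet(tuple(kept))


def extract_region(aln: AlignmentSet, cmap: CoordinateMap, region: RegionDef) -> AlignmentSet:
    """Slice the alignment columns spanned by a region, inclusive of both ends."""
    lo = cmap.column(region.ecoli_start)
    hi = cmap.column(region.ecoli_end)
    return AlignmentSet(tuple((sid, seq[lo - 1 : hi]) for sid, seq in aln.records))


def apply_mask(aln: AlignmentSet, mask: ColumnMask) -> AlignmentSet:
    """Keep exactly the flagged columns, preserving order."""
    if len(mask) != aln.width:
        raise ValueError(f"mask length {len(mask)} does not match alignment width {aln.width}")
    idx = [i for i, k in enumerate(mask.keep) if k]
    return AlignmentSet(tuple((sid, "".join(seq[i] for i in idx)) for sid, seq in aln.records))


@dataclass(frozen=True)
class NWScoring:
    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


def needleman_wunsch(a: str, b: str, scoring: NWScoring | None = None) -> AlignmentSet:
    """Global pairwise alignment with affine gap penalties (Gotoh recursion).

    ``gap_open`` is the cost of the first gapped column of a run and
    ``gap_extend`` of each subsequent one. Traceback ties prefer the diagonal
    move, then the vertical (gap in ``b``), then the horizontal, which makes
    the output deterministic. Terminal gaps are penalized like internal ones.
    """
    sc = scoring or NWScoring()
    a = a.upper().replace("-", "").replace(".", "")
    b = b.upper().replace("-", "").replace(".", "")
    if not a or not b:
        raise ValueError("needleman_wunsch requires two non-empty ungapped sequences")
    n, m = len(a), len(b)
    neg = -np.inf
    # M: a[i] aligned to b[j]; X: gap in b (consume a); Y: gap in a (consume b)
    M = np.full((n + 1, m + 1), neg)
    X = np.full((n + 1, m + 1), neg)
    Y = np.full((n + 1, m + 1), neg)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = sc.gap_open + (i - 1) * sc.gap_extend
    for j in range(1, m + 1):
        Y[0, j] = sc.gap_open + (j - 1) * sc.gap_extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sc.match if a[i - 1] == b[j - 1] else sc.mismatch
            M[i, j] = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]) + s
            X[i, j] = max(M[i - 1, j] + sc.gap_open, X[i - 1, j] + sc.gap_extend, Y[i - 1, j] + sc.gap_open)
            Y[i, j] = max(M[i, j - 1] + sc.gap_open, Y[i, j - 1] + sc.gap_extend, X[i, j - 1] + sc.gap_open)

    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    # final-cell ties resolve M, then X, then Y (diagonal, up, left)
    best = max(M[n, m], X[n, m], Y[n, m])
    state = "M"
    for st, mat in (("M", M), ("X", X), ("Y", Y)):
        if mat[n, m] == best:
            state = st
            break
    while i > 0 or j > 0:
        if state == "M":
            out_a.append(a[i - 1])
            out_b.append(b[j - 1])
            s = sc.match if a[i - 1] == b[j - 1] else sc.mismatch
            prev = M[i, j] - s
            i, j = i - 1, j - 1
            for st, mat in (("M", M), ("X", X), ("Y", Y)):
                if np.isclose(mat[i, j], prev):
                    state = st
                    break
        elif state == "X":
            out_a.append(a[i - 1])
            out_b.append("-")
            val = X[i, j]
            i -= 1
            if i == 0 and j == 0:
                break
            if np.isclose(M[i, j] + sc.gap_open, val):
                state = "M"
            elif np.isclose(X[i, j] + sc.gap_extend, val):
                state = "X"
            else:
                state = "Y"
        else:
            out_a.append("-")
            out_b.append(b[j - 1])
            val = Y[i, j]
            j -= 1
            if i == 0 and j == 0:
                break
            if np.isclose(M[i, j] + sc.gap_open, val):
                state = "M"
            elif np.isclose(Y[i, j] + sc.gap_extend, val):
                state = "Y"
            else:
                state = "X"
    return AlignmentSet((("a", "".join(reversed(out_a))), ("b", "".join(reversed(out_b)))))


def nw_score(aln: AlignmentSet, scoring: NWScoring | None = None) -> float:
    """Score an existing two-row alignment under the affine-gap model."""
    sc = scoring or NWScoring()
    (_, ra), (_, rb) = aln.records
    score = 0.0
    prev_gap_a = prev_gap_b = False
    for ca, cb in zip(ra, rb):
        if ca == "-" and cb == "-":
            continue
        if ca == "-":
            score += sc.gap_extend if prev_gap_a else sc.gap_open
            prev_gap_a, prev_gap_b = True, False
        elif cb == "-":
            score += sc.gap_extend if prev_gap_b else sc.gap_open
            prev_gap_a, prev_gap_b = False, True
        else:
            score += sc.match if ca == cb else sc.mismatch
            prev_gap_a = prev_gap_b = False
    return score
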