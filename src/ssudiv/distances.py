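"""Uncorrected pairwise distance calculators with explicit gap treatments.

Three sequence-based calculators differ only in how gapped columns enter the
numerator (differences) and denominator (compared positions):

* ``ignore_gap`` — any column containing a gap is skipped entirely; only
  base-vs-base columns are compared (the DNADIST convention).
* ``each_gap`` — a gap is a fifth character: every base-vs-gap column is one
  difference over one position; gap-vs-gap columns are skipped.
* ``one_gap`` — a maximal run of base-vs-gap columns counts as a single
  difference over a single position, asserting that an indel of any length is
  one mutation.

Distances are simple mismatch fractions, deliberately not corrected for
multiple substitutions, and are stored rounded half-up to four decimals. A
kmer distance over 7-base word profiles of the unaligned sequences is
provided for comparison with alignment-free practice.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Literal

import numpy as np

GapMode = Literal["one_gap", "each_gap", "ignore_gap"]


@dataclass(frozen=True)
class GapPolicy:
    """Gap treatment for pair_distance; terminal gaps are free by default."""

    mode: GapMode = "one_gap"
    penalize_terminal_gaps: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("one_gap", "each_gap", "ignore_gap"):
            raise ValueError(f"unknown gap mode: {self.mode!r}")


def round4(x: float) -> float:
    """Round half-up to 4 decimals (0.12345 -> 0.1235)."""
    return float(np.floor(x * 10_000.0 + 0.5) / 10_000.0)


def _comparable_span(a: str, b: str, penalize_terminal: bool) -> tuple[int, int]:
    """Half-open column range outside which terminal gaps are discounted."""
    if penalize_terminal:
        return 0, len(a)
    starts, ends = [], []
    for s in (a, b):
        residues = [i for i, ch in enumerate(s) if ch != "-"]
        if not residues:
            return 0, 0
        starts.append(residues[0])
        ends.append(residues[-1] + 1)
    return max(starts), min(ends)


def pair_distance(a: str, b: str, policy: GapPolicy | None = None) -> float:
    """Uncorrected distance between two equal-length gapped rows.

    'N' compared with anything is never a difference but does count as a
    compared position; both-gap columns never count. Raises ``ValueError``
    when no comparable positions remain ("undefined distance").
    """
    policy = policy or GapPolicy()
    if len(a) != len(b):
        raise ValueError("rows must have equal length")
    a = a.upper().replace(".", "-")
    b = b.upper().replace(".", "-")
    lo, hi = _comparable_span(a, b, policy.penalize_terminal_gaps)

    positions = 0
    diffs = 0
    run_row = 0  # 0 = not in a single-gap run; 1/2 = run with gap in row a/b
    for i in range(lo, hi):
        ca, cb = a[i], b[i]
        ga, gb = ca == "-", cb == "-"
        if ga and gb:
            continue  # no information; does not break a one_gap run
        if ga or gb:
            if policy.mode == "ignore_gap":
                run_row = 0
                continue
            if policy.mode == "each_gap":
                positions += 1
                diffs += 1
                continue
            row = 1 if ga else 2
            if row != run_row:
                positions += 1
                diffs += 1
                run_row = row
            continue
        run_row = 0
        positions += 1
        if ca != cb and ca != "N" and cb != "N":
            diffs += 1
    if positions == 0:
        raise ValueError("undefined distance: zero comparable positions")
    return round4(diffs / positions)


def kmer_distance(a: str, b: str, k: int = 7) -> float:
    """1 - (shared k-word count fraction) between two unaligned sequences.

    F = sum_w min(count_a(w), count_b(w)) / (min(len_a, len_b) - k + 1).
    """
    a = a.upper().replace("-", "").replace(".", "")
    b = b.upper().replace("-", "").replace(".", "")
    if len(a) < k or len(b) < k:
        raise ValueError(f"sequences must be at least {k} bases long")
    ca = Counter(a[i : i + k] for i in range(len(a) - k + 1))
    cb = Counter(b[i : i + k] for i in range(len(b) - k + 1))
    shared = sum(min(n, cb[w]) for w, n in ca.items())
    frac = shared / (min(len(a), len(b)) - k + 1)
    return round4(1.0 - frac)


def n_pairs(n: int) -> int:
    """Number of unordered pairs among n ids: n(n-1)/2."""
    return n * (n - 1) // 2


@dataclass(frozen=True)
class DistanceMatrix:
    """Lower-triangular pairwise distances at fixed 4-decimal precision.

    ``values[i, j]`` for i > j holds d(ids[i], ids[j]); the condensed vector
    carries n(n-1)/2 entries in row-major lower-triangle order.
    """

    ids: tuple[str, ...]
    condensed: np.ndarray  # length n(n-1)/2, lower-triangle row-major

    def __post_init__(self) -> None:
        if len(self.condensed) != n_pairs(len(self.ids)):
            raise ValueError("condensed length must be n(n-1)/2")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def entry_count(self) -> int:
        return n_pairs(self.n)

    def _index(self, i: int, j: int) -> int:
        if i < j:
            i, j = j, i
        return i * (i - 1) // 2 + j

    def get(self, id_a: str, id_b: str) -> float:
        if id_a == id_b:
            return 0.0
        i, j = self.ids.index(id_a), self.ids.index(id_b)
        return float(self.condensed[self._index(i, j)])

    def as_square(self) -> np.ndarray:
        n = self.n
        sq = np.zeros((n, n))
        for i in range(n):
            for j in range(i):
                sq[i, j] = sq[j, i] = self.condensed[self._index(i, j)]
        return sq

    def pairs(self) -> Iterable[tuple[str, str, float]]:
        for i in range(self.n):
            for j in range(i):
                yield self.ids[j], self.ids[i], float(self.condensed[self._index(i, j)])


def distance_matrix(
    aln,
    method: GapPolicy | str = "one_gap",
    k: int = 7,
) -> DistanceMatrix:
    """All-pairs distance matrix; ``method`` is a GapPolicy or the string 'kmer'.

    Any pair with an undefined distance raises, naming the offending pair.
    """
    ids = aln.ids
    if len(ids) < 2:
        raise ValueError("distance_matrix requires at least 2 sequences")
    rows = dict(aln.records)
    out = np.empty(n_pairs(len(ids)))
    if method == "kmer":
        fn: Callable[[str, str], float] = lambda x, y: kmer_distance(x.replace("-", ""), y.replace("-", ""), k)
    else:
        policy = GapPolicy(mode=method) if isinstance(method, str) else method
        fn = lambda x, y: pair_distance(x, y, policy)
    idx = 0
    for i in range(len(ids)):
        for j in range(i):
            try:
                out[idx] = fn(rows[ids[i]], rows[ids[j]])
            except ValueError as err:
                raise ValueError(f"pair ({ids[i]}, {ids[j]}): {err}") from err
            idx += 1
    return DistanceMatrix(tuple(ids), out)


def write_phylip(dm: DistanceMatrix, path: str | Path) -> None:
    """Write a lower-triangle PHYLIP-style matrix: count line, then id + row."""
    lines = [str(dm.n)]
    sq = dm.as_square()
    for i, sid in enumerate(dm.ids):
        row = "\t".join(f"{sq[i, j]:.4f}" for j in range(i))
        lines.append(f"{sid}\t{row}" if row else sid)
    Path(path).write_text("\n".join(lines) + "\n")


def read_phylip(path: str | Path) -> DistanceMatrix:
    lines = [ln for ln in Path(path).read_text().splitlines() if ln.strip()]
    n = int(lines[0])
    ids: list[str] = []
    vals: list[float] = []
    for ln in lines[1 : n + 1]:
        parts = ln.split("\t")
        ids.append(parts[0])
        vals.extend(float(v) for v in parts[1:])
    return DistanceMatrix(tuple(ids), np.asarray(vals))


def write_sparse(dm: DistanceMatrix, path: str | Path, cutoff: float | None = None) -> None:
    """Write 3-column (id1, id2, distance) rows, optionally only those <= cutoff."""
    with open(path, "w") as fh:
        for a, b, d in dm.pairs():
            if cutoff is None or d <= cutoff:
                fh.write(f"{a}\t{b}\t{d:.4f}\n")
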