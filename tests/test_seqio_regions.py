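"""Alignment I/O, screening, region extraction, masking, and pairwise alignment."""

import itertools

import pytest

from ssudiv.seqio_regions import (
    AlignmentSet,
    ColumnMask,
    CoordinateMap,
    NWScoring,
    RegionDef,
    ScreenPolicy,
    TABLE1_REGIONS,
    apply_mask,
    extract_region,
    needleman_wunsch,
    nw_score,
    read_coordinate_map,
    read_fasta,
    read_mask,
    screen_sequences,
    write_coordinate_map,
    write_fasta,
    write_mask,
)


def test_fasta_round_trip(tmp_path, small_world):
    path = tmp_path / "aln.fasta"
    write_fasta(small_world.truth_alignment, path)
    assert read_fasta(path) == small_world.truth_alignment


def test_fasta_dot_parses_as_gap(tmp_path):
    path = tmp_path / "dots.fasta"
    path.write_text(">x\nAC.T\n>y\nA--T\n")
    aln = read_fasta(path)
    assert aln["x"] == "AC-T"


def test_empty_fasta_gives_empty_alignment(tmp_path):
    path = tmp_path / "empty.fasta"
    path.write_text("")
    aln = read_fasta(path)
    assert len(aln) == 0 and aln.width == 0


def test_illegal_character_and_ragged_rejected():
    with pytest.raises(ValueError, match="illegal character"):
        AlignmentSet.from_pairs([("x", "ACXT")])
    with pytest.raises(ValueError, match="ragged.*y"):
        AlignmentSet.from_pairs([("x", "ACGT"), ("y", "ACG")])


def test_mask_and_coordinate_map_round_trip(tmp_path):
    mask = ColumnMask((True, False, True, True))
    write_mask(mask, tmp_path / "m.txt")
    assert read_mask(tmp_path / "m.txt") == mask
    cmap = CoordinateMap({1: 2, 2: 5, 3: 6})
    write_coordinate_map(cmap, tmp_path / "c.tsv")
    assert dict(read_coordinate_map(tmp_path / "c.tsv").ref_to_column) == {1: 2, 2: 5, 3: 6}


IDENTITY_MAP = CoordinateMap({i: i for i in range(1, 9)})


def test_screen_removes_excess_ambiguity_and_duplicates():
    policy = ScreenPolicy(min_ungapped_length=4, max_ambiguous=5, must_start_by=2, must_end_after=7)
    aln = AlignmentSet.from_pairs(
        [
            ("ok", "ACGTACGT"),
            ("sixN", "ANNNNNNT"),          # 6 ambiguous bases: out
            ("dup", "ACGTACGT"),           # identical ungapped sequence: out
            ("late_start", "--GTACGT"),    # first residue after position-2 column: out
            ("early_end", "ACGTAC--"),     # last residue before position-7 column: out
            ("fiveN", "ANNNNNGT"),         # exactly 5 ambiguous: kept
        ]
    )
    kept = screen_sequences(aln, IDENTITY_MAP, policy)
    assert kept.ids == ("ok", "fiveN")


def test_screen_is_idempotent(small_world):
    policy = ScreenPolicy(min_ungapped_length=10, max_ambiguous=5, must_start_by=1,
                          must_end_after=len(small_world.coordinate_map.ref_to_column))
    once = screen_sequences(small_world.truth_alignment, small_world.coordinate_map, policy)
    twice = screen_sequences(once, small_world.coordinate_map, policy)
    assert once == twice


def test_table1_region_set():
    assert len(TABLE1_REGIONS) == 13
    by_name = {r.name: r for r in TABLE1_REGIONS}
    assert (by_name["V19"].ecoli_start, by_name["V19"].ecoli_end) == (2, 1491)
    assert (by_name["V6"].ecoli_start, by_name["V6"].ecoli_end) == (986, 1045)
    assert (by_name["V3"].ecoli_start, by_name["V3"].ecoli_end) == (357, 514)


def test_extract_region_width_follows_map():
    cmap = CoordinateMap({1: 1, 2: 3, 3: 4, 4: 7})
    aln = AlignmentSet.from_pairs([("r", "ACGTACG"), ("s", "AC-TA-G")])
    out = extract_region(aln, cmap, RegionDef("mid", 2, 4))
    assert out.width == 7 - 3 + 1
    assert out["r"] == "GTACG"[0:5]
    with pytest.raises(KeyError):
        extract_region(aln, cmap, RegionDef("bad", 2, 9))


def test_apply_mask_examples():
    aln = AlignmentSet.from_pairs([("x", "ACG"), ("y", "A-G")])
    assert apply_mask(aln, ColumnMask((True, True, True))) == aln
    assert apply_mask(aln, ColumnMask((False, False, False))).width == 0
    kept = apply_mask(aln, ColumnMask((True, False, True)))
    assert kept["x"] == "AG" and kept["y"] == "AG"
    with pytest.raises(ValueError, match="length"):
        apply_mask(aln, ColumnMask((True,)))


def test_extract_then_mask_commutes_with_mask_then_extract(small_world):
    """Region slicing and column masking commute when expressed in one column space."""
    from ssudiv.synthdata import generate_mask

    aln = small_world.truth_alignment
    cmap = small_world.coordinate_map
    mask = generate_mask(small_world)
    region = RegionDef("window", 10, 200)
    lo, hi = cmap.column(10), cmap.column(200)
    sub_mask = ColumnMask(mask.keep[lo - 1 : hi])
    a = apply_mask(extract_region(aln, cmap, region), sub_mask)
    # mask first, then slice the surviving columns of the same window
    masked = apply_mask(aln, mask)
    kept_cols = [i for i, k in enumerate(mask.keep) if k]
    sel = [idx for idx, col in enumerate(kept_cols) if lo - 1 <= col < hi]
    b = AlignmentSet(tuple((sid, "".join(seq[i] for i in sel)) for sid, seq in masked.records))
    assert a == b


def enumerate_alignments(a, b):
    """All global alignments of two short strings, as gapped row pairs."""
    if not a and not b:
        yield "", ""
        return
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb


def test_needleman_wunsch_identical_sequences_gap_free():
    aln = needleman_wunsch("ACGTACGT", "ACGTACGT")
    (_, ra), (_, rb) = aln.records
    assert ra == rb == "ACGTACGT"


def test_needleman_wunsch_matches_exhaustive_enumeration():
    """Optimal affine-gap score verified against enumeration of all alignments."""
    scoring = NWScoring(match=1, mismatch=-1, gap_open=-2, gap_extend=-1)
    for a, b in [("ACGT", "AGT"), ("ACGTT", "CGT"), ("AAAA", "AAGAA"), ("ACAC", "CACA")]:
        result = needleman_wunsch(a, b, scoring)
        got = nw_score(result, scoring)
        best = max(
            nw_score(AlignmentSet((("a", ra), ("b", rb))), scoring)
            for ra, rb in enumerate_alignments(a, b)
        )
        assert got == pytest.approx(best), (a, b)
        (_, ra), (_, rb) = result.records
        assert ra.replace("-", "") == a and rb.replace("-", "") == b


def test_needleman_wunsch_single_gap_example():
    aln = needleman_wunsch("ACGT", "AGT")
    (_, ra), (_, rb) = aln.records
    assert ra == "ACGT" and rb.count("-") == 1 and rb.replace("-", "") == "AGT"


def test_needleman_wunsch_rejects_empty():
    with pytest.raises(ValueError):
        needleman_wunsch("", "ACGT")
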