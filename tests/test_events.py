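"""Event coding: channel semantics, coordinate anchoring, oracle agreement."""

import numpy as np
import pytest

from promdiv.events import (
    AlignmentShapeError,
    AlphabetError,
    GeneAnnotation,
    MultipleAlignment,
    anchor_to_tss,
    build_event_vector,
    call_base_change_events,
    call_indel_events,
    combine_channels,
    event_positions,
    offset_channel,
    read_alignment,
    reference_coordinates,
    write_alignment,
)
from conftest import make_alignment, random_alignment


# ---------------------------------------------------------------- construction


def test_read_write_roundtrip(tmp_path):
    aln = make_alignment([("A", "A"), ("C", "-"), ("G", "G"), ("T", "A")])
    path = tmp_path / "aln.fa"
    write_alignment(aln, path)
    back = read_alignment(path, reference_id="ref")
    assert back.records() == aln.records()
    assert back.L == 4


def test_two_identical_sequences_are_valid():
    aln = MultipleAlignment([("ref", "ACGT"), ("sp1", "ACGT")], "ref")
    assert aln.L == 4


def test_lowercase_is_normalised():
    aln = MultipleAlignment([("ref", "acgt"), ("sp1", "acg-")], "ref")
    assert aln.sequence("ref") == "ACGT"


@pytest.mark.parametrize(
    "records, exc",
    [
        ([("ref", "A" * 100), ("sp1", "A" * 99)], AlignmentShapeError),
        ([("ref", "ACGT")], AlignmentShapeError),
        ([("a", "ACGT"), ("b", "ACGT")], LookupError),
        ([("ref", "ACXT"), ("sp1", "ACGT")], AlphabetError),
    ],
)
def test_invalid_alignments_raise(records, exc):
    with pytest.raises(exc):
        MultipleAlignment(records, "ref")


def test_alphabet_error_names_position():
    with pytest.raises(AlphabetError, match="column 2"):
        MultipleAlignment([("ref", "ACXT"), ("sp1", "ACGT")], "ref")


# ---------------------------------------------------------------- base changes


@pytest.mark.parametrize(
    "column, expected",
    [
        (("A", "A", "A", "A", "A"), 0),  # no difference
        (("A", "G", "A", "A", "A"), 1),  # one species differs
        (("A", "-", "A", "A", "A"), 0),  # gap never scores here
        (("A", "N", "A", "A", "A"), 0),  # N is missing data
        (("-", "G", "A", "A", "A"), 0),  # reference gap column
        (("A", "C", "G", "T", "A"), 1),
    ],
)
def test_base_change_single_column(column, expected):
    aln = make_alignment([column])
    assert call_base_change_events(aln)[0] == expected


def _oracle_channels(aln):
    """Brute-force per-column classifier and gap-run enumerator."""
    ids = aln.ids
    seqs = {sid: aln.sequence(sid) for sid in ids}
    ref = seqs[aln.reference_id]
    L = aln.L
    base = [0] * L
    for i in range(L):
        if ref[i] in "-N":
            continue
        for sid in ids:
            if sid == aln.reference_id:
                continue
            c = seqs[sid][i]
            if c not in "-N" and c != ref[i]:
                base[i] = 1
    indel = [0] * L
    for sid in ids:
        s = seqs[sid]
        for i in range(L):
            if s[i] == "-" and (i == 0 or s[i - 1] != "-"):
                indel[i] = 1
    return np.array(base), np.array(indel)


def test_channels_match_brute_force_oracle(rng):
    for _ in range(25):
        aln = random_alignment(rng)
        base_o, indel_o = _oracle_channels(aln)
        assert np.array_equal(call_base_change_events(aln), base_o)
        assert np.array_equal(call_indel_events(aln), indel_o)


# ---------------------------------------------------------------------- indels


def test_gap_free_alignment_has_no_indel_events():
    aln = make_alignment([("A", "A"), ("C", "C"), ("G", "G")])
    assert call_indel_events(aln).sum() == 0


def test_gap_run_registers_single_event_at_five_prime_start():
    ref = "A" * 30
    sp = "A" * 10 + "-" * 5 + "A" * 15  # gaps at columns 10..14
    aln = MultipleAlignment([("ref", ref), ("sp1", sp)], "ref")
    assert list(np.flatnonzero(call_indel_events(aln))) == [10]


def test_coincident_gap_starts_collapse_binary():
    ref = "A" * 30
    sp1 = "A" * 20 + "-" * 3 + "A" * 7
    sp2 = "A" * 20 + "-" * 3 + "A" * 7
    aln = MultipleAlignment([("ref", ref), ("sp1", sp1), ("sp2", sp2)], "ref")
    assert list(np.flatnonzero(call_indel_events(aln))) == [20]


def test_leading_gap_run_scores_at_column_zero():
    aln = MultipleAlignment([("ref", "ACGT"), ("sp1", "--GT")], "ref")
    assert list(np.flatnonzero(call_indel_events(aln))) == [0]


def test_reference_gap_run_counts_as_insertion_event():
    aln = MultipleAlignment([("ref", "AC--GT"), ("sp1", "ACAAGT")], "ref")
    assert list(np.flatnonzero(call_indel_events(aln))) == [2]


# --------------------------------------------------------------------- combine


def test_combine_is_positionwise_or(rng):
    assert combine_channels([0], [0])[0] == 0
    for a, b in [(1, 0), (0, 1), (1, 1)]:
        assert combine_channels([a], [b])[0] == 1
    x = rng.integers(0, 2, 1000)
    y = rng.integers(0, 2, 1000)
    assert np.array_equal(combine_channels(x, y), x | y)
    with pytest.raises(ValueError):
        combine_channels([0, 1], [0])


def test_all_changes_invariant_on_random_alignments(rng):
    for _ in range(10):
        aln = random_alignment(rng)
        ev = build_event_vector(aln)
        assert np.array_equal(ev.all_changes, ev.base_changes | ev.indels)


# ------------------------------------------------------------------- anchoring


def _ann(strand="+"):
    return GeneAnnotation(gene_id="g", contig="c", tss=5000, strand=strand)


def test_gap_free_plus_strand_offsets():
    L = 2000
    aln = MultipleAlignment([("ref", "A" * L), ("sp1", "A" * L)], "ref")
    ev = anchor_to_tss(build_event_vector(aln), _ann("+"), tss_column=1000)
    assert ev.tss_offset[0] == -1000
    assert ev.tss_offset[-1] == L - 1001
    assert ev.tss_offset[1000] == 0


def test_tss_at_column_zero():
    aln = MultipleAlignment([("ref", "ACGT"), ("sp1", "ACGT")], "ref")
    ev = anchor_to_tss(build_event_vector(aln), _ann(), tss_column=0)
    assert ev.tss_offset[0] == 0


def test_minus_strand_flips_sign():
    aln = MultipleAlignment([("ref", "A" * 10), ("sp1", "A" * 10)], "ref")
    ev = anchor_to_tss(build_event_vector(aln), _ann("-"), tss_column=4)
    assert ev.tss_offset[0] == 4  # larger genome coordinate side is upstream
    assert ev.tss_offset[9] == -5


def test_reference_gap_columns_share_preceding_position():
    # reference has a 5-column gap (insertion in sp1) upstream of the TSS
    ref = "AAA-----AAAAA"
    sp1 = "AAACCCCCAAAAA"
    aln = MultipleAlignment([("ref", ref), ("sp1", sp1)], "ref")
    coord = reference_coordinates(aln)
    # hand-walked: columns 0,1,2 -> 0,1,2; gap columns 3..7 -> 2; columns 8.. -> 3..
    assert list(coord) == [0, 1, 2, 2, 2, 2, 2, 2, 3, 4, 5, 6, 7]
    ev = anchor_to_tss(build_event_vector(aln), _ann(), tss_column=10)
    assert ev.tss_offset[10] == 0
    assert list(ev.tss_offset[:3]) == [-5, -4, -3]
    assert all(o == -3 for o in ev.tss_offset[3:8])


def test_tss_column_out_of_range_raises():
    aln = MultipleAlignment([("ref", "ACGT"), ("sp1", "ACGT")], "ref")
    with pytest.raises(IndexError):
        anchor_to_tss(build_event_vector(aln), _ann(), tss_column=4)


def test_offset_channel_collapses_insertions_by_or():
    ref = "AA--AAAA"
    sp1 = "AACCAAAA"
    aln = MultipleAlignment([("ref", ref), ("sp1", sp1)], "ref")
    ev = anchor_to_tss(build_event_vector(aln), _ann(), tss_column=0)
    positions, values = offset_channel(ev, "indel", span=(0, 6))
    assert list(positions) == [0, 1, 2, 3, 4, 5]
    # the insertion's gap-run start (column 2) shares offset 1
    assert values[1] == 1 and values.sum() == 1
    with pytest.raises(ValueError):
        offset_channel(ev, "indel", span=(-5, 6))


# ------------------------------------------------------------------ symmetry


def test_reversal_mirrors_base_channel_and_gap_runs(rng):
    for _ in range(10):
        aln = random_alignment(rng, L=80)
        rev = MultipleAlignment(
            [(sid, seq[::-1]) for sid, seq in aln.records()], "ref"
        )
        assert np.array_equal(
            call_base_change_events(rev), call_base_change_events(aln)[::-1]
        )
        # indel events mark 5' run starts, so reversal maps run starts to run
        # ends; the mirrored run *intervals* coincide exactly.
        def runs(a):
            out = set()
            for sid, seq in a.records():
                i = 0
                while i < len(seq):
                    if seq[i] == "-":
                        j = i
                        while j < len(seq) and seq[j] == "-":
                            j += 1
                        out.add((i, j))
                        i = j
                    else:
                        i += 1
            return out

        L = aln.L
        assert {(L - j, L - i) for i, j in runs(aln)} == runs(rev)


def test_event_positions_lists_channel_hits():
    aln = MultipleAlignment([("ref", "AAAA"), ("sp1", "A-AT")], "ref")
    ev = build_event_vector(aln)
    assert list(event_positions(ev, "indel")) == [1]
    assert list(event_positions(ev, "base")) == [3]


def test_events_to_bed_writes_reference_coordinates(tmp_path):
    from promdiv.events import events_to_bed

    aln = MultipleAlignment([("ref", "AC--GT"), ("sp1", "ACAAAT")], "ref")
    ev = build_event_vector(aln)
    path = tmp_path / "ev.bed"
    events_to_bed("g1", ev, path, channel="all")
    lines = path.read_text().strip().splitlines()
    # insertion run starts at column 2 (ref coord 1); base change at column 4 (ref coord 2)
    assert lines == ["g1\t1\t2\tall", "g1\t2\t3\tall"]
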