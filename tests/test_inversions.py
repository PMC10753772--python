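import pytest

from plastcomp.genome_io import Feature, revcomp
from plastcomp.inversions import (
    find_all_inversions,
    find_inversions,
    find_stems,
    label_location,
    stem_mismatches,
)
from .conftest import make_alignment


def test_reverse_complemented_segment_is_called():
    aln = make_alignment("CCTGATCC", "CCATCACC")  # TGAT vs ATCA
    calls = find_inversions(aln, "r0", "r1")
    assert [(c.start, c.end) for c in calls] == [(2, 6)]
    assert not calls[0].out_of_range


def test_identical_rows_yield_no_call():
    aln = make_alignment("CCGATCCC", "CCGATCCC")
    assert find_inversions(aln, "r0", "r1") == []


def test_single_at_substitution_is_not_a_length_one_inversion():
    # A<->T is a trivial self-palindrome; min_len=2 must exclude it
    aln = make_alignment("CCACC", "CCTCC")
    assert find_inversions(aln, "r0", "r1") == []


def test_long_segments_are_reported_but_flagged():
    loop = "AGGGTTCAAGCTA"  # 13 bp
    aln = make_alignment("CC" + loop + "CC", "CC" + revcomp(loop) + "CC")
    calls = find_inversions(aln, "r0", "r1", min_len=2, max_len=8)
    assert [(c.start, c.end, c.out_of_range) for c in calls] == [(2, 15, True)]


def test_interior_matching_positions_do_not_split_the_call():
    # revcomp-symmetric interior columns coincide between the two rows;
    # the scanner must still report one full-loop interval
    loop = "CAATATTC"  # revcomp = GAATATTG: interior ATAT matches itself
    assert revcomp(loop)[2:6] == loop[2:6]
    aln = make_alignment("GG" + loop + "GG", "GG" + revcomp(loop) + "GG")
    calls = find_inversions(aln, "r0", "r1")
    assert [(c.start, c.end) for c in calls] == [(2, 10)]


def test_published_hairpin_flanks_recover_the_stem_pair():
    # psbA-trnH locus: 16 bp stems immediately flanking a 4 bp loop
    seq = "tcaataccaaacttct" + "tgat" + "agaagtttggtattga"
    stems = find_stems(seq.upper(), (16, 20))
    assert stems.found and stems.stem_length == 16 and stems.n_mismatches == 0
    assert stems.upstream_stem.lower() == "tcaataccaaacttct"
    assert stems.downstream_stem.lower() == "agaagtttggtattga"


def test_three_bp_stem_is_found_at_the_minimum_length():
    # ccsA-psaC locus: 3 bp stems aat/att around loop atc; the poly-A
    # context offers no competing longer stem
    seq = ("AAAAA" + "aat" + "atc" + "att" + "AAAAA").upper()
    stems = find_stems(seq, (8, 11))
    assert stems.found and stems.stem_length == 3
    assert stems.upstream_stem == "AAT" and stems.downstream_stem == "ATT"


def test_no_stem_returns_explicit_not_found_result():
    seq = "AAAAAAAAAA" + "CG" + "GGGGGGGGGG"
    stems = find_stems(seq, (10, 12))
    assert not stems.found and stems.stem_length == 0


def test_stem_mismatch_tolerance_is_opt_in():
    up, dn = "AAAAA", "AAAAA"  # not a palindromic pair (revcomp is TTTTT)
    assert stem_mismatches(up, dn) == 5
    seq = "GG" + up + "CA" + dn + "GG"
    assert not find_stems(seq, (7, 9), max_mismatch=0).found
    tolerant = find_stems(seq, (7, 9), max_mismatch=5, min_stem=5, max_stem=5)
    assert tolerant.found and tolerant.n_mismatches == 5


_FEATS = [
    Feature("psbA", "gene", "+", [(10, 110)]),
    Feature("trnH-GUG", "tRNA", "+", [(150, 200)]),
    Feature("rps16", "gene", "-", [(220, 260), (300, 350)]),
    Feature("ycf2", "gene", "+", [(400, 800)]),
]


@pytest.mark.parametrize(
    "interval,label",
    [
        ((120, 130), "psbA-trnH"),  # spacer, anticodon suffix dropped
        ((265, 290), "rps16 intron"),
        ((500, 520), "ycf2"),
        ((205, 210), "trnH-rps16"),
    ],
)
def test_location_labels(interval, label):
    assert label_location(interval, _FEATS) == label


def test_unannotated_interval_gets_coordinate_label():
    assert label_location((5, 9), []) == "unlabeled:5-9"


def test_detection_is_mirrored_on_reverse_complemented_rows(sim_default):
    _, _, aln, _ = sim_default
    calls = find_all_inversions(aln)
    gap_safe = str.maketrans("ACGTN-", "TGCAN-")
    flipped = make_alignment(
        *[aln.row(lab).translate(gap_safe)[::-1] for lab in aln.labels],
        labels=aln.labels,
    )
    mirrored = find_all_inversions(flipped)
    n = aln.n_cols
    assert {(n - c.end, n - c.start) for c in mirrored} == {
        (c.start, c.end) for c in calls}


def test_planted_inversions_recovered_without_extras(sim_default):
    _, _, aln, truth = sim_default
    calls = find_all_inversions(aln)
    assert {(c.start, c.end, c.bearers) for c in calls} == {
        (v.aligned_start, v.aligned_end, v.carriers) for v in truth.inversions}
    sizes = [c.end - c.start for c in calls]
    lo, hi = 2, 46
    assert all(lo <= s <= hi for s in sizes)
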