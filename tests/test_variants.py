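import numpy as np
import pytest

from plastcomp.variants import (
    VariantError,
    call_indels,
    call_substitutions,
    classify_ssr,
    ssr_motif,
    tally,
)
from .conftest import make_alignment


def test_single_polymorphic_column_is_one_substitution():
    aln = make_alignment("ACGT", "ACGA")
    subs = call_substitutions(aln)
    assert len(subs) == 1 and subs[0].column == 3
    assert subs[0].states == {"r0": "T", "r1": "A"}


def test_gapped_columns_are_excluded_from_substitution_calling():
    aln = make_alignment("AC-T", "ACGT")
    assert call_substitutions(aln) == []


def test_n_is_missing_never_polymorphic():
    aln = make_alignment("ACNT", "ACGT")
    assert call_substitutions(aln) == []


def test_single_gap_run_is_one_indel_event():
    aln = make_alignment("AAA--A", "AAATTA")
    events = call_indels(aln)
    assert len(events) == 1
    ev = events[0]
    assert (ev.start, ev.end, ev.fragment, ev.bearers) == (3, 5, "TT", ("r0",))


def test_adjacent_columns_with_different_bearer_patterns_split_events():
    aln = make_alignment("A--A", "AT-A", "ATTA")
    events = call_indels(aln)
    assert len(events) == 2
    assert events[0].bearers == ("r0",)
    assert set(events[1].bearers) == {"r0", "r1"}


def test_subset_must_have_two_rows():
    aln = make_alignment("ACGT", "ACGA")
    with pytest.raises(VariantError):
        call_substitutions(aln, subset=["r0"])


@pytest.mark.parametrize(
    "fragment,left,right,expected_motif",
    [
        ("A", "CCAAA", "AAGTC", "A"),  # homopolymer slippage
        ("GATC", "TTTTT", "CCCCC", None),  # no repeat context
        ("ATAT", "GGGG", "ATGG", "AT"),  # dinucleotide with one extra copy
        ("TAG", "CCC", "TAGTAG", "TAG"),
        ("AA", "GG", "GG", None),  # fragment repeats but no flanking copy
    ],
)
def test_ssr_motif_rule(fragment, left, right, expected_motif):
    assert ssr_motif(fragment, left, right) == expected_motif


def _brute_force_ssr(fragment, left, right, max_motif=6, min_extra=1):
    """Independent enumeration of the SSR definition."""
    for mlen in range(1, max_motif + 1):
        if len(fragment) % mlen:
            continue
        motif = fragment[:mlen]
        if fragment != motif * (len(fragment) // mlen):
            continue
        need = motif * min_extra
        if left.endswith(need) or right.startswith(need):
            return motif
    return None


def test_ssr_motif_agrees_with_brute_force_enumeration():
    rng = np.random.default_rng(42)
    bases = "ACGT"
    for _ in range(300):
        frag = "".join(rng.choice(list(bases), size=rng.integers(1, 9)))
        left = "".join(rng.choice(list(bases), size=rng.integers(0, 12)))
        right = "".join(rng.choice(list(bases), size=rng.integers(0, 12)))
        assert ssr_motif(frag, left, right) == _brute_force_ssr(frag, left, right)


def test_classify_ssr_reads_context_from_non_bearer_row():
    #           0123456789
    aln = make_alignment("CCAAAAATGC", "CCAA--ATGC")
    events = call_indels(aln)
    assert len(events) == 1
    assert classify_ssr(events[0], aln) == "SSR"
    assert events[0].motif == "A"


@pytest.mark.parametrize(
    "subs,indels,inversions,total",
    [(740, 249, 24, 1013), (0, 0, 0, 0)],
)
def test_tally_totals(subs, indels, inversions, total):
    assert tally(subs, indels, inversions).total == total


def test_recovery_on_truth_alignment(sim_default):
    _, _, aln, truth = sim_default
    from plastcomp.pipeline import analyze_alignment

    inv_calls, subs, indels = analyze_alignment(aln)
    assert {s.column for s in subs} == {s.aligned_col for s in truth.substitutions}
    assert {(e.start, e.end) for e in indels} == {
        (e.aligned_start, e.aligned_end) for e in truth.indels}
    intent = {(e.aligned_start, e.aligned_end): e.ssr_class for e in truth.indels}
    assert all(e.ssr_class == intent[(e.start, e.end)] for e in indels)


def test_row_permutation_changes_no_counts(sim_default):
    _, _, aln, _ = sim_default
    rng = np.random.default_rng(0)
    order = rng.permutation(aln.n_rows)
    shuffled = make_alignment(
        *[aln.row(aln.labels[i]) for i in order],
        labels=[aln.labels[i] for i in order],
    )
    assert len(call_substitutions(shuffled)) == len(call_substitutions(aln))
    assert len(call_indels(shuffled)) == len(call_indels(aln))
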