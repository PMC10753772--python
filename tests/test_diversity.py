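import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from plastcomp.datasets import CASSYTHA_SPECIES, load_divergence_matrix
from plastcomp.diversity import (
    DistanceMatrix,
    DiversityError,
    distance_matrix,
    group_summary,
    name_hotspots,
    nucleotide_diversity,
    pairwise_divergence,
    sliding_pi,
)
from plastcomp.simulate import SimConfig, simulate
from .conftest import make_alignment


@pytest.mark.parametrize(
    "rows,expected",
    [
        (("ACGT", "ACGT"), 0.0),
        (("ACGT", "ACGA"), 0.25),
        (("AC-T", "ACGT"), 0.0),  # pairwise gap deletion: 0 diffs over 3 sites
        (("ANGT", "ACGA"), 1 / 3),  # N removed pairwise
    ],
)
def test_p_distance_examples(rows, expected):
    aln = make_alignment(*rows)
    assert pairwise_divergence(aln, "r0", "r1") == pytest.approx(expected)


def test_no_comparable_columns_is_an_error():
    aln = make_alignment("A-N", "-AN", "AAA")
    with pytest.raises(DiversityError):
        pairwise_divergence(aln, "r0", "r1")


def _brute_force_pi(rows):
    """Mean pairwise difference fraction over complete-deletion columns."""
    cols = [c for c in zip(*rows) if all(x not in "-N" for x in c)]
    if not cols:
        return None
    pairs = list(itertools.combinations(range(len(rows)), 2))
    diffs = sum(
        sum(1 for c in cols if c[i] != c[j]) for i, j in pairs
    )
    return diffs / (len(pairs) * len(cols))


@settings(deadline=None, max_examples=40, derandomize=True)
@given(st.data())
def test_pi_equals_brute_force_pairwise_counting(data):
    n_rows = data.draw(st.integers(2, 10))
    n_cols = data.draw(st.integers(1, 60))
    rows = [
        data.draw(st.text(alphabet="ACGTN-", min_size=n_cols, max_size=n_cols))
        for _ in range(n_rows)
    ]
    if any(all(ch == "-" for ch in col) for col in zip(*rows)):
        rows[0] = "A" * n_cols  # no column may be gap in every row
    aln = make_alignment(*rows)
    expected = _brute_force_pi([aln.row(lab) for lab in aln.labels])
    got = nucleotide_diversity(aln)
    if expected is None:
        assert got is None
    else:
        assert got == pytest.approx(expected, abs=1e-12)


def test_two_row_pi_reduces_to_p_distance():
    aln = make_alignment("ACGTTACAGT", "ACCTTACAAT")
    assert nucleotide_diversity(aln) == pytest.approx(
        pairwise_divergence(aln, "r0", "r1"))


def test_window_starts_step_apart_with_truncated_tail():
    aln = make_alignment("A" * 1000, "A" * 1000)
    windows = sliding_pi(aln, window=600, step=200)
    assert [w.start for w in windows] == [0, 200, 400, 600, 800]
    assert windows[-1].end == 1000
    assert all(w.pi == 0.0 for w in windows)


def test_pi_of_concatenation_is_net_site_weighted_mean():
    rng = np.random.default_rng(5)
    rows = ["".join(rng.choice(list("ACGT"), size=400)) for _ in range(4)]
    aln = make_alignment(*rows)
    pi_a = nucleotide_diversity(aln, interval=(0, 150))
    pi_b = nucleotide_diversity(aln, interval=(150, 400))
    whole = nucleotide_diversity(aln)
    assert whole == pytest.approx((150 * pi_a + 250 * pi_b) / 400)


def test_distance_matrix_is_symmetric_zero_diagonal(sim_default):
    _, _, aln, _ = sim_default
    m = distance_matrix(aln)
    assert np.allclose(m.values, m.values.T)
    assert np.allclose(np.diag(m.values), 0)


def test_published_matrix_group_ratio():
    m = load_divergence_matrix()
    summary = group_summary(m, CASSYTHA_SPECIES)
    # independent arithmetic over the printed entries
    labels = m.labels
    within, between = [], []
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            b = labels[j]
            v = m.value(a, b)
            (within if CASSYTHA_SPECIES[a] == CASSYTHA_SPECIES[b] else between).append(v)
    expected = (sum(between) / len(between)) / (sum(within) / len(within))
    assert summary["ratio"] == pytest.approx(expected)
    assert summary["ratio"] >= 6
    assert summary["ratio"] == pytest.approx(10.48, abs=0.01)


def test_all_equal_matrix_has_unit_ratio():
    labels = ["a1", "a2", "b1", "b2"]
    values = np.full((4, 4), 0.01)
    np.fill_diagonal(values, 0.0)
    summary = group_summary(
        DistanceMatrix(labels, values), {"a1": "A", "a2": "A", "b1": "B", "b2": "B"})
    assert summary["ratio"] == pytest.approx(1.0)


def test_single_group_partition_is_an_error():
    labels = ["a1", "a2"]
    m = DistanceMatrix(labels, np.array([[0, 0.1], [0.1, 0]]))
    with pytest.raises(DiversityError):
        group_summary(m, {"a1": "A", "a2": "A"})


def test_planted_hotspot_is_named_after_its_spacer(sim_default):
    from plastcomp.inversions import find_all_inversions, inversion_column_mask

    _, individuals, aln, truth = sim_default
    mask = inversion_column_mask(aln, find_all_inversions(aln))
    windows = sliding_pi(aln, mask=mask)
    # the reference row's coordinate map indexes that individual's genome,
    # so its own (remapped) annotation provides the labels
    reference = aln.labels[0]
    ref_features = next(r for r in individuals if r.id == reference).features
    labels = name_hotspots(windows, ref_features, k=1,
                           aln=aln, reference=reference)
    assert labels == [truth.hotspot["label"]]
    assert labels == ["trnQ-psbK"]


def test_invariant_alignment_yields_no_hotspots():
    aln = make_alignment("ACGT" * 50, "ACGT" * 50)
    windows = sliding_pi(aln, window=100, step=50)
    assert name_hotspots(windows, [], k=5) == []


def test_k_larger_than_window_count_returns_nonzero_windows():
    aln = make_alignment("AAAAAAAAGT", "AAAAAAAAGA")
    windows = sliding_pi(aln, window=5, step=5)
    labels = name_hotspots(windows, [], k=10)
    assert len(labels) == 1  # only the window containing the variant column


def test_mean_between_rises_with_between_rate():
    lo, hi = [], []
    for seed in range(10):
        for rate, out in ((5.7e-3, lo), (1.2e-2, hi)):
            cfg = SimConfig(seed=seed, subst_rate_between=rate,
                            n_ssr_indels=5, n_nonssr_indels=2, n_inversions=2)
            _, _, aln, truth = simulate(cfg)
            out.append(group_summary(distance_matrix(aln), truth.species_of)[
                "mean_between"])
    assert np.mean(hi) > np.mean(lo)
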