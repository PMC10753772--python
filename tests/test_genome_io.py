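import pytest
from Bio import SeqIO
from hypothesis import given, settings
from hypothesis import strategies as st

from plastcomp.genome_io import (
    Feature,
    GenomeIOError,
    GenomeRecord,
    gc_content,
    read_genome,
    revcomp,
    rotate_to_gene,
    write_genome,
)

# published hairpin stem pairs: upstream stem must reverse-complement to the
# printed downstream stem
@pytest.mark.parametrize(
    "upstream,downstream",
    [
        ("tcaataccaaacttct", "agaagtttggtattga"),  # psbA-trnH locus
        ("tttcattc", "gaatgaaa"),  # ycf2 locus
    ],
)
def test_revcomp_matches_published_stem_pairs(upstream, downstream):
    assert revcomp(upstream) == downstream.upper()


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.text(alphabet="ACGTNacgtn", min_size=0, max_size=200))
def test_revcomp_is_a_length_preserving_involution(s):
    rc = revcomp(s)
    assert len(rc) == len(s)
    assert revcomp(rc) == s.upper()


def test_revcomp_rejects_ambiguity_codes():
    with pytest.raises(GenomeIOError):
        revcomp("ACGR")


@pytest.mark.parametrize(
    "seq,expected",
    [("GGCC", 1.0), ("ATAT", 0.0), ("ACGTN", 0.5), ("ACGTTATTAC", 0.3)],
)
def test_gc_content_excludes_n_from_denominator(seq, expected):
    assert gc_content(seq) == pytest.approx(expected)


def test_gc_content_undefined_on_all_n():
    with pytest.raises(GenomeIOError):
        gc_content("NNNN")


def test_minimal_fasta_without_annotation(tmp_path):
    p = tmp_path / "mini.fa"
    p.write_text(">mini\nACGT\n")
    rec = read_genome(p, "fasta+gff3")
    assert len(rec.seq) == 4 and rec.features == []


def test_genbank_one_based_coordinates_convert_to_half_open(tmp_path):
    rec = GenomeRecord(
        "g1", "A" * 100, circular=False,
        features=[Feature("psbA", "gene", "+", [(0, 90)])],
    )
    path = tmp_path / "g1.gb"
    write_genome(rec, path, "genbank")
    text = path.read_text()
    assert "1..90" in text  # GenBank prints 1-based inclusive
    back = read_genome(path, "genbank", normalize=False)
    assert back.features[0].intervals == [(0, 90)]
    assert back.features[0].strand == "+"


@pytest.mark.parametrize("fmt", ["genbank", "fasta+gff3"])
def test_round_trip_identity_on_synthetic_genome(tmp_path, fmt, sim_default):
    ancestor = sim_default[0]
    path = tmp_path / ("anc.gb" if fmt == "genbank" else "anc.fa")
    write_genome(ancestor, path, fmt)
    back = read_genome(path, fmt)
    assert back.seq == ancestor.seq
    key = lambda f: (f.start, f.name)
    for f1, f2 in zip(sorted(ancestor.features, key=key), sorted(back.features, key=key)):
        assert (f1.name, f1.ftype, f1.strand, f1.intervals) == (
            f2.name, f2.ftype, f2.strand, f2.intervals)


def test_origin_wrapping_feature_round_trips_as_join(tmp_path):
    rec = GenomeRecord(
        "circ", "ACGT" * 30, circular=True,
        features=[Feature("ycf1", "gene", "+", [(110, 120), (0, 10)])],
    )
    path = tmp_path / "circ.gb"
    write_genome(rec, path, "genbank")
    assert "join" in path.read_text()
    # conformance per an independent parser
    sr = next(SeqIO.parse(str(path), "genbank"))
    assert len(sr.features[0].location.parts) == 2
    back = read_genome(path, "genbank", normalize=False)
    assert back.features[0].intervals == [(110, 120), (0, 10)]


def test_rotation_puts_trnh_at_origin():
    seq = "ACGTACGTACGTACGTACGT"
    rec = GenomeRecord(
        "r", seq, circular=True,
        features=[Feature("trnH-GUG", "tRNA", "+", [(8, 12)]),
                  Feature("psbA", "gene", "+", [(14, 20)])],
    )
    rot = rotate_to_gene(rec)
    assert rot.feature_by_name("trnH-GUG").start == 0
    assert len(rot.seq) == len(seq)
    assert rot.seq == seq[8:] + seq[:8]
    # feature sequences survive the rotation
    assert rot.feature_by_name("psbA").extract(rot.seq) == rec.feature_by_name(
        "psbA").extract(seq)


def test_feature_outside_sequence_is_rejected():
    with pytest.raises(GenomeIOError):
        GenomeRecord("x", "ACGT", features=[Feature("g", "gene", "+", [(2, 9)])])
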