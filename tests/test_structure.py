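import numpy as np
import pytest

from plastcomp.genome_io import Feature, GenomeRecord, revcomp
from plastcomp.simulate import SimConfig, simulate
from plastcomp.structure import (
    call_pseudogenes,
    compare,
    find_ir,
    missing_segments,
    summarize,
)


def _random_record(seed: int, n: int) -> GenomeRecord:
    rng = np.random.default_rng(seed)
    return GenomeRecord("rand", "".join(rng.choice(list("ACGT"), size=n)))


def test_ancestor_ir_is_found_exactly(sim_default, sim_config):
    ancestor = sim_default[0]
    res = find_ir(ancestor)
    assert res.ir_status == "quadripartite"
    assert res.length == sim_config.ir_length
    assert res.irb == (sim_config.genome_length - sim_config.ir_length,
                       sim_config.genome_length)
    s, e = res.ira
    assert ancestor.seq[s:e] == revcomp(ancestor.seq[res.irb[0] : res.irb[1]])


def test_individuals_lack_the_ir(sim_default):
    for rec in sim_default[1]:
        assert find_ir(rec).ir_status == "ir_lacking"


def test_random_sequence_has_no_long_inverted_repeat():
    res = find_ir(_random_record(11, 10_000))
    assert res.ir_status == "ir_lacking" and res.length < 1000


def test_ir_lengths_equal_on_reverse_complemented_genome():
    rng = np.random.default_rng(4)
    core = "".join(rng.choice(list("ACGT"), size=2000))
    ira = "".join(rng.choice(list("ACGT"), size=1200))
    seq = core[:800] + ira + core[800:1500] + revcomp(ira) + core[1500:]
    fwd = find_ir(GenomeRecord("f", seq))
    rev = find_ir(GenomeRecord("r", revcomp(seq)))
    assert fwd.length == rev.length >= 1200


def test_identical_genomes_have_no_missing_segments(sim_default):
    ancestor = sim_default[0]
    assert missing_segments(ancestor, ancestor) == []


def test_planted_segment_deletions_are_recovered(sim_default):
    ancestor, individuals, _, truth = sim_default
    planted = {
        frozenset(g.lower() for g in e["genes"]): tuple(e["flanks"])
        for e in truth.structural_edits
        if e["op"] == "delete_segment"
    }
    segs = missing_segments(ancestor, individuals[0])
    assert len(segs) == len(planted) == 2  # two blocks, not merged
    for seg in segs:
        key = frozenset(g.lower() for g in seg.contained_genes)
        assert key in planted
        assert (seg.left_flank, seg.right_flank) == planted[key]


def test_size_difference_reconciles_exactly(sim_default, sim_config):
    ancestor, individuals, _, truth = sim_default
    structural = sum(
        e["interval"][1] - e["interval"][0] for e in truth.structural_edits
    )
    for rec in individuals:
        borne = sum(
            ev.ancestor_end - ev.ancestor_start
            for ev in truth.indels
            if rec.id in ev.bearers
        )
        assert len(ancestor.seq) - len(rec.seq) == structural + borne


def test_planted_pseudogenes_called_with_published_length_pairs(sim_default):
    ancestor, individuals, _, truth = sim_default
    calls = {p.name: p for p in call_pseudogenes(ancestor, individuals[0])}
    planted = {
        e["gene"]: e["keep_bp"]
        for e in truth.structural_edits
        if e["op"] == "truncate_gene"
    }
    assert set(calls) == set(planted)
    for name, keep in planted.items():
        assert calls[name].observed_length == keep
        assert "truncation" in calls[name].evidence
    # the deepest truncation: 1191 bp observed vs 2181 bp reference
    assert (calls["ndhB"].observed_length, calls["ndhB"].reference_length) == (
        1191, 2181)
    assert calls["ndhB"].observed_length / calls["ndhB"].reference_length < 0.9


def test_premature_stop_is_pseudogene_evidence():
    body = "ATG" + "GCT" * 98 + "TAA"  # clean 300 bp ORF
    broken = body[:30] + "TAA" + body[33:]  # stop at codon 10
    ref = GenomeRecord("ref", body + "AAAA",
                       features=[Feature("rbcL", "gene", "+", [(0, 300)])])
    query = GenomeRecord("qry", broken + "AAAA",
                         features=[Feature("rbcL", "gene", "+", [(0, 300)])])
    calls = call_pseudogenes(ref, query)
    assert [(c.name, c.evidence) for c in calls] == [("rbcL", ("premature_stop",))]
    assert call_pseudogenes(ref, ref) == []


def test_truncation_calls_are_monotone_in_threshold(sim_default):
    ancestor, individuals, _, _ = sim_default
    loose = {p.name for p in call_pseudogenes(ancestor, individuals[0], 0.9)}
    strict = {p.name for p in call_pseudogenes(ancestor, individuals[0], 0.99)}
    assert loose <= strict


def test_full_gene_complement_summary():
    # 73 protein-coding + 30 tRNA + 4 rRNA functional genes in the reduced
    # genomes requires 69 filler genes on top of the fixed complement
    cfg = SimConfig(seed=2, genome_length=36_000, n_filler_cds=69)
    _, individuals, _, _ = simulate(cfg)
    s = summarize(individuals[0])
    assert (s.n_protein_coding, s.n_trna, s.n_rrna) == (73, 30, 4)
    assert s.n_genes == 107


def test_pseudogenes_are_excluded_from_all_counts():
    rec = GenomeRecord(
        "r", "ACGT" * 100,
        features=[
            Feature("rbcL", "gene", "+", [(0, 90)]),
            Feature("ndhB", "pseudogene", "+", [(100, 190)]),
            Feature("trnH-GUG", "tRNA", "+", [(200, 270)]),
        ],
    )
    s = summarize(rec)
    assert (s.n_genes, s.n_protein_coding, s.n_trna, s.n_rrna) == (2, 1, 1, 0)
    assert s.gc_percent == 50.0


def test_compare_bundles_all_evidence(sim_default):
    ancestor, individuals, _, truth = sim_default
    diff = compare(ancestor, individuals[-1])
    assert diff.ir_status == "ir_lacking"
    assert len(diff.missing_segments) == 2
    assert {p.name for p in diff.pseudogenes} == {
        e["gene"] for e in truth.structural_edits if e["op"] == "truncate_gene"}
    assert set(diff.lost_genes) == {
        g for e in truth.structural_edits if e["op"] == "delete_segment"
        for g in e["genes"]}
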