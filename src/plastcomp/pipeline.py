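"""End-to-end orchestration: variants -> inversions -> diversity ->
structure -> tree, with config echo and a combined JSON report.

The stages are pure library calls; this module only sequences them,
resolves parameters, and writes the per-stage tables.  In synthetic mode
the planted-event ledger is compared against the calls and a recovery
report (precision/recall per event class) is added to the bundle.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import yaml

from . import diversity, inversions, njtree, simulate, structure, variants
from .alignment import Alignment
from .genome_io import GenomeRecord, write_genome

log = logging.getLogger("plastcomp")


@dataclasses.dataclass
class PipelineConfig:
    """Resolved parameter set for one pipeline run."""

    outdir: str = "plastcomp_out"
    # inputs (synthetic mode fills these itself)
    alignment: str | None = None
    genomes: list[str] = dataclasses.field(default_factory=list)
    reference: str | None = None
    stages: list[str] = dataclasses.field(
        default_factory=lambda: ["variants", "inversions", "diversity", "tree"]
    )
    synthetic: bool = False
    seed: int = 0
    # tunables
    window: int = 600
    step: int = 200
    ssr_max_motif: int = 6
    ssr_min_extra_copies: int = 1
    min_inversion: int = 2
    max_inversion: int = 46
    min_stem: int = 3
    max_stem: int = 23
    stem_max_mismatch: int = 0
    max_gap_to_loop: int = 5
    min_ir: int = 1000
    min_intact_frac: float = 0.9
    distance_model: str = "p"
    hotspot_k: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def validate(self) -> None:
        known = {"variants", "inversions", "diversity", "structure", "tree"}
        bad = set(self.stages) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if not self.synthetic:
            needs_aln = {"variants", "inversions", "diversity", "tree"}
            if needs_aln & set(self.stages) and self.alignment is None:
                raise ValueError("these stages need an alignment input")
            if "structure" in self.stages and (
                self.reference is None or not self.genomes
            ):
                raise ValueError("structure stage needs genomes and a reference")


def analyze_alignment(
    aln: Alignment,
    reference: str | None = None,
    cfg: PipelineConfig | None = None,
):
    """Call inversions, then substitutions (with inversion columns masked so
    inversion mismatches are not double-counted as SNPs), then indels with
    SSR classification.  Returns (inversion_calls, substitutions, indels)."""
    cfg = cfg or PipelineConfig()
    inv_calls = inversions.find_all_inversions(
        aln, reference, cfg.min_inversion, cfg.max_inversion
    )
    mask = inversions.inversion_column_mask(aln, inv_calls)
    subs = variants.call_substitutions(aln, mask=mask)
    indels = variants.call_indels(aln)
    for ev in indels:
        variants.classify_ssr(ev, aln, cfg.ssr_max_motif, cfg.ssr_min_extra_copies)
    return inv_calls, subs, indels


# ---------------------------------------------------------------------------
# Recovery report (synthetic mode)
# ---------------------------------------------------------------------------

def _pr(called: set, planted: set) -> dict:
    tp = len(called & planted)
    return {
        "precision": tp / len(called) if called else 1.0,
        "recall": tp / len(planted) if planted else 1.0,
        "n_called": len(called),
        "n_planted": len(planted),
    }


def recovery_report(
    truth: simulate.TruthTable,
    aln: Alignment,
    ancestor: GenomeRecord | None = None,
    individuals: list[GenomeRecord] | None = None,
    cfg: PipelineConfig | None = None,
) -> dict:
    """Compare calls on the truth alignment against the planted ledger."""
    cfg = cfg or PipelineConfig()
    inv_calls, subs, indels = analyze_alignment(aln, cfg=cfg)
    report: dict = {}

    called_sub_cols = {s.column for s in subs}
    planted_sub_cols = {s.aligned_col for s in truth.substitutions}
    report["substitutions"] = _pr(called_sub_cols, planted_sub_cols)

    called_indels = {(e.start, e.end, e.bearers) for e in indels}
    planted_indels = {
        (e.aligned_start, e.aligned_end, e.bearers) for e in truth.indels
    }
    report["indels"] = _pr(called_indels, planted_indels)

    intent = {(e.aligned_start, e.aligned_end): e.ssr_class for e in truth.indels}
    matched = [e for e in indels if (e.start, e.end) in intent]
    report["ssr_labels_match"] = all(
        e.ssr_class == intent[(e.start, e.end)] for e in matched
    ) and len(matched) == len(indels)

    called_inv = {(c.start, c.end, c.bearers) for c in inv_calls}
    planted_inv = {
        (v.aligned_start, v.aligned_end, v.carriers) for v in truth.inversions
    }
    report["inversions"] = _pr(called_inv, planted_inv)

    if truth.hotspot is not None:
        mask = inversions.inversion_column_mask(aln, inv_calls)
        windows = diversity.sliding_pi(aln, window=cfg.window, step=cfg.step, mask=mask)
        candidates = diversity.hotspot_candidates(windows)
        best = max(candidates, key=lambda w: (w.pi, -w.start))
        hs = truth.hotspot
        report["hotspot_argmax_overlaps_planted"] = (
            best.start < hs["aligned_end"] and hs["aligned_start"] < best.end
        )

    if ancestor is not None and individuals is not None:
        planted_ops = {e["op"] for e in truth.structural_edits}
        seg_sets = {
            frozenset(g.lower() for g in e["genes"])
            for e in truth.structural_edits
            if e["op"] == "delete_segment"
        }
        trunc = {
            e["gene"].lower()
            for e in truth.structural_edits
            if e["op"] == "truncate_gene"
        }
        ok_ir, ok_seg, ok_pseudo = True, True, True
        anc_ir = structure.find_ir(ancestor, min_ir=cfg.min_ir)
        ok_ir &= anc_ir.ir_status == "quadripartite"
        for rec in individuals:
            diff = structure.compare(
                ancestor, rec, min_ir=cfg.min_ir, min_intact_frac=cfg.min_intact_frac
            )
            if "delete_ir_copy" in planted_ops:
                ok_ir &= diff.ir_status == "ir_lacking"
            called_sets = {
                frozenset(g.lower() for g in seg.contained_genes)
                for seg in diff.missing_segments
            }
            ok_seg &= called_sets == seg_sets
            ok_pseudo &= {p.name.lower() for p in diff.pseudogenes} == trunc
        report["ir_calls_match"] = ok_ir
        report["missing_segments_match"] = ok_seg
        report["pseudogenes_match"] = ok_pseudo
    return report


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: PipelineConfig, sim_cfg: simulate.SimConfig | None = None) -> dict:
    """Execute the requested stages in dependency order and write the
    report bundle under ``cfg.outdir``.  Returns the report dictionary."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"parameters": dataclasses.asdict(cfg)}

    truth = ancestor = None
    individuals: list[GenomeRecord] = []
    if cfg.synthetic:
        sim_cfg = sim_cfg or simulate.SimConfig(seed=cfg.seed)
        report["parameters"]["simulation"] = dataclasses.asdict(sim_cfg)
        log.info("simulating: %d bp, %d x %d design", sim_cfg.genome_length,
                 sim_cfg.n_species, sim_cfg.n_individuals_per_species)
        ancestor, individuals, aln, truth = simulate.simulate(sim_cfg)
        aln.to_fasta(out / "alignment.fasta")
        truth.to_json(out / "truth.json")
        write_genome(ancestor, out / "ancestor.gb")
        for rec in individuals:
            write_genome(rec, out / f"{rec.id}.gb")
    elif cfg.alignment:
        aln = Alignment.from_fasta(cfg.alignment)
    else:
        aln = None
    ref_rec = None
    if cfg.reference and not cfg.synthetic:
        from .genome_io import read_genome

        ref_rec = read_genome(cfg.reference)
        individuals = [read_genome(p) for p in cfg.genomes]
    elif cfg.synthetic:
        ref_rec = ancestor

    if {"variants", "inversions"} & set(cfg.stages):
        log.info("calling variants")
        inv_calls, subs, indels = analyze_alignment(aln, cfg=cfg)
        frame = variants.events_to_frame(subs, indels, inv_calls)
        variants.write_events_tsv(frame, out / "events.tsv")
        t = variants.tally(subs, indels, inv_calls)
        report["tally"] = dataclasses.asdict(t) | {"total": t.total}
        if "inversions" in cfg.stages:
            reference = aln.labels[0]
            records = [
                inversions.characterize(
                    aln, c, reference, ref_rec if cfg.synthetic else None,
                    cfg.min_stem, cfg.max_stem, cfg.stem_max_mismatch,
                    cfg.max_gap_to_loop,
                )
                for c in inv_calls
            ]
            inversions.hairpin_table(records).to_csv(
                out / "hairpins.tsv", sep="\t", index=False
            )
            report["n_inversions"] = len(records)

    if "diversity" in cfg.stages:
        log.info("diversity scan: window=%d step=%d", cfg.window, cfg.step)
        inv_mask = inversions.inversion_column_mask(
            aln,
            inversions.find_all_inversions(
                aln, None, cfg.min_inversion, cfg.max_inversion
            ),
        )
        windows = diversity.sliding_pi(
            aln, window=cfg.window, step=cfg.step, mask=inv_mask
        )
        diversity.windows_to_frame(windows).to_csv(
            out / "windows.tsv", sep="\t", index=False
        )
        reference = aln.labels[0]
        ref_row_rec = next((r for r in individuals if r.id == reference), None)
        report["hotspots"] = diversity.name_hotspots(
            windows,
            ref_row_rec.features if ref_row_rec is not None else [],
            k=cfg.hotspot_k,
            aln=aln,
            reference=reference,
        )
        matrix = diversity.distance_matrix(aln, model=cfg.distance_model)
        matrix.to_tsv(out / "distances.tsv")
        if truth is not None:
            partition = truth.species_of
            report["group_summary"] = diversity.group_summary(matrix, partition)
        report["pi_overall"] = diversity.nucleotide_diversity(aln)

    if "structure" in cfg.stages and ref_rec is not None:
        log.info("structural comparison against %s", ref_rec.id)
        diffs = {}
        for rec in individuals:
            diff = structure.compare(
                ref_rec, rec, min_ir=cfg.min_ir, min_intact_frac=cfg.min_intact_frac
            )
            diffs[rec.id] = dataclasses.asdict(diff)
        (out / "structure.json").write_text(json.dumps(diffs, indent=2) + "\n")
        structure.summaries_to_frame([ref_rec] + individuals).to_csv(
            out / "summary.tsv", sep="\t", index=False
        )
        report["structure"] = {
            rec_id: d["ir_status"] for rec_id, d in diffs.items()
        }

    if "tree" in cfg.stages:
        matrix = diversity.distance_matrix(aln, model=cfg.distance_model)
        tree = njtree.neighbor_joining(matrix)
        (out / "tree.nwk").write_text(tree.newick() + "\n")
        if truth is not None:
            report["reciprocal_monophyly"] = njtree.is_reciprocally_monophyletic(
                tree, truth.species_of
            )

    if truth is not None:
        report["recovery"] = recovery_report(truth, aln, ancestor, individuals, cfg)

    (out / "report.json").write_text(
        json.dumps(report, indent=2, default=_json_default) + "\n"
    )
    log.info("report written to %s", out / "report.json")
    return report


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (set, frozenset, tuple)):
        return sorted(obj) if isinstance(obj, (set, frozenset)) else list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
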