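"""Structural comparison of a reduced plastome against a quadripartite
reference.

Covers the hallmarks of plastome reduction in parasitic lineages: loss of
one inverted-repeat (IR) copy, multi-gene segment deletions, and
pseudogenization (truncation, premature stops, frameshifts) of ndh genes.
Gene identity is by name (case-insensitive; the anticodon suffix of tRNAs
is significant, e.g. trnL-CAA), since plastome comparisons of this kind
reason entirely in gene-name space.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import pandas as pd
from Bio.Seq import Seq

from .genome_io import GenomeRecord, gc_content, revcomp


class StructureError(ValueError):
    pass


@dataclasses.dataclass
class IRResult:
    ir_status: str  # "quadripartite" | "ir_lacking"
    ira: tuple[int, int] | None
    irb: tuple[int, int] | None
    length: int


@dataclasses.dataclass
class MissingSegment:
    start: int  # reference coordinates
    end: int
    length: int
    left_flank: str | None  # nearest shared gene on each side
    right_flank: str | None
    contained_genes: tuple[str, ...]


@dataclasses.dataclass
class PseudogeneCall:
    name: str
    observed_length: int
    reference_length: int
    evidence: tuple[str, ...]  # subset of {truncation, premature_stop, frameshift}


@dataclasses.dataclass
class StructuralDiff:
    ir_status: str
    missing_segments: list[MissingSegment]
    lost_genes: list[str]
    pseudogenes: list[PseudogeneCall]


@dataclasses.dataclass
class GenomeSummary:
    """Headline numbers of one plastome (pseudogenes excluded from counts)."""

    plastome_size: int
    gc_percent: float  # one decimal
    n_genes: int
    n_protein_coding: int
    n_trna: int
    n_rrna: int


# ---------------------------------------------------------------------------
# Inverted repeat detection
# ---------------------------------------------------------------------------

def find_ir(rec: GenomeRecord, min_ir: int = 1000, seed_k: int = 21) -> IRResult:
    """Longest pair of disjoint intervals where one equals the reverse
    complement of the other, via exact k-mer seeding plus ungapped
    extension; the genome is quadripartite iff that repeat spans
    ``min_ir`` bp.  Assembled plastome IR copies are near-identical, so
    exact seeds suffice.
    """
    seq = rec.seq
    n = len(seq)
    if n < 2 * min_ir:
        return IRResult("ir_lacking", None, None, 0)
    rc = revcomp(seq)
    seeds: dict[str, list[int]] = {}
    for i in range(0, n - seed_k + 1):
        seeds.setdefault(seq[i : i + seed_k], []).append(i)
    # a match seq[i:i+k] == rc[j:j+k] extends along the diagonal d = i - j
    diagonals: dict[int, set[int]] = {}
    for j in range(0, n - seed_k + 1):
        for i in seeds.get(rc[j : j + seed_k], ()):
            diagonals.setdefault(i - j, set()).add(i)
    best = IRResult("ir_lacking", None, None, 0)
    for d, starts in diagonals.items():
        visited: set[int] = set()
        for i0 in sorted(starts):
            if i0 in visited:
                continue
            lo, hi = i0, i0 + seed_k  # [lo, hi) matched on this diagonal
            while lo > 0 and lo - d - 1 >= 0 and seq[lo - 1] == rc[lo - d - 1]:
                lo -= 1
            while hi < n and hi - d < n and seq[hi] == rc[hi - d]:
                hi += 1
            visited.update(range(lo, hi))
            length = hi - lo
            # partner interval on the forward strand
            j_lo, j_hi = lo - d, hi - d
            partner = (n - j_hi, n - j_lo)
            first, second = sorted([(lo, hi), partner])
            if first[1] > second[0]:  # overlapping (palindrome across one locus)
                continue
            if length > best.length:
                best = IRResult("ir_lacking", first, second, length)
    if best.length >= min_ir:
        return IRResult("quadripartite", best.ira, best.irb, best.length)
    return IRResult("ir_lacking", best.ira, best.irb, best.length)


# ---------------------------------------------------------------------------
# Gene-content comparison
# ---------------------------------------------------------------------------

def _ordered_gene_names(rec: GenomeRecord) -> list:
    return rec.gene_features()


def missing_segments(ref: GenomeRecord, query: GenomeRecord) -> list[MissingSegment]:
    """Maximal runs of reference genes absent from the query, bounded by
    shared genes, reported with reference coordinates and lengths."""
    ref_genes = _ordered_gene_names(ref)
    query_names = {f.name.lower() for f in query.features}
    shared_flags = [f.name.lower() in query_names for f in ref_genes]
    if sum(shared_flags) < 2:
        raise StructureError("fewer than two shared genes between genomes")
    segments: list[MissingSegment] = []
    i = 0
    while i < len(ref_genes):
        if shared_flags[i]:
            i += 1
            continue
        j = i
        while j < len(ref_genes) and not shared_flags[j]:
            j += 1
        left = ref_genes[i - 1] if i > 0 else None
        right = ref_genes[j] if j < len(ref_genes) else None
        start = left.end if left is not None else 0
        end = right.start if right is not None else len(ref.seq)
        segments.append(
            MissingSegment(
                start=start,
                end=end,
                length=end - start,
                left_flank=left.name if left else None,
                right_flank=right.name if right else None,
                contained_genes=tuple(f.name for f in ref_genes[i:j]),
            )
        )
        i = j
    return segments


def lost_genes(ref: GenomeRecord, query: GenomeRecord) -> list[str]:
    query_names = {f.name.lower() for f in query.features}
    return [f.name for f in _ordered_gene_names(ref) if f.name.lower() not in query_names]


def call_pseudogenes(
    ref: GenomeRecord, query: GenomeRecord, min_intact_frac: float = 0.9
) -> list[PseudogeneCall]:
    """Shared genes showing pseudogenization evidence in the query.

    A shared gene is called when its observed length falls below
    ``min_intact_frac`` of the reference length (truncation), when its
    translation under the plastid/bacterial code carries a premature stop,
    or when its length is not a codon multiple (frameshift).  Translation
    evidence applies to protein-coding genes only.
    """
    ref_by_name = {f.name.lower(): f for f in ref.gene_features()}
    calls = []
    for qf in sorted(query.features, key=lambda f: f.start):
        if qf.ftype not in ("gene", "pseudogene"):
            rf = ref_by_name.get(qf.name.lower())
            if rf is None or rf.ftype not in ("tRNA", "rRNA"):
                continue
            # structural RNAs: length evidence only
            if qf.length < min_intact_frac * rf.length:
                calls.append(
                    PseudogeneCall(qf.name, qf.length, rf.length, ("truncation",))
                )
            continue
        rf = ref_by_name.get(qf.name.lower())
        if rf is None or rf.ftype != "gene":
            continue
        evidence = []
        if qf.length < min_intact_frac * rf.length:
            evidence.append("truncation")
        if qf.length % 3 != 0:
            evidence.append("frameshift")
        else:
            protein = str(Seq(qf.extract(query.seq)).translate(table=11))
            if "*" in protein[:-1]:
                evidence.append("premature_stop")
        if evidence:
            calls.append(PseudogeneCall(qf.name, qf.length, rf.length, tuple(evidence)))
    return calls


def compare(
    ref: GenomeRecord,
    query: GenomeRecord,
    min_ir: int = 1000,
    min_intact_frac: float = 0.9,
) -> StructuralDiff:
    """Full structural comparison of ``query`` against the quadripartite
    reference: IR status, missing segments, lost genes, pseudogenes."""
    return StructuralDiff(
        ir_status=find_ir(query, min_ir=min_ir).ir_status,
        missing_segments=missing_segments(ref, query),
        lost_genes=lost_genes(ref, query),
        pseudogenes=call_pseudogenes(ref, query, min_intact_frac),
    )


def summarize(rec: GenomeRecord) -> GenomeSummary:
    """Size, GC (one decimal), and functional gene counts by category."""
    n_protein = sum(1 for f in rec.features if f.ftype == "gene")
    n_trna = sum(1 for f in rec.features if f.ftype == "tRNA")
    n_rrna = sum(1 for f in rec.features if f.ftype == "rRNA")
    return GenomeSummary(
        plastome_size=len(rec.seq),
        gc_percent=round(100 * gc_content(rec), 1),
        n_genes=n_protein + n_trna + n_rrna,
        n_protein_coding=n_protein,
        n_trna=n_trna,
        n_rrna=n_rrna,
    )


def summaries_to_frame(records: list[GenomeRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        s = summarize(rec)
        rows.append(
            {
                "id": rec.id,
                "plastome_size_bp": s.plastome_size,
                "gc_percent": s.gc_percent,
                "n_genes": s.n_genes,
                "protein_coding": s.n_protein_coding,
                "tRNA": s.n_trna,
                "rRNA": s.n_rrna,
            }
        )
    return pd.DataFrame(rows)


def diff_to_json(diff: StructuralDiff, path: str | Path) -> None:
    Path(path).write_text(json.dumps(dataclasses.asdict(diff), indent=2) + "\n")


def diff_to_text(diff: StructuralDiff) -> str:
    """Human-readable narrative of a structural comparison."""
    lines = [f"IR status: {diff.ir_status}"]
    for seg in diff.missing_segments:
        genes = ", ".join(seg.contained_genes) or "no annotated genes"
        lines.append(
            f"missing segment of {seg.length} bp flanked by "
            f"{seg.left_flank or 'genome start'} and {seg.right_flank or 'genome end'}"
            f" (contains {genes})"
        )
    if diff.pseudogenes:
        for p in diff.pseudogenes:
            lines.append(
                f"pseudogene {p.name}: {p.observed_length} bp vs "
                f"{p.reference_length} bp in reference ({', '.join(p.evidence)})"
            )
    else:
        lines.append("no pseudogenes detected")
    return "\n".join(lines)
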