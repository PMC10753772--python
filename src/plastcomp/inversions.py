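"""Micro-inversion detection and hairpin characterization.

A micro-inversion is a short segment (typically 2-46 bp in plastomes)
carried in reverse-complement orientation by one lineage relative to
another.  The canonical mutational model is a hairpin: the inverted
segment is the *loop* and is flanked by a pair of short inverted repeats,
the *stem* (3-23 bp here), whose pairing mediates the flip.

Detection is pairwise between alignment rows: a candidate is a maximal run
of mismatching columns whose segment on one row equals the reverse
complement of the segment on the other.  Runs are greedily merged when the
reverse-complement identity only holds across a span of several runs
(interior positions of a loop may coincide with their complement).  Both
reported interval endpoints are required to be mismatch columns, which
keeps an isolated A<->T substitution (a trivial length-1 palindrome) from
masquerading as an inversion.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .alignment import GAP, Alignment
from .genome_io import Feature, GenomeRecord, revcomp


@dataclasses.dataclass
class InversionCall:
    """A detected inverted segment, in aligned coordinates."""

    start: int
    end: int
    bearers: tuple[str, ...] = ()
    out_of_range: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclasses.dataclass
class StemPair:
    """Flanking inverted-repeat (hairpin stem) search result."""

    found: bool
    upstream_stem: str = ""
    downstream_stem: str = ""
    stem_length: int = 0
    n_mismatches: int = 0
    gap_upstream: int = 0
    gap_downstream: int = 0


@dataclasses.dataclass
class MicroInversion:
    """A fully characterized micro-inversion locus (hairpin-table layout)."""

    location_label: str
    start: int  # aligned
    end: int
    loop_motif: str  # as read on the reference row
    loop_size: int
    upstream_stem: str
    downstream_stem: str
    stem_length: int
    n_stem_mismatches: int
    bearers: tuple[str, ...] = ()


class InversionError(ValueError):
    pass


def _pair_calls(
    a: np.ndarray, b: np.ndarray, min_len: int, max_len: int
) -> list[tuple[int, int]]:
    """Candidate intervals between two gap-aware byte rows."""
    comparable = (a != GAP) & (b != GAP) & (a != ord("N")) & (b != ord("N"))
    mismatch = comparable & (a != b)
    if not mismatch.any():
        return []
    idx = np.flatnonzero(mismatch)
    # maximal runs of consecutive mismatch columns
    breaks = np.flatnonzero(np.diff(idx) != 1) + 1
    runs = [(int(g[0]), int(g[-1]) + 1) for g in np.split(idx, breaks)]
    calls: list[tuple[int, int]] = []
    i = 0
    while i < len(runs):
        emitted = False
        # candidate spans may merge nearby runs (interior positions of a
        # loop can coincide with their reverse complement); spans are
        # bounded at 2*max_len so oversized segments still get reported
        cap = max(2 * max_len, runs[i][1] - runs[i][0])
        for k in range(i, len(runs)):
            s, e = runs[i][0], runs[k][1]
            if e - s > cap:
                break
            if not comparable[s:e].all():
                break  # a gap or N inside the span: not one clean segment
            if e - s < min_len:
                continue
            seg_a = a[s:e].tobytes().decode()
            seg_b = b[s:e].tobytes().decode()
            if seg_a != seg_b and seg_a == revcomp(seg_b):
                calls.append((s, e))
                i = k + 1
                emitted = True
                break
        if not emitted:
            i += 1
    return calls


def find_inversions(
    aln: Alignment,
    row_a: str,
    row_b: str,
    min_len: int = 2,
    max_len: int = 46,
) -> list[InversionCall]:
    """Inverted segments of ``row_b`` relative to ``row_a``.

    Segments longer than ``max_len`` are still reported, flagged
    ``out_of_range``; segments shorter than ``min_len`` are not reported.
    """
    a = aln.matrix[aln.row_index(row_a)]
    b = aln.matrix[aln.row_index(row_b)]
    return [
        InversionCall(s, e, (row_b,), out_of_range=(e - s) > max_len)
        for s, e in _pair_calls(a, b, min_len, max_len)
    ]


def find_all_inversions(
    aln: Alignment,
    reference: str | None = None,
    min_len: int = 2,
    max_len: int = 46,
) -> list[InversionCall]:
    """Inversions of every row against one designated reference row,
    merged across pairs by interval identity (one record per locus)."""
    if reference is None:
        reference = aln.labels[0]
    merged: dict[tuple[int, int], set[str]] = {}
    for label in aln.labels:
        if label == reference:
            continue
        for call in find_inversions(aln, reference, label, min_len, max_len):
            merged.setdefault((call.start, call.end), set()).update(call.bearers)
    return [
        InversionCall(s, e, tuple(sorted(bearers)), out_of_range=(e - s) > max_len)
        for (s, e), bearers in sorted(merged.items())
    ]


def inversion_column_mask(aln: Alignment, calls: list[InversionCall]) -> np.ndarray:
    """Boolean mask over aligned columns covered by any inversion call."""
    mask = np.zeros(aln.n_cols, dtype=bool)
    for c in calls:
        mask[c.start : c.end] = True
    return mask


# ---------------------------------------------------------------------------
# Hairpin stems
# ---------------------------------------------------------------------------

def stem_mismatches(upstream: str, downstream: str) -> int:
    """Hamming distance between the upstream stem and the reverse
    complement of the downstream stem (0 = perfect palindromic pair)."""
    if len(upstream) != len(downstream):
        raise InversionError("stems of unequal length")
    rc = revcomp(downstream)
    return sum(1 for x, y in zip(upstream.upper(), rc) if x != y)


def find_stems(
    rec: GenomeRecord | str,
    interval: tuple[int, int],
    min_stem: int = 3,
    max_stem: int = 23,
    max_mismatch: int = 0,
    max_gap_to_loop: int = 5,
) -> StemPair:
    """Longest flanking inverted-repeat pair around a loop interval.

    Windows of equal length are slid over both flanks, each allowed to sit
    up to ``max_gap_to_loop`` bp away from the loop; a pair qualifies when
    upstream = revcomp(downstream) up to ``max_mismatch`` mismatches.  Ties
    break toward longer stems, then smaller total gap to the loop, then the
    smaller upstream gap.  Returns a not-found StemPair (never raises) when
    no stem of at least ``min_stem`` bp exists.
    """
    seq = (rec.seq if isinstance(rec, GenomeRecord) else rec).upper()
    s, e = interval
    if not (0 <= s < e <= len(seq)):
        raise InversionError(f"interval [{s}, {e}) outside sequence")
    for length in range(max_stem, min_stem - 1, -1):
        best = None
        for total_gap in range(0, 2 * max_gap_to_loop + 1):
            for gap_up in range(0, min(total_gap, max_gap_to_loop) + 1):
                gap_dn = total_gap - gap_up
                if gap_dn > max_gap_to_loop:
                    continue
                up_start = s - gap_up - length
                dn_end = e + gap_dn + length
                if up_start < 0 or dn_end > len(seq):
                    continue
                up = seq[up_start : s - gap_up]
                dn = seq[e + gap_dn : dn_end]
                mm = stem_mismatches(up, dn)
                if mm <= max_mismatch:
                    best = StemPair(True, up, dn, length, mm, gap_up, gap_dn)
                    break
            if best:
                break
        if best:
            return best
    return StemPair(False)


# ---------------------------------------------------------------------------
# Location labels
# ---------------------------------------------------------------------------

def _display_name(name: str) -> str:
    """tRNA anticodon suffixes are dropped in location labels (trnH-GUG -> trnH)."""
    if name.lower().startswith("trn") and "-" in name:
        return name.split("-", 1)[0]
    return name


def label_location(interval: tuple[int, int], features: list[Feature]) -> str:
    """Name an interval: the gene containing it, "geneX intron" between two
    exons of one gene, or "geneX-geneY" for the spacer between the nearest
    flanking genes."""
    s, e = interval
    genes = sorted(
        (f for f in features if f.ftype in ("gene", "tRNA", "rRNA", "pseudogene")),
        key=lambda f: f.start,
    )
    if not genes:
        return f"unlabeled:{s}-{e}"
    for f in genes:
        for iv_start, iv_end in f.intervals:
            if iv_start <= s and e <= iv_end:
                return _display_name(f.name)
        if len(f.intervals) > 1:  # intron check: between consecutive exons
            for (a_s, a_e), (b_s, b_e) in zip(f.intervals, f.intervals[1:]):
                if a_e <= s and e <= b_s:
                    return f"{_display_name(f.name)} intron"
    left = max((f for f in genes if f.end <= s), key=lambda f: f.end, default=None)
    right = min((f for f in genes if f.start >= e), key=lambda f: f.start, default=None)
    if left is None or right is None:
        return f"unlabeled:{s}-{e}"
    return f"{_display_name(left.name)}-{_display_name(right.name)}"


def characterize(
    aln: Alignment,
    call: InversionCall,
    reference: str,
    ref_record: GenomeRecord | None = None,
    min_stem: int = 3,
    max_stem: int = 23,
    max_mismatch: int = 0,
    max_gap_to_loop: int = 5,
) -> MicroInversion:
    """Build the full hairpin-table record for one inversion call."""
    ref_row = aln.matrix[aln.row_index(reference)]
    loop_bytes = ref_row[call.start : call.end]
    loop = loop_bytes[loop_bytes != GAP].tobytes().decode()
    a2u = aln.aligned_to_ungapped(reference)
    u_start = int(a2u[call.start])
    u_end = u_start + len(loop)
    if ref_record is not None:
        stems = find_stems(
            ref_record, (u_start, u_end), min_stem, max_stem, max_mismatch, max_gap_to_loop
        )
        label = label_location((u_start, u_end), ref_record.features)
    else:
        stems = find_stems(
            aln.degapped(reference), (u_start, u_end),
            min_stem, max_stem, max_mismatch, max_gap_to_loop,
        )
        label = f"unlabeled:{u_start}-{u_end}"
    return MicroInversion(
        location_label=label,
        start=call.start,
        end=call.end,
        loop_motif=loop,
        loop_size=len(loop),
        upstream_stem=stems.upstream_stem,
        downstream_stem=stems.downstream_stem,
        stem_length=stems.stem_length,
        n_stem_mismatches=stems.n_mismatches if stems.found else -1,
        bearers=call.bearers,
    )


def hairpin_table(records: list[MicroInversion]):
    """Hairpin records as a table: No, Location, Loop motif, Size,
    Upstream stem, Downstream stem, stem_length, mismatches."""
    import pandas as pd

    return pd.DataFrame(
        [
            dict(
                No=i + 1,
                Location=r.location_label,
                **{"Loop motif": r.loop_motif, "Size": r.loop_size,
                   "Upstream stem": r.upstream_stem,
                   "Downstream stem": r.downstream_stem},
                stem_length=r.stem_length,
                mismatches=r.n_stem_mismatches,
            )
            for i, r in enumerate(records)
        ]
    )
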