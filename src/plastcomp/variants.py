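"""Mutation-spectrum calling from a multiple alignment.

Substitutions are polymorphic gap-free columns; indels are *events* —
maximal runs of consecutive columns sharing one gap/non-gap row pattern —
not gap columns, so a 5-bp deletion counts once.  Indel events are then
classified as SSR (slipped-strand, the inserted/deleted fragment extends or
contracts a tandem repeat of a short motif) or non-SSR.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import GAP, Alignment

_N = ord("N")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclasses.dataclass
class Substitution:
    """One polymorphic alignment column."""

    column: int
    states: dict[str, str]  # label -> base (N/missing rows omitted)
    partition_pattern: tuple[tuple[str, ...], ...]  # labels grouped by shared base


@dataclasses.dataclass
class IndelEvent:
    """One insertion/deletion event (a maximal same-gap-pattern column run)."""

    start: int  # aligned, inclusive
    end: int  # aligned, exclusive
    bearers: tuple[str, ...]  # rows carrying the gap
    fragment: str  # sequence read from the first non-bearer row
    ssr_class: str | None = None  # "SSR" | "non-SSR"
    motif: str | None = None

    @property
    def length(self) -> int:
        return len(self.fragment)


@dataclasses.dataclass
class MutationTally:
    n_substitutions: int
    n_indels: int
    n_ssr_indels: int
    n_nonssr_indels: int
    n_inversions: int

    @property
    def total(self) -> int:
        return self.n_substitutions + self.n_indels + self.n_inversions


class VariantError(ValueError):
    pass


def _subset_matrix(aln: Alignment, subset: list[str] | None) -> tuple[np.ndarray, list[str]]:
    idx = aln.subset_indices(subset)
    if len(idx) < 2:
        raise VariantError("need at least two rows to call variants")
    labels = [aln.labels[i] for i in idx]
    return aln.matrix[idx], labels


def call_substitutions(
    aln: Alignment,
    subset: list[str] | None = None,
    mask: np.ndarray | None = None,
) -> list[Substitution]:
    """One Substitution per polymorphic column among ``subset``.

    Columns with a gap in any subset row are excluded (they belong to indel
    events); N is missing data, never polymorphic.  ``mask`` marks columns
    to skip (e.g. columns inside called micro-inversions, whose mismatches
    are not substitutions).
    """
    m, labels = _subset_matrix(aln, subset)
    gapfree = (m != GAP).all(axis=0)
    if mask is not None:
        gapfree &= ~np.asarray(mask, dtype=bool)
    # a column is polymorphic iff >=2 of A,C,G,T are present
    present = np.zeros(m.shape[1], dtype=np.int8)
    for b in _BASES:
        present += (m == b).any(axis=0)
    poly = np.flatnonzero(gapfree & (present >= 2))
    out = []
    for col in poly:
        states = {
            lab: chr(b) for lab, b in zip(labels, m[:, col]) if b != _N
        }
        groups: dict[str, list[str]] = {}
        for lab, base in states.items():
            groups.setdefault(base, []).append(lab)
        pattern = tuple(tuple(v) for _, v in sorted(groups.items()))
        out.append(Substitution(int(col), states, pattern))
    return out


def call_indels(aln: Alignment, subset: list[str] | None = None) -> list[IndelEvent]:
    """Maximal runs of columns with an identical gap pattern become events.

    Adjacent columns with different bearer sets are distinct events.
    Columns gapped in *all* subset rows carry no fragment within the subset
    and are skipped.
    """
    m, labels = _subset_matrix(aln, subset)
    gapped = m == GAP
    any_gap = gapped.any(axis=0)
    all_gap = gapped.all(axis=0)
    candidate = any_gap & ~all_gap
    if not candidate.any():
        return []
    # encode each column's gap pattern as an integer id
    weights = (1 << np.arange(m.shape[0], dtype=np.uint64))
    pattern_id = (gapped.astype(np.uint64).T * weights).sum(axis=1)
    pattern_id[~candidate] = 0
    boundaries = np.flatnonzero(np.diff(pattern_id) != 0) + 1
    edges = np.concatenate(([0], boundaries, [m.shape[1]]))
    events = []
    for start, end in zip(edges[:-1], edges[1:]):
        if not candidate[start]:
            continue
        col_gaps = gapped[:, start]
        bearers = tuple(lab for lab, g in zip(labels, col_gaps) if g)
        ref_row = int(np.flatnonzero(~col_gaps)[0])
        frag_bytes = m[ref_row, start:end]
        fragment = frag_bytes[frag_bytes != GAP].tobytes().decode()
        if not fragment:
            continue
        events.append(IndelEvent(int(start), int(end), bearers, fragment))
    return events


# ---------------------------------------------------------------------------
# SSR classification
# ---------------------------------------------------------------------------

def _matches(seq: str, motif: str) -> bool:
    """Motif match with N as missing (never breaks a repeat run)."""
    return len(seq) == len(motif) and all(
        a == b or a == "N" or b == "N" for a, b in zip(seq, motif)
    )


def ssr_motif(
    fragment: str,
    left_context: str,
    right_context: str,
    max_motif: int = 6,
    min_extra_copies: int = 1,
) -> str | None:
    """Smallest motif making ``fragment`` an SSR indel, else None.

    SSR means: the fragment is an integer number (>=1) of copies of a motif
    of length 1..max_motif, and at least ``min_extra_copies`` adjacent
    copies of that motif flank the event site (on either side) in the
    sequence that retains the fragment — the slipped-strand signature.
    """
    fragment = fragment.upper()
    left_context = left_context.upper()
    right_context = right_context.upper()
    for mlen in range(1, max_motif + 1):
        if len(fragment) % mlen:
            continue
        motif = fragment[:mlen]
        if not all(
            _matches(fragment[i : i + mlen], motif)
            for i in range(mlen, len(fragment), mlen)
        ):
            continue
        need = mlen * min_extra_copies
        left_ok = len(left_context) >= need and all(
            _matches(left_context[len(left_context) - need + i * mlen :][:mlen], motif)
            for i in range(min_extra_copies)
        )
        right_ok = len(right_context) >= need and all(
            _matches(right_context[i * mlen : (i + 1) * mlen], motif)
            for i in range(min_extra_copies)
        )
        if left_ok or right_ok:
            return motif
    return None


def classify_ssr(
    ev: IndelEvent,
    aln: Alignment,
    max_motif: int = 6,
    min_extra_copies: int = 1,
    context: int = 64,
) -> str:
    """Classify one indel event as "SSR" or "non-SSR" (sets the event fields).

    Context is read from the first non-bearer row, degapped, immediately
    adjacent to the event on both sides.
    """
    non_bearers = [lab for lab in aln.labels if lab not in ev.bearers]
    row_label = non_bearers[0]
    i = aln.row_index(row_label)
    row = aln.matrix[i]
    left_bytes = row[max(0, ev.start - 4 * context) : ev.start]
    right_bytes = row[ev.end : ev.end + 4 * context]
    left = left_bytes[left_bytes != GAP].tobytes().decode()[-context:]
    right = right_bytes[right_bytes != GAP].tobytes().decode()[:context]
    motif = ssr_motif(ev.fragment, left, right, max_motif, min_extra_copies)
    ev.ssr_class = "SSR" if motif else "non-SSR"
    ev.motif = motif
    return ev.ssr_class


def tally(subs, indels, inversions) -> MutationTally:
    """Mutation-spectrum totals; arguments may be event lists or counts."""
    n_subs = subs if isinstance(subs, int) else len(subs)
    if isinstance(indels, int):
        n_ind, n_ssr, n_non = indels, 0, 0
    else:
        n_ind = len(indels)
        n_ssr = sum(1 for e in indels if e.ssr_class == "SSR")
        n_non = sum(1 for e in indels if e.ssr_class == "non-SSR")
    n_inv = inversions if isinstance(inversions, int) else len(inversions)
    return MutationTally(n_subs, n_ind, n_ssr, n_non, n_inv)


def events_to_frame(
    subs: list[Substitution], indels: list[IndelEvent], inversions=()
) -> pd.DataFrame:
    """Per-event table: type, aligned_start, aligned_end, bearers, fragment,
    ssr_class, motif."""
    rows = []
    for s in subs:
        rows.append(
            dict(type="substitution", aligned_start=s.column, aligned_end=s.column + 1,
                 bearers="", fragment="/".join(sorted(set(s.states.values()))),
                 ssr_class="", motif="")
        )
    for e in indels:
        rows.append(
            dict(type="indel", aligned_start=e.start, aligned_end=e.end,
                 bearers=",".join(e.bearers), fragment=e.fragment,
                 ssr_class=e.ssr_class or "", motif=e.motif or "")
        )
    for inv in inversions:
        rows.append(
            dict(type="inversion", aligned_start=inv.start, aligned_end=inv.end,
                 bearers=",".join(getattr(inv, "bearers", ())),
                 fragment=getattr(inv, "loop_motif", ""), ssr_class="", motif="")
        )
    frame = pd.DataFrame(
        rows, columns=["type", "aligned_start", "aligned_end", "bearers",
                       "fragment", "ssr_class", "motif"]
    )
    return frame.sort_values(["aligned_start", "type"]).reset_index(drop=True)


def write_events_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)
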