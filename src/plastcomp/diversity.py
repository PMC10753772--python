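"""Nucleotide diversity, pairwise divergence, and hotspot scanning.

Divergence between two rows is the uncorrected p-distance with pairwise
gap deletion; at plastome scales of 1e-5..1e-3 differences per site a
multiple-hit correction is numerically irrelevant, but a Jukes-Cantor
option is provided.  Nucleotide diversity (pi) over a set of rows uses
complete deletion: only columns free of gaps and N across the whole subset
contribute, matching the common sliding-window convention.
"""

from __future__ import annotations

import dataclasses
import math
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import GAP, Alignment
from .genome_io import Feature
from .inversions import label_location

_N = ord("N")


class DiversityError(ValueError):
    pass


@dataclasses.dataclass
class DiversityWindow:
    start: int  # aligned coords, inclusive
    end: int  # exclusive
    net_sites: int
    pi: float | None  # None when no gap-free sites exist in the window


class DistanceMatrix:
    """Symmetric labelled matrix of pairwise divergences."""

    def __init__(self, labels: list[str], values: np.ndarray):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(labels), len(labels)):
            raise DiversityError("matrix shape does not match labels")
        if not np.allclose(values, values.T):
            raise DiversityError("matrix not symmetric")
        if not np.allclose(np.diag(values), 0):
            raise DiversityError("nonzero diagonal")
        if (values < 0).any() or (values > 1).any():
            raise DiversityError("divergences must lie in [0, 1]")
        self.labels = list(labels)
        self.values = values
        self._index = {lab: i for i, lab in enumerate(labels)}

    def value(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        frame = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(frame.index.astype(str)), frame.to_numpy(dtype=float))

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "DistanceMatrix":
        return cls(list(frame.index.astype(str)), frame.to_numpy(dtype=float))


# ---------------------------------------------------------------------------
# Pairwise divergence
# ---------------------------------------------------------------------------

def _jc_correct(p: float) -> float:
    if p >= 0.75:
        raise DiversityError(f"p-distance {p} not JC-correctable")
    return -0.75 * math.log(1 - 4 * p / 3)


def pairwise_divergence(
    aln: Alignment, label_a: str, label_b: str, model: str = "p"
) -> float:
    """p-distance (or Jukes-Cantor, ``model="jc"``) between two rows,
    with pairwise deletion of gapped or N columns."""
    a = aln.matrix[aln.row_index(label_a)]
    b = aln.matrix[aln.row_index(label_b)]
    comparable = (a != GAP) & (b != GAP) & (a != _N) & (b != _N)
    net = int(comparable.sum())
    if net == 0:
        raise DiversityError(f"no comparable columns between {label_a} and {label_b}")
    p = float(((a != b) & comparable).sum()) / net
    return _jc_correct(p) if model == "jc" else p


def distance_matrix(
    aln: Alignment, labels: list[str] | None = None, model: str = "p"
) -> DistanceMatrix:
    labels = labels if labels is not None else aln.labels
    n = len(labels)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pairwise_divergence(aln, labels[i], labels[j], model)
            values[i, j] = values[j, i] = d
    return DistanceMatrix(labels, values)


# ---------------------------------------------------------------------------
# Nucleotide diversity
# ---------------------------------------------------------------------------

def nucleotide_diversity(
    aln: Alignment,
    subset: list[str] | None = None,
    interval: tuple[int, int] | None = None,
    mask: np.ndarray | None = None,
) -> float | None:
    """pi: mean pairwise differences per site over ``subset``, complete
    deletion within ``interval`` (aligned coordinates).

    ``mask`` marks full-alignment columns to exclude — typically columns
    inside called micro-inversions, whose mismatches are one mutational
    event rather than per-site substitutions.  Returns None (an undefined
    marker) when no column is gap-free across the subset, rather than
    inventing a number.
    """
    idx = aln.subset_indices(subset)
    if len(idx) < 2:
        raise DiversityError("pi needs at least two rows")
    start, end = interval if interval is not None else (0, aln.n_cols)
    m = aln.matrix[idx][:, start:end]
    keep = ((m != GAP) & (m != _N)).all(axis=0)
    if mask is not None:
        keep &= ~np.asarray(mask, dtype=bool)[start:end]
    net = int(keep.sum())
    if net == 0:
        return None
    m = m[:, keep]
    n = m.shape[0]
    total_diffs = 0
    for i in range(n):
        for j in range(i + 1, n):
            total_diffs += int((m[i] != m[j]).sum())
    n_pairs = n * (n - 1) // 2
    return total_diffs / (n_pairs * net)


def window_net_sites(
    aln: Alignment,
    subset: list[str] | None,
    interval: tuple[int, int],
    mask: np.ndarray | None = None,
) -> int:
    idx = aln.subset_indices(subset)
    m = aln.matrix[idx][:, interval[0] : interval[1]]
    keep = ((m != GAP) & (m != _N)).all(axis=0)
    if mask is not None:
        keep &= ~np.asarray(mask, dtype=bool)[interval[0] : interval[1]]
    return int(keep.sum())


def sliding_pi(
    aln: Alignment,
    subset: list[str] | None = None,
    window: int = 600,
    step: int = 200,
    mask: np.ndarray | None = None,
) -> list[DiversityWindow]:
    """Sliding-window pi over aligned coordinates: windows start at 0 and
    every ``step`` columns; the terminal windows are truncated."""
    if not (window >= step >= 1):
        raise DiversityError("need window >= step >= 1")
    out = []
    for start in range(0, aln.n_cols, step):
        end = min(start + window, aln.n_cols)
        pi = nucleotide_diversity(aln, subset, (start, end), mask=mask)
        net = window_net_sites(aln, subset, (start, end), mask=mask)
        out.append(DiversityWindow(start, end, net, pi))
    return out


def windows_to_frame(windows: list[DiversityWindow]) -> pd.DataFrame:
    return pd.DataFrame(
        [dataclasses.asdict(w) for w in windows],
        columns=["start", "end", "net_sites", "pi"],
    )


# ---------------------------------------------------------------------------
# Group summaries and hotspots
# ---------------------------------------------------------------------------

def group_summary(matrix: DistanceMatrix, partition: dict[str, str]) -> dict:
    """Mean within-group and between-group divergence and their ratio.

    ``partition`` maps each matrix label to a group (species) name.  The
    ratio is None when mean_within is exactly zero.
    """
    groups = {partition[lab] for lab in matrix.labels}
    if len(groups) < 2:
        raise DiversityError("partition defines a single group")
    counts = {g: sum(1 for lab in matrix.labels if partition[lab] == g) for g in groups}
    if min(counts.values()) < 2:
        raise DiversityError("each group needs at least two members")
    within, between = [], []
    for i, a in enumerate(matrix.labels):
        for j in range(i + 1, len(matrix.labels)):
            b = matrix.labels[j]
            (within if partition[a] == partition[b] else between).append(
                matrix.values[i, j]
            )
    mean_within = float(np.mean(within))
    mean_between = float(np.mean(between))
    ratio = mean_between / mean_within if mean_within > 0 else None
    return {
        "mean_within": mean_within,
        "mean_between": mean_between,
        "ratio": ratio,
        "n_within_pairs": len(within),
        "n_between_pairs": len(between),
    }


def hotspot_candidates(
    windows: list[DiversityWindow], min_net_sites: int | None = None
) -> list[DiversityWindow]:
    """Windows eligible for hotspot ranking: pi defined and nonzero, and
    enough gap-free support.  A truncated or gap-riddled window of a few
    dozen sites can top the raw ranking on sampling noise alone, so by
    default a window must keep at least half the nominal window length in
    net sites."""
    if min_net_sites is None:
        width = max((w.end - w.start for w in windows), default=0)
        min_net_sites = width // 2
    return [w for w in windows if w.pi and w.net_sites >= min_net_sites]


def name_hotspots(
    windows: list[DiversityWindow],
    features: list[Feature],
    k: int = 5,
    aln: Alignment | None = None,
    reference: str | None = None,
    min_net_sites: int | None = None,
) -> list[str]:
    """Labels of the top-k windows by pi (ties toward the leftmost window).

    Overlapping top windows are merged before labeling; each merged region
    is named by ``label_location`` at its midpoint, translated from aligned
    to reference-row coordinates when an alignment and reference row are
    supplied.  Windows with pi of 0 or undefined, or with too few net
    sites (see :func:`hotspot_candidates`), never qualify.
    """
    scored = hotspot_candidates(windows, min_net_sites)
    scored.sort(key=lambda w: (-w.pi, w.start))
    top = scored[:k]
    if not top:
        return []
    # merge overlapping windows into regions, keeping rank order of regions
    regions: list[list[int]] = []
    for w in sorted(top, key=lambda w: w.start):
        if regions and w.start < regions[-1][1]:
            regions[-1][1] = max(regions[-1][1], w.end)
        else:
            regions.append([w.start, w.end])
    # rank regions by their best window's pi
    def region_rank(region):
        best = max(
            (w.pi for w in top if w.start >= region[0] and w.end <= region[1]),
            default=0.0,
        )
        return (-best, region[0])

    regions.sort(key=region_rank)
    labels = []
    for start, end in regions:
        mid = (start + end) // 2
        if aln is not None and reference is not None:
            pos = int(aln.aligned_to_ungapped(reference)[mid])
            labels.append(label_location((pos, pos + 1), features))
        else:
            labels.append(label_location((mid, mid + 1), features))
    return labels
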