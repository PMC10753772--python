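"""Gapped multiple alignment with aligned <-> ungapped coordinate maps."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .genome_io import read_fasta, write_fasta

GAP = ord("-")
ALPHABET = set("ACGTN-")


class AlignmentError(ValueError):
    pass


class Alignment:
    """Equal-length gapped rows over {A,C,G,T,N,-}.

    Rows are stored as a (n_rows, n_cols) uint8 matrix for vectorised
    column scans; per-row maps between aligned and ungapped coordinates are
    built lazily.
    """

    def __init__(self, labels: list[str], rows: list[str]):
        if len(labels) != len(rows):
            raise AlignmentError("labels and rows differ in number")
        if len(set(labels)) != len(labels):
            raise AlignmentError("duplicate row labels")
        if not rows:
            raise AlignmentError("empty alignment")
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise AlignmentError(f"rows of unequal length: {sorted(lengths)}")
        bad = set("".join(rows).upper()) - ALPHABET
        if bad:
            raise AlignmentError(f"invalid alignment characters: {sorted(bad)}")
        self.labels = list(labels)
        self.matrix = np.frombuffer(
            "".join(r.upper() for r in rows).encode(), dtype=np.uint8
        ).reshape(len(rows), -1)
        if self.matrix.shape[1] == 0:
            raise AlignmentError("zero-length rows")
        if ((self.matrix == GAP).all(axis=0)).any():
            raise AlignmentError("all-gap column")
        self._index = {lab: i for i, lab in enumerate(self.labels)}
        self._maps: dict[int, np.ndarray] = {}

    # -- basic access ------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_cols(self) -> int:
        return self.matrix.shape[1]

    def row_index(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise AlignmentError(f"no row labelled {label!r}") from None

    def row(self, label: str) -> str:
        return self.matrix[self.row_index(label)].tobytes().decode()

    def degapped(self, label: str) -> str:
        r = self.matrix[self.row_index(label)]
        return r[r != GAP].tobytes().decode()

    def subset_indices(self, subset: list[str] | None) -> np.ndarray:
        if subset is None:
            return np.arange(self.n_rows)
        return np.array([self.row_index(lab) for lab in subset])

    # -- coordinate maps ---------------------------------------------------
    def aligned_to_ungapped(self, label: str) -> np.ndarray:
        """For each aligned column, the ungapped position on that row
        (for gap columns: the position of the next non-gap base)."""
        i = self.row_index(label)
        if i not in self._maps:
            nongap = self.matrix[i] != GAP
            self._maps[i] = np.cumsum(nongap) - nongap.astype(int)
        return self._maps[i]

    def ungapped_to_aligned(self, label: str) -> np.ndarray:
        i = self.row_index(label)
        return np.flatnonzero(self.matrix[i] != GAP)

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_fasta(cls, path: str | Path) -> "Alignment":
        pairs = read_fasta(path)
        return cls([p[0] for p in pairs], [p[1] for p in pairs])

    def to_fasta(self, path: str | Path) -> None:
        write_fasta(
            ((lab, self.matrix[i].tobytes().decode()) for i, lab in enumerate(self.labels)),
            path,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment({self.n_rows} rows x {self.n_cols} cols)"
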