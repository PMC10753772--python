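"""Published reference datasets for the two-species *Cassytha* plastome panel.

Two small tables ship with the package:

* the 24 hairpin (micro-inversion) records of the eight *Cassytha*
  plastomes — location, loop motif and size, and the flanking stem pair;
* the 8x8 pairwise nucleotide divergence matrix of the same plastomes
  (accessions OR766688-OR766691 = *C. filiformis*, OR766692-OR766695 =
  *C. larsenii*).

They serve as worked inputs for the hairpin validator, the group-divergence
summary and the neighbor-joining grouping check, with no download needed.
"""

from __future__ import annotations

import dataclasses
from importlib import resources

import pandas as pd

from .diversity import DistanceMatrix
from .inversions import stem_mismatches

CASSYTHA_SPECIES = {
    "OR766688": "C_filiformis",
    "OR766689": "C_filiformis",
    "OR766690": "C_filiformis",
    "OR766691": "C_filiformis",
    "OR766692": "C_larsenii",
    "OR766693": "C_larsenii",
    "OR766694": "C_larsenii",
    "OR766695": "C_larsenii",
}

# Published plastome sizes (bp) and GC content (%) per accession range.
CASSYTHA_SIZE_RANGE = {
    "C_filiformis": (114_215, 114_618),
    "C_larsenii": (114_900, 114_988),
}
CASSYTHA_GC_PERCENT = 37.0


@dataclasses.dataclass
class HairpinRecord:
    """One published micro-inversion locus: loop plus flanking stem pair."""

    no: int
    location: str
    loop_motif: str
    size: int
    upstream_stem: str
    downstream_stem: str

    @property
    def loop_size(self) -> int:
        return len(self.loop_motif)

    @property
    def stem_length(self) -> int:
        return len(self.upstream_stem)

    @property
    def n_stem_mismatches(self) -> int:
        return stem_mismatches(self.upstream_stem, self.downstream_stem)


def _data_path(name: str):
    return resources.files("plastcomp").joinpath("data", name)


def load_hairpin_records() -> list[HairpinRecord]:
    """The 24 published hairpin records."""
    with resources.as_file(_data_path("cassytha_hairpins.tsv")) as p:
        frame = pd.read_csv(p, sep="\t", dtype={"no": int, "size": int})
    return [
        HairpinRecord(r.no, r.location, r.loop_motif, r.size,
                      r.upstream_stem, r.downstream_stem)
        for r in frame.itertuples()
    ]


def load_divergence_matrix() -> DistanceMatrix:
    """The published 8x8 pairwise divergence matrix."""
    with resources.as_file(_data_path("cassytha_divergence.tsv")) as p:
        return DistanceMatrix.from_tsv(p)


def validate_hairpins(
    records: list[HairpinRecord] | None = None, max_mismatch: int = 0
) -> tuple[list[HairpinRecord], list[HairpinRecord]]:
    """Split hairpin records into (palindromic, non-palindromic) under a
    mismatch tolerance.  Records whose stems are not reverse complements
    are reported as-is, never silently corrected."""
    if records is None:
        records = load_hairpin_records()
    good = [r for r in records if r.n_stem_mismatches <= max_mismatch]
    bad = [r for r in records if r.n_stem_mismatches > max_mismatch]
    return good, bad
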