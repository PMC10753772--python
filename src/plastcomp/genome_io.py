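"""Plastome records and annotation I/O.

Sequences and features are held with 0-based, half-open coordinates on the
forward strand; the 1-based inclusive convention of GFF3 and GenBank is
converted exactly once, at the file boundary.  Circular genomes may carry
features that wrap the origin; such features are stored as multi-interval
locations (the same device used for introns).

By convention a circular plastome is linearized so that the first base of
*trnH-GUG* (when annotated) sits at position 0, mirroring how plastome
assemblies are conventionally rotated before comparison.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

NUCLEOTIDES = set("ACGTN")
FEATURE_TYPES = ("gene", "tRNA", "rRNA", "pseudogene", "intergenic")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


class GenomeIOError(ValueError):
    """Malformed input file or invalid record."""


def revcomp(s: str) -> str:
    """Reverse complement of a nucleotide string (A/C/G/T/N, case-insensitive).

    Output is uppercased.  Ambiguity codes other than N are rejected:
    comparative plastome work assumes fully resolved assemblies.
    """
    bad = set(s.upper()) - NUCLEOTIDES
    if bad:
        raise GenomeIOError(f"non-nucleotide characters in sequence: {sorted(bad)}")
    return s.upper().translate(_COMPLEMENT)[::-1]


@dataclasses.dataclass
class Feature:
    """A named, stranded annotation over one or more intervals.

    ``intervals`` is an ordered list of [start, end) pairs; more than one
    interval encodes either an intron-split gene or an origin-wrapping
    location on a circular genome.
    """

    name: str
    ftype: str
    strand: str
    intervals: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.ftype not in FEATURE_TYPES:
            raise GenomeIOError(f"unknown feature type {self.ftype!r}")
        if self.strand not in "+-":
            raise GenomeIOError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.intervals:
            raise GenomeIOError(f"feature {self.name}: no intervals")
        for start, end in self.intervals:
            if end <= start:
                raise GenomeIOError(
                    f"feature {self.name}: empty interval [{start}, {end})"
                )

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.intervals)

    def extract(self, seq: str) -> str:
        """Concatenated feature sequence, reverse-complemented for '-' strand."""
        parts = "".join(seq[s:e] for s, e in self.intervals)
        return revcomp(parts) if self.strand == "-" else parts


@dataclasses.dataclass
class GenomeRecord:
    """One plastome: sequence plus ordered features."""

    id: str
    seq: str
    circular: bool = True
    features: list[Feature] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if not self.seq:
            raise GenomeIOError(f"{self.id}: empty sequence")
        bad = set(self.seq) - NUCLEOTIDES
        if bad:
            raise GenomeIOError(f"{self.id}: invalid characters {sorted(bad)}")
        n = len(self.seq)
        for feat in self.features:
            for start, end in feat.intervals:
                if not (0 <= start < end <= n):
                    raise GenomeIOError(
                        f"{self.id}: feature {feat.name} interval [{start}, {end}) "
                        f"outside sequence of length {n}"
                    )

    def __len__(self) -> int:
        return len(self.seq)

    def feature_by_name(self, name: str) -> Feature | None:
        lowered = name.lower()
        for feat in self.features:
            if feat.name.lower() == lowered:
                return feat
        return None

    def gene_features(self) -> list[Feature]:
        """Features of functional gene categories, in genome order."""
        return sorted(
            (f for f in self.features if f.ftype in ("gene", "tRNA", "rRNA")),
            key=lambda f: f.start,
        )


def gc_content(rec: GenomeRecord | str) -> float:
    """GC fraction over unambiguous bases; N is excluded from the denominator."""
    seq = rec.seq if isinstance(rec, GenomeRecord) else rec.upper()
    acgt = sum(seq.count(b) for b in "ACGT")
    if acgt == 0:
        raise GenomeIOError("GC content undefined: no unambiguous bases")
    return (seq.count("G") + seq.count("C")) / acgt


def rotate_to_gene(rec: GenomeRecord, gene: str = "trnH-GUG") -> GenomeRecord:
    """Rotate a circular genome so that ``gene`` starts at position 0.

    Returns ``rec`` unchanged when the genome is linear or the gene is
    absent.  Features that come to straddle the new origin are split into
    two intervals.
    """
    feat = rec.feature_by_name(gene)
    if not rec.circular or feat is None or feat.start == 0:
        return rec
    shift = feat.start
    n = len(rec.seq)
    seq = rec.seq[shift:] + rec.seq[:shift]
    rotated: list[Feature] = []
    for f in rec.features:
        intervals: list[tuple[int, int]] = []
        for start, end in f.intervals:
            s, e = start - shift, end - shift
            if s < 0 and e <= 0:
                intervals.append((s + n, e + n))
            elif s < 0 < e:  # straddles the new origin
                intervals.append((s + n, n))
                intervals.append((0, e))
            else:
                intervals.append((s, e))
        rotated.append(Feature(f.name, f.ftype, f.strand, intervals))
    rotated.sort(key=lambda f: f.start)
    return GenomeRecord(rec.id, seq, rec.circular, rotated)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

def _write_gff3(rec: GenomeRecord, path: Path) -> None:
    lines = ["##gff-version 3", f"##sequence-region {rec.id} 1 {len(rec.seq)}"]
    for i, feat in enumerate(rec.features):
        fid = f"feat{i}"
        for start, end in feat.intervals:
            attrs = f"ID={fid};Name={feat.name};ftype={feat.ftype}"
            lines.append(
                "\t".join(
                    [
                        rec.id,
                        "plastcomp",
                        feat.ftype if feat.ftype != "intergenic" else "region",
                        str(start + 1),
                        str(end),
                        ".",
                        feat.strand,
                        ".",
                        attrs,
                    ]
                )
            )
    path.write_text("\n".join(lines) + "\n")


def _parse_gff3(path: Path) -> list[Feature]:
    # Grouped by ID so multi-line (origin-wrapping / intron) features are
    # reassembled into one multi-interval Feature.
    grouped: dict[str, dict] = {}
    order: list[str] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise GenomeIOError(f"{path}:{lineno}: expected 9 columns, got {len(cols)}")
        _, _, gtype, start, end, _, strand, _, attr_field = cols
        attrs = dict(
            kv.split("=", 1) for kv in attr_field.split(";") if "=" in kv
        )
        name = attrs.get("Name", attrs.get("ID", f"line{lineno}"))
        fid = attrs.get("ID", f"line{lineno}")
        ftype = attrs.get("ftype", gtype if gtype in FEATURE_TYPES else "gene")
        try:
            interval = (int(start) - 1, int(end))
        except ValueError as exc:
            raise GenomeIOError(f"{path}:{lineno}: bad coordinates") from exc
        if fid not in grouped:
            grouped[fid] = {"name": name, "ftype": ftype, "strand": strand, "iv": []}
            order.append(fid)
        grouped[fid]["iv"].append(interval)
    return [
        Feature(g["name"], g["ftype"], g["strand"], g["iv"])
        for g in (grouped[fid] for fid in order)
    ]


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_GB_TYPE = {"gene": "gene", "tRNA": "tRNA", "rRNA": "rRNA",
            "pseudogene": "gene", "intergenic": "misc_feature"}
_GB_TYPE_BACK = {"gene": "gene", "CDS": "gene", "tRNA": "tRNA", "rRNA": "rRNA",
                 "misc_feature": "intergenic"}


def _to_seqrecord(rec: GenomeRecord) -> SeqRecord:
    sr = SeqRecord(Seq(rec.seq), id=rec.id, name=rec.id[:16], description="")
    sr.annotations["molecule_type"] = "DNA"
    sr.annotations["topology"] = "circular" if rec.circular else "linear"
    for feat in rec.features:
        strand = 1 if feat.strand == "+" else -1
        parts = [SimpleLocation(s, e, strand) for s, e in feat.intervals]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        qualifiers = {"gene": [feat.name]}
        if feat.ftype == "pseudogene":
            qualifiers["pseudo"] = [""]
        sr.features.append(SeqFeature(loc, type=_GB_TYPE[feat.ftype], qualifiers=qualifiers))
    return sr


def _from_seqrecord(sr: SeqRecord) -> GenomeRecord:
    features: list[Feature] = []
    for sf in sr.features:
        if sf.type == "source":
            continue
        ftype = _GB_TYPE_BACK.get(sf.type)
        if ftype is None:
            continue
        if "pseudo" in sf.qualifiers or "pseudogene" in sf.qualifiers:
            ftype = "pseudogene"
        name = (sf.qualifiers.get("gene") or sf.qualifiers.get("Name") or ["?"])[0]
        strand = "-" if sf.location.strand == -1 else "+"
        intervals = [(int(p.start), int(p.end)) for p in sf.location.parts]
        features.append(Feature(name, ftype, strand, intervals))
    circular = sr.annotations.get("topology", "linear") == "circular"
    return GenomeRecord(sr.id, str(sr.seq), circular, features)


# ---------------------------------------------------------------------------
# Public I/O
# ---------------------------------------------------------------------------

def read_genome(
    path: str | Path,
    format: str = "genbank",
    gff: str | Path | None = None,
    normalize: bool = True,
) -> GenomeRecord:
    """Read an annotated plastome.

    Parameters
    ----------
    path:
        FASTA file (``format="fasta+gff3"``) or GenBank flat file
        (``format="genbank"``).
    gff:
        GFF3 annotation path.  Defaults to ``path`` with a ``.gff3`` suffix;
        a missing annotation file yields a feature-less record.
    normalize:
        Rotate circular genomes so trnH-GUG starts at position 0 when that
        gene is annotated (the conventional plastome linearization).
    """
    path = Path(path)
    if not path.exists():
        raise GenomeIOError(f"no such file: {path}")
    if format == "genbank":
        try:
            sr = next(SeqIO.parse(str(path), "genbank"))
        except (StopIteration, ValueError) as exc:
            raise GenomeIOError(f"{path}: cannot parse GenBank record: {exc}") from exc
        rec = _from_seqrecord(sr)
    elif format == "fasta+gff3":
        try:
            sr = next(SeqIO.parse(str(path), "fasta"))
        except (StopIteration, ValueError) as exc:
            raise GenomeIOError(f"{path}: cannot parse FASTA record: {exc}") from exc
        gff_path = Path(gff) if gff is not None else path.with_suffix(".gff3")
        features = _parse_gff3(gff_path) if gff_path.exists() else []
        rec = GenomeRecord(sr.id, str(sr.seq), True, features)
    else:
        raise GenomeIOError(f"unknown format {format!r}")
    return rotate_to_gene(rec) if normalize else rec


def write_genome(rec: GenomeRecord, path: str | Path, format: str = "genbank") -> None:
    """Write a plastome as GenBank or FASTA+GFF3 (GFF3 beside the FASTA)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "genbank":
        SeqIO.write([_to_seqrecord(rec)], str(path), "genbank")
    elif format == "fasta+gff3":
        with open(path, "w") as fh:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), 70):
                fh.write(rec.seq[i : i + 70] + "\n")
        _write_gff3(rec, path.with_suffix(".gff3"))
    else:
        raise GenomeIOError(f"unknown format {format!r}")


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write (label, sequence) pairs as FASTA; gaps are preserved."""
    with open(path, "w") as fh:
        for label, seq in records:
            fh.write(f">{label}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read (label, sequence) pairs from FASTA, sequences uppercased."""
    return [(sr.id, str(sr.seq).upper()) for sr in SeqIO.parse(str(path), "fasta")]
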