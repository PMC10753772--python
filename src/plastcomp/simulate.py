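"""Synthetic plastome generator with a machine-readable truth ledger.

Emulates the study design this package targets: a quadripartite ancestor
(LSC + IRa + SSC + IRb, IRb = revcomp(IRa)) from which two species x four
individuals are derived.  Planted events:

* substitutions at two levels — a species-stem set shared by every
  individual of a species, and individual-private sets — so that
  between-species divergence exceeds within-species divergence the way a
  two-species plastome panel shows;
* SSR indels (inside planted tandem repeats) and non-SSR indels, realized
  as gap patterns in the emitted truth alignment;
* micro-inversions: a loop carried in reverse-complement orientation by a
  subset of individuals, flanked by an exact inverted-repeat stem pair;
* one divergence hotspot: a dense block of species-diagnostic
  substitutions inside a named intergenic spacer;
* structural reduction applied to *all* individuals (as in a genus-wide
  reduction): loss of one IR copy, deletion of multi-gene segments, and
  truncation of ndh genes to pseudogenes.

Identifiability conventions (documented in the methods note): point events
live in the single-copy regions, each indel/inversion in its own spacer;
substitutions keep a minimum spacing and never create stop codons inside
genes, so pseudogene calls on the output reflect planted edits only.

Every random draw comes from one seeded generator; identical configs give
byte-identical output.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import yaml

from .alignment import Alignment
from .genome_io import Feature, GenomeRecord, revcomp
from .variants import ssr_motif

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# ndh reference lengths follow a quadripartite Lauraceae reference plastome
# for the five genes whose pseudogenized lengths are also published; the
# remaining six are scaled-down stand-ins.
_NDH_LENGTHS = {
    "ndhB": 2181, "ndhD": 1509, "ndhE": 306, "ndhF": 2229, "ndhH": 1182,
    "ndhA": 600, "ndhC": 300, "ndhG": 300, "ndhI": 300, "ndhJ": 300, "ndhK": 300,
}

_TRNA_NAMES = [
    "trnH-GUG", "trnK-UUU", "trnQ-UUG", "trnS-GCU", "trnG-UCC", "trnR-UCU",
    "trnC-GCA", "trnD-GUC", "trnY-GUA", "trnE-UUC", "trnT-GGU", "trnS-UGA",
    "trnG-GCC", "trnfM-CAU", "trnS-GGA", "trnT-UGU", "trnL-UAA", "trnF-GAA",
    "trnV-UAC", "trnM-CAU", "trnW-CCA", "trnP-UGG", "trnI-CAU", "trnL-CAA",
    "trnV-GAC", "trnI-GAU", "trnA-UGC", "trnR-ACG", "trnN-GUU", "trnL-UAG",
]

_CDS_POOL = [
    "matK", "rps16", "psbI", "atpA", "atpF", "atpH", "atpI", "rps2",
    "rpoC2", "rpoC1", "rpoB", "petN", "psbM", "psbD", "psbC", "psbZ", "rps14",
    "psaB", "psaA", "pafI", "rps4", "psaI", "ycf4", "cemA", "petA", "psbJ",
    "psbL", "psbF", "psbE", "petL", "petG", "psaJ", "rpl33", "rps18", "rpl20",
    "rps12", "clpP", "psbB", "psbT", "psbN", "psbH", "petB", "petD", "rpoA",
    "rps11", "rpl36", "infA", "rps8", "rpl14", "rpl16", "rps3", "rpl22",
    "rps19", "rpl23", "pafII", "accD", "rbcL", "ccsA", "psaC", "rpl32",
    "rps7", "rps15", "ycf1", "pbf1",
]

_RRNA = [("rrn16", 400), ("rrn23", 500), ("rrn4.5", 103), ("rrn5", 121)]

DEFAULT_STRUCTURAL_EDITS = [
    {"op": "delete_ir_copy"},
    {"op": "delete_segment", "genes": ["ndhC", "ndhJ", "ndhK"]},
    {"op": "delete_segment", "genes": ["ndhA", "ndhG", "ndhI"]},
    {"op": "truncate_gene", "gene": "ndhB", "keep_bp": 1191},
    {"op": "truncate_gene", "gene": "ndhD", "keep_bp": 428},
    {"op": "truncate_gene", "gene": "ndhE", "keep_bp": 159},
    {"op": "truncate_gene", "gene": "ndhF", "keep_bp": 302},
    {"op": "truncate_gene", "gene": "ndhH", "keep_bp": 547},
]


class SimulationError(ValueError):
    pass


@dataclasses.dataclass
class SimConfig:
    """Generator configuration.

    Default point-event counts are the published genome-wide mutation
    spectrum of the two-species plastome panel (195 SSR indels, 54 non-SSR
    indels, 24 micro-inversions over ~114.6 kb) scaled to the default
    30 kb test genome; divergence rates sit at the published within- and
    between-species p-distance scales.
    """

    seed: int = 0
    genome_length: int = 30_000
    ir_length: int = 4_000
    n_species: int = 2
    n_individuals_per_species: int = 4
    subst_rate_within: float = 5e-4
    subst_rate_between: float = 5.7e-3
    n_ssr_indels: int = 51
    n_nonssr_indels: int = 14
    n_inversions: int = 6
    inversion_loop_range: tuple[int, int] = (2, 46)
    stem_length_range: tuple[int, int] = (3, 23)
    hotspot_snps: int = 25
    n_filler_cds: int | None = None  # None: fill the LSC automatically
    structural_edits: list[dict] = dataclasses.field(
        default_factory=lambda: [dict(e) for e in DEFAULT_STRUCTURAL_EDITS]
    )

    def validate(self) -> None:
        if not (0 <= self.subst_rate_within < 1 and 0 <= self.subst_rate_between < 1):
            raise SimulationError("substitution rates must lie in [0, 1)")
        if self.ir_length * 2 >= self.genome_length:
            raise SimulationError("ir_length * 2 must be < genome_length")
        for name in ("inversion_loop_range", "stem_length_range"):
            lo, hi = getattr(self, name)
            if not (1 <= lo <= hi):
                raise SimulationError(f"{name} is empty or invalid")
        if min(self.n_species, self.n_individuals_per_species) < 1:
            raise SimulationError("need at least one species and one individual")
        for n in (self.n_ssr_indels, self.n_nonssr_indels, self.n_inversions,
                  self.hotspot_snps):
            if n < 0:
                raise SimulationError("event counts must be non-negative")

    # -- YAML round trip ---------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        data = dataclasses.asdict(self)
        data["inversion_loop_range"] = list(self.inversion_loop_range)
        data["stem_length_range"] = list(self.stem_length_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("inversion_loop_range", "stem_length_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


# ---------------------------------------------------------------------------
# Truth ledger
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PlantedSubstitution:
    ancestor_pos: int
    aligned_col: int
    ref_base: str
    alt_base: str
    carriers: tuple[str, ...]


@dataclasses.dataclass
class PlantedIndel:
    ancestor_start: int
    ancestor_end: int
    aligned_start: int
    aligned_end: int
    fragment: str
    ssr_class: str  # intended class
    motif: str | None
    bearers: tuple[str, ...]


@dataclasses.dataclass
class PlantedInversion:
    ancestor_start: int
    ancestor_end: int
    aligned_start: int
    aligned_end: int
    loop: str
    stem: str
    stem_length: int
    carriers: tuple[str, ...]
    location_label: str


@dataclasses.dataclass
class TruthTable:
    species_of: dict[str, str]  # individual label -> species label
    substitutions: list[PlantedSubstitution]
    indels: list[PlantedIndel]
    inversions: list[PlantedInversion]
    hotspot: dict | None  # {"aligned_start", "aligned_end", "label", ...}
    structural_edits: list[dict]

    @property
    def n_substitutions(self) -> int:
        return len(self.substitutions)

    @property
    def n_indels(self) -> int:
        return len(self.indels)

    @property
    def n_inversions(self) -> int:
        return len(self.inversions)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")


# ---------------------------------------------------------------------------
# Layout plan
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class _Item:
    kind: str  # gene | tRNA | rRNA | spacer | event_spacer | hotspot_spacer
    name: str
    length: int
    strand: str = "+"
    event_index: int | None = None  # for event spacers


# base weights giving the ~37% GC typical of plastomes
_BASE_P = np.array([0.315, 0.185, 0.185, 0.315])
_SENSE = [a + b + c for a in _BASES for b in _BASES for c in _BASES
          if a + b + c not in _STOPS]
_SENSE_P = np.array(
    [np.prod([_BASE_P["ACGT".index(ch)] for ch in codon]) for codon in _SENSE]
)
_SENSE_P /= _SENSE_P.sum()


def _orf(rng: np.random.Generator, length: int) -> str:
    """Random open reading frame of ``length`` bp (start, no internal stop,
    terminal stop) under the plastid/bacterial code."""
    if length % 3:
        raise SimulationError(f"ORF length {length} not a codon multiple")
    n_codon = length // 3 - 2
    idx = rng.choice(len(_SENSE), size=max(n_codon, 0), p=_SENSE_P)
    return "ATG" + "".join(_SENSE[i] for i in idx) + "TAA"


def _rand_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[i] for i in rng.choice(4, size=length, p=_BASE_P))


@dataclasses.dataclass
class _EventSlot:
    etype: str  # "inversion" | "ssr" | "nonssr"
    payload: dict
    width: int
    # ancestor coordinates, filled in during assembly
    start: int = -1


def _draw_inversion(rng: np.random.Generator, cfg: SimConfig) -> dict:
    lo_l, hi_l = cfg.inversion_loop_range
    lo_s, hi_s = cfg.stem_length_range
    for _ in range(1000):
        loop_len = int(rng.integers(lo_l, hi_l + 1))
        stem_len = int(rng.integers(lo_s, hi_s + 1))
        loop = _rand_seq(rng, loop_len)
        if loop == revcomp(loop):
            continue
        if loop[0] == _COMP[loop[-1]]:
            continue  # inverted loop must mismatch at both ends
        stem = _rand_seq(rng, stem_len)
        # constructive validation: the loop (and only the loop) must be
        # recoverable from the hairpin context by the inversion scanner
        from .alignment import Alignment as _A
        from .inversions import _pair_calls

        pad = _rand_seq(rng, 4)
        pad2 = _rand_seq(rng, 4)
        plain = pad + stem + loop + revcomp(stem) + pad2
        flipped = pad + stem + revcomp(loop) + revcomp(stem) + pad2
        mini = _A(["a", "b"], [plain, flipped])
        calls = _pair_calls(mini.matrix[0], mini.matrix[1], 2,
                            cfg.inversion_loop_range[1])
        want = (len(pad) + stem_len, len(pad) + stem_len + loop_len)
        if calls == [want]:
            return {"loop": loop, "stem": stem}
    raise SimulationError("could not place a valid inversion after 1000 tries")


def _draw_ssr(rng: np.random.Generator) -> dict:
    mlen = int(rng.choice([1, 1, 1, 2, 3]))
    if mlen == 1:
        k = int(rng.integers(8, 15))
    elif mlen == 2:
        k = int(rng.integers(4, 7))
    else:
        k = int(rng.integers(3, 5))
    motif = _rand_seq(rng, mlen)
    d = int(rng.integers(1, min(3, k)))  # copies deleted, at least one kept
    return {"motif": motif, "copies": k, "deleted_copies": d}


def _draw_nonssr(rng: np.random.Generator) -> dict:
    length = int(rng.integers(2, 11))
    return {"fragment": _rand_seq(rng, length)}


def _build_plan(cfg: SimConfig):
    """Deterministic ancestor layout + event slots from cfg.seed."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    # --- event geometry drawn first so spacers can be sized exactly
    slots: list[_EventSlot] = []
    for _ in range(cfg.n_inversions):
        payload = _draw_inversion(rng, cfg)
        width = 2 * len(payload["stem"]) + len(payload["loop"]) + 12
        slots.append(_EventSlot("inversion", payload, width))
    for _ in range(cfg.n_ssr_indels):
        payload = _draw_ssr(rng)
        width = len(payload["motif"]) * payload["copies"] + 12
        slots.append(_EventSlot("ssr", payload, width))
    for _ in range(cfg.n_nonssr_indels):
        payload = _draw_nonssr(rng)
        slots.append(_EventSlot("nonssr", payload, len(payload["fragment"]) + 12))

    # --- fixed gene content
    ira_items = [
        _Item("gene", "rpl2", 825),
        *[_Item("rRNA", n, L) for n, L in _RRNA],
        _Item("gene", "ycf2", 1500),
    ]
    # the ndhA/G/I block sits between retained genes so that a planted
    # segment deletion stays bounded by shared flanking genes
    ssc_gene_items = [
        _Item("gene", "ndhF", _NDH_LENGTHS["ndhF"]),
        _Item("gene", "ndhD", _NDH_LENGTHS["ndhD"]),
        _Item("gene", "ndhE", _NDH_LENGTHS["ndhE"]),
        _Item("gene", "ndhA", _NDH_LENGTHS["ndhA"]),
        _Item("gene", "ndhG", _NDH_LENGTHS["ndhG"]),
        _Item("gene", "ndhI", _NDH_LENGTHS["ndhI"]),
        _Item("gene", "ndhH", _NDH_LENGTHS["ndhH"]),
    ]
    lsc_required: list[list[_Item]] = [
        [_Item("gene", "ndhB", _NDH_LENGTHS["ndhB"])],
        [
            _Item("tRNA", "trnQ-UUG", 75),
            _Item("hotspot_spacer", "hotspot", 700),
            _Item("gene", "psbK", 180),
        ],
    ]
    # trnH opens the LSC and trnQ flanks the hotspot; the rest are swept in here
    lsc_required += [
        [_Item("tRNA", n, 75)]
        for n in _TRNA_NAMES
        if n not in ("trnH-GUG", "trnQ-UUG")
    ]
    lsc_required += [
        [_Item("event_spacer", f"event{i}", slot.width, event_index=i)]
        for i, slot in enumerate(slots)
    ]

    min_spacer = 12
    ira_len_content = sum(i.length for i in ira_items)
    if ira_len_content + (len(ira_items) + 1) * min_spacer > cfg.ir_length:
        raise SimulationError("ir_length too small for the IR gene set")
    ssc_content = sum(i.length for i in ssc_gene_items)
    ssc_len = ssc_content + (len(ssc_gene_items) + 1) * 30
    lsc_len = cfg.genome_length - 2 * cfg.ir_length - ssc_len
    if lsc_len <= 0:
        raise SimulationError("genome_length too small for IR + SSC content")

    # --- filler protein-coding genes to populate the LSC
    fixed_width = 75 + 3 * _NDH_LENGTHS["ndhC"] + 240  # trnH + ndhC/J/K + psbA
    required_width = fixed_width + sum(
        sum(i.length for i in blk) for blk in lsc_required
    )
    filler_lengths: list[int] = []
    pool = list(_CDS_POOL)

    def gaps_needed(n_filler: int) -> int:
        n_items = 5 + sum(len(b) for b in lsc_required) + n_filler
        return (n_items + 1) * min_spacer

    if cfg.n_filler_cds is None:
        n_filler = 0
        while True:
            length = int(rng.integers(30, 51)) * 3
            if (required_width + sum(filler_lengths) + length
                    + gaps_needed(n_filler + 1) > lsc_len):
                break
            filler_lengths.append(length)
            n_filler += 1
    else:
        n_filler = cfg.n_filler_cds
        filler_lengths = [int(rng.integers(30, 51)) * 3 for _ in range(n_filler)]
        if required_width + sum(filler_lengths) + gaps_needed(n_filler) > lsc_len:
            raise SimulationError(
                f"genome_length too small for {n_filler} filler genes"
            )
    filler_items = []
    for i, L in enumerate(filler_lengths):
        name = pool[i] if i < len(pool) else f"orf{i + 1}"
        filler_items.append([_Item("gene", name, L)])

    blocks = lsc_required + filler_items
    order = rng.permutation(len(blocks))
    # the deletable ndhC/J/K block sits between two fixed genes (trnH, psbA)
    # so a planted segment deletion never swallows an event spacer
    lsc_items: list[_Item] = [
        _Item("tRNA", "trnH-GUG", 75),
        _Item("gene", "ndhC", _NDH_LENGTHS["ndhC"]),
        _Item("gene", "ndhJ", _NDH_LENGTHS["ndhJ"]),
        _Item("gene", "ndhK", _NDH_LENGTHS["ndhK"]),
        _Item("gene", "psbA", 240),
    ]
    for bi in order:
        lsc_items.extend(blocks[bi])

    # strands: random per gene, trnH kept on '+'
    for item in lsc_items[1:] + ssc_gene_items + ira_items:
        if item.kind in ("gene", "tRNA", "rRNA"):
            item.strand = "+" if rng.random() < 0.5 else "-"

    # --- interleave spacers to consume the region lengths exactly
    def layout(items: list[_Item], region_len: int, first_gap_zero: bool = False) -> list[_Item]:
        content = sum(i.length for i in items)
        # one gap after every item (plus a leading gap unless the region
        # opens with a gene, i.e. the trnH-GUG linearization point)
        n_gaps = len(items) if first_gap_zero else len(items) + 1
        budget = region_len - content - n_gaps * min_spacer
        if budget < 0:
            raise SimulationError("region too small during layout")
        shares = rng.multinomial(budget, np.full(n_gaps, 1 / n_gaps))
        out: list[_Item] = []
        g = 0
        for i, item in enumerate(items):
            if not (i == 0 and first_gap_zero):
                out.append(_Item("spacer", f"sp{i}", min_spacer + int(shares[g])))
                g += 1
            out.append(item)
        out.append(_Item("spacer", "spEnd", min_spacer + int(shares[g])))
        return out

    lsc = layout(lsc_items, lsc_len, first_gap_zero=True)
    ira = layout(ira_items, cfg.ir_length)
    ssc = layout(ssc_gene_items, ssc_len)
    return rng, slots, lsc, ira, ssc


def _assemble(cfg: SimConfig):
    """Build the ancestor sequence, features, and located event slots."""
    rng, slots, lsc, ira, ssc = _build_plan(cfg)
    seq_parts: list[str] = []
    features: list[Feature] = []
    pos = 0

    def emit(item: _Item) -> None:
        nonlocal pos
        if item.kind == "gene":
            body = _orf(rng, item.length)
            if item.strand == "-":
                body = revcomp(body)
            features.append(Feature(item.name, "gene", item.strand,
                                    [(pos, pos + item.length)]))
        elif item.kind in ("tRNA", "rRNA"):
            body = _rand_seq(rng, item.length)
            features.append(Feature(item.name, item.kind, item.strand,
                                    [(pos, pos + item.length)]))
        elif item.kind == "event_spacer":
            slot = slots[item.event_index]
            slot.start = pos
            pad = (item.length - slot.width) // 2
            if slot.etype == "inversion":
                loop, stem = slot.payload["loop"], slot.payload["stem"]
                inner = stem + loop + revcomp(stem)
                left = _rand_seq(rng, 6 + pad)
                right = _rand_seq(rng, item.length - len(inner) - len(left))
                body = left + inner + right
                slot.payload["loop_start"] = pos + len(left) + len(stem)
            elif slot.etype == "ssr":
                motif, k = slot.payload["motif"], slot.payload["copies"]
                run = motif * k
                left = _rand_seq(rng, 6 + pad)
                right = _rand_seq(rng, item.length - len(run) - len(left))
                body = left + run + right
                slot.payload["run_start"] = pos + len(left)
            else:  # nonssr
                frag = slot.payload["fragment"]
                left = _rand_seq(rng, 6 + pad)
                right = _rand_seq(rng, item.length - len(frag) - len(left))
                body = left + frag + right
                slot.payload["frag_start"] = pos + len(left)
        else:  # spacer / hotspot_spacer
            body = _rand_seq(rng, item.length)
            if item.kind == "hotspot_spacer":
                slot_marker = {"start": pos, "end": pos + item.length}
                features_extra.append(slot_marker)
        seq_parts.append(body)
        pos += item.length

    features_extra: list[dict] = []  # hotspot interval marker
    for item in lsc:
        emit(item)
    lsc_end = pos
    for item in ira:
        emit(item)
    ira_interval = (lsc_end, pos)
    ssc_start = pos
    for item in ssc:
        emit(item)
    ssc_end = pos

    seq = "".join(seq_parts)
    # block IR extension across the SSC boundaries so the planted IR
    # intervals are exactly recoverable
    seq = seq[:ssc_start] + "A" + seq[ssc_start + 1 :]
    seq = seq[: ssc_end - 1] + "A" + seq[ssc_end:]
    ira_seq = seq[ira_interval[0] : ira_interval[1]]
    seq = seq + revcomp(ira_seq)
    irb_interval = (ssc_end, ssc_end + cfg.ir_length)
    if len(seq) != cfg.genome_length:
        raise SimulationError("layout did not reach the configured genome length")

    ancestor = GenomeRecord("ancestor", seq, circular=True, features=features)
    hotspot = features_extra[0] if features_extra else None
    regions = {"ira": ira_interval, "irb": irb_interval,
               "ssc": (ssc_start, ssc_end), "hotspot": hotspot}
    return rng, ancestor, slots, regions


def make_ancestor(cfg: SimConfig) -> GenomeRecord:
    """Quadripartite ancestor plastome for ``cfg`` (deterministic in seed)."""
    _, ancestor, _, _ = _assemble(cfg)
    return ancestor


# ---------------------------------------------------------------------------
# Evolution
# ---------------------------------------------------------------------------

def _individual_labels(cfg: SimConfig) -> tuple[list[str], dict[str, str]]:
    labels, species_of = [], {}
    for s in range(cfg.n_species):
        sp = chr(ord("A") + s)
        for k in range(cfg.n_individuals_per_species):
            lab = f"{sp}{k + 1}"
            labels.append(lab)
            species_of[lab] = f"species{sp}"
    return labels, species_of


def _codon_interval(feat: Feature, p: int) -> tuple[int, int, int]:
    """(codon_start, codon_end, offset of p) in genome coordinates for a
    single-interval gene feature containing p."""
    s, e = feat.intervals[0]
    if feat.strand == "+":
        off = (p - s) % 3
        c0 = p - off
        return c0, c0 + 3, off
    off = (e - 1 - p) % 3
    c_end = p + off + 1
    return c_end - 3, c_end, off


def _creates_stop(seq: list[str], feat: Feature, p: int, new_base: str) -> bool:
    c0, c1, _ = _codon_interval(feat, p)
    codon = "".join(seq[c0:c1])
    codon = codon[: p - c0] + new_base + codon[p - c0 + 1 :]
    if feat.strand == "-":
        codon = revcomp(codon)
    return codon in _STOPS


def simulate(cfg: SimConfig):
    """Run the full generator.

    Returns ``(ancestor, individuals, alignment, truth)`` where the
    alignment is the truth alignment over the individuals (degapping row i
    reproduces individual i exactly) and ``truth`` is the planted-event
    ledger with ancestor and aligned coordinates.
    """
    rng, ancestor, slots, regions = _assemble(cfg)
    n = len(ancestor.seq)
    labels, species_of = _individual_labels(cfg)
    species = sorted(set(species_of.values()))
    members = {sp: [lab for lab in labels if species_of[lab] == sp] for sp in species}
    reference = labels[0]

    # --- structural edit intervals (deleted from every individual)
    feats_by_name = {f.name.lower(): f for f in ancestor.features}
    genes_sorted = sorted(ancestor.features, key=lambda f: f.start)
    struct_intervals: list[tuple[int, int]] = []
    truncations: list[dict] = []
    edits_echo: list[dict] = []
    for edit in cfg.structural_edits:
        op = edit["op"]
        if op == "delete_ir_copy":
            struct_intervals.append(regions["irb"])
            edits_echo.append({"op": op, "interval": list(regions["irb"])})
        elif op == "delete_segment":
            names = [g.lower() for g in edit["genes"]]
            block = [feats_by_name[g] for g in names]
            first = min(block, key=lambda f: f.start)
            last = max(block, key=lambda f: f.end)
            retained = [f for f in genes_sorted if f.name.lower() not in names]
            prev_c = [f for f in retained if f.end <= first.start]
            next_c = [f for f in retained if f.start >= last.end]
            if not prev_c or not next_c:
                raise SimulationError(
                    f"delete_segment {edit['genes']} not bounded by retained genes"
                )
            prev = max(prev_c, key=lambda f: f.end)
            nxt = min(next_c, key=lambda f: f.start)
            interval = (prev.end, nxt.start)
            struct_intervals.append(interval)
            edits_echo.append({"op": op, "genes": edit["genes"],
                               "interval": list(interval),
                               "flanks": [prev.name, nxt.name]})
        elif op == "truncate_gene":
            feat = feats_by_name[edit["gene"].lower()]
            keep = int(edit["keep_bp"])
            if not (0 < keep < feat.length):
                raise SimulationError(f"bad keep_bp for {edit['gene']}")
            s, e = feat.intervals[0]
            tail = (s + keep, e) if feat.strand == "+" else (s, e - keep)
            struct_intervals.append(tail)
            truncations.append({"gene": feat.name, "keep_bp": keep})
            edits_echo.append({"op": op, "gene": feat.name, "keep_bp": keep,
                               "interval": list(tail)})
        else:
            raise SimulationError(f"unknown structural edit {op!r}")
    struct_intervals.sort()
    for (s1, e1), (s2, e2) in zip(struct_intervals, struct_intervals[1:]):
        if s2 < e1:
            raise SimulationError("overlapping structural edits")
    for slot in slots:
        for s, e in struct_intervals:
            if slot.start < e and s < slot.start + slot.width:
                raise SimulationError(
                    f"structural edit [{s}, {e}) overlaps a planted "
                    f"{slot.etype} event"
                )

    # --- placement bookkeeping
    blocked = np.zeros(n, dtype=bool)
    blocked[regions["ira"][0] : regions["ira"][1]] = True
    blocked[regions["irb"][0] : regions["irb"][1]] = True
    for s, e in struct_intervals:
        blocked[max(0, s - 2) : min(n, e + 2)] = True
    for slot in slots:
        blocked[max(0, slot.start - 2) : slot.start + slot.width + 2] = True

    seq_list = list(ancestor.seq)
    pos_to_gene: dict[int, Feature] = {}
    for f in ancestor.features:
        if f.ftype == "gene":
            for s, e in f.intervals:
                for p in range(s, e):
                    pos_to_gene[p] = f

    def place_substitution(positions_blocked: np.ndarray, zone: tuple[int, int] | None,
                           carriers: tuple[str, ...]) -> PlantedSubstitution | None:
        lo, hi = zone if zone else (0, n)
        for _ in range(200):
            p = int(rng.integers(lo, hi))
            if positions_blocked[p]:
                continue
            ref = seq_list[p]
            alts = [b for b in _BASES if b != ref]
            rng.shuffle(alts)
            feat = pos_to_gene.get(p)
            alt = None
            for cand in alts:
                if feat is not None and _creates_stop(seq_list, feat, p, cand):
                    continue
                alt = cand
                break
            if alt is None:
                continue
            positions_blocked[max(0, p - 3) : min(n, p + 4)] = True
            if feat is not None:
                c0, c1, _ = _codon_interval(feat, p)
                positions_blocked[max(0, c0) : min(n, c1)] = True
            return PlantedSubstitution(p, -1, ref, alt, carriers)
        return None

    # --- substitutions: species stems + private sets (+ hotspot block)
    retained = n - sum(e - s for s, e in struct_intervals)
    stem_rate = max(0.0, (cfg.subst_rate_between - cfg.subst_rate_within) / 2)
    priv_rate = cfg.subst_rate_within / 2
    substitutions: list[PlantedSubstitution] = []
    for sp in species:
        carriers = tuple(members[sp])
        n_stem = int(rng.binomial(retained, stem_rate))
        for _ in range(n_stem):
            sub = place_substitution(blocked, None, carriers)
            if sub is None:
                raise SimulationError("could not place a species-stem substitution")
            substitutions.append(sub)
    for lab in labels:
        n_priv = int(rng.binomial(retained, priv_rate))
        for _ in range(n_priv):
            sub = place_substitution(blocked, None, (lab,))
            if sub is None:
                raise SimulationError("could not place a private substitution")
            substitutions.append(sub)
    hotspot_truth = None
    sub_zone: dict[int, tuple[int, int] | None] = {}
    if regions["hotspot"] and cfg.hotspot_snps and cfg.n_species >= 2:
        zone = (regions["hotspot"]["start"], regions["hotspot"]["end"])
        carriers = tuple(members[species[1]])
        for _ in range(cfg.hotspot_snps):
            sub = place_substitution(blocked, zone, carriers)
            if sub is None:
                raise SimulationError("could not place a hotspot substitution")
            substitutions.append(sub)
            sub_zone[id(sub)] = zone
        hotspot_truth = {"ancestor_start": zone[0], "ancestor_end": zone[1]}

    # --- realize rows --------------------------------------------------
    base = np.frombuffer("".join(seq_list).encode(), dtype=np.uint8).copy()
    gap = ord("-")
    rows = {lab: base.copy() for lab in labels}
    for sub in substitutions:
        for lab in sub.carriers:
            rows[lab][sub.ancestor_pos] = ord(sub.alt_base)

    # substitutions whose bases happen to frame a self-reverse-complementary
    # stretch would be indistinguishable from a planted micro-inversion; the
    # ledger must stay unambiguous, so such placements are redrawn
    from .inversions import _pair_calls

    lo_inv, hi_inv = cfg.inversion_loop_range
    for _ in range(50):
        spurious: list[tuple[int, int]] = []
        for lab in labels[1:]:
            spurious += _pair_calls(rows[reference], rows[lab], 2, hi_inv)
        if not spurious:
            break
        for i, sub in enumerate(substitutions):
            if any(s <= sub.ancestor_pos < e for s, e in spurious):
                for lab in sub.carriers:
                    rows[lab][sub.ancestor_pos] = ord(sub.ref_base)
                redo = place_substitution(
                    blocked, sub_zone.get(id(sub)), sub.carriers
                )
                if redo is None:
                    raise SimulationError(
                        "could not re-place an ambiguous substitution")
                sub_zone[id(redo)] = sub_zone.pop(id(sub), None)
                substitutions[i] = redo
                for lab in redo.carriers:
                    rows[lab][redo.ancestor_pos] = ord(redo.alt_base)
    else:
        raise SimulationError(
            "substitution placement kept mimicking an inversion")
    substitutions.sort(key=lambda s: s.ancestor_pos)

    def pick_carriers(exclude_reference: bool) -> tuple[str, ...]:
        if cfg.n_species >= 2 and rng.random() < 0.5:
            pool = species[1:] if exclude_reference else species
            sp = pool[int(rng.integers(0, len(pool)))]
            return tuple(members[sp])
        pool_ind = [lab for lab in labels if not (exclude_reference and lab == reference)]
        return (pool_ind[int(rng.integers(0, len(pool_ind)))],)

    indel_truth: list[PlantedIndel] = []
    inversion_truth: list[PlantedInversion] = []
    for slot in slots:
        if slot.etype == "inversion":
            loop = slot.payload["loop"]
            s = slot.payload["loop_start"]
            e = s + len(loop)
            carriers = pick_carriers(exclude_reference=True)
            flipped = np.frombuffer(revcomp(loop).encode(), dtype=np.uint8)
            for lab in carriers:
                rows[lab][s:e] = flipped
            inversion_truth.append(
                PlantedInversion(s, e, -1, -1, loop, slot.payload["stem"],
                                 len(slot.payload["stem"]), carriers,
                                 location_label="")
            )
        elif slot.etype == "ssr":
            motif = slot.payload["motif"]
            d = slot.payload["deleted_copies"]
            s = slot.payload["run_start"]
            e = s + d * len(motif)
            bearers = pick_carriers(exclude_reference=False)
            for lab in bearers:
                rows[lab][s:e] = gap
            fragment = ancestor.seq[s:e]
            indel_truth.append(
                PlantedIndel(s, e, -1, -1, fragment, "SSR", motif, tuple(sorted(bearers)))
            )
        else:
            frag = slot.payload["fragment"]
            s = slot.payload["frag_start"]
            e = s + len(frag)
            left = ancestor.seq[max(0, s - 64) : s]
            right = ancestor.seq[e : e + 64]
            if ssr_motif(frag, left, right) is not None:
                # rare: the random fragment happens to sit in repeat context;
                # mutate its first base away from the context until clean
                for b in _BASES:
                    cand = b + frag[1:]
                    if cand != frag and ssr_motif(cand, left, right) is None:
                        frag = cand
                        base[s] = ord(b)
                        for lab in labels:
                            rows[lab][s] = ord(b)
                        ancestor = GenomeRecord(
                            ancestor.id,
                            ancestor.seq[:s] + b + ancestor.seq[s + 1 :],
                            True, ancestor.features,
                        )
                        break
                else:
                    raise SimulationError("could not realize a non-SSR indel")
            bearers = pick_carriers(exclude_reference=False)
            for lab in bearers:
                rows[lab][s:e] = gap
            indel_truth.append(
                PlantedIndel(s, e, -1, -1, frag, "non-SSR", None, tuple(sorted(bearers)))
            )

    # --- structural deletions (all individuals), then drop the columns
    keep_col = np.ones(n, dtype=bool)
    for s, e in struct_intervals:
        keep_col[s:e] = False
    aligned_index = np.cumsum(keep_col) - keep_col.astype(int)  # ancestor -> aligned

    row_strings = []
    for lab in labels:
        row_strings.append(rows[lab][keep_col].tobytes().decode())
    alignment = Alignment(labels, row_strings)

    # aligned coordinates into the truth ledger
    for sub in substitutions:
        sub.aligned_col = int(aligned_index[sub.ancestor_pos])
    for ev in indel_truth:
        ev.aligned_start = int(aligned_index[ev.ancestor_start])
        ev.aligned_end = int(aligned_index[ev.ancestor_end - 1]) + 1
    for inv in inversion_truth:
        inv.aligned_start = int(aligned_index[inv.ancestor_start])
        inv.aligned_end = int(aligned_index[inv.ancestor_end - 1]) + 1
        from .inversions import label_location

        inv.location_label = label_location(
            (inv.ancestor_start, inv.ancestor_end), ancestor.features
        )
    if hotspot_truth is not None:
        hotspot_truth["aligned_start"] = int(aligned_index[hotspot_truth["ancestor_start"]])
        hotspot_truth["aligned_end"] = int(
            aligned_index[hotspot_truth["ancestor_end"] - 1]
        ) + 1
        from .inversions import label_location

        mid = (hotspot_truth["ancestor_start"] + hotspot_truth["ancestor_end"]) // 2
        hotspot_truth["label"] = label_location((mid, mid + 1), ancestor.features)

    # --- per-individual genome records with remapped annotations
    truncated_names = {t["gene"].lower() for t in truncations}
    individuals: list[GenomeRecord] = []
    for lab in labels:
        keep_row = rows[lab] != gap
        keep_row &= keep_col
        pos_map = np.cumsum(keep_row) - keep_row.astype(int)
        feats: list[Feature] = []
        for f in ancestor.features:
            new_intervals = []
            observed = 0
            for s, e in f.intervals:
                kept = int(keep_row[s:e].sum())
                if kept == 0:
                    continue
                first = s + int(np.argmax(keep_row[s:e]))
                new_s = int(pos_map[first])
                new_intervals.append((new_s, new_s + kept))
                observed += kept
            if not new_intervals:
                continue
            ftype = f.ftype
            if f.ftype == "gene" and f.name.lower() in truncated_names:
                ftype = "pseudogene"
            feats.append(Feature(f.name, ftype, f.strand, new_intervals))
        seq_i = rows[lab][keep_row].tobytes().decode()
        individuals.append(GenomeRecord(lab, seq_i, circular=True, features=feats))

    truth = TruthTable(
        species_of=species_of,
        substitutions=substitutions,
        indels=indel_truth,
        inversions=inversion_truth,
        hotspot=hotspot_truth,
        structural_edits=edits_echo,
    )
    return ancestor, individuals, alignment, truth


def evolve_individuals(ancestor: GenomeRecord, cfg: SimConfig):
    """Derive individuals from a ``make_ancestor(cfg)`` ancestor.

    Returns ``(individuals, alignment, truth)``; the ancestor must come
    from the same config (the plan is re-derived from the seed).
    """
    anc2, individuals, alignment, truth = simulate(cfg)
    if anc2.seq != ancestor.seq:
        raise SimulationError("ancestor does not match this configuration/seed")
    return individuals, alignment, truth
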