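"""Validate the published hairpin (micro-inversion) records.

Loads the 24 hairpin loci of the eight-plastome Cassytha panel, checks
which flanking stem pairs are exact reverse complements, and prints the
loop/stem extremes.
"""

from plastcomp.datasets import load_hairpin_records, validate_hairpins
from plastcomp.genome_io import revcomp

records = load_hairpin_records()
good, bad = validate_hairpins(records, max_mismatch=0)

loops = [r.loop_size for r in records]
stems = [r.stem_length for r in records]
print(f"{len(records)} hairpin records")
print(f"loop sizes span {min(loops)}-{max(loops)} bp, stems {min(stems)}-{max(stems)} bp")
print(f"{len(good)} stem pairs are exact reverse complements; "
      f"{len(bad)} are not and are reported as printed:")
for r in bad:
    print(f"  record {r.no} ({r.location}): {r.upstream_stem} / {r.downstream_stem} "
          f"({r.n_stem_mismatches} mismatches vs revcomp)")

psba = next(r for r in records if r.location == "psbA-trnH")
print(f"psbA-trnH locus: loop '{psba.loop_motif}' ({psba.loop_size} bp), "
      f"revcomp(upstream) == downstream: "
      f"{revcomp(psba.upstream_stem) == psba.downstream_stem.upper()}")
# A palindromic stem pair means the locus can fold into the hairpin whose
# loop is the inverted segment - the signature of inversion mutagenesis.
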