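"""Generate a synthetic two-species plastome panel with a truth ledger.

Builds a 30 kb quadripartite ancestor, derives 2 species x 4 individuals
carrying planted substitutions, SSR/non-SSR indels, micro-inversions and
the genus-wide structural reduction, and prints what was planted.
"""

from plastcomp.genome_io import gc_content
from plastcomp.simulate import SimConfig, simulate

cfg = SimConfig(seed=1)
ancestor, individuals, alignment, truth = simulate(cfg)

print(f"ancestor: {len(ancestor.seq):,} bp, GC {100 * gc_content(ancestor):.1f}%, "
      f"{len(ancestor.features)} features")
print(f"individuals: {len(individuals)} x ~{len(individuals[0].seq):,} bp "
      "(IR copy and ndh segments deleted, five ndh genes truncated)")
print(f"truth alignment: {alignment.n_rows} rows x {alignment.n_cols:,} columns")
print(f"planted: {truth.n_substitutions} substitutions, {truth.n_indels} indels "
      f"({sum(1 for e in truth.indels if e.ssr_class == 'SSR')} SSR), "
      f"{truth.n_inversions} inversions")
print(f"hotspot spacer: {truth.hotspot['label']} at aligned columns "
      f"{truth.hotspot['aligned_start']}-{truth.hotspot['aligned_end']}")
# Degapping any alignment row reproduces that individual exactly, so the
# alignment is usable as ground truth for variant-calling tests.
assert alignment.degapped(individuals[0].id) == individuals[0].seq
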