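"""Structural comparison of a reduced plastome against its quadripartite
ancestor: IR loss, missing multi-gene segments, and ndh pseudogenes.
"""

from plastcomp.simulate import SimConfig, simulate
from plastcomp.structure import compare, diff_to_text, find_ir, summarize

ancestor, individuals, _, _ = simulate(SimConfig(seed=1))
query = individuals[0]

anc_ir = find_ir(ancestor)
print(f"ancestor: {anc_ir.ir_status}, IR length {anc_ir.length:,} bp")

diff = compare(ancestor, query)
print(f"\n{query.id} vs ancestor:")
print(diff_to_text(diff))

s = summarize(query)
print(f"\nsummary: {s.plastome_size:,} bp, GC {s.gc_percent}%, "
      f"{s.n_genes} functional genes "
      f"({s.n_protein_coding} protein-coding, {s.n_trna} tRNA, {s.n_rrna} rRNA)")
# IR loss plus ndh degradation is the classic reduction syndrome of
# parasitic-plant plastomes.
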