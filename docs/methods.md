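# Methods

`plastcomp` analyses panels of closely related plastid genomes the way
comparative plastome studies of parasitic plants do: it calls the mutation
spectrum (substitutions, indel events, micro-inversions) from a whole-genome
multiple alignment, scans nucleotide diversity for barcode-candidate
hotspots, summarises pairwise divergence within and between species, checks
the species grouping with a distance tree, and compares reduced genomes
against a quadripartite reference to characterise IR loss, segment
deletions and pseudogenes. A synthetic-plastome generator reproduces this
whole study design with a planted-event truth ledger so every stage is
testable without downloads.

## Coordinate and record conventions

Sequences and features use 0-based half-open coordinates internally; the
1-based inclusive conventions of GFF3 and GenBank are converted exactly
once at the file boundary. Circular genomes are linearized by rotation so
that the first base of *trnH-GUG* sits at position 0 when that gene is
annotated — the conventional plastome linearization point. Published
coordinate statements for such panels rarely name their origin, so this
rotation is a convention of the package, not a claim about any deposited
assembly.
Ambiguity codes other than N are rejected on read: the analyses assume
fully resolved assemblies.

## Mutation-spectrum calling

An aligned column belongs to at most one category: indel, micro-inversion,
substitution, or invariant.

* **Substitutions** are gap-free columns with at least two of {A,C,G,T}
  present; N is missing data and never polymorphic. Columns inside called
  micro-inversions are masked first so that the per-site mismatches of one
  inversion are not double-counted as SNPs, keeping the tally additive.
* **Indel events** are maximal runs of columns sharing one gap/non-gap row
  pattern — an event count, not a gap-column count; adjacent columns whose
  bearer sets differ are distinct events. The fragment is read from the
  first non-bearer row.
* **SSR classification**: an indel is an SSR (slipped-strand) indel when
  its fragment is an integer number (≥1) of copies of a motif of length
  1–6 bp and at least one additional adjacent copy of that motif flanks
  the event site, on either side, in the sequence retaining the fragment.
  The motif-length cap (`max_motif`, default 6) and required flanking
  copies (`min_extra_copies`, default 1) are exposed because "SSR indel"
  has no universally fixed definition; the defaults encode the common
  microsatellite convention. N matches any base inside repeat runs.

## Micro-inversions and hairpins

A micro-inversion is a short segment (2–46 bp by default) carried in
reverse-complement orientation by one lineage relative to another,
classically mediated by a flanking pair of short inverted repeats: loop
and stem of a hairpin. Detection is pairwise against a designated
reference row: candidate intervals are built from maximal mismatch-column
runs, merging nearby runs when the reverse-complement identity only holds
across the merged span (interior positions of a loop may coincide with
their own complement); both interval endpoints must be mismatch columns,
which excludes an isolated A↔T substitution (a trivial 1-bp palindrome)
by construction together with the 2-bp minimum. Intervals longer than
`max_len` are reported but flagged out of range; the search span is capped
at twice `max_len`. Calls from different row pairs are merged by interval
identity, one record per locus.

Stems are found by sliding equal-length windows over both flanks (each up
to `max_gap_to_loop` = 5 bp away from the loop, a package choice — the
convention tables in the literature mostly show immediately adjacent
stems, which the tie-break finds first) and accepting the longest pair
with `upstream = revcomp(downstream)` up to `max_mismatch` mismatches.
`max_mismatch` defaults to 0; published hairpin tables of this kind
contain occasional non-palindromic rows, and the validator reports such
records rather than correcting them — a mismatch-tolerant mode is
available but nothing is asserted about whether those rows are typos or a
looser stem definition. Both stems are reported as read 5'→3' on the
reference row's forward strand; the pairing test is upstream versus
revcomp(downstream).

Location labels use gene-name space: the containing gene, "*gene* intron"
between two exons of one feature, or "*left*-*right*" for the spacer
between the nearest flanking genes; tRNA anticodon suffixes are dropped in
labels (trnH-GUG → trnH), matching the tables this layout mirrors.

## Diversity and divergence

Pairwise divergence is the uncorrected p-distance with pairwise deletion
of gapped or N columns. At the 10⁻⁵–10⁻³ scale typical of conspecific
plastomes a multiple-hit correction is numerically irrelevant, so
Jukes–Cantor is an option, not the default. Nucleotide diversity π over a
row set uses complete deletion (columns gap- and N-free across the whole
subset); for two rows the two conventions coincide. Sliding windows
(default 600 bp window, 200 bp step, the standard plastome scan setting)
run over aligned coordinates, the last windows truncated.

Two scan conventions matter and are package design choices:

* window π is computed with called micro-inversion columns masked — an
  inversion is one mutational event, and without the mask a single
  species-carried 46-bp loop inside a 600-bp window outranks any genuine
  substitution hotspot;
* hotspot ranking only considers windows retaining at least half the
  nominal window length in net sites, because a truncated or gap-riddled
  window of a few dozen sites can top the raw ranking on sampling noise
  alone.

Group summaries report mean within-species and mean between-species
divergence and their ratio (mean-over-means, the only reading under which
a "several-fold higher between species" statement is reproducible from a
printed matrix of this shape; the max-within/min-between reading gives a
smaller factor).

## Distance tree and species grouping

Neighbor joining follows Saitou–Nei with the Studier–Keppler Q-criterion.
Ties break deterministically toward the pair whose clusters carry the
lexicographically smallest leaf labels. Negative branch-length estimates —
an expected NJ artifact on near-ultrametric matrices — are clamped to zero
and flagged. Reciprocal monophyly of a two-group partition holds iff one
edge of the unrooted tree induces exactly that split; a singleton group is
trivially monophyletic via its pendant edge. NJ is consistent on additive
matrices, which the tests exploit as an exact oracle; dendropy's
independent NJ implementation serves as a cross-check on the published
divergence matrix.

## Structural comparison

* **IR detection** seeds exact 21-mer matches between the genome and its
  reverse complement and extends them ungapped along the diagonal; the
  genome is quadripartite iff the longest disjoint inverted-repeat pair
  reaches `min_ir` = 1000 bp, a threshold separating true IRs (tens of kb)
  from dispersed repeats and hairpin stems (tens of bp). Assembled
  plastome IR copies are near-identical, so mismatch-tolerant extension is
  deliberately omitted.
* **Missing segments** come from gene order: maximal runs of reference
  genes absent from the query, bounded by shared genes, reported with
  reference coordinates, lengths, flanking gene names and contained genes.
  Gene identity is the case-insensitive name with the tRNA anticodon
  suffix significant (trnL-CAA ≠ trnL-UAG) — these comparisons reason
  entirely in gene-name space.
* **Pseudogenes**: a shared gene is called when its observed length falls
  below `min_intact_frac` = 0.9 of the reference length (truncation), its
  length is not a codon multiple (frameshift), or its translation under
  the bacterial/plastid code (table 11) has a premature stop. The 0.9
  threshold sits far above the 0.14–0.55 length ratios that genuine ψndh
  truncations show, so the calls are insensitive to its exact value.
* **Summaries** count functional genes only (protein-coding + tRNA +
  rRNA), pseudogenes excluded, with GC to one decimal.

## The synthetic plastome generator

The generator emulates the two-species × four-individual plastome panel
end to end. Ancestor: a circular LSC/IRa/SSC/IRb genome (default 30 kb
with a 4 kb IR — a quarter-scale plastome that keeps the default test and
sweep workload in seconds) carrying the 11 ndh genes (reference lengths
2181/1509/306/2229/1182 bp for ndhB/D/E/F/H, matching a quadripartite
Lauraceae reference up to codon rounding, scaled stand-ins for the other
six), rpl2, ycf2 and four rRNAs inside the IR, trnH-GUG at position 0, 30
canonically named tRNAs, and as many real-named filler protein-coding
genes as the LSC holds (or exactly `n_filler_cds` when set). All
protein-coding genes are genuine ORFs (start, no internal stop, stop) so
translation-based pseudogene evidence stays meaningful; base composition
is weighted to the ~37% GC of real plastomes.

Planted events, drawn before layout so each gets a dedicated, exactly
sized intergenic spacer (placement can therefore never fail):

* **Substitutions** at two levels: a species-stem set shared by all
  individuals of a species, drawn binomially at (r_between − r_within)/2
  per retained site, and individual-private sets at r_within/2 — giving
  expected pairwise p-distances of r_within within species and r_between
  between, the two-level hierarchy a two-species panel shows. Defaults
  r_within = 5×10⁻⁴, r_between = 5.7×10⁻³, the published divergence scale.
* **A hotspot**: 25 extra species-diagnostic substitutions inside a
  dedicated 700-bp spacer between trnQ-UUG and psbK, mimicking an
  intergenic barcoding hotspot (~7× the background window π).
* **SSR indels** (default 51): a planted tandem run (motif 1–3 bp) from
  which a subset of individuals or one species loses 1–2 copies, at least
  one copy always remaining adjacent. **Non-SSR indels** (default 14):
  a 2–10 bp fragment verified at planting to fail the SSR rule. The
  51/14/6 event counts are the published genome-wide spectrum
  (195 SSR / 54 non-SSR / 24 inversions over ~114.6 kb) scaled to 30 kb.
* **Micro-inversions** (default 6): loop 2–46 bp flanked by an exact
  inverted-repeat stem pair of 3–23 bp; carriers see revcomp(loop).
  Each loop is validated at planting with the package's own scanner so
  that exactly the planted interval is recoverable.
* **Structural edits**, applied to every individual (a genus-wide
  reduction, matching the biology): loss of the IRb copy, deletion of two
  three-gene ndh segments with their intergenic DNA, and truncation of
  ndhB/D/E/F/H to the published pseudogene lengths 1191/428/159/302/547 bp
  (keeping the 5′ end).

The emitted alignment is the truth alignment: structural-deletion columns
(shared by all individuals) are dropped, indel bearers carry gaps,
degapping row *i* reproduces genome *i* byte for byte. The ledger records
every event in ancestor and aligned coordinates. One seeded
`numpy.random.Generator` drives everything; identical configs are
byte-identical.

Identifiability choices (what makes truth recovery exact, and what real
data would not guarantee): events sit in single-copy DNA, one per spacer,
never inside the IR; substitutions keep ≥4 bp spacing, at most one per
codon, avoid creating stop codons inside genes, and placements whose bases
would frame a self-reverse-complementary background stretch (formally
indistinguishable from a micro-inversion) are redrawn. Real alignments
contain overlapping, ambiguous and alignment-dependent events, so perfect
recovery here demonstrates correctness of the calling logic, not expected
field performance; on real data the counts are alignment-parameter
dependent and the pipeline reports them with parameters echoed.

## Numerical and degenerate-input conventions

π is `None` (undefined), never a number, when a window has no eligible
site; a zero mean-within divergence makes the between/within ratio
undefined rather than infinite. Hotspot ties rank leftmost. The stem
search tie-breaks longer stem, then smaller total gap to the loop, then
smaller upstream gap. All-N sequences make GC undefined. NJ requires ≥3
taxa. Stage order in the pipeline is variants → inversions → diversity →
structure → tree, and a config that requests a stage without its inputs
fails validation before any stage runs.

## Known limitations

Micro-inversion detection needs a mismatch signal: a loop that is its own
reverse complement, or whose ends match the other row, is undetectable in
principle; loops longer than twice `max_len` are not searched. Missing
segments at the very ends of the linearized gene order lack a flanking
gene on one side. The generator plants deletions only (an insertion is
the same gap pattern with roles swapped), does not model rate
heterogeneity, codon selection beyond stop avoidance, recombination, or
sequencing error, and annotates IR genes on one copy only. Exact
reproduction of published divergence tables from deposited accessions
depends on the upstream aligner and is therefore a soft, tolerance-based
check that runs only when those sequences are provided locally.
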