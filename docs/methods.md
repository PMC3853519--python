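# Methods

This note records the models, rules and numerical choices behind each stage
of the pipeline, the design decisions taken where more than one reasonable
convention exists, and what the synthetic-data validation does and does not
demonstrate.

## Read quality control

A read is discarded when its Phred score is **not greater than**
`q_threshold` (default 20) at **strictly more than** `bad_fraction`
(default 0.90) of its positions; both comparisons are strict, so a 100-bp
read with exactly 90 positions at quality 20 is kept.  Order is preserved
and the filter is idempotent.  Instrument-generated CASAVA 1.8 "chastity"
flags can optionally be honored (`skip_chastity_failed`); the flag is never
recomputed.

N50 is the standard descending-cumulative statistic: the largest length L
such that contigs of length ≥ L jointly contain at least half of all
assembled bases.  Some write-ups phrase N50 with a strictly-less-than
convention instead; the standard definition is the one assemblers report,
and it is what the brute-force oracle in the tests checks.  The median of an
even-sized set is the mean of the two central values.  The multi-k assembly
sweep is the inclusive arithmetic grid `k_min, k_min+step, …, k_max`
(52…96 step 2 gives the canonical 23 runs per sample).

## Ortholog-hit reduction

Hits carry a score and an E-value.  Filtering removes hits with E-value
above the cutoff (default 10⁻⁵, compared with ≤) and then keeps, per taxon
and gene, the `ceil(quartile × n)` highest-scoring survivors with a minimum
of one (rounding is not dictated by any convention; ceiling-with-floor-one
never silently drops a taxon).  Whether the quartile should apply per
taxon-gene, per gene, or globally is genuinely open; per taxon-gene is the
default.  Note its consequence on curated inputs: a taxon-locus with two to
four genuine transcript variants keeps only its best one, so the consensus
step often sees a single row unless the quartile is relaxed (driver 03
quantifies this).

The reciprocal-best-hit test accepts a hit iff its best-scoring protein in
the reference proteome belongs to the group that seeded it, ties broken by
lexicographically smallest gene id.  The scorer is a plug-in contract (any
deterministic pairwise scorer); the bundled default is Biopython's global
aligner with BLOSUM62, gap open −11, extend −1.  Inside `run_pipeline` the
best-reference search is pre-screened with a protein 5-mer index (top 3
candidate genes plus the hit's own), the same seeding idea BLAST uses; the
E-values attached to pipeline-internal hits are synthesized BLAST-style as
`m·n·2^(−S)` from the scorer's score, since the upstream search engine is
out of scope and only the ordering matters to the filters.

Protein rows are aligned **reference-anchored**: each hit is globally
aligned to the reference-taxon protein, columns where the reference has a
residue define the frame, and hit insertions relative to the reference are
dropped.  All rows therefore share the reference length and are mutually
comparable without a multiple-alignment step; this is exact for data whose
variation relative to the reference is substitutions and deletions (as in
the simulations) and is the package's stand-in for an external protein
aligner, whose output can be supplied instead.  Back-translation replaces
each residue with its source codon (gaps become `---`) and verifies that
every ungapped row translates its CDS exactly, naming the row and column on
mismatch.

**Consensus** emits, per column, the IUPAC code denoting exactly the union
of the nucleotide sets of the non-gap symbols; a gap is treated as missing
data, so only all-gap columns stay gaps.  This matches the motivation of
absorbing fragments and polymorphism rather than discarding them.  The
operation is idempotent and order-invariant.  **Representative** scores
every subset of mutually non-overlapping rows (zero shared non-gap columns)
merged column-wise against the ungapped reference row and returns the best,
with ties broken by fewest rows, then lexicographically smallest merged
sequence.

## Paralogy screening

Gene trees are neighbor-joining on uncorrected p-distances with pairwise
deletion (sites with a gap or any ambiguity code in either row are
excluded).  A pair of rows with no comparable site (disjoint fragments)
receives the triangle upper bound `min_k d(i,k)+d(k,j)` over rows comparable
to both, or 0 if none exists — this keeps same-locus fragments together
instead of scattering them.  NJ breaks Q-criterion ties by the smallest
(row, column) index pair and clamps negative branch-length estimates to
zero; both choices make the estimate bit-reproducible.

A taxon's retained sequences are **non-polyphyletic** when they could form a
clade under some rooting and, on partially collapsed trees, some resolution
of the polytomies: formally, there is a node v such that every component of
the tree minus v contains either only that taxon's retained leaves or none
of them.  On binary trees this reduces to the split-side criterion.  The
polytomy-aware form is what makes the relaxed mode sensible: with
`support_collapse_threshold` set, internal edges with bootstrap support
below the threshold are collapsed first, and since collapsing only merges
components, it can never increase the number of leaves pruned
(monotonicity, property-tested).

**Maximality.**  The pruned result maximizes, in order, the number of
distinct taxa retained and the number of leaves retained, with the
remaining tie broken by the lexicographically smallest retained leaf set
(leaves sorted by (taxon, sequence-id)).  An earlier design also maximized
total retained branch length between the leaf count and the lexicographic
step, but that objective is exponentially expensive in degenerate tie
spaces — an ancestral duplication spanning k taxa yields ~2^k optima equal
on (taxa, leaves) that differ only in branch length, and no useful bound
exists for it — whereas the lexicographic rule is scale-free, deterministic
and searchable.  Note that a subtree maximizing retained taxa always
exists that retains *every* taxon (keep one sequence per taxon), so the
strict filter's notion of "evidence of paralogy" is carried entirely by
whether any leaf had to be removed.

The search is exact.  Candidate "regions" per multi-copy taxon are minimal
unions of components around a hub node (an antichain per realized
own-leaf-subset); an assignment of one region per taxon, with leaves covered
by two regions deleted, realizes every feasible pruning.  Phase 1 maximizes
(taxa, leaves) by branch-and-bound whose bound caps each remaining taxon's
contribution at the best it could achieve in a completion that keeps every
currently-alive taxon alive (a region contributing more than one leaf must
avoid live singletons and must not wipe out any other taxon); completions
that sacrifice a taxon are dominated through the taxa component, so the
bound is valid lexicographically.  Phase 2 resolves the lexicographic tie by
fixing leaf ranks one at a time, each step a feasibility search for the
phase-1 optimum under the accumulated forced-in/forced-out constraints.
Worst-case cost remains exponential in the number of multi-copy taxa, but
the study-scale instances (up to 19 duplicated taxa out of 20) solve in
well under a second each.  Exhaustive equivalence against a subset-
enumeration oracle is checked over every multi-labeled tree with ≤ 7 leaves
and ≤ 3 taxa (964 isomorphism classes).

The strict filter partitions prune results into clean and flagged gene id
lists and rejects duplicate ids; "no evidence of paralogy" is all-or-nothing.

## Degeneracy recoding

The family table is regenerated from the standard genetic code at import
time rather than hard-coded: each amino acid's codon set is reduced to its
minimal per-position IUPAC pattern (Gly → GGN, Ile → ATH, Met → ATG, …),
with three special cases — the six-fold leucine family is YTN, the six-fold
arginine family MGN, and serine is split into its TCN and AGY subfamilies,
which are not interconvertible by a single synonymous change.  Distinctness
of patterns and coverage of all 61 sense codons are asserted on
construction.

Recoding rules: a codon containing a gap becomes `---`; a sense codon
becomes its family pattern; an ambiguous codon whose compatible sense
expansions all fall in one family (and none is a stop) becomes that
pattern, otherwise `NNN`; stop codons become `NNN` (the matrices are
protein-coding, so a stop is treated as missing).  The family patterns
themselves are fixed points — YTN and MGN deliberately expand beyond their
own families (the Leu/Phe and Arg/Ser2 overlap at the ambiguity level), so
without the fixed-point rule recoding would not be idempotent.  Same-family
codons recode identically, cross-family codons produce distinct strings,
and recoding collapses alignments that differ only synonymously —
exhaustively checked over all 61 sense codons.

## Supermatrix assembly

Genes are concatenated in lexicographic gene-id order; taxa absent from a
gene are filled with gaps; partition coordinates are 1-based inclusive
(RAxML convention) and always tile the matrix.  A site is "represented by
sequence data" in a taxon when it holds any non-gap, non-N symbol —
ambiguity codes other than N constrain the nucleotide and count as data.
The occupancy filter removes columns represented in fewer than `min_taxa`
(default 4) taxa, recomputes partitions and drops emptied ones; it is
idempotent and never lengthens the matrix.  Completeness is the fraction of
non-gap, non-N cells, reported per taxon and overall; the same cell-level
definition as occupancy, applied after recoding, so degenerate third
positions recoded to N count as missing.  Whether the occupancy filter runs
before or after recoding is configurable; the default is after, matching
the natural reading of the processing order, and the all-N columns recoding
creates are then removed by the same filter.

Coverage per base is `read_length × median(reads mapped per sequence) ÷
median(sequence length)` with the same median convention as the assembly
metrics.

`run_pipeline` chains QC → orthology reduction → gene-tree screening →
strict filter → reduction → recoding → concatenation → occupancy filter,
reports gene counts entering and surviving each stage (conservation
`screened = clean + flagged` is asserted by tests), estimates a final NJ
tree, and writes the external-ML export bundle: FASTA and relaxed PHYLIP
matrices, a partition file, and a settings note recording the intended
external analysis (GTR+I+G, 1000 bootstrap replicates × 5 search replicates
each).  Maximum-likelihood search itself is explicitly out of scope; NJ with
bootstrap is the deterministic desk-scale stand-in throughout.

## Tree machinery

Robinson-Foulds distance counts non-trivial splits present in exactly one
tree (cross-checked against dendropy).  The bootstrap resamples alignment
columns (or whole codon triplets, for codon-structured matrices) with
replacement, rebuilds the tree with a pluggable builder (default NJ on
p-distances), and maps the percentage of replicate trees containing each
split of the point-estimate tree onto its internal nodes.  Supports of a
unanimous alignment are exactly 100; on an evenly conflicted quartet they
sit near 50 within binomial error.

## The synthetic-data generator

The generator emulates the statistical structure the pipeline assumes, not
transcriptomics in the large:

- **Species tree**: pure-birth (birth rate 1.0), leaves relabeled T01…,
  branch lengths rescaled so the deepest root-to-tip path equals
  `tree_height` (default 0.5).
- **Substitution process**: per-site nucleotide proposals arrive as a
  Poisson process at the branch length (branch lengths are therefore
  expected *proposals* per site); a proposal creating a stop codon is
  rejected; synonymous proposals are accepted at
  `synonymous_rate_multiplier` (default 5) times the rate of nonsynonymous
  ones.  This is not a full codon model — it is the minimal structure under
  which synonymous positions evolve faster and degeneracy recoding has
  something to remove.  Accepted events are logged per gene so the ratio is
  directly assertable.
- **Duplications**: with probability `dup_probability` a gene gets one
  duplication, planted at a uniform time fraction on a branch whose subtree
  spans at least `dup_min_taxa` (default 3) taxa; both copies evolve
  independently down the subtree; losses are off by default.  Every emitted
  sequence carries an ortholog/paralog truth label.
- **Transcripts**: each taxon-locus CDS always yields its base transcript
  and, at the configured rates, an isoform (internal deletion of 10–30% of
  codons), an allele (substitutions at heterozygosity 0.005, stop-safe) and
  a fragment (codon-aligned 30–60% substring).
- **Reads**: uniform substrings of length `read_length` (whole transcript,
  logged, when shorter) with per-base errors at `read_error_rate` and Phred
  scores i.i.d. normal(`quality_mean`, `quality_sd`) truncated to [2, 41]
  and rounded — the simplest profile that exercises the Phred filter.  With
  the default mean of 35 essentially no read fails the filter, mirroring a
  high-quality run; lowering the mean exercises the discard path.

All randomness flows from a single integer seed through independent
substreams; fixed seed ⇒ byte-identical FASTA/FASTQ output (tested).
Deliberately not emulated: expression-level variation beyond a uniform
reads-per-transcript count, library normalization, sequencing-adapter
artifacts, assembly errors (transcripts are exact variant copies, so
"assembly" is an identity step), spurious cross-gene search hits, and
alignment error from insertions.  Consequently a passing end-to-end run
shows the pipeline's logic is sound under its own assumptions — correct
frame handling, filtering, screening, recoding and assembly — not that it
is robust to misassembly or alignment noise in real transcriptomes.

## Validation problem sizes

The end-to-end analyses use 20 taxa, 50 clean genes (or 100 genes with
`dup_probability` 0.3) of 200 codons, and 2 reads per transcript — enough
signal for exact species-tree recovery while keeping the whole suite around
a minute and the acceptance script a couple of minutes on one CPU.  The
pruner's exhaustive oracle check covers all trees with ≤ 7 leaves and ≤ 3
taxa, deduplicated to 964 isomorphism classes by centroid-rooted AHU
canonical forms (a raw labeled enumeration repeats each class hundreds of
times without adding coverage).

## Known limitations

- The reference-anchored aligner discards hit insertions relative to the
  reference; loci with substantial insertion variation need an external
  aligner upstream.
- The per-taxon top-quartile default interacts with curated inputs (see
  above); on real search output, where most excess hits are divergent junk,
  the default is the conservative choice.
- The pruning search is exponential in the number of multi-copy taxa in the
  worst case; polytomies with more than 16 components around one node are
  rejected rather than searched.
- NJ consistency guarantees exact recovery only for additive distances;
  near-zero internal branches may be collapsed arbitrarily (deterministic
  tie-break).
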