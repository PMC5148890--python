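# Methods

## The problem

De novo transcriptome assemblers applied to the same RNA-seq dataset produce
markedly different outputs: each package misses some genuine transcripts,
truncates others, and invents transcripts of its own.  For organisms with no
reference genome there is no authoritative way to pick "the right" assembly.
`txconsensus` implements the consensus strategy of merging the outputs of
several (canonically three) independent assemblers and reducing the merged
pool to a non-redundant *coding* transcriptome, on the rationale that coding
sequence reconstructed by more than one assembler is far more likely to be
real than sequence reconstructed by only one.

## Pipeline

Given labelled assemblies `{label -> FASTA}` the pipeline executes:

1. **Name harmonization.**  Every record id is prefixed `label|original_id`.
   Assembler outputs reuse generic contig names, so uniqueness is required
   only *after* harmonization; the prefix makes every downstream object
   traceable to `(assembler, original name)`.
2. **Intra-assembly de-duplication.**  Greedy clustering at 100% local
   identity over 100% of the shorter sequence (`c=1.00, aS=1.00, aL=0.005`,
   both strands).  Under these thresholds membership is exactly "the record,
   or its reverse complement, is an exact substring of a longer retained
   record", and the implementation exploits that with a substring fast path.
   `aL=0.005` admits length ratios up to 200x, i.e. effectively any
   transcript-size range.
3. **Concatenation** of the per-assembly survivors.
4. **CDS extraction.**  Six-frame ORF detection; a maximal stop-free stretch
   is reported when it encodes >= 100 amino acids (inclusive threshold,
   configurable).  Within a stretch the CDS starts at the first ATG; a
   stretch reaching the 5' boundary of its frame with no upstream stop is
   reported from its start (5'-partial/internal).  The stop codon is
   excluded from sequence and coordinates; codons containing N translate to
   X and never act as stops; one ORF per stretch (no nested sub-ORFs).
   Detection is purely structural — no coding-likelihood model is applied —
   so ORF-shaped UTR or antisense stretches above the length floor are kept;
   the cross-assembler consensus step, not a classifier, is the filter for
   biological plausibility.
5. **CDS clustering.**  Greedy clustering of the CDS nucleotide sequences at
   `c=0.98` (conservative with respect to a ~1% per-base sequencing error
   rate: two error-bearing copies of the same molecule still align above
   98%), `aL=0.005`, and `aS` configurable over 1.00..0.75 (default 1.00,
   the most conservative grid value).  CDSs are already strand-oriented, so
   only the forward strand is compared by default (configurable).
6. **Representatives.**  Each cluster is represented by its longest CDS
   ("uniCDS"); ties break by assembler-label order, then id.
7. **Provenance categories.**  Each cluster is labelled by the subset of
   assemblers contributing members.  For three assemblers `[A, B, C]` the
   default numbering is 1={A,B,C}, 2={A,B}, 3={A,C}, 4={B,C}, 5={A}, 6={C},
   7={B}; with the canonical labels this makes 5 CLC-only, 6 Trinity-only,
   7 IDBA-only.  Published descriptions of this 7-way scheme are internally
   inconsistent about the ordering of the pair and single categories, so
   the mapping is an explicit configuration option rather than a hard-coded
   fact.  For N != 3 assemblers the 2^N - 1 subsets are numbered by
   decreasing size, then lexicographically.
8. **CDS extension.**  For every cluster and every contributing assembler,
   the assembler's longest member CDS is compared with the representative;
   if strictly shorter, the cluster counts as "extended" for that assembler
   by the bp difference — coding sequence that assembler alone would have
   missed.  Extension is measured on CDS length in bp.
9. **Final transcriptome.**  The transcripts owning at least one
   representative CDS, UTRs intact.  Because one transcript can own several
   representative CDSs, the final transcript count can be *below* the
   uniCDS count, and because final transcripts can carry additional,
   non-representative CDSs, the total CDS count on final transcripts is
   *above* it: `n_final <= n_uniCDS <= n_total_cds_on_final`.

## Clustering semantics

Clustering is greedy and incremental in the CD-HIT-EST style: records are
visited longest-first (ties: id, or a caller-supplied tie-break) and each
joins the first existing cluster, in creation order, whose representative it
matches, else founds a new cluster.  A match requires, simultaneously,

* identity >= `c` — identical columns / alignment columns of the best local
  alignment (gap columns count in the denominator),
* coverage of the shorter sequence >= `aS`,
* coverage of the longer sequence >= `aL`.

The pairwise kernel is an affine-gap Smith–Waterman (match +2, mismatch −3,
first gap column −5, each further gap column −2; N matches nothing,
including another N — a deliberately conservative choice for redundancy
calls).  Representatives are never re-elected, and the result is
deterministic and independent of the input order and of the worker count.

Two accelerations are used, both provably lossless and both re-verified
against brute-force oracles in the test suite:

* **k-mer prefilter (k=16).**  An alignment with at least `m` columns at
  identity `c` contains a gapless run of at least `c·m/((1−c)m+1)` matches;
  whenever the thresholds force that run to reach 16, pairs sharing no
  16-mer (either strand, N-free) are skipped without alignment.  At
  `c=0.98` the guarantee engages once `aS`·len >= 25 nt; at identities
  below c/(1−c) <= k (roughly c < 0.94) the prefilter disables itself.
  k=16 rather than 8 because with 4^8 = 65,536 possible 8-mers, unrelated
  kb-scale sequences almost always share one by chance.
* **Score gate.**  Any threshold-passing alignment scores at least
  `(7c−5)·m`; the (cheaper) score-only pass skips the traceback when the
  best score falls below that bound.
* **Exact mode.**  At `c=1.00, aS=1.00` membership reduces to exact
  substring containment, tested directly on strings.

## Evaluation metrics

* **Length statistics**: count, smallest, largest, median, total size, N50
  (length at which the descending cumulative sum first reaches half the
  total).  These are reported but are weak evidence of quality.
* **Annotatability**: from a 12-column tabular similarity-search file,
  the number of CDSs with at least one hit at e-value <= 1e-3 (inclusive),
  and the number of *distinct* database entries hit.  The second number is
  the informative one: mis-assembled isoforms inflate the first but not the
  second.  Unique subjects are counted as raw subject-id strings.
* **aS sweep**: the CDS clustering is repeated across an aS grid
  (canonically 1.00, 0.99, 0.98, 0.97, 0.96, 0.95, 0.90, 0.85, 0.80, 0.75)
  and the metrics above are recomputed on the representatives; the largest
  aS at which the unique-subject count drops below the aS=1.00 baseline is
  flagged as the information-loss onset.
* **Reference recovery**: against a known transcript set, an original
  counts as recovered iff some assembled transcript aligns at >= 98%
  identity over >= 50% of the *original's* length; an assembled transcript
  with no qualifying alignment to any original is "invented".  When no hit
  table is supplied the built-in kernel aligns the pairs directly (intended
  for desk-scale sets; the same k-mer prefilter prunes hopeless pairs).
  Only the single best alignment is used — disjoint fragments are not
  chained to reach the coverage threshold.
* **Coverage binning**: fractions of missing originals below, and recovered
  originals at or above, a fold-coverage threshold (default 10x); undefined
  fractions (empty denominator) are reported as not-applicable.

## Synthetic data

The generator plants a truth transcriptome — one verified ORF per
transcript, flanked by in-frame stops so the planted ORF is the unique
maximal one, uniform base composition, optional paralog pairs diverged at a
stated ORF substitution rate — and derives per-assembler outputs with
controlled imperfections (duplication as exact copies/substrings,
3'-truncation, substitution error, coverage-biased dropout, and artifact
transcripts unique to one assembler).  Per-gene fold-coverages are
log-normal (median ~25x), and dropout picks genes with probability inversely
proportional to coverage, emulating the empirical pattern that assemblers
mostly miss poorly covered transcripts.

The central design decision is that **the manifest is an exact oracle, by
construction**: every planted fate maps deterministically onto the pipeline
observable that should detect it (duplicates onto intra-assembly
de-duplication, truncations onto CDS extensions, artifacts onto
single-assembler categories, dropouts onto the recovery comparison).  Three
mechanisms enforce this:

* substitutions have a fixed budget of floor(rate x length) per copy,
  placed at most one per equal-length window, never creating an in-frame
  stop and never touching the start codon, stop codon, or flanking planted
  stop.  With the default ORF fraction (>= 50% of the transcript) the
  worst-case pairwise CDS divergence between two copies is provably below
  2(rate) + o(1), so the 98% clustering threshold is met deterministically;
* no substitutions fall within the terminal bases of a planted CDS or
  within ±10 nt of any planned truncation site of the same gene, in any
  copy, so the best local alignment between copies is the full gapless
  overlap and short-sequence coverage is exactly 1.0 even at aS = 1.00;
* truncation points are validated against the truth sequence (removing
  sequence can expose a new boundary-abutting partial ORF on the opposite
  strand; such cut points are redrawn), and every emitted copy is
  re-verified to carry exactly the CDS content its manifest entry promises.
* fragments keep at least 55% of the transcript, so a truncated-but-present
  gene is still recovered under the 50%-coverage rule and truncation
  exercises the extension statistics rather than the recovery comparison.

What this emulates, and what it does not: the generator works at the
transcript level.  It does not simulate reads, expression levels, indels,
chimeras, splice isoforms, or assembler-specific graph artifacts.  Passing
tests therefore demonstrate that the pipeline's bookkeeping — clustering
semantics, provenance classification, extension arithmetic, recovery
accounting — is exactly right under controlled imperfections; they do not
demonstrate that three real assemblers behave like the mock ones.  The
default study conditions (per assembler: 10% dropout, 20% truncation, 0.5%
substitution error; 30% duplication and ORF-bearing artifacts on the
Trinity-like output only; 5 artifacts per assembler; K=50 genes of
0.6–2.5 kb) are scaled to desk size while keeping every rate in the regime
the method is designed for: real concatenated assemblies run from tens of
thousands to hundreds of thousands of transcripts, and intra-assembly
duplication of up to 30% is characteristic of single-transcript-graph
assemblers.

## Numerical and degenerate-input choices

* Threshold comparisons use a 1e-9 slack so that exact rational identities
  (e.g. 49/50 vs 0.98) are never rejected by float rounding.
* `aa_len >= 100` is inclusive ("greater than 100 aa" in common usage
  follows the detector's documented 100-aa minimum).
* Representative ties (equal length) break lexicographically by id in plain
  clustering and by assembler-label order then id in the CDS step.
* Empty inputs, 1-nt alignments, all-N sequences, and clusterings whose
  best alignment has score <= 0 are all defined (empty summary, identity 0).
* The e-value threshold is inclusive; hits referencing unknown queries are
  excluded with a warning, not an error.
* An empty missing set makes the coverage-binned missing fraction
  undefined; it is reported as not-applicable rather than 0.

## Known limitations

* The greedy kernel reproduces the *contract* of the established EST
  clusterer at these parameter sets, not its internal short-word heuristics;
  on borderline inputs (alignments sitting exactly at a threshold with
  co-optimal tracebacks) decisions could differ from other implementations.
* ORF detection keeps every qualifying ORF per transcript; there is no
  homology-guided retention or single-best-ORF mode.
* Recovery does not chain multiple disjoint alignments, so a transcript
  reconstructed in two non-overlapping halves counts as missing.
* The pairwise kernel is quadratic; the package targets desk-scale and
  moderate corpora, not hundreds of thousands of sequences in one pass.
* With 5'-end truncation enabled in the generator (non-default), the
  clusterability guarantee for planted copies is weaker, because the
  restarted CDS may begin outside any substitution-protected zone.
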