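# Methods

`teharvest` reconstructs a consensus transposable element (TE) from a
genome assembly by iterated homology search, hit consolidation, assembly
and majority consensus.  This note records the model behind each stage,
the parameters that matter, the numerical choices and tie-breaks that make
the pipeline deterministic, what the synthetic fixtures do and do not
emulate, and the known limitations.

## Homology search

The internal backend is a classical seed-and-extend local aligner:

* **Modes.**  Protein query against the six-frame-translated genome;
  nucleotide query against both genome strands; translated nucleotide
  query against the translated genome.  Coordinates are always reported
  0-based half-open on the forward strand, with strand and reading frame
  carried as flags.
* **Seeding.**  Exact k-mers (k = 4 for amino acids, k = 11 for
  nucleotides), located by vectorized rolling codes.  Seeds on a diagonal
  already covered by a previous extension on that diagonal are skipped;
  co-located extensions keep the best score.
* **Extension.**  Ungapped, X-drop with X = 20 score units, returning the
  best-scoring end points.  Scoring: BLOSUM62 for proteins with ``X``
  forced to 0 against everything (no evidence) and ``*`` (stop) to −4
  (degraded copies accumulate in-frame stops; terminating there would
  shatter hits a gapped search reports whole); +1/−2 for nucleotides, N
  never matches.
* **Chaining.**  Co-linear extensions separated by a subject gap ≤ 50 bp
  with diagonal drift ≤ 20 are merged into one hit with summed score
  before e-value filtering — the minimal stand-in for gapped extension.
  Without it, copies a few percent diverged fragment into sub-threshold
  pieces between indels and the copy count inflates.
* **Statistics.**  Ungapped Karlin–Altschul e-values
  `E = K·m·n·exp(−λ·S)` with published constants (BLOSUM62:
  λ = 0.3176, K = 0.134; +1/−2: λ = 1.28, K = 0.46); m is the query
  length, n the total translated length over six frames (translated
  modes) or the genome length (nucleotide mode); raw lengths, no edge
  correction.  Only behaviour around the cutoff matters downstream.
  Default cutoff **1e-20** (configurable).

An optional adapter substitutes external BLAST+ binaries (passing only
the e-value cutoff) and converts tabular output into the internal
convention; the internal backend remains the reference.

## Hit combination

Hits are stably sorted by (contig, start, end) and merged to a fixpoint:
two hits or partial regions combine when their intervals overlap or nest
(regardless of query), or when the gap between them is at most the
**combine distance (default 50 bp)** and they share a contributing query;
the merged interval includes the intervening sequence, and a merged region
inherits every contributing query, so it can bridge further through any of
them.  The result is order-invariant and idempotent (property-tested
against a brute-force all-pairs fixpoint oracle).  Region strand is the
strand carrying the majority of contributing hit bp, ties to "+";
extraction reverse-complements minus regions so all instances share the
coding orientation.

## Assembly and quality trimming

Extracted instances are assembled by a greedy, reference-free
overlap-layout-consensus procedure designed for the shape this pipeline
produces — many near-complete copies of one element with short unrelated
flanks:

* **Overlap detection.**  Shared 16-mers vote for layout diagonals
  (k-mers occurring more than 4 times in a sequence are ignored); the
  modal diagonal (ties to the smallest offset) defines the candidate
  layout, and the k-mer-supported span (all matches within ±30 diagonals)
  is verified by edit-distance alignment: minimum overlap 40 bp, minimum
  identity 90%, both orientations.  Restricting the identity check to the
  supported span prevents random overhangs from vetoing a solid overlap.
* **Merging.**  Best-score-first.  Within the supported span, columns are
  paired by an optimal edit-distance alignment.  Beyond the span, columns
  are stacked position-locked at the span edge's *local* diagonal.  Two
  failure modes motivated this: freely aligning unrelated flanks
  manufactures ~50% column agreement purely through alignment
  optimization, and locking tails at the modal diagonal misplaces
  sequence that sits past internal indels.
* **Column model.**  Each contig column carries per-base member counts
  and a span coverage (members whose extent covers the column).  During
  merging, columns where fewer than a third of spanning members have any
  base are pruned — private insertions must not accumulate, or a growing
  contig drifts below the 90% identity floor and the assembly shatters.
  At finalization only columns whose winning base holds a tie-inclusive
  majority against mismatch-plus-gap votes are emitted, and in deep
  contigs (peak coverage ≥ 6) terminal columns with span coverage below a
  third of the peak are shaved as flank debris.  Shallow contigs keep
  their overhangs: a single-member extension there is ordinary assembly
  territory and the quality trim decides its fate.
* **Quality.**  Per emitted column, `clip(10·(2·agree − spancov), 0, 40)`:
  two concordant members score 20, a lone member 10, a deeply covered but
  conflicted column ~0.  The default trim threshold of 18 therefore keeps
  sequence supported by at least two concordant copies.  Sequences that
  assemble with nothing are returned as singlets with uniform quality 20,
  so the singlet fallback does not silently delete them.
* **Trimming.**  A base is high-quality iff some full window of
  **window = 20 bp** covering it has mean quality above **threshold = 18**
  (cumulative-sum windows; contigs shorter than the window use the whole
  mean).  High-quality runs are stitched across low-quality gaps of at
  most **max_low_gap = 50 bp** when flanked on both sides; the longest
  stitched segment wins, leftmost on ties; terminal bases individually
  below the threshold are then shaved (a boundary window would otherwise
  drag up to window−1 weak bases along).
* **Iteration.**  Assemble → trim → reassemble → trim.  Trimmed consensus
  sequences carry their quality into the reassembly as per-column weights
  (`clip(q/10, 1, 4)` pseudo-members), so well-supported single-source
  sequence is not mistaken for thin coverage.  If the first assembly
  yields no contigs the singlets take the same path.

## Multiple alignment and majority consensus

Near-full-length instances (coding candidates re-found in the genome and
extracted with class-dependent flanks: Class II 1000 bp, Class I 1500 bp,
unknown 1000 bp) are aligned by a deterministic center-star: the longest
instance anchors optimal pairwise global alignments (match +1, mismatch
−1, gap open −5, extend −1) whose gap patterns are projected into shared
columns.

The consensus rule, per column over R rows: each base *b* counts `c[b]`;
a gap or N increments **all four** counts (missing data must not vote
against any base); a base whose total exceeds the **threshold (49%)** of R
is emitted; among several qualifying bases the highest gap-free count
wins, ties alphabetically.  Columns where gaps outnumber real bases are
dropped — they are dominated by missing data, typically an insertion
private to one row — and no ambiguity codes are emitted, because the
consensus must remain searchable against the genome.

Two practical corrections bound the consensus at the element's termini.
Unrelated flanking sequence aligned against the center is optimized
toward it, so flank columns reach ~50% agreement by construction, and in
AT-rich genomes the compositional bias pushes individual columns past the
threshold.  The consensus is therefore (a) trimmed with the standard
sliding window over a support-based quality track
(`clip(10·(2·win − dissent − gaps), 0, 40)`), which removes long weak
arms, and (b) end-sharpened: terminal columns must hold a two-thirds
majority of (real bases + gaps).  True termini are carried by a solid
majority of instances and pass both easily, at any tested divergence.

## Pipeline and reporting

Phase 1 (identify coding region): family queries → search → combine →
extract without flanks → assemble/trim/reassemble/trim.  Phase 2
(encompass): candidates → nucleotide search → combine → flanked
extraction → center-star MSA → 49% consensus → boundary cleanup; a single
instance is used directly (elements with one or two genomic copies remain
reconstructable).  Phase 3 (validate): consensus → search → combine →
extraction with **50 bp** flanks → assemble/trim → final element; a final
search of the final sequence defines the instance regions.  Copies =
number of combined regions (raw hit counts are inflated by the very
fragmentation combining exists to fix); full-length copies = regions
spanning ≥ **90%** of the final element (configurable); density = 100 ×
merged instance bp / genome bp — combined regions are disjoint, so no
base is counted twice.  A `max_refine_rounds` knob (default 1) can repeat
phase 3 on its own output.

All defaults reproduce the suggested parameter set (e-value 1e-20,
combine distance 50 bp, window 20 bp, threshold 18, consensus 49%).
Every stage is deterministic for fixed inputs; the config seed is recorded
for any future randomized backend.

## Synthetic fixtures

The generator emulates the situation the pipeline exists for: a host
genome (i.i.d. background at a configurable GC, default 0.40) containing
diverged, truncated, optionally nested and reverse-complemented copies of
a mariner-like ancestor — 26 bp TIRs, 150/180 bp untranslated leaders and
a 300-codon transposase ORF free of internal stops, 1285 bp in total.
Copies receive uniform substitutions and geometric indels (p = 0.5, max
10), fragments keep a uniform 20–40% of either end, and each insertion
duplicates a 2 bp target site drawn from the host.  Insertions extend the
genome, so copies never destroy each other except by explicit nesting.
Truth records carry realized identity to the ancestor measured by
edit-distance alignment.

Default conditions of the end-to-end evaluation: 2 Mb genome, 20
full-length and 30 fragmented copies, divergence 0/2/5% (indel rate a
tenth of the substitution rate).  What passing these tests shows: the
pipeline recovers a planted ancestor essentially exactly under a neutral
divergence model with clean assembly and uniform background.  What they
do not show: behaviour on real repeat landscapes (families of related
elements, solo LTRs, segmental duplications, compositional heterogeneity,
assembly gaps), elements whose nearest library relative is highly
divergent, or very high copy numbers (the P. humanus mariner family has
hundreds of copies; the fixtures use tens, which keeps the whole suite
fast at identical logic).

## Limitations

* Elements without coding regions (SINEs, MITEs) are invisible — the
  entry point is a coding-region homology search.
* Family assignment of the output is whatever family seeded the search;
  no classification is attempted.
* TIR/LTR termini are not detected structurally; boundary precision comes
  entirely from the majority behaviour of the instance stack, so a family
  whose copies all share flanking sequence (e.g. nested in one older
  element) would keep that shared flank.
* The internal search is ungapped-with-chaining; extremely diverged
  copies (≳20%) are better served by the external BLAST+ adapter.
* With a single genomic instance the consensus necessarily includes the
  extraction flanks; the element inside is exact, but its boundaries are
  the researcher's to refine.
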