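# teharvest

Homology-based discovery of consensus transposable elements (TEs) in
assembled genomes.

Most eukaryotic genomes are littered with mobile DNA — retrotransposons
(Class I, copy-and-paste via an RNA intermediate) and DNA transposons
(Class II, cut-and-paste via a transposase, usually bounded by terminal
inverted repeats).  Annotating a newly assembled genome means answering:
*which element families are present, what does a full-length member look
like, and how much of the genome do its copies occupy?*  Individual copies
are diverged, truncated and nested, so no single genomic instance is a
good representative; the goal is a **consensus element** distilled from all
of them.

`teharvest` automates the classical homology-driven workflow used by
repeat curators, starting from a library of representative TE coding
regions (transposases / reverse transcriptases) grouped by family:

1. **Identify the coding region.**  Protein-level search of the family's
   library against the genome (translated in six frames), keeping hits with
   e-value < 1e-20; hits that overlap, nest, or lie within 50 bp of a hit
   from the same query are combined — including the intervening sequence —
   then extracted, assembled into quality-scored contigs, and trimmed with
   a 20 bp sliding window at quality threshold 18.
2. **Encompass the complete element.**  Each coding candidate is searched
   back against the genome at the nucleotide level; instances are extracted
   with generous flanks (1 kb for Class II, 1.5 kb for Class I), multiply
   aligned, and reduced to a consensus by a gap-aware majority rule: per
   column, each base *b* scores `c[b]`, a gap increments *every* base's
   count, and a base exceeding 49% of rows is emitted.
3. **Validate.**  The consensus is searched once more; instances are
   re-extracted with short flanks, reassembled and trimmed to the final
   element, and a last search yields the copy count, the number of
   full-length copies (span ≥ 90% of the element), and the genome density
   (percent of genome bp covered by merged instances).

All stages are deterministic.  A seed-and-extend search backend (exact
k-mer seeding, ungapped X-drop extension, Karlin–Altschul e-values) is
built in; an adapter can substitute external BLAST+ binaries when present.

## Worked example

Generate a synthetic genome with planted copies of a known ancestral
element, then rediscover the element from its transposase alone:

```sh
printf 'genome_length: 200000\nn_full: 5\nn_fragment: 3\nsub_rate: 0.02\nindel_rate: 0.002\nseed: 13\n' > spec.yaml
teharvest make-fixture --spec spec.yaml --out fixture
teharvest run --library library.fasta --family mariner \
    --genome fixture/genome.fasta --out run1
```

where `library.fasta` holds the family's protein queries with headers like
`>mariner_tpase1 family=mariner class=II`.  The run prints:

```
Family:             mariner
Length (bp):        1308
Full-length Copies: 5
Copies:             8
Density:            3.72%
Outputs written to run1
```

meaning: the reconstructed consensus element is 1308 bp long (the planted
ancestor is 1285 bp; at only five full copies the boundary columns keep a
little flanking sequence); 8 genomic instance regions were found, of which
5 span at least 90% of the element (the rest are truncated fragments);
merged instances cover 3.72% of the genome.  `run1/` contains the consensus FASTA, an instances BED, the
report as TSV and text, every intermediate (phase-1 candidates, phase-2
consensus) and a JSON manifest of parameters and stage counts.

The same objects are available as a library:

```python
from teharvest import PipelineConfig, run_pipeline
te = run_pipeline("mariner", "library.fasta", "genome.fasta", PipelineConfig())
print(te.length, te.copies, te.full_length_copies, te.density_percent)
```

`teharvest instances` re-searches a finished consensus against any genome
and writes its instance regions as BED; `teharvest density` prints only
the copy count and density.

## Scope

The approach finds elements with a coding region homologous to something
in the library.  Non-autonomous elements without coding capacity (SINEs,
MITEs), automatic family classification, and structural detection of
LTR/TIR termini are out of scope.
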