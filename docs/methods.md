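# Methods

`sncrnakit` re-implements, as a tested library, the downstream analysis of a
genome-scale small-noncoding-RNA (sncRNA) survey in a basidiomycete fungus:
(1) classifying sncRNA loci by genomic context relative to protein-coding
gene models, (2) tracing each sncRNA across related genomes with a
word-seeded local aligner, and (3) clustering those genomes by the rank
correlation of their sncRNA identity profiles.  Because the original
assemblies are not shipped, a seeded synthetic-data module generates genomes
with planted ground truth for every stage.

## Genomic-context classification

A gene model is reduced to its ORF span (start codon through stop codon) and
its coding-exon intervals; introns are exactly the gaps between consecutive
exons.  Each sncRNA locus receives one of four exclusive categories:

- **intron** — the locus is fully contained in a single intron of some gene
  (the containing gene is its neighbor; no distance is reported);
- **orf_overlap** — any other overlap with an ORF span (exon overlap or
  straddling an ORF edge); flagged and excluded from distance summaries;
- **pseudo_utr** — outside every ORF, with nearest-boundary distance
  `d <= T`;
- **intergenic** — outside every ORF with `d > T` (strict inequality).

The distance is the 1-based coordinate difference to the nearer ORF boundary
(start or stop codon), minimised over both sides of every gene on the
locus's contig; an immediately adjacent locus has distance 1.  Distances are
strand-agnostic, since the underlying survey reports a single "distance to
gene boundary" with no 5'/3' polarity.  Equidistant genes are resolved by
the lexicographically smallest gene id so outputs are deterministic.  The
default threshold `T` = 2,000 bp encodes the rule of thumb that fungal UTRs
lie within about 2 kb of the ORF; with no UTR annotation available, the
within-threshold band is an operational "pseudo-UTR".  The adjacency = 1
convention is this package's own fixed choice: published locus tables do not
define the arithmetic precisely enough to recover it, so the same convention
is used consistently for synthetic ground truth.

All in-memory intervals are 0-based half-open; GFF3 and printed locus tables
are converted at the I/O boundary (1-based inclusive on disk), BED is native
half-open.  Printed location strings (`scaffold_59_650694–650810`) split on
the rightmost underscore because contig ids may themselves contain
underscores; both the en-dash and the ASCII hyphen are accepted between
coordinates.  Repeated identical rows in printed tables are preserved as
distinct records, and all summary counts are over rows, not unique ids.

## Word-seeded homology search

The aligner mirrors classic word-seeded nucleotide BLAST at the scale of
short RNA queries (19–250 nt) against genome assemblies:

1. **Seeding** — every exact `word_size`-mer shared between the oriented
   query (forward, and reverse complement for the minus strand) and the
   subject; the scan is exhaustive, and words containing `N` never match
   (`N` matches nothing, including `N`).
2. **Ungapped extension** — the seed is grown to its maximal exact run and
   extended in both directions under an X-drop rule (drop 20 score units
   from the running maximum stops the extension).
3. **Gapped refinement** — an affine-gap local alignment of the whole
   oriented query against a subject window spanning the ungapped segment
   plus the remaining query length and a fixed 16-bp pad.

Scores: match +2, mismatch −3, gap open −5, gap extend −2 (a gap of length
L costs `−5 − 2L`).  Hits are deduplicated per subject span and strand,
filtered by expectation value, and sorted by ascending e-value then
descending score, so results are fully deterministic.  Normalising the seed
to its maximal exact run also makes the hit set at word size `w+1` a subset
of the hit set at `w`, which the tests exploit: sensitivity decays sharply
with word size, the well-known behaviour for short miRNA-scale queries.

The expectation value is `E = K·m·n·exp(−λS)` with `m` the query length and
`n` twice the total subject length (both strands).  `(λ, K)` =
(0.6495, 0.3327) were fitted once for the default scheme by the shipped,
seeded simulation `calibrate_evalue_params` (Gumbel fit to optimal local
scores of 400 random 50×1000 pairs, seed 20160915).  The fit is approximate
— lattice scores, finite sequences — and is used only to place hits of the
same search on a common scale and to apply the acceptance cutoffs; no
attempt is made to reproduce any external tool's e-values.  Defaults:
word size 19 and cutoff 1e−3; the miRNA preset relaxes the cutoff to 1e−1
because a perfect ~21-nt match cannot reach strong expectation values.

An exact Smith–Waterman implementation with the same affine scoring (and a
deterministic traceback: diagonal preferred, then vertical, then horizontal;
global ties resolved to the smallest row-major cell) serves as the
full-sensitivity oracle.  It shares the DP core with the gapped-refinement
stage; its correctness is cross-checked in the tests against an independent
dynamic-programming implementation (Biopython's `PairwiseAligner`).  The
oracle is capped at 5 kb per sequence — it exists for verification, not
production searching.

## Conservation profiling and clustering

Each sncRNA is searched against every genome of a panel; the best accepted
hit's identity (percent matching columns, 0–100) fills the conservation
matrix, with **0 recorded when no hit passes the cutoff** — absence is
informative and is retained as the "no match" state (flagged distinctly in
heatmap exports).  Short queries (< 40 nt, the mature-miRNA scale) use the
relaxed e-value preset.

Genomes are compared by the Spearman rank correlation ρ of their identity
columns (average ranks for ties) and the dissimilarity `d = 1 − ρ ∈ [0, 2]`.
A constant column — typically an all-zero genome where nothing was found —
has undefined ρ and is assigned the maximal dissimilarity 2 to every other
genome rather than aborting the run.  Clustering is agglomerative with
average linkage (UPGMA) by default (complete and single linkage are
available), merge heights are half the inter-cluster dissimilarity, and the
resulting ultrametric tree is exported as Newick with branch lengths.  Ties
in the merge order are broken toward the lexicographically least label pair,
making the tree fully deterministic.  The `1 − ρ` transform and the UPGMA
default are this package's choices: rank correlation of identity profiles is
the comparison the survey design names, but neither the transform nor the
linkage is specified there.

## Synthetic data

The generators are pure functions of their parameters and a seed.

- `random_genome` draws i.i.d. bases at a target GC fraction (default
  0.4954, the assembly-wide GC content typical of the oyster-mushroom
  genomes this emulates); empirical GC lands within a binomial standard
  error of the target.
- `plant_genes` lays non-overlapping intron-bearing gene models left to
  right with inter-ORF gaps ≥ 500 bp and a 6-kb margin at contig ends so
  deep-intergenic placements (beyond the 2-kb pseudo-UTR band) remain
  possible.
- `plant_sncrnas` places loci to hit an exact target category and distance;
  placements are validated with the generator's own brute-force arithmetic
  (kept separate from the classifier, so truth-recovery tests are a genuine
  cross-check) and the random RNA sequence is written into the genome
  (reverse-complemented for minus-strand loci).  The default plant mix
  spans the class length spectrum — miRNA 19–23 nt, ribozyme 55,
  tRNA 71–90, snoRNA 83–110, snRNA 100–191, plus a graded 24–200 nt band —
  with pseudo-UTR distances drawn mostly within 450 bp of the ORF, the
  regime real loci occupy.
- `diverge_genome` applies Jukes–Cantor-like site-independent substitution
  (uniform over the three alternatives, no rate heterogeneity across
  sites) and optional geometric-length indels.  Planted loci are
  indel-protected by default so each locus's expected identity,
  `100·(1 − subs/len)`, is exact; a flag releases the protection for
  stress tests.

### Species panels and what rank-correlation clustering can and cannot see

`make_species_panel` diverges the reference independently into each named
species.  This is deliberately the simplest panel — but it is important to
understand its limits: because Spearman correlation is invariant to the
clade-level shift in mean identity, and independent substitution leaves
per-locus identity ranks as nearly pure noise, *independently* diverged
genomes carry almost no clade-identifying signal in their rank profiles,
regardless of how the rates are tiered.  (The only residual signal is the
length-dependent probability that a locus retains an exact 19-mer seed,
which is far too noisy to resolve clades reliably.)

Real cross-species profiles cluster by phylogeny because related species
share the divergence accumulated along their common lineage.
`make_clade_panel` therefore implements a two-stage scheme: each clade first
accumulates a shared ancestor's substitutions once, then every member
diverges independently from that ancestor.  The per-locus identity deficits
inherited from the ancestor are correlated within a clade and independent
across clades — exactly the structure UPGMA on `1 − ρ` recovers.  This is
still plain site-independent substitution (no branch-length or coalescent
machinery); it simply composes `diverge_genome` twice.

The default 6+1 panel mirrors the survey's comparison set: one conspecific
genome at ~1% divergence (the strain-level comparison, whose profile is
always the strongest), a close clade (5% shared + 1.5–2% private), a far
clade (15% shared + 5–6% private; ≥3× rate separation from the close clade
at both stages), and one basal outgroup at 40% divergence, beyond the
word-size sensitivity horizon, so its profile is essentially all-zero and it
joins the tree last at the maximal dissimilarity — reproducing the
characteristic black "no match" column of real heat maps.

## Problem sizes and numerical choices

Tests and the acceptance script run on deliberately desk-scale instances:
two to three contigs of 30–60 kb, 10–21 genes, 36–102 planted loci, and
100 seeded clustering replicates; these sizes were chosen so the whole
pipeline exercises every stage in minutes while keeping the statistical
checks (binomial bounds, 95%-of-replicates recovery) well-powered.
Percentages print with two decimals, rounding half away from zero.  All
randomness flows through `numpy.random.default_rng` seeds; same seed, same
bytes.

## Known limitations

- The synthetic genomes have no repeats, codon structure, transposons or
  compositional heterogeneity; passing recovery tests demonstrates
  correctness of the pipeline's logic, not robustness to repeat-rich real
  assemblies (where multi-copy loci produce multiple strong hits).
- The e-value model ignores gapped Karlin–Altschul corrections and
  composition bias; cutoffs are meaningful relative to this model only.
- The aligner is for short nucleotide queries; there is no protein or
  translated search, and the Smith–Waterman oracle is size-capped.
- True UTR inference, strand-aware upstream/downstream semantics and
  overlapping-gene resolution beyond nearest-distance are out of scope.
- Cross-genome conservation counts of the original survey (e.g. presence in
  all six related genomes) depend on its unpublished assemblies and are not
  reproduced at desk scale; the package instead validates the machinery
  that would compute them.
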