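# Methods

This note records the models implemented in `tnperm`, the parameter choices
that matter, and the numerical decisions taken where the design was open.

## Coordinates and input conventions

All intervals are held internally as 0-based half-open on the reference
forward strand; GFF3 (1-based inclusive) and BED (0-based half-open) are
converted only at the file boundary, so a gene `[start, end)` contains
exactly `end − start` integer positions. An insertion's `position` is the
first genome base of the transposon junction on the forward strand
regardless of read orientation; for a reverse-orientation alignment the
junction is the alignment end − 1. A *unique* insertion site is a distinct
(contig, position, strand) triple — junctions on opposite strands are
distinct transposition events and are kept separate in unique counts, while
read-level counting pools strands.

Ingestion accepts either raw (duplicate-bearing) or pre-collapsed site
tables; `collapse_sites` sums read counts per key and is idempotent, so the
two arrive at the same place.

## Per-gene scoring

Insertions are counted inside the central 80% of each gene,
`[start + floor(0.1·L), start + ceil(0.9·L))`, computed on the genomic
interval independent of strand. Trimming 10% off each end avoids crediting
a gene with "tolerated" insertions that merely truncate a few terminal
residues. The score is

    Score = log2( count / (mapped_reads · gene_length / genome_length) + 1 )

i.e. observed over expected-under-uniformity with a pseudocount of 1 inside
the logarithm. Two decisions here were genuinely open:

- **Bracketing.** The normalization could be read as
  `count/(mapped_reads · L/G)` or `(count/mapped_reads) · (L/G)`. The second
  collapses every score to ≈0 at realistic depths (counts in the hundreds
  against a ratio of ~10⁻⁹), destroying all contrast, so the first reading
  is implemented.
- **mapped_reads** is the library's total read-level events within all
  central gene windows (reads mapped in coding regions), making the score a
  within-coding-space enrichment. It follows that summing per-gene counts
  over genes reproduces the library's `insertions_80` statistic exactly —
  a cross-module invariant the tests enforce.
- **Count basis.** Scores use read-level counts by default; unique-site
  counts are available via `use_unique=True`. Read-level counting weights a
  junction by its clonal abundance, which is the quantity the survival
  model acts on.

Z-scores standardize each library across genes with the sample SD (n−1);
per-library mean and SD are 0 and 1 to 10⁻⁹ by construction, and the
per-gene `mean_Z` is the unweighted mean over libraries. Library agreement
is summarized by PCA with libraries as points and genes as features (all
components retained, so explained-variance fractions sum to 1).

## Modality diagnostic

The bimodality coefficient

    BC = (g1² + 1) / (g2 + 3(n−1)²/((n−2)(n−3)))

uses bias-corrected sample skewness g1 and excess kurtosis g2; BC > 5/9
(the uniform distribution's value) is called bimodal. A balanced two-point
mass gives BC → 1, a normal sample BC → 1/3. The coefficient was chosen
over a dip test because it is closed-form, dependency-free and entirely
adequate to separate the two regimes the simulator produces; it is a
screening diagnostic, not a hypothesis test.

## Classification

Genes are clustered on their per-library Z vectors (not on `mean_Z` alone,
which would discard the per-library structure PCA reveals). Candidates:
k-means (k = 2..6, 50 restarts, fixed seed), PAM-style k-medoids (same k
range; greedy BUILD initialisation followed by alternating medoid updates
on the Euclidean distance matrix), and DBSCAN over an eps grid of
{0.1, …, 2.0} × the median 4-NN distance with minPts = 5. The winner is the
highest average silhouette width; solutions with one cluster or only
singleton clusters have no defined silhouette and are recorded as missing.
For DBSCAN the silhouette is computed on non-noise points. If the winner
does not have exactly two clusters, group naming requires an explicit
k = 2 fallback (the error says so).

The higher-mean cluster is named **Highly permissive**, the other
**Intermediate**; the reported boundary is the mean-Z midpoint between the
closest members of the two clusters. The **Less permissive** set is the
bottom `ceil(0.2·n)` genes by mean Z (ceiling guarantees at least 20%;
2263 genes → 453). Ties at the boundary break by gene_id lexical order with
a warning. By default the shortlist is drawn from all genes; the
`within_intermediate` flag restricts the pool to the Intermediate cluster.
The shortlist is a quasi-essential candidate set, not a statistical
essentiality call — with a unimodal score density there is no defensible
mixture model to fit, which is exactly why the fixed-fraction rule exists.

## Synthetic data generator

`simdata` emulates the study conditions: a 2.12 Mb single-contig genome
densely packed with genes of mean length 955 bp, libraries of 10⁵
independent insertion clones, and read depths of a few 10⁵ per library.
Because the generator places non-overlapping genes while real compact
genomes overlap theirs, the default gene count is 2000 (coding density
0.90) rather than the organism's 2263; the study-scale analyses in tests
and the acceptance script use 1000 genes on a proportionally smaller
(1.06 Mb) genome, keeping density and per-gene coverage at study scale.

Mechanics, per clone: position uniform over the genome, with optional
hotspot windows (1 kb by default) receiving a fold-multiplied sampling
weight; strand uniform; if the position falls inside an essential gene
body the clone survives with probability `w` (default `1 − 1/c` for ploidy
`c`, forced to 0 at c = 1 because a monoploid cannot carry a heterozygous
knockout); read counts are 1 + negative binomial (size 2.0, mean 5.0 reads
per clone), with the mean scaled by the allele fraction `(c−1)/c` for
surviving heterozygous essential disruptions. Survival is a single
Bernoulli per insertion rather than an explicit multi-generation
copy-number process: one parameter suffices to create (c = 1) or remove
(c = 8) the bimodal essentiality signature, which is the mechanism under
study. The `(c−1)/c` allele-fraction scaling is likewise a minimal
modeling choice, not a measured quantity. Negative-binomial rather than
Poisson read counts reflect the overdispersion that whole-genome
amplification and PCR introduce.

One global seed drives everything; the genome and each library draw from
fixed-offset child streams, so any fixture is independently reproducible.

What the generator does **not** emulate: sequence-level reads and adapter
chemistry, amplification chimeras, operon polarity, selection during
outgrowth, multi-contig genomes (supported by the data model but not the
generator), and gene overlap. Passing tests therefore demonstrate the
pipeline's arithmetic and the ploidy mechanism's qualitative consequences,
not performance on real sequencing artifacts.

## Integration statistics

Side tables (pangenome partitions, ortholog essentiality counts, expression)
are consumed, not computed. Joins are left joins on the Tn-seq gene set;
missing values become NA (optionally a fill value such as `absent` for
partition columns) and a join report counts matches and misses — nothing is
dropped silently. A packaged 53-row table of cross-domain consensus-essential
orthologs ships with the package for cross-tabulation tests.

Spearman correlations use average ranks on pairwise-complete observations;
pairs with fewer than 10 complete observations are masked. Two-sided
p-values: exact permutation enumeration for n ≤ 8, seeded Monte Carlo
permutation (10⁴ resamples, add-one correction) for 8 < n ≤ 20 — full
enumeration is infeasible there — and the t-approximation for n > 20.
Entries with p ≥ α (default 0.01) display as "n.s.". When only partition
labels exist, correlation uses the ordinal coding persistent = 3, shell = 2,
cloud = 1, absent = 0; when family sizes (isolate counts) are available they
should be used directly.

Category enrichment is a one-sided Fisher exact test (hypergeometric upper
tail) per category with Benjamini–Hochberg FDR across categories.

## Library-design arithmetic

`N = ceil( ln(1−P) / ln(1−f) )` with `f = gene_length/genome_length`; the
ceiling guarantees the achieved coverage probability is at least P, and the
inverse `P = 1 − (1−f)^N` is exposed for self-checks. Direct evaluation at
P = 0.9999, gene 955 bp, genome 2.12 Mb gives N = 20,442; a published figure
of ~2.3 × 10⁴ colonies for these parameters is about 12% above the formula's
value and is treated as a documented discrepancy, not an oracle.

## Hotspot detection

No standard rule exists for "insertion hotspot"; windows are flagged when
their mean coverage exceeds the median + k·MAD (raw MAD, k = 5 default)
across all windows. With ~10³ windows this threshold (~3.4σ under
normality) admits occasional false positives; flags mark candidates for
inspection, not calls.

## Problem sizes

The distribution-level tests and the acceptance script run the simulator at
1000 genes × 4 libraries × 10⁵ clones (and a lighter 500 × 2 × 5·10⁴
variant), sizes at which the bimodality margins are wide (BC ≈ 0.95 vs
≈ 0.38 across seeds against the 5/9 threshold) and a full run completes in
seconds on one core.

## Known limitations

- PAM uses the alternating (Voronoi-style) medoid update after a greedy
  BUILD, not the full O(k(n−k)²) swap search; on well-separated data the
  two agree, and the silhouette comparison — not the optimizer — carries
  the model selection.
- The bimodality coefficient can miss bimodality in strongly skewed
  mixtures; here the monoploid regime produces a far-below-threshold
  essential mode, where the coefficient is reliable.
- `library_stats` totals count a site once per overlapping gene window, so
  with overlapping annotations the library totals can exceed the number of
  distinct events (consistent with the per-gene table, which is the design
  goal).
- The unique-insertions ratio depends on clonal read depth by construction
  (its denominator is read-level), so it is comparable across libraries
  only at similar depth; the per-million column is the depth-adjusted one.
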