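# Methods

## The analysis model

The package targets methylomes in which 5mC is sparse and gene-body
centred. Its unit of observation is the strand-specific CpG: a cytosine in
CG context with a methylation level *m* ∈ [0, 100] (percent of reads
methylated) and read counts (n_meth, n_total). Both strands of a CpG are
kept as distinct sites throughout — genome-wide CpG counts therefore count
each CG dinucleotide twice — with an optional `destrand` merge (counts
summed) off the default path.

Classification uses strict thresholds: methylated iff *m* > hi (default
80), unmethylated iff *m* < lo (default 20), intermediate otherwise.
Values exactly at a threshold are intermediate: the boundary rule is
stated explicitly because sources describing such filters often mix
"below/above" and "</>" phrasing; strict inequality makes the three-way
partition unambiguous and is asserted by tests.

Genomic context is single-valued per CpG with precedence
promoter > exon > intron > intergenic over the union of all transcripts,
matching the behaviour of common annotation toolkits. "Promoter" is the
2,000 bp strand-aware window upstream of the TSS; the width is a parameter
(`promoter_len`) because no universal definition exists, and 2 kb matches
the flank width used for the gene heatmaps. Intergenic CpGs are further
split TE / non-TE repeat / repeat-free, with transposons taking priority
on double overlap.

Metaplots rescale regions of unequal length to B equal bins
(bin = ⌊B·d/L⌋, d the strand-aware distance from the 5′ end, clamped to
B−1; genes use B = 30, repeats B = 15). Reversing a region's strand
reverses its bin vector. Values are pooled **per bin across all regions**
and winsorized at that pooled bin's 1st–99th percentiles (linear
interpolation) before averaging; pooling granularity is a design choice
documented here and pinned by a brute-force-equivalence test. The 95% band
is the normal approximation 1.96·sd/√n computed on the clipped values
(CI on winsorized rather than raw values is the second of the two
defensible readings and is the one implemented), zero for n ≤ 1. With
winsor limits (0, 100) the winsorized mean is exactly the arithmetic mean.
Flanked matrices use fixed-width flanks (2,000 bp in 20 windows of 100 bp,
`flank_bins` exposed because flank resolution is purely presentational)
around the length-scaled body.

## Methylation patterns

The clustering input is the body-only (TSS→TTS) per-transcript mean of
covered-CpG methylation — not the flanked display matrix — with
`min_cpgs = 1` as the default inclusion rule (parameterized; transcripts
with no covered CpG are excluded and reported). One-dimensional k-means
with k = 4 is run as Lloyd's iterations from classic k-means++ seedings,
best of 10 restarts by within-cluster sum of squares, followed by a
boundary-transfer polish: in 1-D every k-means solution is an interval
partition of the sorted values, so single-point transfers across adjacent
boundaries (accepted while they reduce the SSE, in the spirit of
Hartigan–Wong, the default of R's `kmeans`) cheaply escape the shallow
local optima that plain Lloyd is prone to on unstructured data. On random
instances of ≤ 50 points the polished best-of-10 solution matches the
exact dynamic-programming optimum in every tested case; the DP solver
lives in the test suite as an independent oracle. Clusters are relabelled
1..k by strictly descending center (a non-strict ordering raises a
degeneracy error, as does input with fewer than k distinct values), and
every transcript is assigned to its nearest ordered center with ties
breaking toward the smaller (more methylated) label. Cross-sample
comparison fixes the reference sample's labels and merely regroups other
samples' means under them — no re-clustering.

## Expression integration

Expression enters as TPM and is analysed as e = log2(TPM+1). Percentile
curves rank transcripts by e (average ranks on ties, residual ties broken
by transcript id), cut them into equal-frequency groups (sizes differing
by at most 1) and average body methylation per group. Pattern–expression
differences use Kruskal–Wallis plus Dunn's pairwise z tests on the pooled
ranks with tie correction, Bonferroni-adjusted over pairs by default
(`fdr_bh` selectable); patterns with fewer than two expressed members are
dropped from the pairwise stage with a warning. Tissue transcriptomes are
clustered on row z-scores of e with Euclidean distance and complete
linkage (linkage is a parameter; complete is the default of the heatmap
tooling this reproduces), the tree cut to k = 13 by default; zero-variance
rows are excluded and reported. Top-n overlap breaks TPM ties by
transcript id for determinism. GO over-representation is the upper-tail
hypergeometric probability per term with Benjamini–Hochberg adjustment
across tested terms; the universe defaults to all genes carrying at least
one term (parameterized, since over-representation is sensitive to the
universe), and the reported `gene_ratio` is observed/expected with
expected = n_list·K/N.

## The synthetic-data generator

The generator emulates the statistical structure the analysis assumes,
not the sequence biology producing it:

* **Layout.** 8 scaffolds × 7 Mb; 2,000 non-overlapping genes of 1,200 bp
  (3 equal exons, 2 introns) with 2 kb repeat-free margins; transposons
  (400 DNA, 300 LTR, 400 LINE, 200 SINE of 500 bp), 60 satellite arrays
  (1.5 kb), 150 simple repeats, 100 other repeats, all placed uniformly in
  the remaining intergenic space. CpG-start rates: 0.006/bp intergenic,
  0.015/bp gene bodies, 0.012/bp repeats — gene bodies and repeats are
  CpG-enriched, and ~84% of CpG sites end up intergenic by construction.
  Sequences are materialized lazily (CG dinucleotides exactly at the
  planted sites, filler bases never forming CG) since most analyses need
  only coordinates.
* **Methylation truth.** Four gene archetypes with weights
  (0.142, 0.233, 0.170, 0.455) and methylated-segment levels
  (0.75, 0.75, 0.60, 0.02), per-gene scatter sd 0.05 on the level. MP1 is
  methylated across promoter, body and downstream; MP2 lacks methylation
  over promoter and the first third of its body CpGs; MP3 over the first
  half, with its 3′ half (and downstream) at 0.60; MP4 is unmethylated
  throughout. Low segments are assigned over each gene's **body CpG sites**
  (first ⌈frac·n⌋ from the 5′ end) rather than by base-pair cutoff: with
  ~18 CpG sites per gene a bp cutoff would make the realized low-segment
  share binomially noisy (several points of body-mean scatter), blurring
  the archetype separation the recovery analyses rely on. The realized
  archetype body means are ~75 / 51 / 31 / 3 percent. Repeats sit at 0.05
  (TEs) and 0.15 (satellites — the deliberately higher exception), open
  intergenic space at 0.03. Per-CpG truth p_true is drawn from a Beta
  centred on the positional level with concentration ν = 12; this CpG-level
  heterogeneity is what produces the ~7–8% intermediate band and the
  <10%-methylated regime.
* **Read simulation.** Per strand and sample: depth c ~ Poisson(30 for
  WGBS, 40 for RRBS), methylation probability q ~ Beta(p_true, ν = 200),
  n_meth ~ Binomial(c, q); depth-0 draws are unobserved. RRBS is modelled
  as random retention of 3% of CpG sites — sparsity is what matters
  downstream, not MspI fragment chemistry. Both strands share p_true but
  draw independently.
* **Expression.** Expected log2(TPM+1) rises logistically with true body
  methylation (floor 0.5, span 5.5, midpoint 25%, scale 12), giving
  MP1/MP2 high expression in all tissues, MP3 intermediate, and a
  mid-range band (~1.5–4.5 log2(TPM+1)) where expression increases with
  methylation. MP4 genes are additionally zero-inflated: 55% fully silent,
  the rest bursting in random ~35% tissue subsets. Per-gene noise sd 0.8,
  per-tissue sd 0.3, 13 tissues.
* **Determinism.** All randomness flows from `GeneratorConfig.seed`
  through named child generators (CRC-derived spawn keys); equal configs
  give byte-identical outputs.

What the generator does **not** emulate: real sequence composition and
CpG-island structure, bisulfite conversion failure, mapping bias,
fragment-level RRBS coverage correlation, overlapping/nested gene models,
and biological correlation between neighbouring CpGs beyond the shared
site probability. Tests passing on this generator therefore demonstrate
the correctness and calibration of the *pipeline*, not the biology of any
particular genome.

## Numerical choices and degenerate inputs

Percentiles use numpy's linear interpolation. Winsorized-mean CI is 0 for
n ≤ 1; empty bins report NaN means with n = 0. Classification at exactly
lo/hi → intermediate. `join_common_cpgs` of an empty intersection returns
an empty matrix; duplicate sample names get numeric suffixes.
Down-sampling is uniform without replacement with an explicit seed.
Zero-length transcripts are excluded from length statistics with a
warning; zero-variance rows from z-scoring; empty genomes count 0 CpGs
with a warning. Bismark coverage rows carry no strand: with a genome the
strand is resolved by base lookup, otherwise recorded as "+" with a
`strand_resolved = False` flag (no downstream analysis needs RRBS strand).
CGmap depth filtering defaults to min_total = 1 (deposited whole-genome
CGmaps are typically depth-handled upstream) and is a parameter on every
reader; the coverage reader defaults to min_total = 10, the standard
reduced-representation filter.

## Problem sizes

The default synthetic study — 56 Mb, ~360k CpG sites (~720k strand rows),
2,000 genes, 13 tissues — was chosen so that archetype recovery is
measured at realistic WGBS depth while a full end-to-end run (generation,
simulation, analysis) completes in well under a minute; the test suite
uses smaller layouts (40–200 genes) for oracle-equivalence checks where
brute-force references are quadratic.
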