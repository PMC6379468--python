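# Methods

This note records the models, conventions and design choices behind each
pipeline stage, the parameters that matter, and what the synthetic-data
generators do and do not emulate.

## Coordinates and formats

All intervals are 0-based half-open internally. BED is consumed natively;
VCF positions are converted on load and restored on write. Depth tables
follow the samtools-depth dialect (`contig <TAB> 1-based pos <TAB> depth`);
positions absent from the table are depth 0.

## Presence calling

A locus is present in a sample iff its depth profile contains ≥ `min_run`
(default 30) consecutive positions each with depth ≥ `min_depth` (default
5), counting only reads with mapping quality strictly greater than 20 and
only aligned (M/=/X) bases — soft-clipped bases never contribute. The depth
threshold is inclusive ("five reads of depth" = depth ≥ 5) and the MAPQ
cut is strict, the most literal reading of the criterion. The MAPQ filter
is applied before the run test. Loci shorter than `min_run` are callable
(always absent) with a warning rather than an error, because annotated
integrations can be short. Only the leftmost maximal qualifying run is
reported; presence needs just one. The call is monotone in depth and
anti-monotone in both thresholds, which the property tests exploit.

Prevalence divides the number of detected loci of a viral family by the
family's *annotated* total (40 Rhabdovirus-like, 32 Flavivirus-like in the
reference annotation), not by the loci present in the matrix.

## Variant consensus and LoP

Cross-caller matching requires a common key. Records are normalized by
(1) trimming shared trailing bases, (2) left-shifting indels through the
reference context when a reference lookup is available (without one,
alleles stay in their anchored representation and only shared prefixes and
suffixes are trimmed), (3) trimming shared leading bases, and (4)
decomposing equal-length multi-nucleotide substitutions into per-base
SNPs. Per-base keys maximize cross-caller agreement because callers
disagree on MNP packing and indel anchoring.

The consensus allele frequency is the **median** of the reporting callers'
non-missing AFs — robust to a single outlier caller. AF precedence when
loading a VCF: the `AF` INFO field, else AD/DP of the first sample, else
missing. The retention rule is the disjunction *AF > 0.1* (strict) *or*
*≥ 2 callers*; a variant with missing AF can therefore still be retained
through the caller arm.

LoP = retained events / locus length, events per bp; an indel counts once
regardless of span. Loci absent in a sample carry a missing LoP cell, not
zero, and missing cells are excluded from that locus's distribution. The
table is per-sample; aggregation happens in the statistics stage.

## Statistics

The locus-vs-slow-gene comparison is a **two-sample** KS test: the locus's
LoP values across samples against the per-sample SG reference (the median
LoP over SG loci in that sample). A one-sample test against a point mass
would make the D statistic degenerate. P-values are asymptotic; the D
statistic itself is exact and is verified against a brute-force ECDF sup.
Fold change is the ratio of medians; a locus of all zeros yields FC 0 with
`log2FC = -inf` as an explicit sentinel, and a zero reference median is an
error rather than an infinity.

Bonferroni: the per-test threshold is α/m with α = 0.05 and m the number
of tested loci. Note that −log10(0.05/99) = 3.297.

Enrichment of the core set is a one-sided (upper-tail) hypergeometric
test, P(X ≥ k), per annotation level over four partitions: viral family,
viral ORF, length (loci of exactly 500 bp count as "short"; the dichotomy
covers every locus), and genomic context.

## Integration age

The two published display equations for this estimator are dimensionally
inconsistent if "mean mutations per sequence" is read per-site (the
alignment length would divide twice). The package adopts the dimensionally
consistent reading:

    mean_mut = tot_mut / n_seqs
    age      = mean_mut / (MR × L × GpY)

where MR × L is mutations per sequence per generation, so the quotient is
in years. All gap-containing columns are removed before counting; mutations
are counted per sequence against the majority-rule consensus (a proxy for
the ancestral state). Ties go to the earliest sequence's base; `N` never
counts as a mutation and never wins the consensus. A designated reference
sequence can replace the consensus via a flag. All mutations are assumed
neutral — no selection or saturation correction is applied, so estimates
are slightly biased downward when the expected per-site load is
non-negligible (about 3% at 0.05 substitutions/site).

Grid defaults: MR ∈ [3.5 × 10⁻⁹, 8.4 × 10⁻⁹] per site per generation
(Drosophila-like rates) and GpY ∈ [4, 17] (temperate to tropical mosquito
generations per year). The youngest bound uses the fastest clock
(max MR × max GpY), the oldest the slowest.

## Shared-allele distance and trees

Populations are treated as pooled multi-allelic profiles (≥ 5 amplicons per
population per locus in the motivating design), so the per-locus sharing
term is the Dice coefficient of allele sets rather than the diploid
individual-level variant:

    DAS(A,B) = 1 − (1/L) Σ_l 2|A_l ∩ B_l| / (|A_l| + |B_l|)

Locus absence is an explicit `null` allele, shared between two populations
that both lack the locus — absence is informative under presence/size
scoring. DAS is a bounded semimetric (symmetric, zero on the diagonal,
range [0, 1]); it does not satisfy the triangle inequality in general.

Neighbor joining follows Saitou–Nei exactly (Q-criterion, standard branch
lengths, trifurcating unrooted output). Negative branch-length estimates
are clamped to zero with the deficit transferred to the sister branch.
Q-ties break on the smallest index pair, making the procedure
deterministic. On any additive matrix the output tree reproduces the input
distances exactly; the tests verify this by regenerating patristic
distances, and cross-check against an independent NJ implementation.

Bootstrap: loci are resampled with replacement from a single seeded stream;
the support of an internal edge is the fraction of replicate trees
containing its bipartition. The main tree always comes from the full table.
Default 1000 replicates.

## Evolutionary-rate ranking

Smith–Waterman local alignment with BLOSUM62 and BLAST-convention affine
gaps (a gap of length k costs 11 + k × 1); all three constants are
configurable. Identity = identical aligned residue pairs / alignment
columns, **including** gap columns (a flag switches the denominator to the
shorter sequence length). Group divergence is the unweighted mean identity
over all cross-species member pairs, normalized by the mean identity of
all interspecies best-reciprocal hits; BRH ties break lexicographically by
sequence id. Tail selection takes ceil(0.001 × N) groups per tail with
deterministic id tie-breaks and refuses overlapping tails.

## Chimera screening

"More than 80% in mono- and di-nucleotides" is operationalized as the
largest fraction of sequence positions covered by tandem runs (≥ 2
consecutive copies, partial trailing copies included, any phase) of a
single 1-mer or heterogeneous 2-mer unit. This is one defensible reading of
an informal metric; the threshold and the definition's unit set are
configurable, and the implementation is verified against an exhaustive
substring oracle. Rejection requires strictly > 0.8; a candidate at exactly
0.8 is retained, and a viral segment of exactly 50 nt passes the length
rule. The soft-clip consensus constants (`min_clip_len` 20, `min_support`
3, `consensus_frac` 0.8) are plumbing defaults for a step that was
originally manual inspection; all are exposed as flags.

## Synthetic data

The generators produce the statistical structure each stage assumes, at the
motivating study's design scale by default: 16 samples; 72 loci (32
Flavivirus-like, 40 Rhabdovirus-like; lengths 151–3206 bp) with 20 planted
core and 11 planted universally absent, the core biased toward
Rhabdovirus/exon annotations so the enrichment tests have signal; mean
sequencing depth 30× (a realistic single-insect WGS coverage); four
callers at sensitivity 0.9 with Poisson false positives at sub-threshold
AFs (0.01–0.09) and Gaussian AF noise (sd 0.05); per-locus mutation
densities log-uniform over 0.0004–0.0258 events/bp (the magnitude range of
observed integration-locus polymorphism), with slow-gene loci planted at
0.0071; five populations in two divergence clusters; 5-species proteomes
with per-group substitution rates spanning 0 to 0.3 plus heavily diverged
paralog decoys; and chimera candidates whose decoys each violate exactly
one screening rule.

Each generator derives its RNG stream from the top-level seed plus a fixed
stream id, so outputs are byte-reproducible and adding a generator never
shifts another's draws. One caller intentionally emits indels in a padded,
unnormalized representation to exercise left-normalization end to end.

What the generators do **not** emulate: read-level sequencing error and
mapping artifacts, transposon background, linkage between variants,
population admixture or gene flow, indel realism in alignments (the
default age simulation is substitution-only, with an optional gap mode via
the alignment filter), and genome-scale proteomes. Passing tests therefore
demonstrate correctness of the computations and recovery under idealized
noise models, not robustness to real sequencing pathologies.

## Problem sizes and numerical tolerances

The test suite runs the statistical recovery checks at reduced but
informative sizes chosen for tight bounds: age recovery with 16 sequences
of 2000 bp at a planted age of 10⁶ years (3 SE ≈ 75,000 years), LoP
recovery within 3 binomial SEs on ~3 kb loci, bootstrap support ≥ 0.95 at
200 replicates on a strongly diverged two-cluster design, and exhaustive
oracles capped where enumeration is exact (hypergeometric N ≤ 12, filter
pools of 12 variants, peptides ≤ 12 residues). The acceptance script runs
the full 16-sample, 86-locus (72 + 14 slow-gene) design with 1000
bootstrap replicates.

## Known limitations

- The indel left-normalizer requires a reference lookup for full
  left-alignment; VCFs merged without one rely on anchored trimming only.
- Asymptotic KS p-values are approximate below ~10 observations per side;
  the D statistic is exact.
- The age estimator ignores multiple hits and back-mutation (neutral
  infinite-sites approximation) and treats the consensus as the ancestor.
- DAS trees from pooled allele profiles are not comparable to
  individual-genotype DAS implementations.
- The low-complexity metric is a tandem-repeat coverage, not an entropy
  measure; sequences that are compositionally biased but non-tandem score
  low.
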