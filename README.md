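# nirvspipe

Tools for characterizing **non-retroviral integrated RNA virus sequences
(NIRVS)** — fragments of *Flavivirus*- and *Rhabdovirus*-like genomes
endogenized in mosquito genomes — from whole-genome resequencing of
individual mosquitoes and from population amplicon surveys.

The package is aimed at arbovirus-vector genomicists who have a set of
annotated integration loci and want to know, per individual and per
population: which integrations are actually there, how polymorphic each one
is relative to the host gene background, how old the integrations are, and
how their allele content structures natural populations.

## What it computes

**Presence calling.** A locus is called present in a sample when its
mapping-quality-filtered depth profile (MAPQ > 20) contains a run of at
least 30 consecutive positions with depth ≥ 5. From the loci × samples
matrix the pipeline derives the *core* set (present in every individual),
the universally absent set, and per-family prevalence (detected / annotated
loci of that family).

**Level of polymorphism (LoP).** Calls from four variant callers are
left-normalized onto shared keys and merged; a variant is retained when its
allele frequency exceeds 0.1 *or* at least two callers report it. For a
region of length *L* with *k* retained SNPs and indels,

    LoP = k / L        (events per bp)

**Comparison statistics.** Each locus's LoP distribution across samples is
compared with a per-sample slow-gene (SG) reference — the median LoP of the
SG set — by a two-sample Kolmogorov–Smirnov test, with fold change
FC = median(locus)/median(SG), Bonferroni-adjusted significance and a
volcano table. Core-set composition is tested for enrichment (viral family,
viral ORF, the 500-bp length dichotomy, genomic context) with a one-sided
hypergeometric test.

**Integration age.** After removing all gap-containing alignment columns
and counting mutations against the majority-rule consensus,

    age (years) = (tot_mut / n_seqs) / (MR × L × GpY)

scanned over a mutation-rate grid MR ∈ [3.5, 8.4] × 10⁻⁹ per site per
generation and GpY ∈ [4, 17] generations per year.

**Population structure.** Per-population allele sets (size classes plus an
explicit `null` allele for absence) give a shared-allele distance

    DAS(A,B) = 1 − (1/L) Σ_l 2|A_l ∩ B_l| / (|A_l| + |B_l|)

from which Saitou–Nei neighbor-joining trees are built with bipartition
support from 1000 locus bootstraps.

**Evolutionary-rate ranking.** Ortholog groups are scored by mean
interspecies Smith–Waterman identity (BLOSUM62, affine gaps) normalized by
the mean identity of all interspecies best-reciprocal hits; the extreme
0.1% tails mark slow- and fast-evolving genes.

**Chimera screening.** Host–virus chimeric read candidates are rejected
when the viral segment is shorter than 50 nt or more than 80% of it is
covered by mono-/di-nucleotide tandem repeats; soft-clipped read tails
anchored at locus boundaries are collapsed into consensus extensions.

A seeded synthetic-data generator (`nirvspipe.simulate`) produces all of
these inputs with planted truth, so the full pipeline is testable without
any sequencing data.

## Worked example

Generate a miniature dataset (4 samples, 10 loci) and run three stages:

```
$ nirvspipe simulate --seed 11 --n-samples 4 --n-flavi 4 --n-rhabdo 6 \
      --n-core 3 --n-absent 2 --out demo/fixtures
fixtures written to demo/fixtures

$ nirvspipe presence --bed demo/fixtures/loci.bed \
      --depth-tsv demo/fixtures/depth/SSM1.tsv ... --out demo/presence
4 core loci, 2 universally absent

$ nirvspipe age --alignment demo/fixtures/locus_alignment.fasta --out demo/age
n=16 L=2000 tot_mut=1573 age 344231-3511161 yr

$ nirvspipe popgen --alleles demo/fixtures/population_alleles.csv \
      --bootstrap 200 --seed 11 --out demo/popgen
((China:0.0384615,Thailand:0.0641026)0.56:0.0128205,LaReunion:0.0641026,(Italy:0.0897436,USA:0.0897436)1:0.846154):0;
```

Reading the output: the presence stage found 4 loci covered by a
≥ 30-nt run of ≥ 5× depth in all four samples and 2 loci in none (both
match the planted design). The age stage counted 1573 mutations across 16
sequences of a 2000-bp gap-free alignment; dividing the 98.3 mean
mutations per sequence by MR × L × GpY at the grid corners brackets the
integration between ~0.34 and ~3.5 million years (the alignment was
simulated at a true age of 1 Myr with MR = 5 × 10⁻⁹, GpY = 10, inside the
grid). The tree separates the two planted population clusters
(Italy + USA vs the rest) with bootstrap support 1.0 on the long internal
branch; the shallow within-cluster split has support 0.56, as expected
when within-cluster drift is weak.

Each subcommand writes a `manifest.json` capturing every materialized
parameter, so a run can be replayed exactly.

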