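# isohap

Genomic scans for locating a colour-associated autosomal haplotype from
**Iso-Y breeding lines** (pooled sequencing) and a **sexed natural
population** (individual whole-genome genotypes), with a synthetic-data
generator that makes the whole chain verifiable against planted truth.

The package is aimed at population geneticists working with guppy-style
breeding designs: several lines propagated through males carrying one
founder's colour pattern, repeatedly backcrossed into a stock population so
that everything *except* the selected region is homogenised (after *g*
backcross generations only (1/2)^*g* of the founder genome remains).
Differentiation that is consistent across all line pairs then points at the
colour-linked region, and the source population can be dissected for the
same haplotype.

## What it computes

**Pool-seq side** (per-pool ref/alt read counts, `poolstats`, `zscan`,
`segment`, `bands`):

- Site filters (coverage bounds, allele support, pooled MAF) and pooled
  allele frequencies p̂ = alt/coverage.
- Pairwise F_ST per SNP with a two-level ANOVA (method-of-moments)
  estimator in which the effective chromosome number
  ñ = c·n/(c+n−1) replaces the sample size (c = read depth, n = pool
  chromosomes); multi-locus values are ratio-of-sums. Pooled π with the
  c/(c−1) small-sample correction.
- Z-normalisation of the SNPs × comparisons F_ST (or π) matrix and a
  SNP-wise PCA of it: PC1 scores measure *consensus* differentiation, and
  per-chromosome summaries report the mean score and the fraction of SNPs
  above the genome-wide 95% quantile.
- Change-in-mean detection (binary segmentation, SIC penalty β = 2·log n)
  on polarised allele frequencies and PC1 scores, and consensus-region
  delineation across lines (clustered changepoints, innermost bounds).
- Allele frequencies polarised to a reference line's major alleles, kernel
  density mode detection, and closed-form prediction of the AF "bands"
  implied by a nested-haplotype pool composition (a copies of A1, b of A2,
  c of B in T chromosomes: A-shared sites band at (a+b)/T, A1-private at
  a/T, flipped classes at 1−b/T and 1−c/T).

**Natural-population side** (diploid, optionally phased genotypes,
`natscan`, `localpca`, `phasing`):

- Windowed intersex statistics: Hudson-type F_ST, d_xy, per-sex π and
  D_a = d_xy − π_female (negative D_a = male diversity deficit), with
  quantile outlier windows.
- Hardy–Weinberg expected genotype-class counts and a chi-square audit.
- LD r² matrices on 5-kb-thinned SNPs, within or between chromosomes.
- Local-ancestry scan: per-window genotype PCA, Frobenius distances between
  window covariance approximations, classical MDS, trimmed-3σ outlier
  windows, and ≥3-adjacent-window outlier regions.
- Phased haplotypes polarised against a reference line, phase-switch
  breakpoints at run boundaries (midpoint convention), and conserved
  breakpoints (≥2 individuals within 50 kb) with per-sex support counts.

**Phenotype side** (`permtest`): PCA reduction of colour-measurement
matrices, distance-based PERMANOVA (pseudo-F with permutation p-values,
(1+count)/(B+1) convention), and two-tailed permutation tests on the trace
of the within-line covariance.

**Simulator** (`sim`): a focal region carrying three divergent haplotypes
related as an ancestral-A → (A1, A2) split plus a distant B haplotype, with
per-class SNP densities; pooled lines with arbitrary diplotype
compositions, Poisson coverage and binomial read sampling; a sexed
population with per-sex diplotype frequencies, recombinants at weighted
crossover hotspots and genotyping errors — everything accompanied by a
`TruthSet`.

## Worked example

Simulate the default study (four pools of 48 males — one line fixed for a
derived haplotype — and a 26-individual sexed population) and scan it:

```bash
isohap simulate --seed 11 --coverage 100 --outdir sim
isohap poolscan fst sim/pools.tsv --out fst.tsv --no-filter
isohap zscan fst.tsv --out-scores scores.tsv --out-summary summary.tsv
```

which prints

```
IsoY6-IsoY8     global_fst=0.0842
IsoY6-IsoY9     global_fst=0.1296
IsoY6-IsoY10    global_fst=0.0855
IsoY8-IsoY9     global_fst=0.1211
IsoY8-IsoY10    global_fst=0.0945
IsoY9-IsoY10    global_fst=0.1449
PC1 variance: 39.6%
```

Multi-locus F_ST is highest for every comparison against the fixed line
(IsoY9), and Z-F_ST PC1 — explaining 39.6% of the variance across the six
comparisons — loads all strongly differentiated pairs with one sign, so its
top-scoring SNPs mark the region where the lines are *consistently*
different. `summary.tsv` reports, per chromosome, the mean PC1 score and
the fraction of SNPs above the genome-wide 95% quantile (3.43 here).
Downstream, `isohap cpd` turns polarised AFs + PC1 into consensus region
bounds, `isohap bands` reports AF modes per line (the fixed line unimodal
at 1.0; segregating lines bimodal/trimodal with bands that do not sum
to 1), and `isohap localpca` / `isohap breakpoints` dissect the natural
population.

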