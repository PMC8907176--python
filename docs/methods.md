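# Methods

This note documents the models, estimators and numerical conventions behind
`isohap`, the defaults and why they were chosen, and what the synthetic data
does and does not emulate.

## The breeding-design model

An Iso-Y line fixes a male colour phenotype through the patriline while
repeated backcrossing into a stock population randomises the rest of the
genome: after *g* backcross generations the expected residual founder
fraction is (1/2)^*g* (`breeding`), below 0.01% for *g* ≥ 14. Consistent
differentiation among several such lines therefore localises the selected
region. The simulator encodes the inferred haplotype structure of such a
region as a three-tip tree: an ancestral A lineage that split into derived
versions A1 and A2, plus a distant B haplotype. Region SNPs fall into four
disjoint classes by the branch on which the derived allele arose
(`A_shared`, `A1_private`, `A2_private`, `B_private`); each class has a
per-kb density. A pool containing a/b/c chromosomes of A1/A2/B then shows
its allele frequencies concentrated at class-wise "bands", which is what the
band-prediction and mode-detection machinery closes the loop on.

## Synthetic data: what it emulates, what it does not

Defaults (chosen once as the study conditions, at desk scale):

| parameter | default | rationale |
|---|---|---|
| chromosome / region | 25 Mb, 12.0–13.5 Mb | region a ~6% minority of SNPs, as a focal region on a real chromosome |
| class densities (per kb) | 0.7 / 0.3 / 0.3 / 0.7 | shared > private (longer stem branch); free parameters — divergence per kb is not empirically constrained |
| background density | 2.0 / kb (~50k SNPs total) | matches the region densities so SNP spacing is continuous across the bounds, which changepoint localisation needs |
| background AFs | Beta(0.8, 0.8) | U-shaped site-frequency spectrum typical of population resequencing |
| line drift | Balding–Nichols, F = 0.09 | the genome-wide differentiation level of the emulated four-line design |
| pools | 4 × 48 males, equal contribution | wet protocol normalised DNA; Dirichlet(α) option for unequal contribution |
| coverage | Poisson(λ), λ = 100 (scans) / 150 (band densities) | the two coverage conditions used throughout |
| reads | Binomial(c, q), with replacement | standard pool-seq assumption; justifies ñ = c·n/(c+n−1) |
| natural population | 16 females, 10 males | females HWE at carrier frequency 0.7; males all carriers (the planted male HOM-REF deficit) |
| recombinants | fraction ρ per haplotype, crossovers at weighted hotspots | conserved-breakpoint structure; ε flips phase alleles (genotype error) |

Not emulated: linkage disequilibrium among background SNPs (they are drawn
independently, so background LD is pure sampling noise at the 1/n level),
elevated SNP density inside the region, mutation/sequencing error at the
base level, and multi-generation pedigree structure. Passing recovery tests
therefore demonstrates that the estimators find planted structure under
realistic sampling noise — not that they are robust to background LD or
reference bias in real data.

## Estimators and numerical conventions

**Pooled F_ST** (`poolstats`). Two-level ANOVA with r = 2 pools: with
ñ_i = c_i·n_i/(c_i+n_i−1),

    MSP = Σ ñ_i (p̂_i − p̄)²,  p̄ = Σ ñ_i p̂_i / Σ ñ_i
    MSG = Σ ñ_i p̂_i(1−p̂_i) / Σ (ñ_i − 1)
    n_c = Σñ_i − Σñ_i²/Σñ_i
    F_ST = (MSP − MSG) / (MSP + (n_c − 1)·MSG)

Per-site estimates may be negative and are not clamped; multi-locus values
are Σnum/Σden over sites (ratio-of-sums), with num = den = 0 sites (both
pools fixed for the same allele) excluded. As c → ∞ the estimator reduces
to the classic allele-count Weir–Cockerham form, which an independently
coded implementation cross-checks to 1e-12. Pooled π uses the read-depth
correction c/(c−1) by default; an n/(n−1) pool-size variant is selectable.
The pooled-MAF site filter weights pools by read counts (a mean-of-AFs
variant would weight pools equally; count-weighting uses the data that
exist).

**Z-score PCA** (`zscan`). Columns (comparisons) are standardised
genome-wide over SNPs complete in every comparison; subsetting to one
chromosome is a re-run on the subset, not a separate code path. The PCA is
an SVD of the re-standardised matrix; each component's sign is fixed so the
sum of its loadings is non-negative (majority direction, tie-broken by the
first nonzero loading). This orients consensus components so shared
outliers score positively even when one weakly differentiated pair loads
near zero or negative — which the default line design produces, since two
of its lines share segregating haplotypes. Quantile thresholds use the
type-7 (linear interpolation) estimator.

**Changepoints** (`segment`). Gaussian mean-change cost on the
variance-normalised series; a split is accepted iff it reduces cost by more
than β = k·log n with k = 2 (one mean + one location per changepoint —
the criterion family names the penalty, not the constant). Splitting is
best-first with leftmost tie-breaking, at most Q = 5 splits, automatically
re-run with Q = 10 when the budget is exhausted. Changepoint bp positions
use the midpoint between flanking SNPs. Consensus regions: single-linkage
clustering of all series' changepoints at 100 kb; clusters supported by ≥2
distinct series are boundaries; consecutive boundaries delimit candidates
using the innermost member positions (the smallest delimitable region — the
minimum unit of inheritance); a candidate is kept iff ≥2 series shift their
mean inside it by more than 1 sd of their outside values, which discards
the undifferentiated gaps between two genuine regions. The innermost rule
inherits the most-inward per-series estimation error (typically one to two
inter-SNP gaps), the price of never over-extending the region. The penalty
is on the normalised scale; no affine invariance is claimed.

**AF bands** (`bands`). Polarisation flips sites where the reference
pool's alt frequency is < 0.5 (ties left unflipped, deterministically).
Mode detection uses a Gaussian KDE with Silverman bandwidth computed on the
original sample and boundary correction by reflection about 0 and 1; modes
are maxima ≥5% of the peak density, merged when closer than 0.05 (grid
ripple within one band). Band predictions report both the raw derived-allele
frequency per class and its polarised value; the closure test (detected
modes vs predicted bands on simulated pools) uses the polarised values,
which is the internally consistent pairing with the polarisation rule.

**Intersex statistics** (`natscan`). Hudson-type F_ST with n/(n−1)
sample-size corrections (a Weir–Cockerham variant is out of scope here;
the Hudson form is insensitive to unequal group sizes). F_ST windows
average per-site values; d_xy and π windows are per-bp sums over the full
fixed window width (no accessibility mask is modelled, and the final window
is not truncated). D_a = d_xy − π_female; negative values mean male
diversity deficit. Genotype-level site filters: missingness ≤ 50%, MAF ≥
10% (read-depth bounds act upstream of genotypes and are not re-applied
here). LD thinning keeps the first SNP per 5-kb bin (deterministic); r² is
the squared Pearson correlation of dosages over pairwise-complete samples.

**Local PCA** (`localpca`). Windows are 100 consecutive SNPs by default: a
literal handful of base pairs cannot hold multiple SNPs, so window size is
interpreted in SNP count (a bp mode can be built from the same pieces).
Missing dosages are mean-imputed within the window; the sample covariance
is normalised to unit trace and truncated to k = 3 eigenpairs; window
distances are Frobenius norms between the truncated approximations;
classical (Torgerson) MDS embeds them, truncating negative eigenvalues with
a warning. An MDS axis is "significant" if its normalised eigenvalue
exceeds 0.01. Outlier windows lie beyond 3 trimmed standard deviations,
where the trim drops 5% of the mass in total (2.5% per tail) — under this
reading a Gaussian axis flags under 1% of windows, which is the behaviour
the outlier rule needs to be informative; regions require ≥3 adjacent
flagged windows.

**Phased breakpoints** (`phasing`). The reference haplotype is the
designated line's pooled major allele per site (undefined at exactly 0.5);
a designated-sample alternative exists. Polarisation uses all
reference-defined sites by default: restricting to sites heterozygous in
the individual removes per-site noise but silently truncates the
informative series exactly where a crossover abuts a homozygous stretch,
missing it (the option remains). Sites monomorphic in the population —
where both divergent haplotypes share the reference allele — should be
removed by the MAF filter before phasing, otherwise they add constant
'match' states to every series; with majority smoothing (window 11, off by
default for error-free data) isolated genotype or phasing errors cannot
move a run boundary by more than 5 sites. Breakpoints are midpoints between
opposite-state neighbours; conserved breakpoints are single-linkage
clusters (50 kb) with ≥2 distinct samples, reported at the cluster median
with per-sex tallies.

**Permutation tests** (`permtest`). PERMANOVA partitions squared Euclidean
distances; p-values use (1+count)/(B+1) and can never be 0; in one
dimension the pseudo-F equals the classical ANOVA F (checked numerically).
The variance test permutes whole individuals between two groups and
compares |trace difference| two-tailed. Both degrees of freedom (between,
within) are reported separately. Permutation streams are seeded
independently of the data stream.

## Problem sizes

The default evaluation (`isohap.evaluate`, driven by
`scripts/acceptance.py` and the acceptance tests) uses the full default
simulation (~50k SNPs, 4 pools × 48, 26 individuals), 500 null datasets of
20 × 5 for the type-I error estimates with 99 permutations each, 100
white-noise series of length 1000 for the segmentation false-positive
rate, and two 2-Mb unlinked chromosomes for the inter-chromosomal r² null.
The unit-test fixtures use a denser 2-Mb chromosome with a 400-kb region.

## Known limitations

- The consensus-region innermost rule biases bounds inward by the
  most-inward per-series error; a median representative would be unbiased
  but could over-extend the region.
- Background sites carry no LD, so the local-PCA and LD analyses face an
  easier null than real data.
- Pooled AF mode detection assumes enough SNPs per class (≥50) and cannot
  assign individual SNPs to branches — that is underdetermined from pooled
  data.
- The chi-square HWE audit uses expected counts that can be small at n ≤ 10
  individuals; it is a signal audit, not a calibrated test, at that size.
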