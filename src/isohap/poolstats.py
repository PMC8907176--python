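"""Pool-seq filtering, allele frequencies, pairwise FST and nucleotide diversity.

The FST estimator is a two-level analysis-of-variance (method-of-moments)
estimator for pooled read counts. Read sampling with replacement means a pool
of n chromosomes sequenced at depth c carries information equivalent to

    n_eff = c * n / (c + n - 1)

chromosomes, and this effective number replaces the sample size in the
two-population Weir-Cockerham decomposition. Multi-locus values are the
ratio of summed numerators to summed denominators (ratio-of-sums), the
standard low-bias combination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .dataio import PoolCountTable, WindowTrack

logger = logging.getLogger(__name__)


@dataclass
class PoolAF:
    """Per pool x site alt-allele frequency estimates with their coverages."""

    sites: pd.DataFrame
    pools: pd.DataFrame
    freq: np.ndarray  # p-hat, NaN where coverage 0
    coverage: np.ndarray

    @classmethod
    def from_counts(cls, table: PoolCountTable) -> "PoolAF":
        cov = table.coverage.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(cov > 0, table.alt_count / np.maximum(cov, 1), np.nan)
        freq = np.where(cov > 0, freq, np.nan)
        return cls(sites=table.sites, pools=table.pools, freq=freq, coverage=cov)

    @property
    def n_pools(self) -> int:
        return len(self.pools)


@dataclass
class FstResult:
    """Per-site and multi-locus FST for one pool pair (numerator/denominator
    kept so multi-locus values are ratio-of-sums)."""

    pair: tuple[str, str]
    per_site: np.ndarray  # NaN where undefined
    numerator: np.ndarray
    denominator: np.ndarray

    @property
    def global_fst(self) -> float:
        ok = np.isfinite(self.numerator) & np.isfinite(self.denominator)
        den = self.denominator[ok].sum()
        return float(self.numerator[ok].sum() / den) if den != 0 else np.nan

    @property
    def mean_fst(self) -> float:
        return float(np.nanmean(self.per_site))


def filter_pool_variants(
    table: PoolCountTable,
    min_cov: int = 30,
    max_cov: int = 500,
    min_allele_reads: int = 10,
    maf: float = 0.25,
) -> tuple[PoolCountTable, dict[str, int]]:
    """Site filters applied jointly across pools.

    A site is kept iff every pool's coverage lies in [min_cov, max_cov], each
    segregating allele has >= ``min_allele_reads`` reads summed across pools,
    and the count-weighted pooled minor-allele frequency is >= ``maf``.
    Returns the filtered table and per-rule removal counts.
    """
    cov = table.coverage
    cov_ok = ((cov >= min_cov) & (cov <= max_cov)).all(axis=0)

    ref_total = table.ref_count.sum(axis=0)
    alt_total = table.alt_count.sum(axis=0)
    allele_ok = (ref_total >= min_allele_reads) & (alt_total >= min_allele_reads)

    total = ref_total + alt_total
    with np.errstate(invalid="ignore", divide="ignore"):
        pooled_af = np.where(total > 0, alt_total / np.maximum(total, 1), np.nan)
    pooled_maf = np.minimum(pooled_af, 1 - pooled_af)
    maf_ok = pooled_maf >= maf

    keep = cov_ok & allele_ok & maf_ok
    log = {
        "coverage": int((~cov_ok).sum()),
        "allele_support": int((cov_ok & ~allele_ok).sum()),
        "maf": int((cov_ok & allele_ok & ~maf_ok).sum()),
        "kept": int(keep.sum()),
    }
    if log["kept"] == 0:
        logger.warning("filter_pool_variants removed every site")
    return table.subset_sites(keep), log


def effective_chromosomes(coverage: np.ndarray, pool_size: np.ndarray) -> np.ndarray:
    """Effective number of chromosomes sampled: c*n/(c + n - 1)."""
    c = np.asarray(coverage, dtype=float)
    n = np.asarray(pool_size, dtype=float)
    return c * n / (c + n - 1.0)


def pairwise_pool_fst(af: PoolAF, pair: tuple[int, int] | None = None) -> FstResult:
    """ANOVA FST between two pools from read-count allele frequencies.

    With effective sizes ñ_i and r = 2 pools:
        MSP = Σ ñ_i (p_i - p̄)² / (r - 1),  p̄ = Σ ñ_i p_i / Σ ñ_i
        MSG = Σ ñ_i p_i (1 - p_i) / Σ (ñ_i - 1)
        n_c = (Σ ñ_i - Σ ñ_i² / Σ ñ_i) / (r - 1)
        FST = (MSP - MSG) / (MSP + (n_c - 1) MSG)
    Sites where both pools are monomorphic for the same allele contribute
    num = den = 0 and are NaN per-site (excluded from the global sums).
    """
    i, j = pair if pair is not None else (0, 1)
    p = np.stack([af.freq[i], af.freq[j]])
    c = np.stack([af.coverage[i], af.coverage[j]])
    n = af.pools["size"].to_numpy()[[i, j], None].astype(float)
    nt = effective_chromosomes(c, n)

    valid = np.isfinite(p).all(axis=0)
    nt_sum = nt.sum(axis=0)
    pbar = (nt * p).sum(axis=0) / nt_sum
    msp = (nt * (p - pbar) ** 2).sum(axis=0)  # /(r-1) with r=2
    msg = (nt * p * (1 - p)).sum(axis=0) / (nt - 1.0).sum(axis=0)
    n_c = nt_sum - (nt**2).sum(axis=0) / nt_sum  # /(r-1) with r=2

    num = msp - msg
    den = msp + (n_c - 1.0) * msg
    num = np.where(valid, num, np.nan)
    den = np.where(valid, den, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        per_site = np.where(np.abs(den) > 0, num / den, np.nan)
    per_site = np.where(valid, per_site, np.nan)
    # degenerate sites (both fixed same allele): num=den=0 -> no contribution
    degenerate = valid & (den == 0)
    num = np.where(degenerate, 0.0, num)
    den = np.where(degenerate, 0.0, den)
    pair_ids = tuple(af.pools["id"].iloc[[i, j]])
    return FstResult(pair=pair_ids, per_site=per_site, numerator=num, denominator=den)


def all_pairwise_fst(af: PoolAF) -> dict[tuple[str, str], FstResult]:
    """FST for every pool pair, keyed by (id_i, id_j)."""
    return {
        tuple(af.pools["id"].iloc[[i, j]]): pairwise_pool_fst(af, (i, j))
        for i, j in combinations(range(af.n_pools), 2)
    }


def weir_cockerham_fst_counts(
    alt1: int, n1: int, alt2: int, n2: int
) -> tuple[float, float]:
    """Classic two-population Weir-Cockerham components from exact allele
    counts (haploid sample sizes n1, n2). Returns (numerator, denominator).

    Serves as the allele-count limit of the pooled estimator: as read depth
    grows the effective chromosome number approaches the pool size and the
    pooled ANOVA converges to this form.
    """
    p1, p2 = alt1 / n1, alt2 / n2
    n = np.array([n1, n2], dtype=float)
    p = np.array([p1, p2])
    nsum = n.sum()
    pbar = (n * p).sum() / nsum
    msp = (n * (p - pbar) ** 2).sum()
    msg = (n * p * (1 - p)).sum() / (n - 1).sum()
    n_c = nsum - (n**2).sum() / nsum
    return msp - msg, msp + (n_c - 1) * msg


def pool_pi(af: PoolAF, window: int = 10_000, unbiased_by: str = "coverage") -> tuple[np.ndarray, dict[str, WindowTrack]]:
    """Per-site nucleotide diversity from pool frequencies plus windowed means.

    π_site = (c/(c-1)) * 2 p̂ (1 - p̂) with the read-depth small-sample
    correction (``unbiased_by='pool'`` substitutes the pool size n for c).
    Window values are the mean over SNPs in each fixed-width window per pool;
    windows without SNPs are NaN, not 0.
    """
    c = af.coverage
    if unbiased_by == "pool":
        corr_n = np.broadcast_to(af.pools["size"].to_numpy()[:, None].astype(float), c.shape)
    elif unbiased_by == "coverage":
        corr_n = c
    else:
        raise ValueError("unbiased_by must be 'coverage' or 'pool'")
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(corr_n >= 2, corr_n / (corr_n - 1.0) * 2.0 * af.freq * (1.0 - af.freq), np.nan)

    tracks: dict[str, WindowTrack] = {}
    pos = af.sites["pos"].to_numpy()
    for chrom in pd.unique(af.sites["chrom"]):
        cmask = (af.sites["chrom"] == chrom).to_numpy()
        cpos = pos[cmask]
        starts = np.arange(1, cpos.max() + 1, window)
        ends = starts + window - 1
        bins = np.searchsorted(starts, cpos, side="right") - 1
        for k, pool_id in enumerate(af.pools["id"]):
            vals = np.full(len(starts), np.nan)
            pvals = pi[k, cmask]
            for b in range(len(starts)):
                inb = pvals[bins == b]
                inb = inb[np.isfinite(inb)]
                if inb.size:
                    vals[b] = inb.mean()
            tracks[f"{chrom}:{pool_id}"] = WindowTrack(chrom=chrom, start=starts, end=ends, value=vals)
    return pi, tracks
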