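"""Windowed intersex statistics, quantile outliers, HWE expectations and LD
r² matrices on individual genotype data.

Intersex differentiation between males and females sharing one gene pool is
a signature of sex-differential selection or sex-linked haplotype structure.
Per site, with group alt frequencies p1, p2 estimated from n1, n2 non-missing
alleles, the statistics are:

    FST (Hudson) = [(p1-p2)² - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)]
                   / [p1(1-p2) + p2(1-p1)]
    d_xy  = p1(1-p2) + p2(1-p1)
    π_g   = 2 p (1-p) n/(n-1)
    D_a   = d_xy - π_female          (negative: male diversity deficit)

FST windows average per-site values; d_xy and π windows are per-bp sums over
the full window width.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chisquare

from .dataio import MISSING, GenotypeMatrix, RegionSet, WindowTrack

logger = logging.getLogger(__name__)


@dataclass
class GroupSpec:
    """A two-group partition of samples (typically male/female) as index arrays."""

    name1: str
    idx1: np.ndarray
    name2: str
    idx2: np.ndarray

    @classmethod
    def by_sex(cls, gm: GenotypeMatrix) -> "GroupSpec":
        sex = gm.samples["sex"].to_numpy()
        return cls(
            "male",
            np.flatnonzero(sex == "male"),
            "female",
            np.flatnonzero(sex == "female"),
        )


def group_allele_stats(gm: GenotypeMatrix, idx: np.ndarray):
    """(alt frequency, non-missing allele count) per site for a sample subset."""
    d = gm.dosage[idx].astype(float)
    miss = gm.dosage[idx] == MISSING
    d[miss] = 0.0
    n_alleles = 2.0 * (~miss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(n_alleles > 0, d.sum(axis=0) / np.maximum(n_alleles, 1), np.nan)
    return p, n_alleles


def _site_stats(gm: GenotypeMatrix, groups: GroupSpec):
    p1, n1 = group_allele_stats(gm, groups.idx1)
    p2, n2 = group_allele_stats(gm, groups.idx2)
    usable = (n1 >= 2) & (n2 >= 2) & np.isfinite(p1) & np.isfinite(p2)
    return p1, n1, p2, n2, usable


def hudson_fst_site(p1, n1, p2, n2):
    """Hudson estimator per site; NaN where the denominator is 0."""
    num = (
        (p1 - p2) ** 2
        - p1 * (1 - p1) / np.maximum(n1 - 1, 1)
        - p2 * (1 - p2) / np.maximum(n2 - 1, 1)
    )
    den = p1 * (1 - p2) + p2 * (1 - p1)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(den > 0, num / den, np.nan)


def _windows(pos: np.ndarray, width: int):
    # full-width windows throughout (the chromosome end is unknown from a
    # site list, so the last window is not truncated; per-bp denominators
    # then use the same width everywhere)
    last = int(pos.max())
    starts = np.arange(1, last + 1, width)
    ends = starts + width - 1
    bins = np.searchsorted(starts, pos, side="right") - 1
    return starts, ends, bins


def _window_aggregate(pos, values, width, chrom, how, denom=None):
    starts, ends, bins = _windows(pos, width)
    out = np.full(len(starts), np.nan)
    fin = np.isfinite(values)
    df = pd.DataFrame({"b": bins[fin], "v": values[fin]})
    if len(df):
        agg = df.groupby("b")["v"].agg("mean" if how == "mean" else "sum")
        out[agg.index.to_numpy()] = agg.to_numpy()
        if how == "persite_sum":
            width_arr = (ends - starts + 1).astype(float)
            out[agg.index.to_numpy()] = agg.to_numpy() / width_arr[agg.index.to_numpy()]
    return WindowTrack(chrom=chrom, start=starts, end=ends, value=out)


def _single_chrom(gm: GenotypeMatrix) -> str:
    chroms = pd.unique(gm.sites["chrom"])
    if len(chroms) != 1:
        raise ValueError("windowed statistics expect a single-chromosome matrix")
    return chroms[0]


def windowed_intersex_fst(
    gm: GenotypeMatrix, groups: GroupSpec | None = None, width: int = 1000
) -> WindowTrack:
    """Mean per-site Hudson FST between the two groups in fixed windows."""
    chrom = _single_chrom(gm)
    groups = groups or GroupSpec.by_sex(gm)
    p1, n1, p2, n2, usable = _site_stats(gm, groups)
    fst = hudson_fst_site(p1, n1, p2, n2)
    fst = np.where(usable, fst, np.nan)
    return _window_aggregate(gm.sites["pos"].to_numpy(), fst, width, chrom, "mean")


def windowed_dxy(
    gm: GenotypeMatrix, groups: GroupSpec | None = None, width: int = 1000
) -> WindowTrack:
    """Between-group mean pairwise difference per bp in fixed windows."""
    chrom = _single_chrom(gm)
    groups = groups or GroupSpec.by_sex(gm)
    p1, n1, p2, n2, usable = _site_stats(gm, groups)
    dxy = p1 * (1 - p2) + p2 * (1 - p1)
    dxy = np.where(usable, dxy, np.nan)
    return _window_aggregate(gm.sites["pos"].to_numpy(), dxy, width, chrom, "persite_sum")


def windowed_pi(
    gm: GenotypeMatrix, idx: np.ndarray | None = None, width: int = 1000
) -> WindowTrack:
    """Within-group nucleotide diversity per bp in fixed windows."""
    chrom = _single_chrom(gm)
    if idx is None:
        idx = np.arange(gm.n_samples)
    p, n = group_allele_stats(gm, idx)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = np.where(n >= 2, 2.0 * p * (1 - p) * n / np.maximum(n - 1, 1), np.nan)
    return _window_aggregate(gm.sites["pos"].to_numpy(), pi, width, chrom, "persite_sum")


def windowed_da(dxy: WindowTrack, pi_female: WindowTrack) -> WindowTrack:
    """Intersex D_a = d_xy - female π, window by window (missing propagates)."""
    if len(dxy) != len(pi_female) or (dxy.start != pi_female.start).any():
        raise ValueError("misaligned window tracks")
    return WindowTrack(
        chrom=dxy.chrom, start=dxy.start, end=dxy.end, value=dxy.value - pi_female.value
    )


def window_quantile_outliers(
    track: WindowTrack,
    q_low: float = 0.05,
    q_high: float = 0.95,
    tails: str = "both",
) -> RegionSet:
    """Windows beyond the empirical quantiles, merged when contiguous.

    Missing windows are never flagged. ``tails`` selects 'low', 'high' or
    'both'.
    """
    vals = track.value
    finite = np.isfinite(vals)
    if finite.sum() < 20:
        raise ValueError("need >= 20 non-missing windows")
    lo = np.quantile(vals[finite], q_low)
    hi = np.quantile(vals[finite], q_high)
    flag = np.zeros(len(track), dtype=bool)
    if tails in ("low", "both"):
        flag |= finite & (vals < lo)
    if tails in ("high", "both"):
        flag |= finite & (vals > hi)
    rows = []
    i = 0
    while i < len(flag):
        if flag[i]:
            j = i
            while j + 1 < len(flag) and flag[j + 1]:
                j += 1
            label = "low" if vals[i] < lo else "high"
            rows.append(
                {
                    "chrom": track.chrom,
                    "start": int(track.start[i]),
                    "end": int(track.end[j]),
                    "label": label,
                }
            )
            i = j + 1
        else:
            i += 1
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))


def hwe_expected_counts(p: float, n: int, observed=None):
    """Expected (HOM ALT, HET, HOM REF) counts under Hardy-Weinberg at alt
    frequency p for n individuals; optionally a chi-square test vs observed."""
    if not 0 <= p <= 1:
        raise ValueError("p must be in [0, 1]")
    if n < 1:
        raise ValueError("n must be >= 1")
    expected = np.array([p**2, 2 * p * (1 - p), (1 - p) ** 2]) * n
    if observed is None:
        return expected
    observed = np.asarray(observed, dtype=float)
    keep = expected > 0
    stat, pval = chisquare(observed[keep], expected[keep] * observed.sum() / expected[keep].sum())
    return expected, float(stat), float(pval)


@dataclass
class LDMatrix:
    sites: pd.DataFrame
    r2: np.ndarray
    sites_cols: pd.DataFrame | None = None  # set for cross-chromosome mode


def _thin_and_clean(gm: GenotypeMatrix, thin: int, region=None) -> GenotypeMatrix:
    sub = gm
    if region is not None:
        chrom, start, end = region
        m = (
            (gm.sites["chrom"] == chrom)
            & (gm.sites["pos"] >= start)
            & (gm.sites["pos"] <= end)
        ).to_numpy()
        sub = gm.subset_sites(m)
    keep = np.zeros(sub.n_sites, dtype=bool)
    for chrom in pd.unique(sub.sites["chrom"]):
        cmask = (sub.sites["chrom"] == chrom).to_numpy()
        pos = sub.sites["pos"].to_numpy()[cmask]
        bins = pos // thin
        first = np.concatenate([[True], bins[1:] != bins[:-1]])
        keep[np.flatnonzero(cmask)[first]] = True
    sub = sub.subset_sites(keep)
    # drop monomorphic / zero-variance dosage columns
    var_ok = np.zeros(sub.n_sites, dtype=bool)
    for j in range(sub.n_sites):
        d = sub.dosage[:, j]
        d = d[d != MISSING]
        var_ok[j] = d.size >= 2 and d.std() > 0
    n_drop = int((~var_ok).sum())
    if n_drop:
        logger.info("ld_r2_matrix: excluded %d invariant/zero-variance SNPs", n_drop)
    return sub.subset_sites(var_ok)


def _pairwise_r2(d1: np.ndarray, d2: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation between dosage columns, pairwise-complete.

    Complete data takes a vectorised path; missing entries fall back to a
    per-pair loop over the samples non-missing at both SNPs.
    """
    if (d1 != MISSING).all() and (d2 != MISSING).all():
        x = d1.astype(float)
        y = d2.astype(float)
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        xs = xc.std(axis=0)
        ys = yc.std(axis=0)
        cov = xc.T @ yc / x.shape[0]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = cov / np.outer(xs, ys)
        return r**2
    out = np.full((d1.shape[1], d2.shape[1]), np.nan)
    for i in range(d1.shape[1]):
        x = d1[:, i]
        for j in range(d2.shape[1]):
            y = d2[:, j]
            ok = (x != MISSING) & (y != MISSING)
            if ok.sum() < 2:
                continue
            xv, yv = x[ok].astype(float), y[ok].astype(float)
            if xv.std() == 0 or yv.std() == 0:
                continue
            r = np.corrcoef(xv, yv)[0, 1]
            out[i, j] = r * r
    return out


def ld_r2_matrix(
    gm: GenotypeMatrix,
    thin: int = 5000,
    region=None,
    cross: tuple[str, str] | None = None,
) -> LDMatrix:
    """Thinned r² matrix (first SNP per ``thin``-bp bin, invariant sites
    removed). ``cross=(chromA, chromB)`` returns the rectangular
    between-chromosome matrix instead of the square within matrix."""
    if cross is not None:
        sub = _thin_and_clean(gm, thin, region)
        m1 = (sub.sites["chrom"] == cross[0]).to_numpy()
        m2 = (sub.sites["chrom"] == cross[1]).to_numpy()
        a, b = sub.subset_sites(m1), sub.subset_sites(m2)
        if a.n_sites < 1 or b.n_sites < 1:
            raise ValueError("need SNPs on both chromosomes after thinning")
        return LDMatrix(
            sites=a.sites, r2=_pairwise_r2(a.dosage, b.dosage), sites_cols=b.sites
        )
    sub = _thin_and_clean(gm, thin, region)
    if sub.n_sites < 2:
        raise ValueError("need >= 2 SNPs after thinning")
    r2 = _pairwise_r2(sub.dosage, sub.dosage)
    np.fill_diagonal(r2, 1.0)
    return LDMatrix(sites=sub.sites, r2=r2)


def filter_genotype_variants(
    gm: GenotypeMatrix, max_missing: float = 0.5, maf: float = 0.10
) -> tuple[GenotypeMatrix, dict[str, int]]:
    """Site filters on genotype data: missingness <= ``max_missing`` and
    minor-allele frequency >= ``maf`` (biallelic SNPs are guaranteed by the
    container)."""
    miss = (gm.dosage == MISSING).mean(axis=0)
    miss_ok = miss <= max_missing
    p, n = group_allele_stats(gm, np.arange(gm.n_samples))
    with np.errstate(invalid="ignore"):
        maf_val = np.minimum(p, 1 - p)
    maf_ok = np.isfinite(maf_val) & (maf_val >= maf)
    keep = miss_ok & maf_ok
    log = {
        "missingness": int((~miss_ok).sum()),
        "maf": int((miss_ok & ~maf_ok).sum()),
        "kept": int(keep.sum()),
    }
    return gm.subset_sites(keep), log
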