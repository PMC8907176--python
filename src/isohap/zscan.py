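"""Z-normalisation of per-SNP statistics, SNP-wise PCA and chromosome summaries.

Per-SNP pairwise FST (or per-SNP diversity) values from several comparisons
are standardised column-wise genome-wide and summarised by a principal
component analysis with SNPs as observations. A region differentiated in the
same direction in every comparison loads all comparisons with one sign on
PC1, so the PC1 score is a consensus-differentiation statistic. Chromosome
summaries report the mean score and the fraction of SNPs above a genome-wide
upper quantile, identifying chromosomes enriched for consensus outliers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class ZScoreMatrix:
    """SNPs x comparisons matrix of column-standardised scores."""

    sites: pd.DataFrame
    comparisons: list[str]
    z: np.ndarray

    def __post_init__(self) -> None:
        if self.z.shape != (len(self.sites), len(self.comparisons)):
            raise ValueError("z shape inconsistent with sites x comparisons")


@dataclass
class PCResult:
    """SNP-wise principal components of the standardised comparison matrix."""

    sites: pd.DataFrame
    comparisons: list[str]
    scores: np.ndarray  # SNPs x components
    loadings: np.ndarray  # comparisons x components, orthonormal columns
    explained_variance_ratio: np.ndarray


def zscore_matrix(
    values: np.ndarray, sites: pd.DataFrame, comparisons: list[str]
) -> ZScoreMatrix:
    """Column-standardise a SNPs x comparisons matrix genome-wide.

    SNPs with a missing value in any comparison are dropped (logged), so that
    every column of the result has mean 0 and sample sd 1 over the same SNPs.
    A zero-variance column raises, naming the comparison.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 SNPs")
    complete = np.isfinite(values).all(axis=1)
    n_drop = int((~complete).sum())
    if n_drop:
        logger.info("zscore_matrix: dropped %d SNPs with missing comparisons", n_drop)
    values = values[complete]
    sites = sites.loc[complete].reset_index(drop=True)
    sd = values.std(axis=0, ddof=1)
    for name, s in zip(comparisons, sd):
        if s == 0:
            raise ValueError(f"zero-variance comparison column: {name}")
    z = (values - values.mean(axis=0)) / sd
    return ZScoreMatrix(sites=sites, comparisons=list(comparisons), z=z)


def snp_matrix_pca(zm: ZScoreMatrix, n_components: int | None = None) -> PCResult:
    """PCA of the SNPs x comparisons Z matrix (SNPs as observations).

    Columns are re-centred/scaled, decomposed by SVD, and each component's
    sign is fixed so the loading of the first comparison is non-negative
    (falling back to the first nonzero loading when it is exactly 0).
    """
    x = zm.z
    n_snps, n_comp = x.shape
    if n_snps < n_comp:
        raise ValueError("need at least as many SNPs as comparisons")
    k = n_comp if n_components is None else min(n_components, n_comp)
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    u, s, vt = np.linalg.svd(xs, full_matrices=False)
    rank = int((s > s[0] * 1e-12).sum()) if s.size else 0
    if rank < k:
        logger.warning("snp_matrix_pca: rank %d < requested %d components", rank, k)
        k = rank
    loadings = vt[:k].T
    scores = u[:, :k] * s[:k]
    var = s**2 / (n_snps - 1)
    ratio = var / var.sum()
    for comp in range(k):
        col = loadings[:, comp]
        # orient toward the majority loading direction (consensus components
        # then score shared outliers positively); tie -> first nonzero >= 0
        pivot = col.sum()
        if pivot == 0 and np.any(col):
            pivot = col[np.flatnonzero(col)[0]]
        if pivot < 0:
            loadings[:, comp] = -col
            scores[:, comp] = -scores[:, comp]
    return PCResult(
        sites=zm.sites,
        comparisons=zm.comparisons,
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=ratio[:k],
    )


def chromosome_summary(
    pc: PCResult, component: int = 0, q: float = 0.95
) -> pd.DataFrame:
    """Per-chromosome mean score and % of SNPs above the genome-wide q-quantile.

    The threshold is the empirical type-7 (linear interpolation) quantile of
    the component's scores over all SNPs.
    """
    scores = pc.scores[:, component]
    threshold = float(np.quantile(scores, q))  # numpy default = type 7
    df = pd.DataFrame({"chrom": pc.sites["chrom"].to_numpy(), "score": scores})
    out = (
        df.groupby("chrom", sort=True)
        .agg(
            n_snps=("score", "size"),
            mean_score=("score", "mean"),
            frac_above=("score", lambda s: float((s > threshold).mean())),
        )
        .reset_index()
    )
    out["threshold"] = threshold
    return out
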