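"""Local-ancestry heterogeneity scan: windowed PCA of genotypes, distances
between window subspaces, classical MDS embedding and outlier-region calling.

Each window of consecutive SNPs is summarised by the top-k eigenpairs of the
unit-trace sample covariance of centred dosages. Windows whose truncated
covariance approximations differ strongly from the chromosomal norm — long
haplotypes, inversions, balanced polymorphism — separate on the leading MDS
axes of the window-to-window Frobenius distance matrix, and runs of flagged
windows delineate candidate regions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd

from .dataio import MISSING, GenotypeMatrix, RegionSet

logger = logging.getLogger(__name__)


@dataclass
class WindowPCA:
    window_id: int
    chrom: str
    start: int
    end: int
    eigenvalues: np.ndarray  # top-k of the unit-trace covariance, descending
    eigenvectors: np.ndarray  # samples x k


@dataclass
class MDSResult:
    coords: np.ndarray  # windows x axes, centred
    eigenvalues: np.ndarray  # normalised (sum of positives = 1), descending
    windows: pd.DataFrame  # window_id, chrom, start, end


def _window_bounds(gm: GenotypeMatrix, window_snps: int):
    pos = gm.sites["pos"].to_numpy()
    n = gm.n_sites
    for wid, lo in enumerate(range(0, n - window_snps + 1, window_snps)):
        yield wid, lo, lo + window_snps, int(pos[lo]), int(pos[lo + window_snps - 1])


def window_pca(
    gm: GenotypeMatrix, lo: int, hi: int, k: int = 3, window_id: int = 0
) -> WindowPCA | None:
    """Top-k eigenpairs of the unit-trace covariance of one SNP window.

    Missing dosages are mean-imputed within the window; windows with fewer
    polymorphic SNPs than k are skipped (None, logged).
    """
    x = gm.dosage[:, lo:hi].astype(float)
    miss = gm.dosage[:, lo:hi] == MISSING
    if miss.any():
        col_mean = np.where(
            (~miss).sum(axis=0) > 0,
            np.where(miss, 0, x).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1),
            0.0,
        )
        x = np.where(miss, col_mean[None, :], x)
    poly = x.std(axis=0) > 0
    if poly.sum() < k:
        logger.info("window_pca: window %d has < %d polymorphic SNPs", window_id, k)
        return None
    x = x[:, poly]
    x = x - x.mean(axis=0)
    cov = x @ x.T / x.shape[1]
    trace = np.trace(cov)
    if trace <= 0:
        return None
    cov = cov / trace
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1][:k]
    chrom = gm.sites["chrom"].iloc[lo]
    return WindowPCA(
        window_id=window_id,
        chrom=chrom,
        start=int(gm.sites["pos"].iloc[lo]),
        end=int(gm.sites["pos"].iloc[hi - 1]),
        eigenvalues=np.maximum(vals[order], 0.0),
        eigenvectors=vecs[:, order],
    )


def windowed_pca(
    gm: GenotypeMatrix, window_snps: int = 100, k: int = 3
) -> list[WindowPCA]:
    """Run :func:`window_pca` over consecutive ``window_snps``-SNP windows."""
    out = []
    for wid, lo, hi, _, _ in _window_bounds(gm, window_snps):
        w = window_pca(gm, lo, hi, k=k, window_id=wid)
        if w is not None:
            out.append(w)
    return out


def _approx(w: WindowPCA) -> np.ndarray:
    """Rank-k unit-trace covariance approximation Σ λ_l u_l u_lᵀ."""
    return (w.eigenvectors * w.eigenvalues) @ w.eigenvectors.T


def window_distance_matrix(windows: list[WindowPCA]) -> np.ndarray:
    """Frobenius distances between the windows' truncated covariance
    approximations (a metric on the window subspaces)."""
    if not windows:
        return np.zeros((0, 0))
    n_samples = windows[0].eigenvectors.shape[0]
    for w in windows:
        if w.eigenvectors.shape[0] != n_samples:
            raise ValueError("windows computed on different sample sets")
    mats = np.stack([_approx(w) for w in windows])
    flat = mats.reshape(len(windows), -1)
    sq = (flat**2).sum(axis=1)
    gram = flat @ flat.T
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2 * gram, 0.0)
    d = np.sqrt(d2)
    np.fill_diagonal(d, 0.0)
    return d


def classical_mds(dist: np.ndarray, m: int = 3, windows: pd.DataFrame | None = None) -> MDSResult:
    """Torgerson classical MDS of a symmetric distance matrix.

    B = -J d² J / 2 is double-centred; coordinates are eigenvector √eigenvalue
    on the top-m non-negative eigenpairs (negative eigenvalues truncated with
    a warning). Axis sign is fixed so the first nonzero coordinate of each
    axis is non-negative. Eigenvalues are reported normalised by the positive
    spectrum's sum.
    """
    dist = np.asarray(dist, dtype=float)
    if dist.ndim != 2 or dist.shape[0] != dist.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(dist, dist.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = dist.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dist**2) @ j
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if (vals < -1e-8 * max(vals.max(), 1.0)).any():
        warnings.warn("classical_mds: negative eigenvalues truncated", stacklevel=2)
    m = min(m, n)
    take = vals[:m].clip(min=0.0)
    coords = vecs[:, :m] * np.sqrt(take)
    for ax in range(m):
        nz = np.flatnonzero(np.abs(coords[:, ax]) > 1e-12)
        if nz.size and coords[nz[0], ax] < 0:
            coords[:, ax] = -coords[:, ax]
    pos_sum = vals.clip(min=0.0).sum()
    norm = vals[:m].clip(min=0.0) / pos_sum if pos_sum > 0 else np.zeros(m)
    if windows is None:
        windows = pd.DataFrame({"window_id": np.arange(n)})
    return MDSResult(coords=coords, eigenvalues=norm, windows=windows)


def mds_from_windows(windows: list[WindowPCA], m: int = 3) -> MDSResult:
    meta = pd.DataFrame(
        {
            "window_id": [w.window_id for w in windows],
            "chrom": [w.chrom for w in windows],
            "start": [w.start for w in windows],
            "end": [w.end for w in windows],
        }
    )
    return classical_mds(window_distance_matrix(windows), m=m, windows=meta)


def mds_outlier_windows(
    axis_values: np.ndarray, trim: float = 0.05, k_sd: float = 3.0
) -> np.ndarray:
    """Boolean flags for windows outside mean ± k_sd·sd of the trimmed axis.

    ``trim`` is the total trimmed mass: trim/2 is dropped from each tail
    before computing the trimmed mean and sd (a Gaussian axis then flags
    under 1% of windows at k_sd = 3). A degenerate sd of 0 flags nothing
    (warned).
    """
    v = np.asarray(axis_values, dtype=float)
    if len(v) < 20:
        raise ValueError("need >= 20 windows")
    order = np.sort(v)
    cut = int(np.floor(trim / 2 * len(v)))
    core = order[cut : len(v) - cut] if cut else order
    mu, sd = core.mean(), core.std(ddof=1)
    if sd == 0:
        warnings.warn("mds_outlier_windows: degenerate trimmed sd", stacklevel=2)
        return np.zeros(len(v), dtype=bool)
    return (v < mu - k_sd * sd) | (v > mu + k_sd * sd)


def mds_regions(
    flags: np.ndarray, windows: pd.DataFrame, min_run: int = 3, label: str = "mds1"
) -> RegionSet:
    """Maximal runs of >= ``min_run`` adjacent flagged windows as regions.

    Adjacency means consecutive rows of ``windows`` (which are consecutive
    genomic windows); region bounds span [start of first, end of last].
    """
    flags = np.asarray(flags, dtype=bool)
    rows = []
    i = 0
    while i < len(flags):
        if flags[i]:
            j = i
            while j + 1 < len(flags) and flags[j + 1]:
                j += 1
            if j - i + 1 >= min_run:
                rows.append(
                    {
                        "chrom": windows["chrom"].iloc[i],
                        "start": int(windows["start"].iloc[i]),
                        "end": int(windows["end"].iloc[j]),
                        "label": label,
                    }
                )
            i = j + 1
        else:
            i += 1
    return RegionSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "label"]))
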