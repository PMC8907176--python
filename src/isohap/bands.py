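"""Polarised pool allele frequencies, AF band (mode) detection, and band
prediction from nested-haplotype pool compositions.

A pool of T chromosomes composed of a copies of A1, b of A2 and c of B shows
its allele frequencies concentrated in discrete 'bands' determined by the
site class. Polarised to the A1-fixed reference line (flip every site where
the reference's alt frequency is below 0.5):

    A_shared    -> (a + b) / T
    A1_private  -> a / T
    A2_private  -> 1 - b / T   (the reference carries REF here, so flipped)
    B_private   -> 1 - c / T   (likewise flipped)

When two or more haplotypes segregate with private site classes the distinct
band values do not sum to 1 — the signature of nested haplotypes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .poolstats import PoolAF

logger = logging.getLogger(__name__)


@dataclass
class PolarisedAF:
    """Pool AFs re-expressed as the frequency of the reference line's major
    allele; ``flipped`` marks sites where alleles were swapped."""

    sites: pd.DataFrame
    pools: pd.DataFrame
    freq: np.ndarray
    reference_pool: str
    flipped: np.ndarray


def polarise_to_line(af: PoolAF, reference_pool: str) -> PolarisedAF:
    """Polarise every pool's AF to the reference pool's per-site major allele.

    Sites where the reference is missing are dropped (logged). A reference
    frequency of exactly 0.5 is left unflipped (deterministic tie rule).
    """
    ids = list(af.pools["id"])
    if reference_pool not in ids:
        raise ValueError(f"reference pool {reference_pool!r} not in table")
    r = ids.index(reference_pool)
    usable = np.isfinite(af.freq[r])
    n_drop = int((~usable).sum())
    if n_drop:
        logger.info("polarise_to_line: dropped %d sites missing in reference", n_drop)
    freq = af.freq[:, usable]
    flip = freq[r] < 0.5
    out = np.where(flip[None, :], 1.0 - freq, freq)
    return PolarisedAF(
        sites=af.sites.loc[usable].reset_index(drop=True),
        pools=af.pools,
        freq=out,
        reference_pool=reference_pool,
        flipped=flip,
    )


@dataclass
class ModeResult:
    n_modes: int
    locations: np.ndarray
    densities: np.ndarray
    grid: np.ndarray
    density: np.ndarray


def detect_af_modes(
    values: np.ndarray,
    prominence: float = 0.05,
    bandwidth: float | str = "silverman",
    min_snps: int = 50,
    grid_points: int = 512,
    min_separation: float = 0.05,
) -> ModeResult | None:
    """Modes of an AF distribution on [0, 1] by Gaussian KDE.

    The sample is reflected about 0 and 1 before density estimation to avoid
    boundary bias. Modes are local maxima of the density on [0, 1] with
    height >= ``prominence`` x the global maximum; maxima closer than
    ``min_separation`` are merged to the higher one (a single AF band can
    ripple into adjacent grid maxima at large SNP counts). Returns None
    (missing verdict) when fewer than ``min_snps`` values are available.
    """
    values = np.asarray(values, dtype=float)
    values = values[np.isfinite(values)]
    if values.size < min_snps:
        return None
    if np.ptp(values) < 1e-12:
        loc = float(values[0])
        grid = np.linspace(0, 1, grid_points)
        dens = np.zeros_like(grid)
        dens[np.argmin(np.abs(grid - loc))] = 1.0
        return ModeResult(1, np.array([loc]), np.array([1.0]), grid, dens)
    if bandwidth == "silverman":
        # Silverman's rule on the *original* sample; the reflected copies
        # below must not inflate the data spread the bandwidth sees
        sd = values.std(ddof=1)
        iqr = np.subtract(*np.percentile(values, [75, 25]))
        spread = min(sd, iqr / 1.349) if iqr > 0 else sd
        h = 0.9 * spread * values.size ** (-0.2)
    else:
        h = float(bandwidth)
    h = max(h, 1e-4)
    grid = np.linspace(0.0, 1.0, grid_points)
    # boundary-corrected KDE: reflect the sample about 0 and 1
    reflected = np.concatenate([values, -values, 2.0 - values])
    diff = (grid[:, None] - reflected[None, :]) / h
    dens = np.exp(-0.5 * diff**2).sum(axis=1) / (values.size * h * np.sqrt(2 * np.pi))
    peaks, _ = find_peaks(dens, height=prominence * dens.max())
    # boundary maxima are not interior peaks for find_peaks; check explicitly
    locs = list(grid[peaks])
    heights = list(dens[peaks])
    if dens[0] >= prominence * dens.max() and dens[0] > dens[1]:
        locs.insert(0, grid[0])
        heights.insert(0, dens[0])
    if dens[-1] >= prominence * dens.max() and dens[-1] > dens[-2]:
        locs.append(grid[-1])
        heights.append(dens[-1])
    # merge near-coincident maxima, keeping the higher of each close pair
    merged: list[tuple[float, float]] = []
    for loc, height in sorted(zip(locs, heights), key=lambda t: -t[1]):
        if all(abs(loc - m[0]) >= min_separation for m in merged):
            merged.append((loc, height))
    merged.sort()
    locs_arr = np.array([m[0] for m in merged])
    return ModeResult(
        len(locs_arr), locs_arr, np.array([m[1] for m in merged]), grid, dens
    )


@dataclass
class BandModel:
    """Haplotype chromosome counts in one pool: a of A1, b of A2, c of B."""

    a: int
    b: int
    c: int

    @property
    def total(self) -> int:
        return self.a + self.b + self.c

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) < 0:
            raise ValueError("counts must be >= 0")
        if self.total == 0:
            raise ValueError("empty pool (T = 0)")


def predict_band_frequencies(model: BandModel) -> pd.DataFrame:
    """Expected AF band per site class for a pool, raw and polarised.

    ``alt_frequency`` is the derived-allele frequency in the pool;
    ``polarised`` re-expresses it as the frequency of the A1-fixed reference
    line's major allele (flipped at classes where the reference carries REF).
    """
    t = float(model.total)
    a, b, c = model.a, model.b, model.c
    rows = [
        ("A_shared", (a + b) / t, False),
        ("A1_private", a / t, False),
        ("A2_private", b / t, True),
        ("B_private", c / t, True),
    ]
    return pd.DataFrame(
        {
            "cls": [r[0] for r in rows],
            "alt_frequency": [r[1] for r in rows],
            "polarised": [1.0 - r[1] if r[2] else r[1] for r in rows],
        }
    )
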