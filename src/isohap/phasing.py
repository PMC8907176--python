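"""Genotype-class signatures, phased-haplotype polarisation to a reference
line, phase-switch breakpoint detection and conserved-breakpoint calling.

A phased haplotype polarised against a reference line's major alleles becomes
a binary match/mismatch series along the region; a run change marks a
candidate historical crossover between the reference-like haplotype and the
alternative. Breakpoints recurring within a tolerance across individuals
('conserved') indicate positions where recombination is repeatedly permitted
within an otherwise maintained haplotype.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import MISSING, GenotypeMatrix
from .poolstats import PoolAF

logger = logging.getLogger(__name__)

GENOTYPE_CLASSES = {0: "HOM_REF", 1: "HET", 2: "HOM_ALT", MISSING: "missing"}


def classify_genotypes(gm: GenotypeMatrix) -> np.ndarray:
    """Map dosages to genotype-class labels (samples x sites, object array)."""
    out = np.empty(gm.dosage.shape, dtype=object)
    for d, name in GENOTYPE_CLASSES.items():
        out[gm.dosage == d] = name
    return out


def region_signature(gm: GenotypeMatrix, region: tuple[str, int, int]) -> pd.Series:
    """Majority genotype class per sample over a region's sites.

    Missing genotypes are excluded from the vote; a tie gives 'mixed', an
    all-missing region gives 'missing'.
    """
    chrom, start, end = region
    mask = (
        (gm.sites["chrom"] == chrom)
        & (gm.sites["pos"] >= start)
        & (gm.sites["pos"] <= end)
    ).to_numpy()
    sigs = []
    for i in range(gm.n_samples):
        d = gm.dosage[i, mask]
        d = d[d != MISSING]
        if d.size == 0:
            sigs.append("missing")
            continue
        counts = np.bincount(d, minlength=3)
        top = counts.max()
        winners = np.flatnonzero(counts == top)
        sigs.append("mixed" if len(winners) > 1 else GENOTYPE_CLASSES[int(winners[0])])
    return pd.Series(sigs, index=gm.samples["id"].to_numpy(), name="signature")


@dataclass
class ReferenceHaplotype:
    """The reference line's major allele (0/1) per site, defined only where
    its allele frequency is not exactly 0.5."""

    sites: pd.DataFrame
    major_allele: np.ndarray  # 0/1, MISSING where undefined

    @classmethod
    def from_pool(cls, af: PoolAF, pool_id: str) -> "ReferenceHaplotype":
        ids = list(af.pools["id"])
        r = ids.index(pool_id)
        p = af.freq[r]
        major = np.full(len(p), MISSING, dtype=np.int8)
        major[np.isfinite(p) & (p > 0.5)] = 1
        major[np.isfinite(p) & (p < 0.5)] = 0
        return cls(sites=af.sites, major_allele=major)

    @classmethod
    def from_samples(cls, gm: GenotypeMatrix, sample_ids) -> "ReferenceHaplotype":
        idx = gm.samples["id"].isin(list(sample_ids)).to_numpy()
        d = gm.dosage[idx].astype(float)
        miss = gm.dosage[idx] == MISSING
        d[miss] = 0
        n = 2.0 * (~miss).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n > 0, d.sum(axis=0) / np.maximum(n, 1), np.nan)
        major = np.full(len(p), MISSING, dtype=np.int8)
        major[np.isfinite(p) & (p > 0.5)] = 1
        major[np.isfinite(p) & (p < 0.5)] = 0
        return cls(sites=gm.sites, major_allele=major)


@dataclass
class HaplotypeStates:
    """Binary match(1)/mismatch(0) series per haplotype in a region."""

    sample_id: str
    sex: str
    hap_index: int
    positions: np.ndarray
    states: np.ndarray


def majority_smooth(states: np.ndarray, w: int = 11) -> np.ndarray:
    """Centred moving-majority vote; absorbs isolated genotype/phasing errors
    without moving long run boundaries by more than w//2 sites."""
    if w < 3 or w % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    n = len(states)
    if n == 0:
        return states.copy()
    half = w // 2
    padded = np.concatenate(
        [np.full(half, states[0]), states, np.full(half, states[-1])]
    )
    csum = np.concatenate([[0], np.cumsum(padded)])
    window_sum = csum[w:] - csum[:-w]
    return (window_sum * 2 > w).astype(states.dtype)


def polarise_phased_haplotypes(
    gm: GenotypeMatrix,
    reference: ReferenceHaplotype,
    region: tuple[str, int, int],
    sample_ids=None,
    smooth_window: int | None = None,
    het_sites_only: bool = False,
) -> list[HaplotypeStates]:
    """Match/mismatch series vs the reference for each phased haplotype.

    Sites undefined in the reference (AF exactly 0.5 or missing) are skipped.
    Samples lacking phase anywhere in the region are excluded (logged).
    Typically run on the region-heterozygous individuals, whose two
    haplotypes are informative about both ancestral types.

    Sites where the divergent haplotypes happen to share the reference's
    major allele contribute constant 'match' states to every series; with
    majority smoothing on they cannot move a run boundary. ``het_sites_only``
    restricts each individual's series to its heterozygous sites instead —
    cleaner per site, but a crossover at the edge of a homozygous stretch
    then falls outside the informative series and is missed, so the default
    keeps all reference-defined sites.
    """
    if gm.phase is None:
        raise ValueError("matrix has no phase information")
    chrom, start, end = region
    mask = (
        (gm.sites["chrom"] == chrom)
        & (gm.sites["pos"] >= start)
        & (gm.sites["pos"] <= end)
    ).to_numpy()
    # align the reference to the matrix's region sites by (chrom, pos);
    # sites absent from the reference are treated as undefined
    ref_lookup = pd.Series(
        reference.major_allele,
        index=pd.MultiIndex.from_frame(reference.sites[["chrom", "pos"]]),
    )
    gm_region = pd.MultiIndex.from_frame(gm.sites.loc[mask, ["chrom", "pos"]])
    ref = ref_lookup.reindex(gm_region, fill_value=MISSING).to_numpy().astype(np.int8)
    usable = ref != MISSING
    if usable.sum() < 2:
        raise ValueError("reference defines < 2 sites in the region")
    pos = gm.sites["pos"].to_numpy()[mask][usable]

    wanted = (
        gm.samples["id"].isin(list(sample_ids)).to_numpy()
        if sample_ids is not None
        else np.ones(gm.n_samples, dtype=bool)
    )
    out: list[HaplotypeStates] = []
    for i in np.flatnonzero(wanted):
        sample_phase = gm.phase[i][mask][usable]
        if (sample_phase < 0).any():
            logger.info(
                "polarise_phased_haplotypes: %s unphased in region, excluded",
                gm.samples["id"].iloc[i],
            )
            continue
        if het_sites_only:
            informative = sample_phase[:, 0] != sample_phase[:, 1]
        else:
            informative = np.ones(sample_phase.shape[0], dtype=bool)
        if informative.sum() < 2:
            logger.info(
                "polarise_phased_haplotypes: %s has < 2 informative sites",
                gm.samples["id"].iloc[i],
            )
            continue
        for h in (0, 1):
            states = (
                sample_phase[informative, h] == ref[usable][informative]
            ).astype(np.int8)
            if smooth_window:
                states = majority_smooth(states, smooth_window)
            out.append(
                HaplotypeStates(
                    sample_id=gm.samples["id"].iloc[i],
                    sex=gm.samples["sex"].iloc[i],
                    hap_index=h,
                    positions=pos[informative],
                    states=states,
                )
            )
    return out


def detect_phase_switchpoints(hs: HaplotypeStates) -> np.ndarray:
    """Breakpoint positions: midpoints between consecutive sites whose
    (smoothed) states differ."""
    if len(hs.states) < 2:
        raise ValueError("need >= 2 usable sites")
    change = np.flatnonzero(np.diff(hs.states) != 0)
    return (hs.positions[change] + hs.positions[change + 1]) / 2.0


def conserved_breakpoints(
    state_series: list[HaplotypeStates],
    tol: float = 50_000.0,
    min_support: int = 2,
) -> pd.DataFrame:
    """Cluster per-haplotype breakpoints and report the conserved ones.

    Single-linkage clustering of all breakpoint positions at ``tol``;
    clusters containing >= ``min_support`` distinct samples are reported at
    the cluster median with per-sex support counts.
    """
    rows = []
    for hs in state_series:
        for bp in detect_phase_switchpoints(hs):
            rows.append({"sample_id": hs.sample_id, "sex": hs.sex, "pos": float(bp)})
    if not rows:
        return pd.DataFrame(
            columns=["pos", "n_samples", "n_females", "n_males", "samples"]
        )
    df = pd.DataFrame(rows).sort_values("pos").reset_index(drop=True)
    cluster_id = np.zeros(len(df), dtype=int)
    cid = 0
    for i in range(1, len(df)):
        if df["pos"].iloc[i] - df["pos"].iloc[i - 1] > tol:
            cid += 1
        cluster_id[i] = cid
    df["cluster"] = cluster_id
    out = []
    for _, grp in df.groupby("cluster"):
        samples = sorted(set(grp["sample_id"]))
        if len(samples) < min_support:
            continue
        sex_of = grp.drop_duplicates("sample_id").set_index("sample_id")["sex"]
        out.append(
            {
                "pos": float(grp["pos"].median()),
                "n_samples": len(samples),
                "n_females": int((sex_of == "female").sum()),
                "n_males": int((sex_of == "male").sum()),
                "samples": ",".join(samples),
            }
        )
    return pd.DataFrame(out, columns=["pos", "n_samples", "n_females", "n_males", "samples"])
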