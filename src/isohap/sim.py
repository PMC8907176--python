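"""Synthetic data emulating the Iso-Y breeding design and its source population.

The generator plants one focal region per chromosome carrying three divergent
haplotypes related as a 'Y'-shaped tree: an ancestral A lineage that split
into derived versions A1 and A2, and a distant B haplotype. Region SNPs fall
into four disjoint classes by which branch the derived allele arose on:

* ``A_shared``  — derived on the A stem; carried by A1 and A2, absent from B
* ``A1_private``— derived on the A1 branch only
* ``A2_private``— derived on the A2 branch only
* ``B_private`` — derived on the B branch only

Outside the region, background SNPs segregate independently with population
frequencies drawn from a Beta distribution. Pooled lines drift apart at
background sites under a Balding-Nichols model with differentiation
parameter ``drift_f`` (default 0.09, the genome-wide differentiation level of
the breeding lines this design emulates).

Every generator returns the emitted data together with a :class:`TruthSet`
recording region bounds, compositions, per-individual haplotypes and
crossover positions, so downstream recovery is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .dataio import MISSING, GenotypeMatrix, PoolCountTable

HAPLOTYPE_NAMES = ("A1", "A2", "B")
SITE_CLASSES = ("A_shared", "A1_private", "A2_private", "B_private")

#: which haplotypes carry the derived (alt) allele for each site class
CLASS_CARRIERS = {
    "A_shared": ("A1", "A2"),
    "A1_private": ("A1",),
    "A2_private": ("A2",),
    "B_private": ("B",),
}

_BASES = np.array(list("ACGT"))


@dataclass
class HaplotypeModel:
    """Parameters of the focal-region haplotype tree and the background."""

    chrom: str = "LG1"
    chrom_length: int = 25_000_000
    region_start: int = 12_000_001
    region_end: int = 13_500_000
    #: derived-SNP densities per kb of region, by site class (sum matches the
    #: background density so SNP spacing is continuous across the bounds)
    density_a_shared: float = 0.7
    density_a1_private: float = 0.3
    density_a2_private: float = 0.3
    density_b_private: float = 0.7
    #: background SNP density per kb outside the region
    background_density: float = 2.0
    #: Beta(a, b) of background population allele frequencies
    background_beta: tuple[float, float] = (0.8, 0.8)

    def __post_init__(self) -> None:
        if not (1 <= self.region_start <= self.region_end <= self.chrom_length):
            raise ValueError("region must lie inside the chromosome")
        for d in (
            self.density_a_shared,
            self.density_a1_private,
            self.density_a2_private,
            self.density_b_private,
            self.background_density,
        ):
            if d < 0:
                raise ValueError("densities must be >= 0")


@dataclass
class HaplotypeSet:
    """Simulated site table plus the three focal haplotype allele vectors.

    ``sites`` has columns chrom, pos, ref, alt, cls ('background' or a site
    class) and bg_freq (population alt frequency, NaN at class sites).
    ``alleles`` maps haplotype name -> 0/1 alt indicator over all sites
    (background entries are 0 placeholders; individual background alleles are
    drawn per chromosome at genotype time).
    """

    model: HaplotypeModel
    sites: pd.DataFrame
    alleles: dict[str, np.ndarray]

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def in_region(self) -> np.ndarray:
        return (self.sites["cls"] != "background").to_numpy()


@dataclass
class LineComposition:
    """Diplotype makeup of one pooled line of ``n_individuals`` males."""

    line_id: str
    diplotypes: dict[tuple[str, str], int]

    @property
    def n_individuals(self) -> int:
        return sum(self.diplotypes.values())

    def chromosome_counts(self) -> dict[str, int]:
        counts = {h: 0 for h in HAPLOTYPE_NAMES}
        for (h1, h2), n in self.diplotypes.items():
            counts[h1] += n
            counts[h2] += n
        return counts


@dataclass
class NaturalPopConfig:
    """Sexed natural population carrying the focal haplotypes.

    ``diplotype_freqs`` maps sex -> {(hap, hap): probability}. The default
    emulates a population where every male carries two copies of the derived
    haplotype (a male-specific depletion of the other homozygote class) while
    females follow Hardy-Weinberg proportions at carrier frequency 0.7.
    """

    n_males: int = 10
    n_females: int = 16
    diplotype_freqs: dict[str, dict[tuple[str, str], float]] = field(
        default_factory=lambda: {
            "male": {("A1", "A1"): 1.0},
            "female": hwe_diplotype_freqs({"A1": 0.7, "B": 0.3}),
        }
    )
    recombinant_fraction: float = 0.0
    crossover_positions: tuple[int, ...] = ()
    crossover_weights: tuple[float, ...] | None = None
    error_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.recombinant_fraction <= 1:
            raise ValueError("recombinant_fraction must be in [0, 1]")
        if not 0 <= self.error_rate <= 1:
            raise ValueError("error_rate must be in [0, 1]")
        for sex, freqs in self.diplotype_freqs.items():
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"{sex} diplotype frequencies sum to {total}, not 1")


def hwe_diplotype_freqs(hap_freqs: dict[str, float]) -> dict[tuple[str, str], float]:
    """Diplotype distribution under random mating from haplotype frequencies."""
    names = sorted(hap_freqs)
    out: dict[tuple[str, str], float] = {}
    for i, h1 in enumerate(names):
        for h2 in names[i:]:
            p = hap_freqs[h1] * hap_freqs[h2]
            out[(h1, h2)] = p if h1 == h2 else 2 * p
    return out


@dataclass
class TruthSet:
    """Ground truth emitted alongside simulated data."""

    region: tuple[str, int, int]
    site_classes: pd.Series | None = None
    line_compositions: list[LineComposition] | None = None
    individuals: pd.DataFrame | None = None  # id, sex, hap1, hap2
    crossovers: pd.DataFrame | None = None  # sample_id, hap_index, pos, left, right


# ---------------------------------------------------------------------------
# haplotype simulation
# ---------------------------------------------------------------------------

def simulate_haplotypes(model: HaplotypeModel, seed: int) -> HaplotypeSet:
    """Draw site positions/classes and the three haplotype allele vectors.

    Class site counts are Poisson with mean density x region length; all
    positions (class and background) are drawn without replacement so site
    classes are disjoint. Reproducible given ``seed``.
    """
    rng = np.random.default_rng(seed)
    region_kb = (model.region_end - model.region_start + 1) / 1000.0
    class_counts = {
        "A_shared": rng.poisson(model.density_a_shared * region_kb),
        "A1_private": rng.poisson(model.density_a1_private * region_kb),
        "A2_private": rng.poisson(model.density_a2_private * region_kb),
        "B_private": rng.poisson(model.density_b_private * region_kb),
    }
    n_class = sum(class_counts.values())
    region_span = model.region_end - model.region_start + 1
    if n_class > region_span:
        raise ValueError("region too small for requested class densities")

    bg_span = model.chrom_length - region_span
    n_bg = rng.poisson(model.background_density * bg_span / 1000.0) if bg_span else 0

    # disjoint positions: class sites inside the region, background outside
    class_pos = rng.choice(region_span, size=n_class, replace=False) + model.region_start
    outside = np.concatenate(
        [
            np.arange(1, model.region_start),
            np.arange(model.region_end + 1, model.chrom_length + 1),
        ]
    )
    n_bg = min(n_bg, len(outside))
    bg_pos = rng.choice(outside, size=n_bg, replace=False)

    pos = np.concatenate([class_pos, bg_pos])
    cls = np.concatenate(
        [
            np.repeat(list(class_counts), list(class_counts.values())),
            np.repeat("background", n_bg),
        ]
    )
    bg_freq = np.full(len(pos), np.nan)
    a, b = model.background_beta
    bg_freq[n_class:] = rng.beta(a, b, size=n_bg)

    ref_idx = rng.integers(0, 4, size=len(pos))
    alt_idx = (ref_idx + rng.integers(1, 4, size=len(pos))) % 4

    sites = pd.DataFrame(
        {
            "chrom": model.chrom,
            "pos": pos,
            "ref": _BASES[ref_idx],
            "alt": _BASES[alt_idx],
            "cls": cls,
            "bg_freq": bg_freq,
        }
    )
    order = np.argsort(sites["pos"].to_numpy(), kind="stable")
    sites = sites.iloc[order].reset_index(drop=True)

    alleles = {}
    for hap in HAPLOTYPE_NAMES:
        carried = np.zeros(len(sites), dtype=np.int8)
        for c, carriers in CLASS_CARRIERS.items():
            if hap in carriers:
                carried[(sites["cls"] == c).to_numpy()] = 1
        alleles[hap] = carried
    return HaplotypeSet(model=model, sites=sites, alleles=alleles)


def _balding_nichols(rng, p: np.ndarray, f: float) -> np.ndarray:
    """Line-level allele frequencies drifted from ancestral ``p`` at FST ~ f."""
    if f <= 0:
        return p.copy()
    scale = (1.0 - f) / f
    return rng.beta(np.maximum(p * scale, 1e-9), np.maximum((1.0 - p) * scale, 1e-9))


# ---------------------------------------------------------------------------
# pooled Iso-Y lines
# ---------------------------------------------------------------------------

def default_line_compositions(n: int = 48) -> list[LineComposition]:
    """Four-line design after the breeding study: one line fixed for a derived
    haplotype, the others heterozygous with segregating nested haplotypes."""
    half = n // 2
    return [
        LineComposition("IsoY6", {("A1", "B"): half, ("A2", "B"): n - half}),
        LineComposition("IsoY8", {("A1", "B"): n}),
        LineComposition("IsoY9", {("A1", "A1"): n}),
        LineComposition("IsoY10", {("A2", "B"): n}),
    ]


def simulate_iso_pools(
    haplotypes: HaplotypeSet,
    compositions: list[LineComposition],
    coverage: float = 100.0,
    seed: int = 0,
    drift_f: float = 0.09,
    dirichlet_alpha: float | None = None,
) -> tuple[PoolCountTable, TruthSet]:
    """Pool-seq read counts for each line under equal-contribution pooling.

    Per pool and site, coverage c ~ Poisson(``coverage``) and alt reads ~
    Binomial(c, q) where q is the alt-chromosome fraction in the pool. With
    ``dirichlet_alpha`` set, individual contributions to q are perturbed by a
    Dirichlet(alpha) weight vector instead of being exactly equal.
    """
    if coverage <= 0:
        raise ValueError("coverage must be > 0")
    rng = np.random.default_rng(seed)
    sites = haplotypes.sites
    n_sites = len(sites)
    bg_mask = (sites["cls"] == "background").to_numpy()
    bg_p = sites["bg_freq"].to_numpy()[bg_mask]

    ref_counts = np.zeros((len(compositions), n_sites), dtype=np.int64)
    alt_counts = np.zeros_like(ref_counts)
    pool_rows = []
    for i, comp in enumerate(compositions):
        n_ind = comp.n_individuals
        t = 2 * n_ind
        pool_rows.append({"id": comp.line_id, "size": t})

        # per-individual dosages at every site (region from diplotype classes,
        # background from line-drifted frequencies)
        dosage = np.zeros((n_ind, n_sites), dtype=np.int64)
        row = 0
        for (h1, h2), count in comp.diplotypes.items():
            d = haplotypes.alleles[h1].astype(np.int64) + haplotypes.alleles[h2]
            dosage[row : row + count] = d
            row += count
        line_p = _balding_nichols(rng, bg_p, drift_f)
        dosage[:, bg_mask] = rng.binomial(2, line_p, size=(n_ind, bg_p.size))

        if dirichlet_alpha is not None:
            w = rng.dirichlet(np.full(n_ind, dirichlet_alpha))
            q = w @ (dosage / 2.0)
        else:
            q = dosage.sum(axis=0) / t

        cov = rng.poisson(coverage, size=n_sites)
        alt = rng.binomial(cov, q)
        ref_counts[i] = cov - alt
        alt_counts[i] = alt

    order = np.argsort(sites["pos"].to_numpy(), kind="stable")  # already sorted
    table = PoolCountTable(
        sites=sites[["chrom", "pos", "ref", "alt"]].iloc[order],
        pools=pd.DataFrame(pool_rows),
        ref_count=ref_counts[:, order],
        alt_count=alt_counts[:, order],
    )
    truth = TruthSet(
        region=(haplotypes.model.chrom, haplotypes.model.region_start, haplotypes.model.region_end),
        site_classes=sites["cls"],
        line_compositions=compositions,
    )
    return table, truth


# ---------------------------------------------------------------------------
# sexed natural population
# ---------------------------------------------------------------------------

def simulate_natural_population(
    haplotypes: HaplotypeSet,
    config: NaturalPopConfig,
    seed: int = 0,
) -> tuple[GenotypeMatrix, TruthSet]:
    """Phased genotypes for a sexed population carrying the focal haplotypes.

    Each individual receives two haplotypes drawn from its sex's diplotype
    distribution. With probability ``recombinant_fraction`` a haplotype is a
    recombinant: it switches to a different haplotype class at a crossover
    position drawn from ``crossover_positions`` (weighted). Genotyping errors
    flip individual phase alleles at rate ``error_rate``. All crossovers are
    recorded in the truth set.
    """
    rng = np.random.default_rng(seed)
    sites = haplotypes.sites
    n_sites = len(sites)
    pos = sites["pos"].to_numpy()
    bg_mask = (sites["cls"] == "background").to_numpy()
    bg_p = sites["bg_freq"].to_numpy()[bg_mask]

    # population-wide haplotype frequencies, for drawing recombination partners
    pop_freq = {h: 0.0 for h in HAPLOTYPE_NAMES}
    sex_n = {"male": config.n_males, "female": config.n_females}
    for sex, freqs in config.diplotype_freqs.items():
        for (h1, h2), p in freqs.items():
            pop_freq[h1] += 0.5 * p * sex_n[sex]
            pop_freq[h2] += 0.5 * p * sex_n[sex]
    total = sum(pop_freq.values())
    pop_freq = {h: v / total for h, v in pop_freq.items()}

    if config.crossover_weights is None:
        xo_w = None
    else:
        xo_w = np.asarray(config.crossover_weights, dtype=float)
        xo_w = xo_w / xo_w.sum()
    xo_pos = np.asarray(config.crossover_positions, dtype=np.int64)
    if config.recombinant_fraction > 0 and xo_pos.size == 0:
        raise ValueError("recombinant_fraction > 0 requires crossover_positions")

    ids, sexes, hap1, hap2 = [], [], [], []
    phase = np.zeros((config.n_males + config.n_females, n_sites, 2), dtype=np.int8)
    xo_rows = []

    idx = 0
    for sex, n in (("female", config.n_females), ("male", config.n_males)):
        freqs = config.diplotype_freqs.get(sex)
        if freqs is None:
            raise ValueError(f"no diplotype frequencies for sex {sex!r}")
        diplos = list(freqs)
        probs = np.array([freqs[d] for d in diplos])
        for k in range(n):
            sid = f"NAT{idx + 1:02d}"
            d = diplos[rng.choice(len(diplos), p=probs)]
            labels = []
            for hap_index, h in enumerate(d):
                allele = haplotypes.alleles[h].copy()
                label = h
                if config.recombinant_fraction > 0 and rng.random() < config.recombinant_fraction:
                    others = [o for o in HAPLOTYPE_NAMES if o != h and pop_freq[o] > 0]
                    if others:
                        w = np.array([pop_freq[o] for o in others])
                        partner = others[rng.choice(len(others), p=w / w.sum())]
                        xo = (
                            xo_pos[rng.choice(len(xo_pos), p=xo_w)]
                            if xo_w is not None
                            else xo_pos[rng.integers(len(xo_pos))]
                        )
                        right = pos > xo
                        allele[right] = haplotypes.alleles[partner][right]
                        label = f"{h}>{partner}@{xo}"
                        xo_rows.append(
                            {
                                "sample_id": sid,
                                "hap_index": hap_index,
                                "pos": int(xo),
                                "left": h,
                                "right": partner,
                            }
                        )
                # background alleles: iid Bernoulli(population frequency)
                allele[bg_mask] = rng.random(bg_p.size) < bg_p
                phase[idx, :, hap_index] = allele
                labels.append(label)
            ids.append(sid)
            sexes.append(sex)
            hap1.append(labels[0])
            hap2.append(labels[1])
            idx += 1

    if config.error_rate > 0:
        flips = rng.random(phase.shape) < config.error_rate
        phase[flips] = 1 - phase[flips]

    dosage = phase.sum(axis=2, dtype=np.int8)
    samples = pd.DataFrame({"id": ids, "sex": sexes})
    gm = GenotypeMatrix(
        sites=sites[["chrom", "pos", "ref", "alt"]],
        samples=samples,
        dosage=dosage,
        phase=phase,
    )
    truth = TruthSet(
        region=(haplotypes.model.chrom, haplotypes.model.region_start, haplotypes.model.region_end),
        site_classes=sites["cls"],
        individuals=pd.DataFrame({"id": ids, "sex": sexes, "hap1": hap1, "hap2": hap2}),
        crossovers=pd.DataFrame(
            xo_rows, columns=["sample_id", "hap_index", "pos", "left", "right"]
        ),
    )
    return gm, truth


# ---------------------------------------------------------------------------
# colour phenotype fixture
# ---------------------------------------------------------------------------

def simulate_colour_matrix(
    n_per_group: dict[str, int],
    n_traits: int = 40,
    group_shift: float = 1.0,
    var_inflation: dict[str, float] | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic colour-measurement matrix: shared covariance, per-group mean
    shifts, optional per-group variance inflation. Returns (matrix, labels)."""
    rng = np.random.default_rng(seed)
    var_inflation = var_inflation or {}
    rows, labels = [], []
    for g, (name, n) in enumerate(sorted(n_per_group.items())):
        mean = np.zeros(n_traits)
        mean[g % n_traits] = group_shift
        sd = np.sqrt(var_inflation.get(name, 1.0))
        rows.append(mean + sd * rng.standard_normal((n, n_traits)))
        labels.extend([name] * n)
    return np.vstack(rows), np.array(labels)
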