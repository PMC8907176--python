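"""Shared fixtures: small simulated datasets reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from isohap import poolstats, sim
from isohap.dataio import GenotypeMatrix, PoolCountTable


@pytest.fixture(scope="session")
def small_model():
    """A dense 2 Mb chromosome with a 400 kb focal region (fast unit scale)."""
    return sim.HaplotypeModel(
        chrom="LG1",
        chrom_length=2_000_000,
        region_start=800_001,
        region_end=1_200_000,
        density_a_shared=1.5,
        density_a1_private=0.75,
        density_a2_private=0.75,
        density_b_private=1.5,
        background_density=2.0,
    )


@pytest.fixture(scope="session")
def small_haps(small_model):
    return sim.simulate_haplotypes(small_model, seed=1)


@pytest.fixture(scope="session")
def small_pools(small_haps):
    return sim.simulate_iso_pools(
        small_haps, sim.default_line_compositions(48), coverage=150, seed=2
    )


@pytest.fixture(scope="session")
def small_af(small_pools):
    table, _ = small_pools
    return poolstats.PoolAF.from_counts(table)


@pytest.fixture(scope="session")
def natpop(small_haps):
    """26-individual sexed population with recombinants at three hotspots."""
    cfg = sim.NaturalPopConfig(
        recombinant_fraction=0.3,
        crossover_positions=(900_000, 1_000_000, 1_100_000),
        error_rate=0.002,
        diplotype_freqs={
            "male": sim.hwe_diplotype_freqs({"A1": 0.7, "B": 0.3}),
            "female": sim.hwe_diplotype_freqs({"A1": 0.7, "B": 0.3}),
        },
    )
    return sim.simulate_natural_population(small_haps, cfg, seed=7)


def make_pool_table(rows, pools):
    """Hand-build a PoolCountTable from (chrom,pos,ref,alt,[(r,a),...]) rows."""
    sites = pd.DataFrame(
        [(r[0], r[1], r[2], r[3]) for r in rows],
        columns=["chrom", "pos", "ref", "alt"],
    )
    counts = np.array([r[4] for r in rows], dtype=np.int64)  # sites x pools x 2
    return PoolCountTable(
        sites=sites,
        pools=pd.DataFrame(pools, columns=["id", "size"]),
        ref_count=counts[:, :, 0].T,
        alt_count=counts[:, :, 1].T,
    )


def make_genotypes(dosage, pos=None, sex=None, phase=None, chrom="LG1"):
    """Hand-build a GenotypeMatrix from a dosage array (samples x sites)."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n_samples, n_sites = dosage.shape
    if pos is None:
        pos = np.arange(1, n_sites + 1) * 100
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": pos, "ref": "A", "alt": "G"}
    )
    samples = pd.DataFrame(
        {
            "id": [f"S{i:02d}" for i in range(n_samples)],
            "sex": sex if sex is not None else ["unknown"] * n_samples,
        }
    )
    return GenotypeMatrix(sites=sites, samples=samples, dosage=dosage, phase=phase)
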