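"""Generator correctness: site classes, pooled sampling, population truth."""

import numpy as np
import pytest

from isohap import sim
from isohap.dataio import MISSING
from isohap.sim import HaplotypeModel, LineComposition, NaturalPopConfig


class TestSimulateHaplotypes:
    def test_class_counts_match_densities(self):
        model = HaplotypeModel(
            chrom_length=1_500_000,
            region_start=250_001,
            region_end=1_250_000,
            density_a_shared=2.0,
            density_a1_private=1.0,
            density_a2_private=1.0,
            density_b_private=2.0,
            background_density=1.0,
        )
        haps = sim.simulate_haplotypes(model, seed=3)
        counts = haps.sites["cls"].value_counts()
        # Poisson(mean) counts: allow 5 sigma around the 1 Mb expectations
        for cls, mean in [
            ("A_shared", 2000),
            ("A1_private", 1000),
            ("A2_private", 1000),
            ("B_private", 2000),
        ]:
            assert abs(counts[cls] - mean) < 5 * np.sqrt(mean)

    def test_zero_density_class_absent(self):
        model = HaplotypeModel(
            chrom_length=1_000_000,
            region_start=1,
            region_end=500_000,
            density_a1_private=0.0,
        )
        haps = sim.simulate_haplotypes(model, seed=4)
        assert (haps.sites["cls"] == "A1_private").sum() == 0
        # A1 then only differs from the ancestral A pattern nowhere: it
        # matches A2 except at A2's own private sites
        a2p = (haps.sites["cls"] == "A2_private").to_numpy()
        assert (haps.alleles["A1"][~a2p] == haps.alleles["A2"][~a2p]).all()

    def test_carrier_pattern_per_class(self, small_haps):
        cls = small_haps.sites["cls"].to_numpy()
        a1, a2, b = (small_haps.alleles[h] for h in ("A1", "A2", "B"))
        shared = cls == "A_shared"
        assert (a1[shared] == 1).all() and (a2[shared] == 1).all()
        assert (b[shared] == 0).all()
        assert (b[cls == "B_private"] == 1).all()
        assert (a1[cls == "A2_private"] == 0).all()

    def test_seed_reproducibility(self, small_model):
        h1 = sim.simulate_haplotypes(small_model, seed=9)
        h2 = sim.simulate_haplotypes(small_model, seed=9)
        assert h1.sites.equals(h2.sites)
        for k in h1.alleles:
            np.testing.assert_array_equal(h1.alleles[k], h2.alleles[k])

    def test_region_too_small_raises(self):
        model = HaplotypeModel(
            chrom_length=10_000, region_start=1, region_end=100,
            density_a_shared=5000.0,
        )
        with pytest.raises(ValueError, match="too small"):
            sim.simulate_haplotypes(model, seed=0)


class TestSimulateIsoPools:
    def test_fixed_line_concentrates_at_one(self, small_haps, small_pools):
        from isohap.poolstats import PoolAF

        table, truth = small_pools
        af = PoolAF.from_counts(table)
        iso9 = list(table.pools["id"]).index("IsoY9")
        cls = truth.site_classes.to_numpy()
        carried = np.isin(cls, ["A_shared", "A1_private"])
        assert np.nanmean(af.freq[iso9, carried]) > 0.98

    def test_heterozygous_line_near_half(self, small_haps, small_pools):
        from isohap.poolstats import PoolAF

        table, truth = small_pools
        af = PoolAF.from_counts(table)
        iso8 = list(table.pools["id"]).index("IsoY8")  # 48 x A1/B
        cls = truth.site_classes.to_numpy()
        a_lineage = np.isin(cls, ["A_shared", "A1_private"])
        assert abs(np.nanmean(af.freq[iso8, a_lineage]) - 0.5) < 0.02

    def test_mixed_line_band_fractions(self, small_haps):
        # 24 A1/B + 24 A2/B: chromosome counts 24/96, 24/96, 48/96
        comp = LineComposition("mix", {("A1", "B"): 24, ("A2", "B"): 24})
        table, truth = sim.simulate_iso_pools(
            small_haps, [comp], coverage=200, seed=5
        )
        from isohap.poolstats import PoolAF

        af = PoolAF.from_counts(table)
        cls = truth.site_classes.to_numpy()
        for c, expected in [
            ("A1_private", 0.25),
            ("A2_private", 0.25),
            ("A_shared", 0.5),
            ("B_private", 0.5),
        ]:
            assert abs(np.nanmean(af.freq[0, cls == c]) - expected) < 0.02

    def test_pooled_af_estimator_unbiased(self):
        model = HaplotypeModel(
            chrom_length=100_000, region_start=1, region_end=100_000,
            background_density=0.0,
        )
        haps = sim.simulate_haplotypes(model, seed=6)
        comp = LineComposition("mix", {("A1", "B"): 24, ("A2", "B"): 24})
        cls = haps.sites["cls"].to_numpy()
        sums = np.zeros(haps.n_sites)
        reps = 200
        for r in range(reps):
            table, _ = sim.simulate_iso_pools(haps, [comp], coverage=100, seed=100 + r)
            from isohap.poolstats import PoolAF

            sums += PoolAF.from_counts(table).freq[0]
        mean_af = sums / reps
        q = (24 * haps.alleles["A1"] + 24 * haps.alleles["A2"] + 48 * haps.alleles["B"]) / 96
        # mean over replicates converges on q: tolerance 4 binomial SEs
        se = np.sqrt(0.25 / (100 * reps))
        assert np.abs(mean_af[cls != "background"] - q[cls != "background"]).max() < 6 * se + 0.01

    def test_determinism_and_truth_consistency(self, small_haps):
        comps = sim.default_line_compositions(48)
        t1, truth = sim.simulate_iso_pools(small_haps, comps, coverage=80, seed=11)
        t2, _ = sim.simulate_iso_pools(small_haps, comps, coverage=80, seed=11)
        np.testing.assert_array_equal(t1.alt_count, t2.alt_count)
        assert truth.region == (
            small_haps.model.chrom,
            small_haps.model.region_start,
            small_haps.model.region_end,
        )
        assert all(c.n_individuals == 48 for c in truth.line_compositions)

    def test_bad_coverage_rejected(self, small_haps):
        with pytest.raises(ValueError, match="coverage"):
            sim.simulate_iso_pools(
                small_haps, sim.default_line_compositions(4), coverage=0, seed=0
            )


class TestNaturalPopulation:
    def test_pure_population_has_no_crossovers(self, small_haps):
        cfg = NaturalPopConfig()
        gm, truth = sim.simulate_natural_population(small_haps, cfg, seed=3)
        assert len(truth.crossovers) == 0
        assert gm.phase is not None
        np.testing.assert_array_equal(gm.dosage, gm.phase.sum(axis=2))
        # males are all A1/A1 under the default male-carrier config
        males = truth.individuals.query("sex == 'male'")
        assert (males["hap1"] == "A1").all() and (males["hap2"] == "A1").all()

    def test_crossovers_only_at_hotspots(self, natpop):
        _, truth = natpop
        assert len(truth.crossovers) > 0
        assert set(truth.crossovers["pos"]).issubset({900_000, 1_000_000, 1_100_000})

    def test_male_homref_deficit_creates_intersex_contrast(self, small_haps):
        gm, truth = sim.simulate_natural_population(
            small_haps, NaturalPopConfig(), seed=13
        )
        sex = gm.samples["sex"].to_numpy()
        cls = truth.site_classes.to_numpy()
        a_sites = np.isin(cls, ["A_shared", "A1_private"])
        p_m = gm.dosage[sex == "male"][:, a_sites].mean() / 2
        p_f = gm.dosage[sex == "female"][:, a_sites].mean() / 2
        # males fixed for the carrier haplotype, females near HWE(0.7)
        # (16 drawn diplotypes; allow sampling noise ~ 2*sqrt(p q / 32))
        assert p_m > 0.95
        assert abs(p_f - 0.7) < 0.17
        assert p_m - p_f > 0.1

    def test_error_rate_flips_alleles(self, small_haps):
        cfg0 = NaturalPopConfig(error_rate=0.0)
        cfg1 = NaturalPopConfig(error_rate=0.05)
        g0, _ = sim.simulate_natural_population(small_haps, cfg0, seed=21)
        g1, _ = sim.simulate_natural_population(small_haps, cfg1, seed=21)
        frac = (g0.phase != g1.phase).mean()
        assert 0.03 < frac < 0.07

    def test_recombination_requires_hotspots(self, small_haps):
        with pytest.raises(ValueError, match="crossover_positions"):
            sim.simulate_natural_population(
                small_haps,
                NaturalPopConfig(recombinant_fraction=0.5),
                seed=0,
            )


def test_colour_matrix_groups_and_inflation():
    x, labels = sim.simulate_colour_matrix(
        {"a": 30, "b": 30}, n_traits=20, var_inflation={"b": 9.0}, seed=1
    )
    assert x.shape == (60, 20) and (labels == "a").sum() == 30
    va = x[labels == "a"].var(axis=0, ddof=1).sum()
    vb = x[labels == "b"].var(axis=0, ddof=1).sum()
    assert vb / va > 5
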