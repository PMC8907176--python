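"""Intersex windowed statistics, quantile outliers, HWE and LD matrices."""

import numpy as np
import pandas as pd
import pytest

from isohap import natscan, sim
from isohap.dataio import MISSING, WindowTrack, concat_genotype_matrices
from isohap.natscan import (
    GroupSpec,
    hudson_fst_site,
    hwe_expected_counts,
    ld_r2_matrix,
    window_quantile_outliers,
    windowed_da,
    windowed_dxy,
    windowed_intersex_fst,
    windowed_pi,
)

from conftest import make_genotypes


class TestHudsonFst:
    def test_toy_counts_match_hand_evaluation(self):
        # males 3/10 alt alleles, females 12/20
        p1, n1, p2, n2 = 0.3, 10.0, 0.6, 20.0
        expected_num = (
            (p1 - p2) ** 2 - p1 * (1 - p1) / (n1 - 1) - p2 * (1 - p2) / (n2 - 1)
        )
        expected_den = p1 * (1 - p2) + p2 * (1 - p1)
        got = hudson_fst_site(
            np.array([p1]), np.array([n1]), np.array([p2]), np.array([n2])
        )
        assert got[0] == pytest.approx(expected_num / expected_den, abs=1e-15)

    def test_identical_frequencies_near_zero_window(self):
        rng = np.random.default_rng(0)
        dosage = rng.binomial(2, 0.4, size=(20, 200)).astype(np.int8)
        gm = make_genotypes(dosage, sex=["male"] * 10 + ["female"] * 10,
                            pos=np.arange(1, 201) * 5)
        track = windowed_intersex_fst(gm, width=1000)
        assert abs(np.nanmean(track.value)) < 0.05

    def test_opposite_fixation_gives_one(self):
        dosage = np.vstack([np.full((5, 10), 2), np.zeros((5, 10))]).astype(np.int8)
        gm = make_genotypes(dosage, sex=["male"] * 5 + ["female"] * 5)
        track = windowed_intersex_fst(gm, width=10_000)
        assert track.value[0] == pytest.approx(1.0)


class TestDxyPiDa:
    def test_site_dxy_half_when_groups_at_half(self):
        # p_m = p_f = 0.5 exactly: half of each group carries 2, half 0
        col = np.array([0, 0, 2, 2, 0, 0, 2, 2], dtype=np.int8)
        dosage = np.repeat(col[:, None], 10, axis=1)
        gm = make_genotypes(dosage, sex=["male"] * 4 + ["female"] * 4)
        g = GroupSpec.by_sex(gm)
        track = windowed_dxy(gm, g, width=1000)
        # one 1 kb window with 10 sites at d_xy 0.5 each
        assert track.value[0] == pytest.approx(10 * 0.5 / 1000)

    def test_monomorphic_window_zero(self):
        gm = make_genotypes(np.zeros((6, 4), dtype=np.int8),
                            sex=["male"] * 3 + ["female"] * 3)
        g = GroupSpec.by_sex(gm)
        assert windowed_dxy(gm, g, width=1000).value[0] == 0.0
        assert windowed_pi(gm, g.idx2, width=1000).value[0] == 0.0

    def test_single_site_window_value(self):
        # one site at p_m = 1, p_f = 0.5 in a 1 kb window
        dosage = np.array([[2], [2], [2], [2], [0], [2], [1], [1]], dtype=np.int8)
        gm = make_genotypes(dosage, sex=["male"] * 4 + ["female"] * 4, pos=[500])
        g = GroupSpec.by_sex(gm)
        track = windowed_dxy(gm, g, width=1000)
        assert track.value[0] == pytest.approx(0.5 / 1000)

    def test_da_subtracts_female_pi_and_propagates_missing(self):
        dxy = WindowTrack("LG1", [1, 1001], [1000, 2000], [0.004, np.nan])
        pif = WindowTrack("LG1", [1, 1001], [1000, 2000], [0.003, 0.001])
        da = windowed_da(dxy, pif)
        assert da.value[0] == pytest.approx(0.001)
        assert np.isnan(da.value[1])

    def test_misaligned_windows_rejected(self):
        dxy = WindowTrack("LG1", [1], [1000], [0.004])
        pif = WindowTrack("LG1", [1, 1001], [1000, 2000], [0.003, 0.001])
        with pytest.raises(ValueError, match="misaligned"):
            windowed_da(dxy, pif)

    def test_male_deficit_region_depresses_da(self, small_haps, small_model):
        gm, _ = sim.simulate_natural_population(
            small_haps, sim.NaturalPopConfig(), seed=5
        )
        g = GroupSpec.by_sex(gm)
        dxy = windowed_dxy(gm, g, width=10_000)
        pif = windowed_pi(gm, g.idx2, width=10_000)
        da = windowed_da(dxy, pif)
        in_region = (da.start >= small_model.region_start) & (
            da.end <= small_model.region_end
        )
        assert np.nanmean(da.value[in_region]) < np.nanmean(da.value[~in_region])


class TestQuantileOutliers:
    def test_uniform_track_flags_about_ten_percent(self):
        rng = np.random.default_rng(1)
        n = 2000
        track = WindowTrack(
            "LG1",
            np.arange(n) * 1000 + 1,
            np.arange(n) * 1000 + 1000,
            rng.uniform(size=n),
        )
        out = window_quantile_outliers(track)
        flagged = sum(
            (r["end"] - r["start"] + 1) // 1000 for _, r in out.regions.iterrows()
        )
        assert abs(flagged / n - 0.10) < 0.02

    def test_single_spike_flagged_exactly(self):
        # constant background: the empirical q95 equals the background value,
        # so only the strictly-greater spiked window is flagged
        v = np.zeros(1000)
        v[500] = 10.0
        track = WindowTrack(
            "LG1", np.arange(1000) * 1000 + 1, np.arange(1000) * 1000 + 1000, v
        )
        out = window_quantile_outliers(track, tails="high")
        high = out.regions
        assert len(high) == 1
        assert high.iloc[0]["start"] == 500 * 1000 + 1

    def test_missing_windows_never_flagged(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=100)
        v[10:20] = np.nan
        track = WindowTrack(
            "LG1", np.arange(100) * 1000 + 1, np.arange(100) * 1000 + 1000, v
        )
        out = window_quantile_outliers(track)
        for _, r in out.regions.iterrows():
            assert not (10_001 <= r["start"] <= 19_001 and r["end"] <= 20_000)

    def test_insufficient_windows_rejected(self):
        track = WindowTrack("LG1", [1], [1000], [0.5])
        with pytest.raises(ValueError, match="20"):
            window_quantile_outliers(track)


class TestHwe:
    def test_fixed_and_symmetric_cases(self):
        np.testing.assert_allclose(hwe_expected_counts(1.0, 7), [7, 0, 0])
        np.testing.assert_allclose(hwe_expected_counts(0.5, 10), [2.5, 5, 2.5])

    def test_closed_form(self):
        exp = hwe_expected_counts(0.8125, 10)
        np.testing.assert_allclose(exp, [6.6015625, 3.046875, 0.3515625])

    def test_chisquare_detects_deviation(self):
        # observed all HOM ALT at p = 0.7: strongly out of HWE
        _, stat, p = hwe_expected_counts(0.7, 10, observed=[10, 0, 0])
        assert p < 0.01
        _, _, p_ok = hwe_expected_counts(0.7, 10, observed=[5, 4, 1])
        assert p_ok > 0.1


class TestLd:
    def test_self_r2_is_one_and_symmetry(self):
        rng = np.random.default_rng(4)
        dosage = rng.binomial(2, 0.4, size=(20, 8)).astype(np.int8)
        gm = make_genotypes(dosage, pos=np.arange(8) * 6000 + 1)
        mat = ld_r2_matrix(gm, thin=5000)
        np.testing.assert_allclose(np.diag(mat.r2), 1.0)
        np.testing.assert_allclose(mat.r2, mat.r2.T, atol=1e-12)
        assert np.nanmax(mat.r2) <= 1.0 + 1e-9

    def test_hand_computed_pair(self):
        dosage = np.array([[0, 0], [1, 1], [2, 2], [0, 2]], dtype=np.int8)
        gm = make_genotypes(dosage, pos=[1, 6001])
        mat = ld_r2_matrix(gm, thin=5000)
        assert mat.r2[0, 1] == pytest.approx(0.2066, abs=0.0005)

    def test_allele_relabel_invariance(self):
        rng = np.random.default_rng(5)
        dosage = rng.binomial(2, 0.5, size=(15, 4)).astype(np.int8)
        gm = make_genotypes(dosage, pos=np.arange(4) * 6000 + 1)
        gm2 = make_genotypes(2 - dosage, pos=np.arange(4) * 6000 + 1)
        np.testing.assert_allclose(
            ld_r2_matrix(gm).r2, ld_r2_matrix(gm2).r2, atol=1e-12
        )

    def test_thinning_keeps_first_snp_per_bin(self):
        rng = np.random.default_rng(6)
        dosage = rng.binomial(2, 0.5, size=(10, 4)).astype(np.int8)
        gm = make_genotypes(dosage, pos=[100, 200, 5100, 5200])
        mat = ld_r2_matrix(gm, thin=5000)
        assert list(mat.sites["pos"]) == [100, 5100]

    def test_monomorphic_snps_excluded(self):
        dosage = np.column_stack(
            [np.zeros(10), np.random.default_rng(7).binomial(2, 0.5, 10),
             np.random.default_rng(8).binomial(2, 0.5, 10)]
        ).astype(np.int8)
        gm = make_genotypes(dosage, pos=[1, 6001, 12001])
        mat = ld_r2_matrix(gm, thin=5000)
        assert 1 not in list(mat.sites["pos"])

    def test_interchromosomal_r2_near_null_expectation(self):
        # unlinked chromosomes: E[r^2] ~ 1/n for n samples
        models = [
            sim.HaplotypeModel(
                chrom=c, chrom_length=2_000_000, region_start=1, region_end=2,
                density_a_shared=0, density_a1_private=0, density_a2_private=0,
                density_b_private=0, background_density=1.0,
                background_beta=(2.0, 2.0),
            )
            for c in ("LG1", "LG2")
        ]
        cfg = sim.NaturalPopConfig(
            n_males=13, n_females=13,
            diplotype_freqs={
                "male": {("A1", "A1"): 1.0},
                "female": {("A1", "A1"): 1.0},
            },
        )
        parts = [
            sim.simulate_natural_population(
                sim.simulate_haplotypes(m, seed=40 + i), cfg, seed=50 + i
            )[0]
            for i, m in enumerate(models)
        ]
        gm = concat_genotype_matrices(parts)
        mat = ld_r2_matrix(gm, thin=5000, cross=("LG1", "LG2"))
        n = 26
        mean_r2 = np.nanmean(mat.r2)
        se = np.nanstd(mat.r2) / np.sqrt(mat.r2.size)
        assert abs(mean_r2 - 1 / n) < max(2 * se, 0.01)


def test_genotype_filter_rules():
    dosage = np.array(
        [
            [0, 2, MISSING, 1],
            [0, 2, MISSING, 1],
            [0, 1, MISSING, 0],
            [0, 1, 1, 2],
        ],
        dtype=np.int8,
    )
    gm = make_genotypes(dosage)
    kept, log = natscan.filter_genotype_variants(gm, max_missing=0.5, maf=0.10)
    # site 1 monomorphic (maf 0), site 3 75% missing
    assert list(kept.sites["pos"]) == [200, 400]
    assert log["missingness"] == 1 and log["maf"] == 1
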