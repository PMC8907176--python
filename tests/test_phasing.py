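"""Genotype classes, haplotype polarisation and breakpoint calling."""

import numpy as np
import pandas as pd
import pytest

from isohap import natscan, phasing, poolstats, sim
from isohap.dataio import MISSING
from isohap.phasing import (
    HaplotypeStates,
    ReferenceHaplotype,
    classify_genotypes,
    conserved_breakpoints,
    detect_phase_switchpoints,
    majority_smooth,
    polarise_phased_haplotypes,
    region_signature,
)

from conftest import make_genotypes


class TestGenotypeClasses:
    def test_dosage_mapping(self):
        gm = make_genotypes([[0, 1, 2, MISSING]])
        classes = classify_genotypes(gm)
        assert classes[0].tolist() == ["HOM_REF", "HET", "HOM_ALT", "missing"]

    def test_majority_signature(self):
        # 60% HOM_ALT / 40% HET -> HOM_ALT
        gm = make_genotypes([[2, 2, 2, 1, 1]])
        sig = region_signature(gm, ("LG1", 1, 1000))
        assert sig.iloc[0] == "HOM_ALT"

    def test_all_missing_region(self):
        gm = make_genotypes([[MISSING, MISSING]])
        assert region_signature(gm, ("LG1", 1, 1000)).iloc[0] == "missing"

    def test_tie_is_mixed(self):
        gm = make_genotypes([[2, 2, 1, 1]])
        assert region_signature(gm, ("LG1", 1, 1000)).iloc[0] == "mixed"


def phased_gm(hap0, hap1, pos=None):
    hap0 = np.asarray(hap0, dtype=np.int8)
    hap1 = np.asarray(hap1, dtype=np.int8)
    phase = np.stack([hap0, hap1], axis=1)[None, :, :]
    return make_genotypes((hap0 + hap1)[None, :], pos=pos, phase=phase,
                          sex=["female"])


def reference_all_ones(gm):
    return ReferenceHaplotype(
        sites=gm.sites, major_allele=np.ones(gm.n_sites, dtype=np.int8)
    )


class TestPolarisation:
    def test_identical_and_complement_haplotypes(self):
        gm = phased_gm([1, 1, 1, 1], [0, 0, 0, 0])
        states = polarise_phased_haplotypes(
            gm, reference_all_ones(gm), ("LG1", 1, 1000)
        )
        np.testing.assert_array_equal(states[0].states, 1)
        np.testing.assert_array_equal(states[1].states, 0)

    def test_single_flip_absorbed_by_smoothing(self):
        hap = np.ones(30, dtype=np.int8)
        hap[15] = 0
        gm = phased_gm(hap, np.zeros(30, dtype=np.int8))
        states = polarise_phased_haplotypes(
            gm, reference_all_ones(gm), ("LG1", 1, 5000), smooth_window=11
        )
        np.testing.assert_array_equal(states[0].states, 1)
        assert len(detect_phase_switchpoints(states[0])) == 0

    def test_reference_complement_preserves_breakpoints(self):
        hap0 = np.concatenate([np.ones(20), np.zeros(20)]).astype(np.int8)
        gm = phased_gm(hap0, 1 - hap0)
        ref = reference_all_ones(gm)
        anti = ReferenceHaplotype(sites=gm.sites, major_allele=1 - ref.major_allele)
        s_ref = polarise_phased_haplotypes(gm, ref, ("LG1", 1, 5000))
        s_anti = polarise_phased_haplotypes(gm, anti, ("LG1", 1, 5000))
        np.testing.assert_array_equal(s_ref[0].states, 1 - s_anti[0].states)
        np.testing.assert_array_equal(
            detect_phase_switchpoints(s_ref[0]), detect_phase_switchpoints(s_anti[0])
        )

    def test_unphased_sample_excluded(self):
        gm = make_genotypes([[1, 1]], sex=["female"])  # no phase at all
        with pytest.raises(ValueError, match="no phase"):
            polarise_phased_haplotypes(gm, reference_all_ones(gm), ("LG1", 1, 1000))

    def test_smoothing_window_must_be_odd(self):
        with pytest.raises(ValueError, match="odd"):
            majority_smooth(np.ones(10, dtype=np.int8), w=4)


class TestSwitchpoints:
    def test_constant_series_none(self):
        hs = HaplotypeStates("s", "female", 0, np.arange(10) * 100, np.ones(10, dtype=np.int8))
        assert len(detect_phase_switchpoints(hs)) == 0

    def test_midpoint_convention(self):
        pos = np.array([12_150_000, 12_190_000, 12_210_000, 12_300_000])
        states = np.array([1, 1, 0, 0], dtype=np.int8)
        hs = HaplotypeStates("s", "female", 0, pos, states)
        bp = detect_phase_switchpoints(hs)
        assert bp.tolist() == [12_200_000.0]

    def test_short_series_rejected(self):
        hs = HaplotypeStates("s", "female", 0, np.array([100]), np.array([1], dtype=np.int8))
        with pytest.raises(ValueError, match=">= 2"):
            detect_phase_switchpoints(hs)


class TestConserved:
    def make_states(self, specs):
        out = []
        for sid, sex, bp in specs:
            pos = np.array([bp - 20_000, bp - 10, bp + 10, bp + 20_000])
            states = np.array([1, 1, 0, 0], dtype=np.int8)
            out.append(HaplotypeStates(sid, sex, 0, pos, states))
        return out

    def test_two_samples_within_tolerance_cluster(self):
        cons = conserved_breakpoints(
            self.make_states([("a", "female", 100_000), ("b", "male", 110_000)])
        )
        assert len(cons) == 1
        assert cons.iloc[0]["n_samples"] == 2
        assert cons.iloc[0]["n_females"] == 1 and cons.iloc[0]["n_males"] == 1

    def test_samples_beyond_tolerance_not_conserved(self):
        cons = conserved_breakpoints(
            self.make_states([("a", "female", 100_000), ("b", "female", 160_000)])
        )
        assert len(cons) == 0

    def test_same_sample_twice_is_single_support(self):
        cons = conserved_breakpoints(
            self.make_states([("a", "female", 100_000), ("a", "female", 101_000)])
        )
        assert len(cons) == 0


@pytest.fixture(scope="module")
def pipeline(small_haps, small_pools, natpop):
    table, _ = small_pools
    gm, truth = natpop
    gm_f, _ = natscan.filter_genotype_variants(gm)
    af = poolstats.PoolAF.from_counts(table)
    ref = ReferenceHaplotype.from_pool(af, "IsoY9")
    region = (
        small_haps.model.chrom,
        small_haps.model.region_start,
        small_haps.model.region_end,
    )
    states = polarise_phased_haplotypes(gm_f, ref, region, smooth_window=11)
    return states, truth


class TestSimulatedRecovery:
    def test_precision_and_recall_of_conserved_breakpoints(self, pipeline):
        states, truth = pipeline
        cons = conserved_breakpoints(states)
        true_hotspots = (
            truth.crossovers.groupby("pos")["sample_id"].nunique()
        )
        true_conserved = true_hotspots[true_hotspots >= 2].index.to_numpy(float)
        detected = cons["pos"].to_numpy()
        tol = 50_000
        matched_det = sum(
            np.min(np.abs(true_conserved - d)) <= tol for d in detected
        )
        matched_true = sum(
            np.min(np.abs(detected - t)) <= tol for t in true_conserved
        )
        assert matched_det / max(len(detected), 1) >= 0.9  # precision
        assert matched_true / len(true_conserved) >= 0.9  # recall

    def test_sex_tallies_match_truth(self, pipeline):
        states, truth = pipeline
        cons = conserved_breakpoints(states)
        sex_of = truth.individuals.set_index("id")["sex"]
        for _, row in cons.iterrows():
            near = truth.crossovers[
                np.abs(truth.crossovers["pos"] - row["pos"]) <= 50_000
            ]
            expected_f = sex_of[near["sample_id"].unique()].eq("female").sum()
            assert row["n_females"] == expected_f

    def test_male_zygosity_deviates_from_hwe_in_deficit_region(self, small_haps):
        gm, truth = sim.simulate_natural_population(
            small_haps, sim.NaturalPopConfig(), seed=17
        )
        cls = truth.site_classes.to_numpy()
        informative = cls == "A_shared"
        sex = gm.samples["sex"].to_numpy()
        females = gm.dosage[sex == "female"][:, informative]
        males = gm.dosage[sex == "male"][:, informative]
        p_f = females.mean() / 2
        # genotype-class counts at a representative site-averaged scale
        def class_counts(d):
            return [
                int((d == 2).sum(1).mean().round()),
                int((d == 1).sum(1).mean().round()),
                int((d == 0).sum(1).mean().round()),
            ]

        n_m = males.shape[0]
        obs_m = np.array([ (males == k).mean(0).mean() * n_m for k in (2, 1, 0)])
        _, _, p_male = natscan.hwe_expected_counts(p_f, n_m, observed=obs_m)
        n_f = females.shape[0]
        obs_f = np.array([(females == k).mean(0).mean() * n_f for k in (2, 1, 0)])
        _, _, p_female = natscan.hwe_expected_counts(p_f, n_f, observed=obs_f)
        assert p_male < 0.01
        assert p_female > 0.1


from hypothesis import given, settings
from hypothesis import strategies as st


@settings(derandomize=True, max_examples=50, deadline=None)
@given(
    states=st.lists(st.integers(0, 1), min_size=1, max_size=200),
    w=st.sampled_from([3, 5, 11]),
)
def test_majority_smoothing_complement_symmetry(states, w):
    """Smoothing commutes with complementing the state labels and never
    leaves {0, 1}."""
    arr = np.array(states, dtype=np.int8)
    sm = majority_smooth(arr, w)
    sm_c = majority_smooth(1 - arr, w)
    assert set(np.unique(sm)) <= {0, 1}
    np.testing.assert_array_equal(sm, 1 - sm_c)
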