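"""End-to-end evaluation of the pipeline on its default synthetic study.

Each function regenerates data under the package's default study conditions
(four pools of 48 males, one line fixed for a derived haplotype; a
26-individual sexed population) and measures how well the analysis chain
recovers the planted truth, plus oracle-equivalence and statistical
calibration checks. Used by the acceptance script and the acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import bands, breeding, localpca, natscan, permtest, phasing, poolstats, segment, sim, zscan

#: recombination hotspots planted in the natural population (bp)
DEFAULT_HOTSPOTS = (12_200_000, 12_700_000, 13_100_000)


def backcross_metrics() -> dict:
    """Homogenisation arithmetic of the repeated-backcross breeding design."""
    g14 = breeding.homogenised_fraction(14)
    residuals = [breeding.residual_parental_fraction(g) for g in range(14, 21)]
    return {
        "backcross_homogenised_pct_g14": {"value": 100 * g14, "n": 14},
        "backcross_max_residual_pct_g14_20": {"value": 100 * max(residuals), "n": 7},
    }


def oracle_errors(seed: int) -> dict:
    """Implementation-vs-independent-oracle discrepancies (ideally ~0)."""
    rng = np.random.default_rng(seed)

    # pooled ANOVA FST vs a separately coded evaluation of the same formula
    from .poolstats import PoolAF, pairwise_pool_fst, weir_cockerham_fst_counts

    def af_of(freqs, covs, sizes):
        n_pools, n_sites = np.shape(freqs)
        sites = pd.DataFrame(
            {"chrom": "LG1", "pos": np.arange(1, n_sites + 1) * 1000,
             "ref": "A", "alt": "G"}
        )
        pools = pd.DataFrame({"id": [f"p{i}" for i in range(n_pools)], "size": sizes})
        return PoolAF(sites=sites, pools=pools, freq=np.asarray(freqs, float),
                      coverage=np.asarray(covs, float))

    c1 = c2 = 40.0
    p1, p2, n = 10 / c1, 30 / c2, 96.0
    nt1 = c1 * n / (c1 + n - 1)
    nt2 = c2 * n / (c2 + n - 1)
    pbar = (nt1 * p1 + nt2 * p2) / (nt1 + nt2)
    msp = nt1 * (p1 - pbar) ** 2 + nt2 * (p2 - pbar) ** 2
    msg = (nt1 * p1 * (1 - p1) + nt2 * p2 * (1 - p2)) / (nt1 + nt2 - 2)
    n_c = (nt1 + nt2) - (nt1**2 + nt2**2) / (nt1 + nt2)
    expected = (msp - msg) / (msp + (n_c - 1) * msg)
    got = pairwise_pool_fst(af_of([[p1], [p2]], [[c1], [c2]], [96, 96])).per_site[0]
    fst_formula_err = abs(got - expected)

    # allele-count limit vs the classic Weir-Cockerham estimator
    k1 = rng.integers(1, 96, size=20)
    k2 = rng.integers(1, 96, size=20)
    af = af_of(np.stack([k1 / 96, k2 / 96]), np.full((2, 20), 1e16), [96, 96])
    res = pairwise_pool_fst(af)
    wc_err = max(
        abs(res.per_site[j] - np.divide(*weir_cockerham_fst_counts(k1[j], 96, k2[j], 96)))
        for j in range(20)
    )

    # binary segmentation first split vs exhaustive single-split search
    binseg_mismatches = 0
    for i in range(20):
        r = np.random.default_rng(seed + 100 + i)
        m = int(r.integers(20, 200))
        x = r.normal(size=m) + np.where(np.arange(m) > m // 3, 1.0, 0.0)
        cfg = segment.ChangepointConfig(max_changepoints=1, escalation_max=1, normalise=False)
        cps = segment.binseg_mean(x, cfg)
        if cps.n_changepoints and cps.indices[0] != segment.exhaustive_single_split(x):
            binseg_mismatches += 1

    # window PCA / classical MDS vs brute-force eigen-decomposition
    dosage = rng.binomial(2, 0.4, size=(6, 30)).astype(np.int8)
    sites = pd.DataFrame({"chrom": "LG1", "pos": np.arange(30) * 10 + 1,
                          "ref": "A", "alt": "G"})
    from .dataio import GenotypeMatrix

    gm = GenotypeMatrix(sites=sites,
                        samples=pd.DataFrame({"id": [f"s{i}" for i in range(6)]}),
                        dosage=dosage)
    w = localpca.window_pca(gm, 0, 30, k=3)
    x = dosage.astype(float)
    x = x[:, x.std(axis=0) > 0]
    x = x - x.mean(axis=0)
    cov = x @ x.T / x.shape[1]
    cov /= np.trace(cov)
    vals = np.linalg.eigvalsh(cov)[::-1]
    pca_err = float(np.abs(w.eigenvalues - vals[:3]).max())

    coords = np.sort(rng.normal(size=8))
    from scipy.spatial.distance import pdist, squareform

    dist = squareform(pdist(coords[:, None]))
    mds = localpca.classical_mds(dist, m=2)
    centred = coords - coords.mean()
    mds_err = float(
        min(np.abs(mds.coords[:, 0] - centred).max(),
            np.abs(mds.coords[:, 0] + centred).max())
    )

    # PERMANOVA partition vs the hand-computed toy
    res_p = permtest.permanova(
        np.array([0.0, 0.1, 1.0, 1.1]), np.array(["a", "a", "b", "b"]),
        n_permutations=99, seed=seed,
    )
    perm_err = max(
        abs(res_p.ss_between - 1.0), abs(res_p.ss_within - 0.01),
        abs(res_p.pseudo_f - 200.0) / 200.0,
    )

    return {
        "oracle_pool_fst_formula_abs_err": {"value": float(fst_formula_err), "n": 1},
        "oracle_pool_fst_wc_limit_abs_err": {"value": float(wc_err), "n": 20},
        "oracle_binseg_exhaustive_mismatches": {"value": binseg_mismatches, "n": 20},
        "oracle_window_pca_eigenvalue_abs_err": {"value": pca_err, "n": 6},
        "oracle_mds_embedding_abs_err": {"value": mds_err, "n": 8},
        "oracle_permanova_partition_rel_err": {"value": float(perm_err), "n": 4},
    }


def _jaccard(a: tuple[float, float], b: tuple[float, float]) -> float:
    inter = max(0.0, min(a[1], b[1]) - max(a[0], b[0]))
    union = max(a[1], b[1]) - min(a[0], b[0])
    return inter / union if union > 0 else 0.0


def pool_side_recovery(
    seed: int, coverage_scan: float = 100.0, coverage_bands: float = 150.0
) -> dict:
    """Pool-seq chain: FST -> Z-PCA -> CPD -> AF bands vs planted truth.

    Runs on the generator's full ~50k-SNP output; the read-count site filter
    has its own unit-level checks and is not interposed here, so recovery is
    measured on the stated simulation size. The FST/changepoint scan uses
    100x pools and the band-density stage 150x, the two coverage conditions
    of the study design.
    """
    model = sim.HaplotypeModel()
    haps = sim.simulate_haplotypes(model, seed=seed)
    comps = sim.default_line_compositions(48)
    table, truth = sim.simulate_iso_pools(
        haps, comps, coverage=coverage_scan, seed=seed + 1
    )
    af = poolstats.PoolAF.from_counts(table)

    allf = poolstats.all_pairwise_fst(af)
    per_site = np.column_stack([r.per_site for r in allf.values()])
    zm = zscan.zscore_matrix(per_site, af.sites, [f"{a}-{b}" for a, b in allf])
    pc = zscan.snp_matrix_pca(zm)
    scores = pc.scores[:, 0]
    pos = zm.sites["pos"].to_numpy()
    in_region = (pos >= model.region_start) & (pos <= model.region_end)
    top = scores >= np.quantile(scores, 0.99)
    top1pct_in_region = float((top & in_region).sum() / top.sum())

    pol = bands.polarise_to_line(af, "IsoY9")
    ppos = pol.sites["pos"].to_numpy()
    cfg = segment.ChangepointConfig()
    inputs = []
    for k, pid in enumerate(pol.pools["id"]):
        cps = segment.binseg_mean(pol.freq[k], cfg, positions=ppos)
        inputs.append((pid, pol.freq[k], ppos, cps))
    cps_pc = segment.binseg_mean(scores, cfg, positions=pos)
    inputs.append(("zfst_pc1", scores, pos, cps_pc))
    regions = segment.consensus_regions(inputs, chrom=model.chrom).regions
    spacing = model.chrom_length / len(ppos)
    if len(regions):
        best = max(
            regions.itertuples(),
            key=lambda r: _jaccard((r.start, r.end), (model.region_start, model.region_end)),
        )
        bound_err = max(
            abs(best.start - model.region_start), abs(best.end - model.region_end)
        )
    else:
        bound_err = float("inf")

    # AF band closure: detected modes per line vs the composition's
    # prediction, on a deeper-coverage pool run
    table_b, _ = sim.simulate_iso_pools(
        haps, comps, coverage=coverage_bands, seed=seed + 4
    )
    pol_b = bands.polarise_to_line(poolstats.PoolAF.from_counts(table_b), "IsoY9")
    region_mask = (
        (pol_b.sites["pos"] >= model.region_start)
        & (pol_b.sites["pos"] <= model.region_end)
    ).to_numpy()
    band_errs = []
    mode_counts = {}
    band_values = {}
    for k, comp in enumerate(comps):
        counts = comp.chromosome_counts()
        pred = bands.predict_band_frequencies(
            bands.BandModel(counts["A1"], counts["A2"], counts["B"])
        )
        detected = bands.detect_af_modes(pol_b.freq[k, region_mask])
        mode_counts[comp.line_id] = detected.n_modes
        band_values[comp.line_id] = sorted(set(pred["polarised"].round(6)))
        for band in band_values[comp.line_id]:
            band_errs.append(float(np.min(np.abs(detected.locations - band))))

    return {
        "zfst_pc1_variance_pct": {
            "value": 100 * float(pc.explained_variance_ratio[0]), "n": len(scores)
        },
        "zfst_top1pct_snps_in_region_pct": {
            "value": 100 * top1pct_in_region, "n": int(top.sum())
        },
        "cpd_region_bound_error_over_half_spacing": {
            "value": float(bound_err / (spacing / 2)), "n": len(ppos)
        },
        "af_band_max_abs_error": {"value": float(max(band_errs)), "n": len(band_errs)},
        "_mode_counts": mode_counts,
        "_band_values": band_values,
        "_n_snps": len(ppos),
    }


def natural_recovery(seed: int) -> dict:
    """Natural-population chain: local PCA, D_a outliers, phased breakpoints."""
    model = sim.HaplotypeModel()
    haps = sim.simulate_haplotypes(model, seed=seed)
    region = (model.chrom, model.region_start, model.region_end)

    # population with recombinants at conserved hotspots (both sexes carriers)
    cfg = sim.NaturalPopConfig(
        recombinant_fraction=0.3,
        crossover_positions=DEFAULT_HOTSPOTS,
        error_rate=0.002,
        diplotype_freqs={
            "male": sim.hwe_diplotype_freqs({"A1": 0.7, "B": 0.3}),
            "female": sim.hwe_diplotype_freqs({"A1": 0.7, "B": 0.3}),
        },
    )
    gm, truth = sim.simulate_natural_population(haps, cfg, seed=seed + 2)
    gm_f, _ = natscan.filter_genotype_variants(gm)

    wins = localpca.windowed_pca(gm_f, window_snps=100)
    mds = localpca.mds_from_windows(wins)
    flags = localpca.mds_outlier_windows(mds.coords[:, 0])
    regs = localpca.mds_regions(flags, mds.windows).regions
    jaccard = max(
        (
            _jaccard((r.start, r.end), (model.region_start, model.region_end))
            for r in regs.itertuples()
        ),
        default=0.0,
    )

    # phased-haplotype breakpoints vs planted hotspots
    pools, _ = sim.simulate_iso_pools(
        haps, sim.default_line_compositions(48), coverage=150, seed=seed + 1
    )
    af = poolstats.PoolAF.from_counts(pools)
    ref = phasing.ReferenceHaplotype.from_pool(af, "IsoY9")
    states = phasing.polarise_phased_haplotypes(gm_f, ref, region, smooth_window=11)
    cons = phasing.conserved_breakpoints(states)
    usage = truth.crossovers.groupby("pos")["sample_id"].nunique()
    true_cons = usage[usage >= 2].index.to_numpy(float)
    detected = cons["pos"].to_numpy()
    tol = 50_000
    if len(detected) and len(true_cons):
        precision = float(
            np.mean([np.min(np.abs(true_cons - d)) <= tol for d in detected])
        )
        recall = float(
            np.mean([np.min(np.abs(detected - t)) <= tol for t in true_cons])
        )
    else:
        precision = recall = 0.0

    # male-diversity-deficit population scanned with the D_a quantile rule
    gm2, _ = sim.simulate_natural_population(
        haps, sim.NaturalPopConfig(), seed=seed + 3
    )
    gm2_f, _ = natscan.filter_genotype_variants(gm2)
    groups = natscan.GroupSpec.by_sex(gm2_f)
    dxy = natscan.windowed_dxy(gm2_f, groups, width=1000)
    pif = natscan.windowed_pi(gm2_f, groups.idx2, width=1000)
    da = natscan.windowed_da(dxy, pif)
    out = natscan.window_quantile_outliers(da, tails="low").regions
    starts = out["start"].to_numpy()
    inside = (starts >= model.region_start) & (starts <= model.region_end)
    widths = (out["end"] - out["start"] + 1).to_numpy()
    flagged_bp_inside = float(widths[inside].sum())
    region_len = model.region_end - model.region_start + 1
    frac_flagged_low_in_region = (
        flagged_bp_inside / widths.sum() if widths.sum() else 0.0
    )

    return {
        "localpca_region_jaccard": {"value": float(jaccard), "n": len(wins)},
        "breakpoint_precision": {"value": precision, "n": len(detected)},
        "breakpoint_recall": {"value": recall, "n": len(true_cons)},
        "da_low_outlier_bp_in_region_pct": {
            "value": 100 * frac_flagged_low_in_region, "n": int(widths.sum())
        },
        "da_region_bp_flagged_pct": {
            "value": 100 * flagged_bp_inside / region_len, "n": int(region_len)
        },
        "_conserved_breakpoints": cons,
        "_hotspots": true_cons,
    }


def calibration(seed: int, n_datasets: int = 500) -> dict:
    """Type-I error and null-expectation checks of the statistical machinery."""
    # independent child streams for data and the two permutation tests
    ss_data, ss_perm, ss_var = np.random.SeedSequence(seed).spawn(3)
    rng = np.random.default_rng(ss_data)
    perm_seeds = np.random.default_rng(ss_perm).integers(2**31, size=n_datasets)
    var_seeds = np.random.default_rng(ss_var).integers(2**31, size=n_datasets)
    labels = np.repeat(["a", "b"], 10)
    hits_perm = hits_var = 0
    for i in range(n_datasets):
        x = rng.normal(size=(20, 5))
        res = permtest.permanova(
            x, labels, n_permutations=99, seed=int(perm_seeds[i])
        )
        hits_perm += res.p_value <= 0.05
        _, p = permtest.permutation_variance_test(
            x, labels, ("a", "b"), n_permutations=99, seed=int(var_seeds[i])
        )
        hits_var += p <= 0.05

    binseg_fp = 0
    for i in range(100):
        x = np.random.default_rng(seed + 10_000 + i).normal(size=1000)
        if segment.binseg_mean(x).n_changepoints > 0:
            binseg_fp += 1

    # unlinked chromosomes: E[r^2] ~ 1/n samples
    from .dataio import concat_genotype_matrices

    parts = []
    for i, chrom in enumerate(("LG1", "LG2")):
        m = sim.HaplotypeModel(
            chrom=chrom, chrom_length=2_000_000, region_start=1, region_end=2,
            density_a_shared=0, density_a1_private=0, density_a2_private=0,
            density_b_private=0, background_density=1.0,
            background_beta=(2.0, 2.0),
        )
        h = sim.simulate_haplotypes(m, seed=seed + 20 + i)
        pop = sim.NaturalPopConfig(
            n_males=13, n_females=13,
            diplotype_freqs={"male": {("A1", "A1"): 1.0},
                             "female": {("A1", "A1"): 1.0}},
        )
        parts.append(sim.simulate_natural_population(h, pop, seed=seed + 30 + i)[0])
    gm = concat_genotype_matrices(parts)
    mat = natscan.ld_r2_matrix(gm, thin=5000, cross=("LG1", "LG2"))
    mean_r2 = float(np.nanmean(mat.r2))

    return {
        "permanova_type1_error_rate": {"value": hits_perm / n_datasets, "n": n_datasets},
        "variance_test_type1_error_rate": {"value": hits_var / n_datasets, "n": n_datasets},
        "binseg_false_positive_rate": {"value": binseg_fp / 100, "n": 100},
        "interchrom_mean_r2_times_n": {"value": mean_r2 * 26, "n": int(mat.r2.size)},
    }
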