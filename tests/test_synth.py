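"""Generator correctness: determinism, LD structure, calibration, planted truth."""

import numpy as np
import pytest
from scipy import stats as sps

from postgwas import mr, synth
from postgwas.sumstats import ConfigurationError

from conftest import make_panel


class TestLDPanel:
    def test_same_seed_bitwise_identical(self):
        _, p1, _ = make_panel(seed=5)
        _, p2, _ = make_panel(seed=5)
        assert np.array_equal(p1.dosages, p2.dosages)
        assert p1.variants.equals(p2.variants)

    def test_different_seed_differs(self):
        _, p1, _ = make_panel(seed=5)
        _, p2, _ = make_panel(seed=6)
        assert not np.array_equal(p1.dosages, p2.dosages)

    def test_rho_zero_independence(self):
        _, panel, _ = make_panel(seed=1, n=2000, block_sizes=(25, 25), rho=0.0)
        C = panel.corr()
        off = C[np.triu_indices_from(C, k=1)]
        assert np.nanmean(np.abs(off)) < 0.05

    def test_across_block_independence(self):
        _, panel, _ = make_panel(seed=2, n=2000, block_sizes=(25, 25), rho=0.9)
        C = panel.corr()
        assert np.nanmean(np.abs(C[:25, 25:])) < 0.05

    def test_within_block_r2_matches_two_locus_oracle(self):
        """Mean within-block dosage r² agrees with a brute-force two-locus
        simulation at the same latent correlation and MAF range."""
        rho, n = 0.9, 5000
        _, panel, _ = make_panel(seed=3, n=n, block_sizes=(10,), rho=rho,
                                 maf_range=(0.2, 0.4))
        C = panel.corr()
        r2_obs = np.mean(C[np.triu_indices(10, k=1)] ** 2)
        # oracle: direct two-locus thresholded-bivariate-normal simulation
        orng = np.random.default_rng(999)
        r2s = []
        for _ in range(40):
            maf = orng.uniform(0.2, 0.4, size=2)
            thr = sps.norm.ppf(maf)
            dos = np.zeros((n, 2))
            for _hap in range(2):
                shared = orng.standard_normal((n, 1))
                indep = orng.standard_normal((n, 2))
                z = np.sqrt(rho) * shared + np.sqrt(1 - rho) * indep
                dos += z < thr
            r2s.append(np.corrcoef(dos[:, 0], dos[:, 1])[0, 1] ** 2)
        assert abs(r2_obs - np.mean(r2s)) < 0.1

    def test_dosage_values_and_maf_bounds(self):
        config, panel, _ = make_panel(seed=4, n=800, maf_range=(0.1, 0.4))
        assert set(np.unique(panel.dosages)) <= {0.0, 1.0, 2.0}
        freq = panel.dosages.mean(axis=0) / 2
        maf = np.minimum(freq, 1 - freq)
        assert (maf >= 0.1 - 0.05).all() and (maf <= 0.4 + 0.05).all()

    @pytest.mark.parametrize(
        "bad",
        [
            {"within_block_rho": 1.0},
            {"within_block_rho": -0.1},
            {"block_sizes": [0, 40]},
            {"block_sizes": [10, 10]},  # does not sum to n_variants
            {"maf_range": (0.0, 0.5)},
            {"causal_spec": ((999, 0.1),)},
        ],
    )
    def test_invalid_config_rejected(self, bad):
        config = synth.SimConfig(n_variants=40, **bad)
        with pytest.raises(ConfigurationError):
            config.validate()


class TestGwasSumstats:
    def test_null_p_calibration(self):
        config, panel, truth = make_panel(seed=7, n=500, block_sizes=(40,) * 50, rho=0.0)
        gwas = synth.simulate_gwas_sumstats(panel, truth, config)
        frac = (gwas["P"] < 0.05).mean()
        assert 0.03 <= frac <= 0.07

    def test_causal_variant_attains_block_minimum_p(self):
        wins = 0
        for s in range(50):
            config, panel, truth = make_panel(seed=s, n=3000, block_sizes=(20, 20),
                                              causal=((10, 0.25),))
            gwas = synth.simulate_gwas_sumstats(panel, truth, config)
            block = gwas.iloc[:20]
            wins += block["P"].idxmin() == 10
        assert wins >= 45

    def test_planted_beta_recovered(self):
        """Mean marginal estimate at the causal variant, rescaled to the
        standardized-genotype scale, matches an independent Monte-Carlo
        oracle of the same regression within the joint 2 MC-SE."""
        effect, n, ests = 0.3, 1000, []
        for s in range(100):
            config, panel, truth = make_panel(seed=s, n=n, block_sizes=(20,),
                                              rho=0.0, causal=((10, effect),))
            gwas = synth.simulate_gwas_sumstats(panel, truth, config)
            sd = panel.dosages[:, 10].std()
            ests.append(gwas["BETA"].iloc[10] * sd)
        # oracle: direct simple-OLS simulation at the same parameters
        orng = np.random.default_rng(77)
        oracle = []
        for _ in range(100):
            g = orng.binomial(2, orng.uniform(0.05, 0.5), size=n).astype(float)
            y = effect * (g - g.mean()) / g.std() + orng.standard_normal(n)
            gc = g - g.mean()
            oracle.append(float(gc @ y / (gc @ gc)) * g.std())
        joint_se = np.hypot(np.std(ests) / 10, np.std(oracle) / 10)
        assert abs(np.mean(ests) - np.mean(oracle)) < 2 * joint_se

    def test_binary_trait_detects_causal(self):
        config, panel, truth = make_panel(seed=9, n=4000, block_sizes=(20,),
                                          causal=((10, 0.4),), trait_type="binary",
                                          case_fraction=0.3)
        gwas = synth.simulate_gwas_sumstats(panel, truth, config)
        assert gwas["P"].iloc[10] < 1e-4
        assert gwas["P"].idxmin() == 10

    def test_monomorphic_excluded_with_warning(self):
        config, panel, truth = make_panel(seed=10, n=50, block_sizes=(30,),
                                          maf_range=(0.01, 0.02))
        if (panel.dosages.std(axis=0) > 0).all():
            pytest.skip("no monomorphic variant drawn at this seed")
        with pytest.warns(UserWarning, match="monomorphic"):
            gwas = synth.simulate_gwas_sumstats(panel, truth, config)
        assert len(gwas) < panel.n_variants


class TestEqtl:
    def test_shared_causal_is_gwas_causal(self):
        config, panel, truth = make_panel(seed=12, n=800, causal=((10, 0.3),))
        tss = int(panel.variants["BP"].iloc[10])
        stats, causal = synth.simulate_eqtl_sumstats(panel, tss, True, config, truth)
        assert causal == 10
        assert stats["P"].idxmin() < 20  # top association in the causal block

    def test_distinct_causal_in_same_block(self):
        config, panel, truth = make_panel(seed=12, n=800, causal=((10, 0.3),))
        tss = int(panel.variants["BP"].iloc[10])
        _, causal = synth.simulate_eqtl_sumstats(panel, tss, False, config, truth)
        assert causal != 10 and 0 <= causal < 20

    def test_deterministic(self):
        config, panel, truth = make_panel(seed=13, n=400, causal=((10, 0.3),))
        tss = int(panel.variants["BP"].iloc[10])
        a, _ = synth.simulate_eqtl_sumstats(panel, tss, True, config, truth)
        b, _ = synth.simulate_eqtl_sumstats(panel, tss, True, config, truth)
        assert a.equals(b)


class TestPeaks:
    def test_non_overlapping_and_sorted(self):
        config = synth.SimConfig(seed=1, peak_enrichment=5.0)
        peaks = synth.simulate_peaks(config, [(1000, 1400), (50_000, 50_400)])
        starts, ends = peaks["start"].to_numpy(), peaks["end"].to_numpy()
        assert (starts[1:] >= ends[:-1]).all()

    def test_enrichment_one_matches_background_rate(self):
        covered, genome_rate = 0, []
        targets = [(i * 100_000, i * 100_000 + 400) for i in range(1, 21)]
        for s in range(30):
            config = synth.SimConfig(seed=s, peak_enrichment=1.0)
            peaks = synth.simulate_peaks(config, targets, genome_size=2_000_000)
            genome_rate.append((peaks["end"] - peaks["start"]).sum() / 2_000_000)
            for ts, te in targets:
                mid = (ts + te) // 2
                covered += ((peaks["start"] <= mid) & (mid < peaks["end"])).any()
        target_rate = covered / (30 * len(targets))
        assert abs(target_rate - np.mean(genome_rate)) < 0.05

    def test_high_enrichment_covers_all_targets(self):
        targets = [(i * 100_000, i * 100_000 + 400) for i in range(1, 11)]
        for s in range(20):
            config = synth.SimConfig(seed=s, peak_enrichment=1e9)
            peaks = synth.simulate_peaks(config, targets, genome_size=2_000_000)
            for ts, te in targets:
                mid = (ts + te) // 2
                assert ((peaks["start"] <= mid) & (mid < peaks["end"])).any()

    def test_deterministic(self):
        config = synth.SimConfig(seed=3, peak_enrichment=2.0)
        a = synth.simulate_peaks(config, [(500, 900)])
        b = synth.simulate_peaks(config, [(500, 900)])
        assert a.equals(b)


class TestContactMap:
    def test_symmetry_and_nonnegative(self):
        config = synth.SimConfig(seed=2, contact_decay_gamma=1.2)
        cmap = synth.simulate_contact_map(config, n_bins=60, resolution=10_000)
        assert np.array_equal(cmap.matrix, cmap.matrix.T)
        assert (cmap.matrix >= 0).all()

    def test_log_log_slope_matches_gamma(self):
        """Regression of log mean count on log distance recovers −gamma."""
        gamma = 1.0
        config = synth.SimConfig(seed=4, contact_decay_gamma=gamma, contact_scale=500.0)
        cmap = synth.simulate_contact_map(config, n_bins=120, resolution=10_000)
        d = np.arange(1, 40)
        means = [np.diagonal(cmap.matrix, k).mean() for k in d]
        slope = np.polyfit(np.log(d), np.log(means), 1)[0]
        assert abs(slope + gamma) < 0.15

    def test_planted_loop_exceeds_local_background(self):
        config = synth.SimConfig(seed=5, loop_spec=((10, 40, 200.0),), contact_scale=100.0)
        cmap = synth.simulate_contact_map(config, n_bins=60, resolution=10_000)
        neighbours = [cmap.matrix[10 + di, 40 + dj]
                      for di in (-2, -1, 1, 2) for dj in (-2, -1, 1, 2)]
        assert cmap.matrix[10, 40] > 5 * np.mean(neighbours)
        assert cmap.matrix[40, 10] == cmap.matrix[10, 40]


class TestMrDataset:
    def test_deterministic(self):
        a = synth.simulate_mr_dataset(30, 0.4, seed=7)
        b = synth.simulate_mr_dataset(30, 0.4, seed=7)
        assert a.equals(b)

    def test_null_egger_intercept_unbiased(self):
        ints = [mr.mr_egger(synth.simulate_mr_dataset(40, 0.4, 0.0, seed=s)).extras["intercept"]
                for s in range(200)]
        mc_se = np.std(ints) / np.sqrt(len(ints))
        assert abs(np.mean(ints)) < 2 * mc_se + 1e-3

    def test_null_effect_ivw_p_calibrated(self):
        ps = np.array([mr.ivw_re(synth.simulate_mr_dataset(40, 0.0, seed=s)).p
                       for s in range(300)])
        assert 0.02 <= (ps < 0.05).mean() <= 0.08
        # coarse uniformity: quartile occupancy
        hist, _ = np.histogram(ps, bins=4, range=(0, 1))
        assert (hist > 0.15 * len(ps)).all()
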