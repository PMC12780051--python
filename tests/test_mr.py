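"""Two-sample MR estimator suite: algebra, oracles, robustness properties."""

import numpy as np
import pandas as pd
import pytest

from postgwas import mr, synth

from conftest import make_panel


def _instruments(beta_exp, beta_out, se_exp=0.01, se_out=0.05, eaf=0.3):
    k = len(beta_exp)
    return pd.DataFrame({
        "SNP": [f"iv{i}" for i in range(k)],
        "beta_exp": beta_exp, "se_exp": se_exp,
        "beta_out": beta_out, "se_out": se_out,
        "eaf": eaf, "A1": "A", "A2": "G",
    })


class TestSelectInstruments:
    def test_pruned_set_pairwise_independent(self):
        _, panel, _ = make_panel(seed=61, n=3000, block_sizes=(10,) * 6, rho=0.9)
        exposure = panel.variants.copy()
        rng = np.random.default_rng(0)
        exposure["FREQ"] = panel.dosages.mean(axis=0) / 2
        exposure["BETA"] = rng.normal(0.1, 0.01, panel.n_variants)
        exposure["SE"] = 0.005
        exposure["P"] = 1e-10
        kept = mr.select_instruments(exposure, panel)
        C = panel.corr()
        idx = [panel.index_of(s) for s in kept]
        for a in idx:
            for b in idx:
                if a != b:
                    assert C[a, b] ** 2 < 0.01

    def test_threshold_filters(self):
        _, panel, _ = make_panel(seed=62, n=500, block_sizes=(1,) * 4, rho=0.0)
        exposure = panel.variants.copy()
        exposure["FREQ"] = [0.3, 0.005, 0.3, 0.3]
        exposure["BETA"] = 0.1
        exposure["SE"] = 0.01
        exposure["P"] = [1e-10, 1e-10, 1e-4, 1e-10]
        kept = mr.select_instruments(exposure, panel)
        assert kept == [panel.variants["SNP"].iloc[0], panel.variants["SNP"].iloc[3]]


class TestHarmonise:
    @staticmethod
    def _table(snp, a1, a2, beta, freq):
        return pd.DataFrame({"SNP": [snp], "CHR": "1", "BP": [1], "A1": [a1],
                             "A2": [a2], "FREQ": [freq], "BETA": [beta],
                             "SE": [0.01], "P": [1e-9]})

    def test_aligned_untouched(self):
        out = mr.harmonise(self._table("v", "A", "G", 0.1, 0.3),
                           self._table("v", "A", "G", 0.05, 0.3))
        assert out["beta_out"].iloc[0] == pytest.approx(0.05)

    def test_swapped_alleles_flip_sign(self):
        out = mr.harmonise(self._table("v", "A", "G", 0.1, 0.3),
                           self._table("v", "G", "A", 0.05, 0.7))
        assert out["beta_out"].iloc[0] == pytest.approx(-0.05)

    def test_ambiguous_palindromic_dropped(self):
        out = mr.harmonise(self._table("v", "A", "T", 0.1, 0.5),
                           self._table("v", "A", "T", 0.05, 0.5))
        assert out.empty

    def test_irreconcilable_alleles_dropped(self):
        out = mr.harmonise(self._table("v", "A", "G", 0.1, 0.3),
                           self._table("v", "C", "T", 0.05, 0.3))
        assert out.empty


class TestWaldAndIvw:
    def test_wald_ratio_value_and_sign(self):
        out = mr.wald_ratios(_instruments([0.1, -0.1], [0.2, 0.2]))
        assert out["beta"].iloc[0] == pytest.approx(2.0)
        assert out["beta"].iloc[1] == pytest.approx(-2.0)

    def test_wald_se_matches_delta_method(self):
        """First-order delta SE of b_out/b_exp with b_exp treated fixed."""
        inst = _instruments([0.08], [0.2], se_out=0.03)
        out = mr.wald_ratios(inst)
        assert out["se"].iloc[0] == pytest.approx(0.03 / 0.08)

    def test_ivw_equal_weights_is_mean(self):
        inst = _instruments([0.1, 0.1, 0.1], [0.1, 0.2, 0.3])
        est = mr.ivw_re(inst)
        assert est.beta == pytest.approx(2.0)

    def test_single_instrument_reduces_to_wald(self):
        inst = _instruments([0.1], [0.25])
        est = mr.ivw_re(inst)
        assert est.beta == pytest.approx(2.5)
        assert est.se == pytest.approx(0.05 / 0.1)
        assert np.isnan(est.extras["Q"])

    def test_recovers_planted_effect(self):
        ests = [mr.ivw_re(synth.simulate_mr_dataset(40, 0.4, seed=s)).beta
                for s in range(200)]
        mc_se = np.std(ests) / np.sqrt(200)
        assert abs(np.mean(ests) - 0.4) < 2 * mc_se + 0.01


class TestEgger:
    def test_line_through_origin_zero_intercept(self):
        be = np.array([0.05, 0.08, 0.1, 0.12])
        inst = _instruments(be, 0.5 * be)
        est = mr.mr_egger(inst)
        assert est.extras["intercept"] == pytest.approx(0.0, abs=1e-12)
        assert est.beta == pytest.approx(0.5)

    def test_two_points_exact_fit_flagged(self):
        inst = _instruments([0.05, 0.1], [0.03, 0.05])
        est = mr.mr_egger(inst)
        assert est.extras["exact_fit"]

    def test_planted_pleiotropy_recovered(self):
        ints = [mr.mr_egger(synth.simulate_mr_dataset(40, 0.4, 0.03, seed=s)).extras["intercept"]
                for s in range(200)]
        mc_se = np.std(ints) / np.sqrt(200)
        assert abs(np.mean(ints) - 0.03) < 2 * mc_se + 2e-3

    def test_orientation_invariance(self):
        """Flipping the reported allele of an instrument (both betas) leaves
        the Egger fit unchanged."""
        inst = synth.simulate_mr_dataset(20, 0.3, 0.01, seed=5)
        flipped = inst.copy()
        flipped.loc[3, ["beta_exp", "beta_out"]] *= -1
        a, b = mr.mr_egger(inst), mr.mr_egger(flipped)
        assert a.beta == pytest.approx(b.beta)
        assert a.extras["intercept"] == pytest.approx(b.extras["intercept"])


class TestMedianAndMode:
    def test_equal_weight_odd_k_is_median(self):
        inst = _instruments([0.1] * 5, [0.1, 0.2, 0.3, 0.4, 0.5])
        est = mr.weighted_median(inst, n_boot=50, seed=0)
        assert est.beta == pytest.approx(3.0)

    def test_median_robust_to_minority_outliers(self):
        """With a third of the instruments grossly pleiotropic, the weighted
        median stays near the planted effect while IVW is dragged away."""
        med_err, ivw_err = [], []
        for s in range(50):
            inst = synth.simulate_mr_dataset(30, 0.4, seed=s, se_out=0.005)
            inst.loc[:9, "beta_out"] += 0.5  # 10/30 invalid instruments
            med_err.append(mr.weighted_median(inst, n_boot=100, seed=s).beta - 0.4)
            ivw_err.append(mr.ivw_re(inst).beta - 0.4)
        assert abs(np.mean(med_err)) < 0.15
        assert abs(np.mean(med_err)) < 0.25 * abs(np.mean(ivw_err))

    def test_median_deterministic_given_seed(self):
        inst = synth.simulate_mr_dataset(25, 0.4, seed=2)
        a = mr.weighted_median(inst, n_boot=200, seed=9)
        b = mr.weighted_median(inst, n_boot=200, seed=9)
        assert a.beta == b.beta and a.se == b.se

    def test_mode_all_ratios_equal(self):
        be = np.array([0.05, 0.1, 0.2])
        inst = _instruments(be, 0.7 * be)
        est = mr.weighted_mode(inst, n_boot=50, seed=0)
        assert est.beta == pytest.approx(0.7, abs=1e-3)

    def test_mode_picks_heavier_cluster_grid_oracle(self):
        """Bimodal ratio cloud: the weighted mode lands on the cluster holding
        most weight, confirmed by a dense grid search over the same kernel."""
        be = np.full(12, 0.1)
        bo = np.concatenate([np.full(8, 0.04), np.full(4, 0.12)])
        bo = bo + np.linspace(-0.002, 0.002, 12)
        inst = _instruments(be, bo)
        est = mr.weighted_mode(inst, n_boot=50, seed=1)
        assert abs(est.beta - 0.4) < 0.1
        ratios = bo / be
        w = (0.05 / be) ** -2
        grid = np.linspace(0, 1.5, 20_001)
        s = 1.4826 * np.median(np.abs(ratios - np.median(ratios)))
        h = 1.0 * 0.9 * s * 12 ** (-0.2)
        dens = (w[:, None] * np.exp(-0.5 * ((grid[None, :] - ratios[:, None]) / h) ** 2)).sum(0)
        assert abs(est.beta - grid[np.argmax(dens)]) < 5e-3


class TestSteigerLooPower:
    def test_zero_outcome_association_direction(self):
        inst = _instruments([0.1] * 5, [1e-6] * 5)
        st = mr.steiger(inst, 100_000, 100_000)
        assert st["correct_direction"]

    def test_symmetric_r2_p_near_one(self):
        inst = _instruments([0.1] * 5, [0.1] * 5, se_exp=0.01, se_out=0.01)
        st = mr.steiger(inst, 50_000, 50_000)
        assert st["p"] > 0.99

    def test_planted_direction_recovered(self):
        good = sum(mr.steiger(synth.simulate_mr_dataset(40, 0.4, seed=s),
                              400_000, 50_000)["correct_direction"]
                   for s in range(40))
        assert good >= 38

    def test_leave_one_out_two_instruments(self):
        inst = _instruments([0.1, 0.1], [0.2, 0.4])
        loo = mr.leave_one_out(inst)
        assert loo["beta"].tolist() == pytest.approx([4.0, 2.0])

    def test_removing_outlier_restores_truth(self):
        inst = synth.simulate_mr_dataset(20, 0.4, seed=3)
        inst.loc[0, "beta_out"] += 1.0
        loo = mr.leave_one_out(inst)
        full = mr.ivw_re(inst).beta
        without = loo["beta"].iloc[0]
        assert abs(without - 0.4) < abs(full - 0.4)

    def test_pve_zero_for_null_betas(self):
        inst = _instruments([1e-12] * 3, [0.0] * 3)
        assert mr.pve(inst) == pytest.approx(0.0, abs=1e-20)

    def test_power_monotone_in_or(self):
        curve = mr.mr_power(0.02, 100_000, 0.1, np.linspace(1.01, 2.0, 30))
        assert (np.diff(curve["power"]) >= 0).all()

    def test_power_matches_simulation_oracle(self):
        """Analytic power agrees with a Monte-Carlo rejection rate simulated
        from the implied IVW sampling distribution at the same parameters."""
        r2, n_out, v, odds = 0.02, 50_000, 0.1, 1.25
        power = mr.mr_power(r2, n_out, v, [odds])["power"].iloc[0]
        rng = np.random.default_rng(17)
        se_ivw = 1.0 / np.sqrt(n_out * v * (1 - v) * r2)
        draws = rng.normal(np.log(odds), se_ivw, size=20_000)
        mc = np.mean(np.abs(draws / se_ivw) > 1.959964)
        assert abs(power - mc) < 0.05


class TestOrderInvariance:
    @pytest.mark.parametrize("fn", [mr.ivw_re, mr.mr_egger])
    def test_estimators_ignore_row_order(self, fn):
        inst = synth.simulate_mr_dataset(30, 0.4, 0.01, seed=8)
        shuffled = inst.sample(frac=1, random_state=4).reset_index(drop=True)
        assert fn(inst).beta == pytest.approx(fn(shuffled).beta)

    def test_agreement_without_pleiotropy(self):
        """IVW-RE, Egger slope and weighted median agree within joint 95%
        intervals on clean data."""
        inst = synth.simulate_mr_dataset(60, 0.4, seed=10)
        ests = [mr.ivw_re(inst), mr.mr_egger(inst),
                mr.weighted_median(inst, n_boot=500, seed=1)]
        for a in ests:
            for b in ests:
                assert abs(a.beta - b.beta) < 1.96 * np.hypot(a.se, b.se)
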