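import numpy as np
import pytest

from conftest import make_set
from mrkit import (SimulationConfig, ivw, maximum_likelihood, median_estimator,
                   mode_estimator, mr_all, mr_egger, simulate_summary_set,
                   wald_ratio)
from mrkit.estimators import weighted_quantile


class TestWaldRatio:
    def test_printed_formulas(self):
        row = {"beta_exp": 0.5, "se_exp": 0.01, "beta_out": 0.2,
               "se_out": 0.05}
        res = wald_ratio(row)
        assert res.estimate == pytest.approx(0.4)
        assert res.se == pytest.approx(0.1)
        assert res.nsnp == 1

    def test_unit_exposure_effect_is_identity(self):
        row = {"beta_exp": 1.0, "se_exp": 0.01, "beta_out": 0.37,
               "se_out": 0.05}
        assert wald_ratio(row).estimate == pytest.approx(0.37)

    def test_allele_flip_symmetry(self):
        a = {"beta_exp": 0.5, "se_exp": 0.01, "beta_out": 0.2, "se_out": 0.05}
        b = {**a, "beta_exp": -0.5, "beta_out": -0.2}
        assert wald_ratio(a).estimate == wald_ratio(b).estimate
        assert wald_ratio(a).se == wald_ratio(b).se

    def test_null_instrument_rejected(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio({"beta_exp": 0.0, "se_exp": 0.01, "beta_out": 0.2,
                        "se_out": 0.05})

    def test_second_order_se_exceeds_first_order(self):
        row = {"beta_exp": 0.5, "se_exp": 0.1, "beta_out": 0.2, "se_out": 0.05}
        assert wald_ratio(row, second_order=True).se > wald_ratio(row).se


class TestIVW:
    def test_common_ratio_recovered_with_zero_q(self):
        s = make_set([0.1, 0.2, 0.3], [0.07, 0.14, 0.21], [0.1, 0.1, 0.1])
        res = ivw(s)
        assert res.estimate == pytest.approx(0.7)
        assert res.info["Q"] == pytest.approx(0.0, abs=1e-20)
        assert res.model_flavour == "fixed"  # underdispersion -> fixed

    def test_hand_computed_slope_with_equal_weights(self):
        # sum(bx*by)/sum(bx^2) = 0.09/0.14
        s = make_set([0.1, 0.2, 0.3], [0.05, 0.2, 0.15], [0.1, 0.1, 0.1])
        assert ivw(s).estimate == pytest.approx(0.642857, abs=1e-6)

    def test_fixed_and_random_share_slope_random_se_not_smaller(self):
        s = make_set([0.1, 0.2, 0.3], [0.01, 0.25, 0.12], [0.05, 0.1, 0.07])
        fe, re = ivw(s, "fixed"), ivw(s, "random")
        assert fe.estimate == re.estimate
        assert re.se >= fe.se

    def test_simulation_recovery_within_3_se(self):
        cfg = SimulationConfig(theta=0.5, L=50, seed=23,
                               pleiotropy_mode="balanced",
                               pleiotropy_sd=0.003)
        s, _ = simulate_summary_set(cfg)
        res = ivw(s)
        assert abs(res.estimate - 0.5) < 3 * res.se

    def test_single_snp_directs_to_wald(self, sim_set):
        s, _ = sim_set
        with pytest.raises(ValueError, match="wald_ratio"):
            ivw(s.subset(np.arange(s.n_kept) == 0))

    def test_scale_equivariance(self, sim_set):
        s, _ = sim_set
        c = 3.7
        scaled = s.kept().copy()
        scaled["beta_out"] *= c
        scaled["se_out"] *= c
        from mrkit.harmonise import SummarySet
        s2 = SummarySet(scaled, action=1)
        r1, r2 = ivw(s), ivw(s2)
        assert r2.estimate == pytest.approx(c * r1.estimate)
        assert r2.se == pytest.approx(c * r1.se)


class TestMaximumLikelihood:
    def test_matches_ivw_when_exposure_noise_negligible(self, sim_set):
        s, _ = sim_set
        k = s.kept().copy()
        k["se_exp"] = 1e-8
        from mrkit.harmonise import SummarySet
        s0 = SummarySet(k, action=1)
        assert maximum_likelihood(s0).estimate == pytest.approx(
            ivw(s0, "fixed").estimate, abs=1e-4)

    def test_common_ratio_exact(self):
        s = make_set([0.1, 0.2, 0.3], [0.07, 0.14, 0.21], [0.1, 0.1, 0.1])
        assert maximum_likelihood(s).estimate == pytest.approx(0.7, abs=1e-6)

    def test_less_attenuated_than_ivw_under_exposure_noise(self):
        """With sizeable measurement error in beta_x, IVW suffers regression
        dilution; the likelihood model accounts for it."""
        rng = np.random.default_rng(5)
        reps, theta = 200, 0.5
        ml_est, ivw_est = [], []
        for _ in range(reps):
            L = 30
            xi = np.abs(rng.normal(0, 0.1, L))
            sx = np.full(L, 0.05)
            sy = np.full(L, 0.02)
            s = make_set(rng.normal(xi, sx), rng.normal(theta * xi, sy), sy,
                         sx=sx)
            ml_est.append(maximum_likelihood(s).estimate)
            ivw_est.append(ivw(s, "fixed").estimate)
        assert abs(np.mean(ml_est) - theta) <= abs(np.mean(ivw_est) - theta)


class TestEgger:
    def test_exact_linear_data_recovered(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.013 + 0.5 * bx
        res = mr_egger(make_set(bx, by, np.full(4, 0.05)))
        assert res.intercept == pytest.approx(0.013, abs=1e-12)
        assert res.estimate == pytest.approx(0.5, abs=1e-12)
        assert res.info["Q"] == pytest.approx(0.0, abs=1e-20)

    def test_intercept_free_data_slope_matches_ivw(self):
        bx = np.array([0.1, 0.2, 0.3])
        by = 0.5 * bx
        s = make_set(bx, by, np.full(3, 0.1))
        assert mr_egger(s).estimate == pytest.approx(ivw(s).estimate)

    def test_orientation_invariance(self):
        """Flipping the allele coding of a subset of SNPs (negating both
        betas) leaves the Egger fit unchanged."""
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        by = 0.02 + 0.6 * bx
        s1 = make_set(bx, by, np.full(5, 0.05))
        flip = np.array([1, -1, 1, -1, 1.0])
        s2 = make_set(bx * flip, by * flip, np.full(5, 0.05))
        r1, r2 = mr_egger(s1), mr_egger(s2)
        assert r2.estimate == pytest.approx(r1.estimate)
        assert r2.intercept == pytest.approx(r1.intercept)

    def test_requires_three_snps(self):
        with pytest.raises(ValueError):
            mr_egger(make_set([0.1, 0.2], [0.05, 0.1], [0.1, 0.1]))

    def test_recovers_slope_under_directional_pleiotropy(self):
        cfg = SimulationConfig(theta=0.5, L=80, seed=31, n_exp=1_000_000,
                               pleiotropy_mode="directional_inside",
                               pleiotropy_mean=0.01, pleiotropy_sd=0.004)
        s, _ = simulate_summary_set(cfg)
        egger, ivw_res = mr_egger(s), ivw(s)
        assert abs(egger.estimate - 0.5) < 3 * egger.se
        assert abs(ivw_res.estimate - 0.5) > 3 * ivw_res.se  # IVW is biased


class TestMedian:
    def test_interpolated_simple_median(self):
        s = make_set([1, 1, 1, 1], [0.4, 0.5, 0.6, 5.0], [0.1] * 4)
        res = median_estimator(s, "simple", n_boot=50, seed=1)
        assert res.estimate == pytest.approx(0.55)

    def test_common_ratio_small_bootstrap_se(self):
        s = make_set([0.1, 0.2, 0.3], [0.05, 0.1, 0.15],
                     [1e-4, 1e-4, 1e-4], sx=np.full(3, 1e-8))
        res = median_estimator(s, "weighted", n_boot=200, seed=2)
        assert res.estimate == pytest.approx(0.5, abs=1e-3)
        assert res.se < 0.01

    def test_weighted_quantile_against_numpy_on_equal_weights(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=101)
        assert weighted_quantile(x, np.ones_like(x), 0.5) == pytest.approx(
            np.median(x))

    def test_robust_to_40pct_invalid_instruments(self):
        cfg = SimulationConfig(theta=0.5, L=50, seed=37, n_exp=1_000_000,
                               n_out=1_000_000,
                               pleiotropy_mode="directional_inside",
                               pleiotropy_mean=0.05, pleiotropy_sd=0.01,
                               invalid_fraction=0.4)
        s, _ = simulate_summary_set(cfg)
        med = median_estimator(s, "weighted", n_boot=200, seed=3)
        # fixed-effects IVW: its se does not absorb the pleiotropy, so the
        # bias of the estimate itself is visible
        ivw_res = ivw(s, "fixed")
        assert abs(med.estimate - 0.5) < 3 * med.se
        assert abs(ivw_res.estimate - 0.5) > 3 * ivw_res.se
        assert abs(med.estimate - 0.5) < abs(ivw_res.estimate - 0.5)

    def test_seed_reproducibility(self, sim_set):
        s, _ = sim_set
        a = median_estimator(s, "weighted", n_boot=100, seed=9)
        b = median_estimator(s, "weighted", n_boot=100, seed=9)
        assert (a.estimate, a.se) == (b.estimate, b.se)

    def test_seed_mandatory(self, sim_set):
        s, _ = sim_set
        with pytest.raises(ValueError, match="seed"):
            median_estimator(s, "weighted")


class TestMode:
    def test_all_ratios_equal(self):
        s = make_set([0.1, 0.2, 0.3], [0.03, 0.06, 0.09], [0.1] * 3)
        res = mode_estimator(s, "simple", n_boot=50, seed=4)
        assert res.estimate == pytest.approx(0.3, abs=1e-6)

    def test_largest_cluster_wins(self):
        # 6 SNPs implying theta=0.5, 3 implying 2.0; KDE argmax near 0.5
        bx = np.full(9, 0.2)
        by = np.concatenate([np.full(6, 0.1), np.full(3, 0.4)])
        by = by + np.linspace(-0.003, 0.003, 9)  # tiny jitter within clusters
        s = make_set(bx, by, np.full(9, 0.05))
        res = mode_estimator(s, "simple", n_boot=50, seed=5)
        assert abs(res.estimate - 0.5) < 0.15

    def test_plurality_valid_simulation(self):
        cfg = SimulationConfig(theta=0.5, L=60, seed=41, n_exp=1_000_000,
                               n_out=1_000_000,
                               pleiotropy_mode="clustered",
                               cluster_spec=[(0.30, 1.5), (0.25, 0.0)])
        s, _ = simulate_summary_set(cfg)
        # bandwidth_factor < 1: the Silverman rule is computed on the whole
        # (multimodal) ratio spread, so resolving well-separated clusters
        # needs a tighter kernel
        res = mode_estimator(s, "simple", bandwidth_factor=0.5,
                             n_boot=100, seed=6)
        assert abs(res.estimate - 0.5) < 3 * max(res.se, 0.02)


class TestMrAll:
    def test_single_snp_gates_to_wald(self, sim_set):
        s, _ = sim_set
        one = s.subset(np.arange(s.n_kept) == 0)
        results, skipped = mr_all(one, seed=0, n_boot=20)
        assert [r.method for r in results] == ["wald_ratio"]
        assert {s_["method"] for s_ in skipped} == {
            "ivw", "max_lik", "mr_egger", "weighted_median", "weighted_mode"}

    def test_default_battery_count(self, sim_set):
        s, _ = sim_set
        results, skipped = mr_all(s, seed=0, n_boot=20)
        assert len(results) == 5 and skipped == []

    def test_determinism(self, sim_set):
        s, _ = sim_set
        r1, _ = mr_all(s, seed=7, n_boot=50)
        r2, _ = mr_all(s, seed=7, n_boot=50)
        assert [(a.estimate, a.se) for a in r1] == \
            [(b.estimate, b.se) for b in r2]

    def test_unknown_method_is_config_error(self, sim_set):
        s, _ = sim_set
        with pytest.raises(KeyError, match="unknown method"):
            mr_all(s, ["ivw", "mr_banana"], seed=0)

    def test_result_invariants(self, sim_set):
        s, _ = sim_set
        results, _ = mr_all(s, seed=0, n_boot=50)
        for r in results:
            assert r.ci_low <= r.estimate <= r.ci_high
            assert r.se > 0
            assert 0 < r.pval <= 1
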