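import numpy as np
import pytest
from scipy import stats

from conftest import make_set
from mrkit import (SimulationConfig, funnel_data, heterogeneity,
                   instrument_strength, ivw, leave_one_out,
                   overlap_percentage, simulate_summary_set,
                   single_snp_forest, steiger, wald_ratio)
from mrkit.harmonise import SummarySet


class TestHeterogeneity:
    def test_identical_ratios_give_zero_q(self):
        s = make_set([0.1, 0.2, 0.3], [0.05, 0.1, 0.15], [0.1, 0.1, 0.1])
        h = heterogeneity(s, "ivw")
        assert h.Q == pytest.approx(0.0, abs=1e-18)
        assert h.pval == pytest.approx(1.0)
        assert h.df == 2

    def test_two_study_closed_form(self):
        """For two instruments Q reduces to the textbook two-study
        meta-analysis form w1*w2/(w1+w2) * (b1-b2)^2 on the ratio scale."""
        bx = np.array([0.2, 0.4])
        by = np.array([0.12, 0.1])
        sy = np.array([0.05, 0.08])
        ratios = by / bx
        w = (bx / sy) ** 2
        expected = w[0] * w[1] / (w[0] + w[1]) * (ratios[0] - ratios[1]) ** 2
        h = heterogeneity(make_set(bx, by, sy), "ivw")
        assert h.Q == pytest.approx(expected, rel=1e-12)
        assert h.df == 1

    def test_ratio_and_regression_scales_agree(self):
        # algebraically identical weightings of the same residuals
        rng = np.random.default_rng(3)
        bx = np.abs(rng.normal(0.1, 0.03, 10))
        by = 0.5 * bx + rng.normal(0, 0.01, 10)
        s = make_set(bx, by, np.full(10, 0.01))
        h1 = heterogeneity(s, "ivw", scale="ratio")
        h2 = heterogeneity(s, "ivw", scale="regression")
        assert h1.Q == pytest.approx(h2.Q, rel=1e-10)

    def test_exact_intercept_line_egger_zero_ivw_positive(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.02 + 0.5 * bx  # non-zero intercept, perfect line
        s = make_set(bx, by, np.full(4, 0.01))
        assert heterogeneity(s, "egger").Q == pytest.approx(0.0, abs=1e-18)
        assert heterogeneity(s, "ivw").Q > 1.0

    def test_q_invariant_to_order_and_allele_flips(self):
        rng = np.random.default_rng(7)
        bx = np.abs(rng.normal(0.1, 0.05, 8))
        by = 0.4 * bx + rng.normal(0, 0.02, 8)
        sy = np.full(8, 0.02)
        q0 = heterogeneity(make_set(bx, by, sy), "ivw").Q
        perm = rng.permutation(8)
        assert heterogeneity(make_set(bx[perm], by[perm], sy), "ivw"
                             ).Q == pytest.approx(q0)
        flip = np.where(np.arange(8) % 2 == 0, -1.0, 1.0)
        assert heterogeneity(make_set(bx * flip, by * flip, sy), "ivw"
                             ).Q == pytest.approx(q0)

    def test_insufficient_snps(self):
        s = make_set([0.1], [0.05], [0.1])
        with pytest.raises(ValueError):
            heterogeneity(s, "ivw")


class TestLeaveOneOut:
    def test_row_count_and_all_row(self, sim_set):
        s, _ = sim_set
        loo = leave_one_out(s, "ivw")
        assert len(loo) == s.n_kept + 1
        all_row = loo[loo["snp"] == "All"].iloc[0]
        full = ivw(s)
        assert all_row["estimate"] == pytest.approx(full.estimate)
        assert all_row["se"] == pytest.approx(full.se)

    def test_homogeneous_set_is_stable(self, sim_set):
        s, _ = sim_set
        loo = leave_one_out(s, "ivw")
        all_est = loo[loo["snp"] == "All"]["estimate"].iloc[0]
        all_se = loo[loo["snp"] == "All"]["se"].iloc[0]
        drops = loo[loo["snp"] != "All"]["estimate"]
        assert (np.abs(drops - all_est) < 2 * all_se).all()

    def test_outlier_snp_shows_largest_shift(self, sim_set):
        s, _ = sim_set
        k = s.kept().copy()
        k.loc[0, "beta_out"] = 5.0  # gross pleiotropic outlier
        s2 = SummarySet(k, action=1)
        loo = leave_one_out(s2, "ivw")
        all_est = loo[loo["snp"] == "All"]["estimate"].iloc[0]
        shifts = (loo[loo["snp"] != "All"]
                  .assign(shift=lambda d: np.abs(d["estimate"] - all_est)))
        assert shifts.loc[shifts["shift"].idxmax(), "snp"] == k.loc[0, "SNP"]


class TestForestAndFunnel:
    def test_forest_rows_delegate_to_wald(self, sim_set):
        s, _ = sim_set
        table = single_snp_forest(s, ["ivw"], seed=0, n_boot=20)
        per_snp = table[table["snp"] != "All"]
        assert len(per_snp) == s.n_kept
        first = s.kept().iloc[0]
        expected = wald_ratio(first)
        assert per_snp.iloc[0]["estimate"] == pytest.approx(expected.estimate)
        combined = table[table["snp"] == "All"]
        assert combined["method"].tolist() == ["ivw_fe"] or \
            combined["method"].tolist() == ["ivw_re"]
        assert combined.iloc[0]["estimate"] == pytest.approx(ivw(s).estimate)

    def test_funnel_matches_wald_and_is_symmetric(self, sim_set):
        s, _ = sim_set
        f = funnel_data(s)
        assert len(f) == s.n_kept
        first = wald_ratio(s.kept().iloc[0])
        assert f.iloc[0]["estimate"] == pytest.approx(first.estimate)
        assert f.iloc[0]["precision"] == pytest.approx(1 / first.se)
        # no pleiotropy: estimate ~ precision regression slope near zero
        slope, _, _, p, _ = stats.linregress(f["precision"], f["estimate"])
        assert p > 0.05

    def test_single_snp_set(self):
        s = make_set([0.2], [0.1], [0.05])
        assert len(funnel_data(s)) == 1
        table = single_snp_forest(s, ["wald_ratio"], seed=0, n_boot=20)
        assert len(table) == 2  # one per-SNP row + one combined row


class TestSteiger:
    def test_equal_r2_is_undecided(self):
        # same effects and sample sizes on both sides
        s = make_set([0.1, 0.2], [0.1, 0.2], [0.01, 0.01],
                     sx=np.array([0.01, 0.01]))
        res = steiger(s)
        assert res.r2_exposure == pytest.approx(res.r2_outcome)
        assert not res.direction_correct
        assert res.steiger_pval == pytest.approx(1.0)

    def test_role_swap_negates_direction(self, sim_set):
        s, _ = sim_set
        fwd = steiger(s)
        k = s.kept().rename(columns={
            "beta_exp": "beta_out", "beta_out": "beta_exp",
            "se_exp": "se_out", "se_out": "se_exp",
            "n_exp": "n_out", "n_out": "n_exp",
            "eaf_exp": "eaf_out", "eaf_out": "eaf_exp",
            "pval_exp": "pval_out", "pval_out": "pval_exp"})
        rev = steiger(SummarySet(k, action=1))
        assert fwd.direction_correct and not rev.direction_correct
        assert fwd.steiger_pval == pytest.approx(rev.steiger_pval)

    def test_pvalue_monotone_in_r2_gap(self):
        base = make_set([0.1] * 5, [0.02] * 5, [0.01] * 5,
                        sx=np.full(5, 0.005))
        wider = make_set([0.12] * 5, [0.02] * 5, [0.01] * 5,
                         sx=np.full(5, 0.005))
        assert steiger(wider).steiger_pval < steiger(base).steiger_pval

    def test_detects_causal_direction_in_simulation(self):
        hits = 0
        reps = 200
        for i in range(reps):
            cfg = SimulationConfig(theta=0.3, L=20, n_exp=20_000,
                                   n_out=20_000, seed=1000 + i)
            s, _ = simulate_summary_set(cfg)
            res = steiger(s)
            hits += res.direction_correct and res.steiger_pval < 0.05
        assert hits / reps >= 0.95

    def test_missing_n_lists_snps(self, sim_set):
        s, _ = sim_set
        k = s.kept().copy()
        k.loc[0, "n_out"] = np.nan
        with pytest.raises(ValueError, match="rs1"):
            steiger(SummarySet(k, action=1))


class TestInstrumentStrength:
    def test_zero_r2_gives_zero_f(self):
        assert instrument_strength(0.0, 5, 1000) == 0.0

    def test_single_snp_reduction(self):
        r2 = 0.01
        n = 5000
        assert instrument_strength(r2, 1, n) == pytest.approx(
            r2 * (n - 2) / (1 - r2))

    def test_monotone_in_r2_and_n(self):
        assert instrument_strength(0.03, 10, 10_000) > \
            instrument_strength(0.02, 10, 10_000)
        assert instrument_strength(0.02, 10, 20_000) > \
            instrument_strength(0.02, 10, 10_000)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            instrument_strength(1.0, 5, 1000)
        with pytest.raises(ValueError):
            instrument_strength(0.1, 5, 6)


def test_overlap_percentage():
    assert overlap_percentage(50, 200) == pytest.approx(25.0)
    with pytest.raises(ValueError):
        overlap_percentage(300, 200)
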