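"""MR estimators, heterogeneity, Egger, PRESSO, Steiger and FDR control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_instruments
from omicmr.mr import (
    AnalysisConfig, MRInputError, analyze_exposure, bh_fdr, cochran_q, egger,
    ivw, mr_presso, steiger_filter, wald_ratio,
)
from omicmr.simulate import noiseless_pleiotropy_instruments, outlier_instruments


class TestWald:
    def test_ratio_and_delta_se(self):
        est = wald_ratio(0.5, 0.02, 0.1, 0.05)
        assert est.theta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1)
        assert est.or_ == pytest.approx(np.exp(0.2))
        assert est.k == 1

    def test_null_outcome_gives_unit_or(self):
        est = wald_ratio(0.5, 0.02, 0.0, 0.05)
        assert est.theta == 0.0
        assert est.or_ == 1.0
        assert est.pvalue == pytest.approx(1.0)

    def test_zero_exposure_effect_is_error(self):
        with pytest.raises(MRInputError, match="undefined_wald"):
            wald_ratio(0.0, 0.02, 0.1, 0.05)

    def test_negative_exposure_effect_absolute_se(self):
        est = wald_ratio(-0.5, 0.02, 0.1, 0.05)
        assert est.theta == pytest.approx(-0.2)
        assert est.se == pytest.approx(0.1)


def _wls_through_origin(bx, by, w):
    """Closed-form normal-equation oracle for weighted LS through the origin."""
    bx, by, w = map(np.asarray, (bx, by, w))
    theta = np.sum(w * bx * by) / np.sum(w * bx * bx)
    se = np.sum(w * bx * bx) ** -0.5
    return theta, se


class TestIVW:
    def test_single_instrument_directed_to_wald(self):
        with pytest.raises(MRInputError, match="use_wald"):
            ivw(make_instruments([0.1], [0.05]))

    def test_duplicate_instrument_halves_variance(self):
        instr = make_instruments([1.0, 1.0], [0.2, 0.2], se_y=0.1)
        est = ivw(instr, "fixed")
        assert est.theta == pytest.approx(0.2)
        assert est.se == pytest.approx(0.1 / np.sqrt(2))

    def test_matches_normal_equation_oracle(self, rng):
        bx = rng.normal(0.2, 0.1, 3)
        by = rng.normal(0.1, 0.05, 3)
        se_y = rng.uniform(0.01, 0.1, 3)
        instr = make_instruments(bx, by, se_y=se_y)
        est = ivw(instr, "fixed")
        theta, se = _wls_through_origin(bx, by, se_y ** -2.0)
        assert est.theta == pytest.approx(theta, abs=1e-12)
        assert est.se == pytest.approx(se, abs=1e-12)

    def test_k_copies_match_wald_with_root_k_se(self):
        k = 5
        instr = make_instruments([0.4] * k, [0.12] * k, se_y=0.06)
        wald = wald_ratio(0.4, 0.01, 0.12, 0.06)
        est = ivw(instr, "fixed")
        assert est.theta == pytest.approx(wald.theta, abs=1e-12)
        assert est.se == pytest.approx(wald.se / np.sqrt(k), abs=1e-12)

    def test_invariant_under_joint_sign_flip(self, rng):
        bx = rng.normal(0.3, 0.1, 8)
        by = 0.5 * bx + rng.normal(0, 0.02, 8)
        se_y = rng.uniform(0.01, 0.05, 8)
        base = ivw(make_instruments(bx, by, se_y=se_y), "fixed")
        flip = rng.uniform(size=8) < 0.5
        s = np.where(flip, -1.0, 1.0)
        flipped = ivw(make_instruments(bx * s, by * s, se_y=se_y), "fixed")
        assert flipped.theta == pytest.approx(base.theta, abs=1e-12)
        assert flipped.se == pytest.approx(base.se, abs=1e-12)

    def test_random_effects_inflates_se(self):
        instr = make_instruments([1.0, 1.0, 1.0], [0.0, 0.5, 1.0], se_y=0.05)
        fixed = ivw(instr, "fixed")
        random = ivw(instr, "random")
        assert random.theta == pytest.approx(fixed.theta)
        assert random.se > fixed.se
        auto = ivw(instr, "auto")
        assert auto.method == "ivw_random"

    def test_auto_chooses_fixed_when_homogeneous(self):
        instr = make_instruments([1.0, 1.2, 0.8], [0.30, 0.36, 0.24], se_y=0.05)
        assert ivw(instr, "auto").method == "ivw_fixed"


class TestCochranQ:
    def test_identical_ratios_give_zero_q(self):
        instr = make_instruments([1.0, 2.0], [0.3, 0.6], se_y=0.1)
        rep = cochran_q(instr, 0.3)
        assert rep.q == pytest.approx(0.0, abs=1e-20)
        assert rep.pvalue == pytest.approx(1.0)
        assert rep.df == 1

    def test_hand_computed_three_instrument_q(self):
        # bx = 1, by = (0.1, 0.2, 0.3), se_y = 0.1 -> theta = 0.2,
        # Q = 100*(0.01 + 0 + 0.01) = 2, p = chi2.sf(2, 2) = exp(-1)
        instr = make_instruments([1.0, 1.0, 1.0], [0.1, 0.2, 0.3], se_y=0.1)
        rep = cochran_q(instr, 0.2)
        assert rep.q == pytest.approx(2.0)
        assert rep.df == 2
        assert rep.pvalue == pytest.approx(np.exp(-1.0))

    def test_single_instrument_is_error(self):
        with pytest.raises(MRInputError):
            cochran_q(make_instruments([1.0], [0.1]), 0.1)


class TestEgger:
    def test_exact_fit_through_origin(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        instr = make_instruments(bx, 0.3 * bx)
        rep = egger(instr)
        assert rep.intercept == pytest.approx(0.0, abs=1e-12)
        assert rep.slope == pytest.approx(0.3, abs=1e-12)
        assert rep.intercept_p > 0.9

    def test_exact_intercept_recovery(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        instr = make_instruments(bx, 0.05 + 0.3 * bx, se_y=0.01)
        rep = egger(instr)
        assert rep.intercept == pytest.approx(0.05, abs=1e-12)
        assert rep.slope == pytest.approx(0.3, abs=1e-12)
        assert rep.intercept_p < 0.05

    def test_matches_weighted_ls_oracle(self, rng):
        bx = rng.uniform(0.1, 0.5, 5)
        by = rng.normal(0.02 + 0.4 * bx, 0.03)
        se_y = rng.uniform(0.02, 0.08, 5)
        rep = egger(make_instruments(bx, by, se_y=se_y))
        w = se_y ** -2.0
        X = np.column_stack([np.ones(5), bx])
        coef = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * by))
        assert rep.intercept == pytest.approx(coef[0], abs=1e-12)
        assert rep.slope == pytest.approx(coef[1], abs=1e-12)

    def test_orientation_invariance(self, rng):
        bx = rng.uniform(0.1, 0.5, 6)
        by = 0.04 + 0.3 * bx + rng.normal(0, 0.01, 6)
        base = egger(make_instruments(bx, by))
        s = np.where(rng.uniform(size=6) < 0.5, -1.0, 1.0)
        flipped = egger(make_instruments(bx * s, by * s))
        assert flipped.intercept == pytest.approx(base.intercept, abs=1e-12)
        assert flipped.slope == pytest.approx(base.slope, abs=1e-12)

    def test_needs_three_instruments(self):
        with pytest.raises(MRInputError, match="egger_skipped"):
            egger(make_instruments([0.1, 0.2], [0.03, 0.06]))


class TestPresso:
    def test_needs_four_instruments(self):
        with pytest.raises(MRInputError, match="presso_skipped"):
            mr_presso(make_instruments([0.1] * 3, [0.05] * 3), seed=1)

    def test_homogeneous_set_not_flagged(self):
        table, _ = outlier_instruments(shift_se=0.0, k=8, seed=4)
        rep = mr_presso(table, n_sim=1000, seed=7)
        assert rep.global_p > 0.05
        assert rep.removed_ids == []

    def test_gross_outlier_detected_and_removed(self):
        table, outlier_id = outlier_instruments(shift_se=10.0, k=8, seed=4)
        rep = mr_presso(table, n_sim=1000, seed=7)
        assert rep.global_p < 0.05
        assert outlier_id in rep.removed_ids

    def test_deterministic_given_seed(self):
        table, _ = outlier_instruments(shift_se=10.0, k=8, seed=4)
        a = mr_presso(table, n_sim=200, seed=9)
        b = mr_presso(table, n_sim=200, seed=9)
        assert a == b


class TestSteiger:
    def test_forward_direction_kept(self):
        instr = make_instruments([0.15], [0.02], eaf=0.3)
        rep, kept = steiger_filter(instr, 10_000, 20_000, case_fraction=0.1)
        assert rep.table.iloc[0]["direction_ok"]
        assert len(kept) == 1

    def test_reversed_direction_removed(self):
        # outcome correlation far exceeds exposure correlation
        instr = make_instruments([0.02], [1.5], eaf=0.3)
        rep, kept = steiger_filter(instr, 10_000, 20_000, case_fraction=0.1)
        assert not rep.table.iloc[0]["direction_ok"]
        assert rep.table.iloc[0]["steiger_p"] < 0.05
        assert len(kept) == 0

    def test_equal_r2_is_kept_with_null_p(self):
        # with equal implied correlations the z statistic is exactly zero
        instr = make_instruments([0.1], [0.1], eaf=0.3)
        instr["beta_out"] = instr["beta_exp"] / np.sqrt(0.1 * 0.9)
        rep, kept = steiger_filter(instr, 10_000, 10_000, case_fraction=0.1)
        assert rep.table.iloc[0]["steiger_p"] == pytest.approx(1.0)
        assert len(kept) == 1

    def test_missing_eaf_exempted(self):
        instr = make_instruments([0.02], [1.5])
        instr["eaf_exp"] = np.nan
        rep, kept = steiger_filter(instr, 10_000, 20_000, case_fraction=0.1)
        assert rep.skipped_ids == ["iv0"]
        assert len(kept) == 1


class TestFDR:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_all_ones_and_singleton(self):
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        np.testing.assert_allclose(bh_fdr([0.2]), [0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])

    @staticmethod
    def _bh_reference(p):
        """Quadratic-time step-up reference: adj_i = min over p_j >= p_i of m*p_j/rank_j."""
        p = np.asarray(p, dtype=float)
        m = len(p)
        order = np.argsort(p, kind="stable")
        ranks = np.empty(m, dtype=int)
        ranks[order] = np.arange(1, m + 1)
        adj = np.empty(m)
        for i in range(m):
            candidates = [m * p[j] / ranks[j] for j in range(m) if p[j] >= p[i]]
            adj[i] = min(1.0, min(candidates))
        return adj

    def test_agrees_with_quadratic_reference(self, rng):
        for _ in range(20):
            p = rng.uniform(1e-6, 1.0, int(rng.integers(1, 40)))
            np.testing.assert_allclose(bh_fdr(p), self._bh_reference(p), atol=1e-12)

    def test_preserves_input_order(self, rng):
        p = rng.uniform(0.001, 1.0, 25)
        adj = bh_fdr(p)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_fdr(p[perm]), adj[perm], atol=1e-12)


class TestAnalyzeExposure:
    CFG = AnalysisConfig(n_exposure=10_000, n_outcome=20_000,
                         case_fraction=0.1, presso_seed=3)

    def test_single_instrument_wald_path(self):
        res = analyze_exposure(make_instruments([0.2], [0.08]), self.CFG)
        assert res.estimate.method == "wald"
        assert res.heterogeneity is None and res.egger is None
        assert res.presso is None
        assert res.steiger is not None
        assert res.qc_verdict == "pass"

    def test_noiseless_pleiotropy_is_excluded(self):
        instr = noiseless_pleiotropy_instruments(intercept=0.1)
        res = analyze_exposure(instr, self.CFG)
        assert res.egger.intercept == pytest.approx(0.1, abs=1e-10)
        assert res.qc_verdict == "excluded_pleiotropy"

    def test_homogeneous_set_uses_fixed_effects(self):
        table, _ = outlier_instruments(shift_se=0.0, k=8, seed=4)
        res = analyze_exposure(table, self.CFG)
        assert res.estimate.method == "ivw_fixed"
        assert res.heterogeneity.pvalue >= 0.05
        assert res.qc_verdict == "pass"

    def test_outlier_removed_before_estimation(self):
        table, outlier_id = outlier_instruments(shift_se=10.0, k=8, seed=4)
        res = analyze_exposure(table, self.CFG)
        assert res.n_removed_presso >= 1
        assert outlier_id in res.presso.removed_ids
        assert res.estimate.k == 8 - res.n_removed_presso

    def test_empty_table_skipped(self):
        res = analyze_exposure(make_instruments([], []), self.CFG)
        assert res.estimate is None
        assert res.qc_verdict == "no_instruments"
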