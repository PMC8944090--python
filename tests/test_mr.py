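"""Harmonisation and the MR estimator suite, checked against independent
brute-force oracles on fixed tables."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats as sps

from repromr.mr import (cochran_q, harmonise, i2_gx, mean_f_statistic,
                        mr_egger, mr_ivw, simex_egger, wald_ratios,
                        weighted_median, weighted_mode)
from repromr.examples import instrument_strength_examples
from repromr.studies import two_sample_pair

from conftest import make_harmonised, make_sumstats


# ---------------------------------------------------------------------------
# harmonisation
# ---------------------------------------------------------------------------

class TestHarmonise:
    def test_identical_alleles_unchanged(self):
        exp = make_sumstats(["rs1"], beta=[0.2], se=[0.05], ea="A", oa="G")
        out = make_sumstats(["rs1"], beta=[0.1], se=[0.04], ea="A", oa="G")
        h = harmonise(exp, out)
        assert h.table.loc[0, "action"] == "kept"
        assert h.table.loc[0, "beta_out"] == pytest.approx(0.1)

    def test_swapped_alleles_flip(self):
        exp = make_sumstats(["rs1"], beta=[0.2], se=[0.05], ea="A", oa="G",
                            eaf=[0.3])
        out = make_sumstats(["rs1"], beta=[0.1], se=[0.04], ea="G", oa="A",
                            eaf=[0.7])
        h = harmonise(exp, out)
        assert h.table.loc[0, "action"] == "flipped"
        assert h.table.loc[0, "beta_out"] == pytest.approx(-0.1)
        assert h.table.loc[0, "eaf_out"] == pytest.approx(0.3)

    def test_strand_flip_resolved_by_complement(self):
        exp = make_sumstats(["rs1"], beta=[0.2], se=[0.05], ea="A", oa="G")
        out = make_sumstats(["rs1"], beta=[0.1], se=[0.04], ea="T", oa="C")
        h = harmonise(exp, out)
        assert h.table.loc[0, "action"] == "kept"
        assert h.table.loc[0, "beta_out"] == pytest.approx(0.1)

    def test_ambiguous_palindrome_dropped(self):
        exp = make_sumstats(["rs1"], beta=[0.2], se=[0.05], ea="A", oa="T",
                            eaf=[0.50])
        out = make_sumstats(["rs1"], beta=[0.1], se=[0.04], ea="A", oa="T",
                            eaf=[0.50])
        h = harmonise(exp, out)
        assert h.k == 0
        assert h.audit.loc[0, "action"] == "dropped_palindromic"

    def test_inferable_palindrome_kept(self):
        exp = make_sumstats(["rs1"], beta=[0.2], se=[0.05], ea="A", oa="T",
                            eaf=[0.2])
        out = make_sumstats(["rs1"], beta=[0.1], se=[0.04], ea="A", oa="T",
                            eaf=[0.25])
        h = harmonise(exp, out)
        assert h.k == 1 and h.table.loc[0, "action"] == "kept"

    def test_unresolvable_mismatch_dropped_with_reason(self):
        exp = make_sumstats(["rs1"], beta=[0.2], se=[0.05], ea="A", oa="G")
        out = make_sumstats(["rs1"], beta=[0.1], se=[0.04], ea="A", oa="C")
        h = harmonise(exp, out)
        assert h.k == 0
        assert "dropped_mismatch" in set(h.audit["action"])

    def test_idempotent(self):
        exp = make_sumstats(["rs1", "rs2"], beta=[0.2, 0.1], se=[0.05, 0.04],
                            ea=["A", "T"], oa=["G", "C"], eaf=[0.3, 0.4])
        out = make_sumstats(["rs1", "rs2"], beta=[0.1, -0.05],
                            se=[0.04, 0.03], ea=["G", "T"], oa=["A", "C"],
                            eaf=[0.7, 0.4])
        h1 = harmonise(exp, out)
        # rebuild both sides on the harmonised orientation and re-harmonise
        exp2 = make_sumstats(h1.table["snp"], beta=h1.table["beta_exp"],
                             se=h1.table["se_exp"], ea=["A", "T"],
                             oa=["G", "C"], eaf=list(h1.table["eaf_exp"]))
        out2 = make_sumstats(h1.table["snp"], beta=h1.table["beta_out"],
                             se=h1.table["se_out"], ea=["A", "T"],
                             oa=["G", "C"], eaf=list(h1.table["eaf_out"]))
        h2 = harmonise(exp2, out2)
        pd.testing.assert_frame_equal(
            h1.table.drop(columns="action"), h2.table.drop(columns="action"))

    def test_no_shared_snps_rejected(self):
        exp = make_sumstats(["rs1"], beta=[0.2], se=[0.05])
        out = make_sumstats(["rs2"], beta=[0.1], se=[0.04])
        with pytest.raises(ValueError, match="share no SNPs"):
            harmonise(exp, out)


# ---------------------------------------------------------------------------
# Wald ratios and IVW
# ---------------------------------------------------------------------------

class TestWaldRatios:
    def test_arithmetic(self):
        h = make_harmonised([0.1], [0.01], [0.05], [0.01])
        ratio, se, _ = wald_ratios(h)
        assert ratio[0] == pytest.approx(0.5)
        assert se[0] == pytest.approx(0.1)

    def test_null_numerator_and_scale_invariance(self):
        h1 = make_harmonised([0.1, 0.2], [0.01, 0.01], [0.0, 0.08],
                             [0.01, 0.01])
        r1, _, _ = wald_ratios(h1)
        assert r1[0] == 0.0
        h2 = make_harmonised([0.2, 0.4], [0.01, 0.01], [0.0, 0.16],
                             [0.01, 0.01])
        r2, _, _ = wald_ratios(h2)
        np.testing.assert_allclose(r1, r2)

    def test_zero_exposure_beta_excluded(self):
        h = make_harmonised([0.0, 0.1], [0.01, 0.01], [0.05, 0.05],
                            [0.01, 0.01])
        ratio, _, snps = wald_ratios(h)
        assert len(ratio) == 1 and snps[0] == "rs2"


class TestIvw:
    def test_homogeneous_ratios(self):
        bx = np.array([0.1, 0.2, 0.05])
        h = make_harmonised(bx, [0.01] * 3, 0.4 * bx, [0.01, 0.02, 0.01])
        res = mr_ivw(h)
        assert res.estimate == pytest.approx(0.4, abs=1e-12)
        assert res.q == pytest.approx(0.0, abs=1e-20)
        w = 1.0 / np.array([0.01, 0.02, 0.01]) ** 2
        assert res.se == pytest.approx(1 / np.sqrt(np.sum(w * bx ** 2)))

    def test_matches_wls_oracle(self, fixed_harmonised):
        """IVW equals weighted least squares through the origin (statsmodels
        oracle) to 1e-10."""
        t = fixed_harmonised.table
        w = 1.0 / t["se_out"] ** 2
        oracle = sm.WLS(t["beta_out"], t[["beta_exp"]], weights=w).fit()
        res = mr_ivw(fixed_harmonised)
        assert res.estimate == pytest.approx(oracle.params.iloc[0], abs=1e-10)

    def test_equals_weighted_mean_of_ratios(self, fixed_harmonised):
        ratio, se_ratio, _ = wald_ratios(fixed_harmonised)
        w = se_ratio ** -2
        res = mr_ivw(fixed_harmonised)
        assert res.estimate == pytest.approx(np.sum(w * ratio) / np.sum(w),
                                             abs=1e-10)

    def test_sign_flip_invariance(self, fixed_harmonised):
        flipped = fixed_harmonised.table.copy()
        flipped.loc[[1, 3], ["beta_exp", "beta_out"]] *= -1
        from repromr.mr import HarmonisedSet
        h2 = HarmonisedSet(flipped, "exp", "out")
        for fn in (mr_ivw, mr_egger):
            assert fn(fixed_harmonised).estimate == pytest.approx(
                fn(h2).estimate, abs=1e-12)

    def test_too_few_snps_skipped(self):
        h = make_harmonised([0.1], [0.01], [0.05], [0.01])
        assert mr_ivw(h).skipped


class TestCochranQ:
    def test_summation_oracle(self, fixed_harmonised):
        res = mr_ivw(fixed_harmonised)
        q, df, p, flag = cochran_q(fixed_harmonised, res.estimate)
        t = fixed_harmonised.table
        ratio = t["beta_out"] / t["beta_exp"]
        se_ratio = t["se_out"] / t["beta_exp"].abs()
        manual = np.sum(se_ratio ** -2 * (ratio - res.estimate) ** 2)
        assert q == pytest.approx(manual, abs=1e-12)
        assert df == 4
        assert p == pytest.approx(sps.chi2.sf(manual, 4), abs=1e-12)

    def test_order_invariance(self, fixed_harmonised):
        from repromr.mr import HarmonisedSet
        res = mr_ivw(fixed_harmonised)
        q1, *_ = cochran_q(fixed_harmonised, res.estimate)
        perm = HarmonisedSet(fixed_harmonised.table.iloc[::-1], "exp", "out")
        q2, *_ = cochran_q(perm, res.estimate)
        assert q1 == pytest.approx(q2, abs=1e-12)


# ---------------------------------------------------------------------------
# Egger, SIMEX
# ---------------------------------------------------------------------------

class TestEgger:
    def test_points_through_origin(self):
        bx = np.array([0.05, 0.1, 0.2, 0.3])
        h = make_harmonised(bx, [0.01] * 4, 0.7 * bx, [0.01] * 4)
        res = mr_egger(h)
        assert res.egger_intercept == pytest.approx(0.0, abs=1e-12)
        assert res.estimate == pytest.approx(0.7, abs=1e-12)
        assert res.estimate == pytest.approx(mr_ivw(h).estimate, abs=1e-12)

    def test_zero_intercept_constraint_reproduces_ivw(self, fixed_harmonised):
        """Constraining the Egger intercept to zero is the IVW regression."""
        t = fixed_harmonised.table
        w = 1.0 / t["se_out"] ** 2
        constrained = np.sum(w * t["beta_exp"] * t["beta_out"]) / \
            np.sum(w * t["beta_exp"] ** 2)
        assert constrained == pytest.approx(mr_ivw(fixed_harmonised).estimate,
                                            abs=1e-12)

    def test_i2_gx_closed_form_equal_se(self):
        bx = np.array([0.1, 0.15, 0.25, 0.4])
        h = make_harmonised(bx, [0.02] * 4, 0.1 * bx, [0.01] * 4)
        q_gx = np.sum((bx - bx.mean()) ** 2 / 0.02 ** 2)
        assert i2_gx(h) == pytest.approx(1 - 3 / q_gx, abs=1e-12)

    def test_intercept_detects_directional_pleiotropy(self):
        h = two_sample_pair(k=50, n_exposure=200_000, n_outcome=200_000,
                            theta=0.09, seed=1, pleiotropy_mean=0.03,
                            pleiotropy_sd=0.005, effect_dist="fixed")
        res = mr_egger(h)
        assert abs(res.egger_intercept - 0.03) < 3 * res.egger_intercept_se
        assert res.egger_intercept_p < 0.05

    def test_skipped_below_minimum(self):
        h = make_harmonised([0.1, 0.2], [0.01] * 2, [0.05, 0.1], [0.01] * 2)
        assert mr_egger(h).skipped


class TestSimex:
    def test_deterministic(self, fixed_harmonised):
        a = simex_egger(fixed_harmonised, seed=5, n_boot=50)
        b = simex_egger(fixed_harmonised, seed=5, n_boot=50)
        assert a.estimate == b.estimate and a.se == b.se

    def test_nome_satisfied_limit(self):
        """With negligible exposure noise the correction leaves the naive
        slope unchanged."""
        h = two_sample_pair(k=30, n_exposure=10_000_000, n_outcome=20_000,
                            theta=0.2, seed=2)
        naive = mr_egger(h)
        corrected = simex_egger(h, seed=2, n_boot=200)
        assert corrected.estimate == pytest.approx(naive.estimate, abs=0.01)

    def test_needs_three_lambdas(self, fixed_harmonised):
        with pytest.raises(ValueError, match="lambdas"):
            simex_egger(fixed_harmonised, lambdas=(0.0, 1.0))

    def test_corrects_dilution_more_often_than_not(self):
        """Under regression dilution the extrapolated slope is closer to the
        truth than the naive slope in most replicates."""
        wins = 0
        for s in range(40):
            h = two_sample_pair(k=100, n_exposure=5_000, n_outcome=200_000,
                                theta=0.3, seed=s)
            naive = mr_egger(h)
            corr = simex_egger(h, seed=s, n_boot=200)
            wins += abs(corr.estimate - 0.3) < abs(naive.estimate - 0.3)
        assert wins >= 32  # >= 80%


# ---------------------------------------------------------------------------
# median / mode
# ---------------------------------------------------------------------------

class TestWeightedMedian:
    def test_equal_weights_odd_k_is_plain_median(self):
        bx = np.array([0.1, 0.1, 0.1])
        by = np.array([0.01, 0.03, 0.02])
        h = make_harmonised(bx, [0.01] * 3, by, [0.01] * 3)
        res = weighted_median(h, n_boot=100, seed=0)
        assert res.estimate == pytest.approx(0.2, abs=1e-10)

    def test_outlier_robustness(self):
        bx = np.full(12, 0.1)
        by = np.full(12, 0.02)
        h_clean = make_harmonised(bx, [0.01] * 12, by, [0.01] * 12)
        by_out = by.copy()
        by_out[0] = 0.5  # one wild ratio with <10% of total weight
        h_out = make_harmonised(bx, [0.01] * 12, by_out, [0.01] * 12)
        clean = weighted_median(h_clean, n_boot=300, seed=1)
        dirty = weighted_median(h_out, n_boot=300, seed=1)
        assert abs(dirty.estimate - clean.estimate) < dirty.se

    def test_bootstrap_se_close_to_replicate_sd(self):
        ests, ses = [], []
        for s in range(150):
            h = two_sample_pair(k=40, theta=0.1, seed=s)
            res = weighted_median(h, n_boot=200, seed=s)
            ests.append(res.estimate)
            ses.append(res.se)
        assert np.mean(ses) == pytest.approx(np.std(ests), rel=0.3)


class TestWeightedMode:
    def test_degenerate_density(self):
        bx = np.array([0.1, 0.2, 0.4])
        h = make_harmonised(bx, [0.01] * 3, 0.3 * bx, [0.01] * 3)
        res = weighted_mode(h, n_boot=50, seed=0)
        assert res.estimate == pytest.approx(0.3, abs=1e-10)

    def test_plurality_cluster_wins(self):
        # 60% of weight at ratio 0.1, 40% at ratio 0.5
        bx = np.full(10, 0.1)
        by = np.concatenate([np.full(6, 0.01), np.full(4, 0.05)])
        by += np.linspace(-1e-4, 1e-4, 10)  # break exact ties
        h = make_harmonised(bx, [0.01] * 10, by, [0.01] * 10)
        res = weighted_mode(h, n_boot=50, seed=0)
        assert res.estimate == pytest.approx(0.1, abs=0.05)

    def test_deterministic(self, fixed_harmonised):
        a = weighted_mode(fixed_harmonised, n_boot=100, seed=3)
        b = weighted_mode(fixed_harmonised, n_boot=100, seed=3)
        assert a.se == b.se


# ---------------------------------------------------------------------------
# instrument strength
# ---------------------------------------------------------------------------

class TestMeanF:
    def test_published_rows_recomputed(self):
        table = instrument_strength_examples()
        assert (table["f_computed"] > 10).all()
        menarche = table.set_index("exposure").loc["menarche"]
        assert menarche["f_lo"] <= menarche["f_published"] <= menarche["f_hi"]

    def test_zero_r2(self):
        assert mean_f_statistic(0.0, 1000, 10) == 0.0

    @pytest.mark.parametrize("r2,n,k", [(1.0, 100, 5), (0.1, 5, 10),
                                        (0.1, 100, 0)])
    def test_invalid_inputs(self, r2, n, k):
        with pytest.raises(ValueError):
            mean_f_statistic(r2, n, k)
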