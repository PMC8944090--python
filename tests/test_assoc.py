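"""Association scan, standardisation, instrument selection, cohort split."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from repromr.assoc import (rank_inverse_normal, run_gwas, select_instruments,
                           split_cohort, standardise_sumstats)
from repromr.simulate import Block, CausalConfig, simulate_genotypes, simulate_traits
from repromr.sumstats import BINARY, CONTINUOUS

from conftest import make_sumstats


class TestRankInverseNormal:
    def test_median_maps_to_zero(self):
        out = rank_inverse_normal([1.0, 2.0, 3.0])
        assert out[1] == pytest.approx(0.0, abs=1e-12)

    def test_blom_closed_form(self):
        out = rank_inverse_normal([10.0, 20.0, 30.0, 40.0, 50.0])
        expected = sps.norm.ppf((np.arange(1, 6) - 0.375) / 5.25)
        np.testing.assert_allclose(out, expected, atol=1e-12)

    def test_missing_preserved_and_ties_averaged(self):
        out = rank_inverse_normal([1.0, np.nan, 2.0, 2.0, 3.0])
        assert np.isnan(out[1])
        assert out[2] == out[3] == pytest.approx(0.0, abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=40,
                    unique=True))
    def test_monotone(self, values):
        out = rank_inverse_normal(values)
        order = np.argsort(values)
        assert np.all(np.diff(out[order]) > 0)

    def test_all_missing_rejected(self):
        with pytest.raises(ValueError):
            rank_inverse_normal([np.nan, np.nan, np.nan])


class TestRunGwas:
    def test_perfect_signal(self, cohort):
        panel, traits, _ = cohort
        fake = traits.values.copy()
        fake["signal"] = 2.0 * panel.dosages[:, 0]
        from repromr.simulate import TraitTable
        tt = TraitTable(fake, {**traits.types, "signal": CONTINUOUS},
                        traits.covariates, {})
        stats = run_gwas(panel, tt, "signal")
        row = stats.table.set_index("snp").loc[panel.snp_meta["snp"].iloc[0]]
        assert row["beta"] == pytest.approx(2.0, abs=1e-8)
        assert row["p"] < 1e-200

    def test_null_pvalues_uniform(self):
        panel = simulate_genotypes(
            2_000, [Block(50, 0.0) for _ in range(40)], seed=21)
        config = CausalConfig(
            trait_ids=("null",), n_snps_per_trait=10, h2={"null": 0.0},
            theta={}, confounder_gamma={}, confounder_h2=0.0,
            covariate_loadings={}, prevalence={}, binary_traits=(), seed=21)
        traits = simulate_traits(panel, config)
        stats = run_gwas(panel, traits, "null")
        _, ks_p = sps.kstest(stats.table["p"], "uniform")
        assert ks_p > 0.01

    def test_covariate_equal_to_trait_removes_signal(self, cohort):
        panel, traits, _ = cohort
        from repromr.simulate import TraitTable
        cov = traits.covariates.copy()
        cov["self"] = traits.values["menarche"]
        tt = TraitTable(traits.values, traits.types, cov, {})
        stats = run_gwas(panel, tt, "menarche",
                         covariates=("age", "batch", "self"))
        assert np.abs(stats.table["beta"]).max() < 1e-8

    def test_binary_trait_gives_log_odds(self, cohort):
        """Per-SNP logistic betas agree with the statsmodels oracle."""
        import statsmodels.api as sm
        panel, traits, _ = cohort
        stats = run_gwas(panel, traits, "parous")
        assert stats.trait_type == BINARY
        y = traits.values["parous"].to_numpy()
        X = np.column_stack([
            np.ones(panel.n_individuals), panel.dosages[:, 3].astype(float),
            traits.covariates["age"], traits.covariates["batch"]])
        oracle = sm.Logit(y, X).fit(disp=0)
        row = stats.table.set_index("snp").loc[panel.snp_meta["snp"].iloc[3]]
        assert row["beta"] == pytest.approx(oracle.params[1], abs=1e-6)
        assert row["se"] == pytest.approx(oracle.bse[1], rel=1e-5)


class TestStandardise:
    def test_unit_sd_is_identity(self):
        stats = make_sumstats(["rs1", "rs2"], beta=[0.3, -0.1], se=[0.1, 0.2])
        out = standardise_sumstats(stats, trait_sd=1.0)
        np.testing.assert_allclose(out.table["beta"], stats.table["beta"])
        assert out.units == "sd"

    def test_scale_invariance(self):
        stats = make_sumstats(["rs1", "rs2"], beta=[0.3, -0.1], se=[0.1, 0.2])
        scaled = make_sumstats(["rs1", "rs2"], beta=[0.9, -0.3], se=[0.3, 0.6])
        out = standardise_sumstats(scaled, trait_sd=3.0)
        np.testing.assert_allclose(out.table["beta"], stats.table["beta"],
                                   atol=1e-10)
        np.testing.assert_allclose(out.table["se"], stats.table["se"],
                                   atol=1e-10)

    def test_summary_only_route_agrees_with_trait_sd_route(self):
        """The z/eaf/n approximation tracks exact rescaling on real scans."""
        panel = simulate_genotypes(20_000, [Block(10, 0.0) for _ in range(4)],
                                   seed=22)
        config = CausalConfig(
            trait_ids=("t",), n_snps_per_trait=20, h2={"t": 0.3}, theta={},
            confounder_gamma={}, confounder_h2=0.0, covariate_loadings={},
            prevalence={}, binary_traits=(), seed=22)
        traits = simulate_traits(panel, config)
        sd = 3.7
        from repromr.simulate import TraitTable
        scaled = TraitTable(traits.values * sd, traits.types,
                            traits.covariates, {})
        stats = run_gwas(panel, scaled, "t")
        exact = standardise_sumstats(stats, trait_sd=sd)
        approx = standardise_sumstats(stats)
        ratio = approx.table["beta"] / exact.table["beta"]
        assert np.abs(ratio - 1).max() < 0.01

    def test_idempotent_with_warning(self):
        stats = make_sumstats(["rs1"], beta=[0.3], se=[0.1], units="sd")
        with pytest.warns(UserWarning, match="already standardised"):
            out = standardise_sumstats(stats, trait_sd=2.0)
        np.testing.assert_allclose(out.table["beta"], stats.table["beta"])


class TestSelectInstruments:
    def _stats(self, pvals, chrom=None, pos=None, panel=None):
        k = len(pvals)
        z = sps.norm.isf(np.asarray(pvals) / 2)
        se = np.full(k, 0.01)
        snp = panel.snp_meta["snp"].iloc[:k] if panel is not None \
            else [f"rs{i+1}" for i in range(k)]
        return make_sumstats(
            snp, beta=z * se, se=se,
            chrom=chrom if chrom is not None else
            (panel.snp_meta["chr"].iloc[:k] if panel is not None else 1),
            pos=pos if pos is not None else
            (panel.snp_meta["pos"].iloc[:k] if panel is not None else None))

    def test_independent_snps_both_retained(self):
        panel = simulate_genotypes(
            5_000, [Block(1, 0.0), Block(1, 0.0)], seed=23)
        stats = self._stats([1e-10, 1e-9], panel=panel)
        inst = select_instruments(stats, panel)
        assert sorted(inst.snps) == sorted(stats.table["snp"])

    def test_ld_pair_keeps_smaller_p(self):
        panel = simulate_genotypes(
            5_000, [Block(2, 0.95, mafs=[0.3, 0.3])], seed=24)
        stats = self._stats([1e-9, 1e-12], panel=panel)
        inst = select_instruments(stats, panel, clump_r2=0.5)
        assert inst.snps == [stats.table["snp"].iloc[1]]

    def test_threshold_is_strict(self):
        panel = simulate_genotypes(5_000, [Block(2, 0.0)], seed=25)
        stats = self._stats([6e-8, 1e-9], panel=panel)
        inst = select_instruments(stats, panel)
        assert inst.snps == [stats.table["snp"].iloc[1]]

    def test_no_survivors_gives_empty_status(self):
        panel = simulate_genotypes(5_000, [Block(2, 0.0)], seed=26)
        stats = self._stats([0.5, 0.1], panel=panel)
        inst = select_instruments(stats, panel)
        assert inst.status == "empty" and inst.k == 0

    def test_row_order_invariance(self):
        panel = simulate_genotypes(5_000, [Block(3, 0.2)], seed=27)
        stats = self._stats([1e-9, 1e-12, 1e-10], panel=panel)
        shuffled = make_sumstats(
            stats.table["snp"].iloc[::-1], beta=stats.table["beta"].iloc[::-1],
            se=stats.table["se"].iloc[::-1],
            chrom=stats.table["chr"].iloc[::-1],
            pos=list(stats.table["pos"].iloc[::-1]))
        a = select_instruments(stats, panel)
        b = select_instruments(shuffled, panel)
        assert a.snps == b.snps

    def test_clump_r2_one_retains_all_survivors(self):
        panel = simulate_genotypes(
            5_000, [Block(4, 0.9, mafs=[0.3] * 4)], seed=28)
        stats = self._stats([1e-9, 1e-10, 1e-11, 1e-12], panel=panel)
        inst = select_instruments(stats, panel, clump_r2=1.01)
        assert inst.k == 4

    def test_zero_window_removes_only_colocated(self):
        panel = simulate_genotypes(
            5_000, [Block(2, 0.95, mafs=[0.3, 0.3])], seed=29)
        stats = self._stats([1e-9, 1e-12], panel=panel)
        inst = select_instruments(stats, panel, clump_r2=0.5, clump_kb=0)
        assert inst.k == 2  # 1 kb apart, window 0 kb: both kept

    def test_r2_total_matches_joint_ols(self):
        """Sum of per-SNP contributions tracks variance explained by a joint
        fit on independent SNPs."""
        panel = simulate_genotypes(
            20_000, [Block(1, 0.0) for _ in range(30)], seed=30)
        config = CausalConfig(
            trait_ids=("t",), n_snps_per_trait=30, h2={"t": 0.2}, theta={},
            confounder_gamma={}, confounder_h2=0.0, covariate_loadings={},
            prevalence={}, binary_traits=(), seed=30)
        traits = simulate_traits(panel, config)
        stats = run_gwas(panel, traits, "t")
        inst = select_instruments(stats, panel, p_threshold=1e-4)
        idx = panel.snp_indices(inst.snps)
        g = panel.dosages[:, idx].astype(float)
        y = traits.values["t"].to_numpy()
        resid = y - g @ np.linalg.lstsq(
            np.column_stack([np.ones(len(y)), g]), y, rcond=None)[0][1:] \
            - np.mean(y)
        joint_r2 = 1 - np.var(y - np.column_stack([np.ones(len(y)), g]) @
                              np.linalg.lstsq(np.column_stack(
                                  [np.ones(len(y)), g]), y, rcond=None)[0]) \
            / np.var(y)
        assert inst.r2_total == pytest.approx(joint_r2, rel=0.05)


class TestSplitCohort:
    def test_partition(self, cohort):
        panel, traits, _ = cohort
        (p1, t1), (p2, t2) = split_cohort(panel, traits, seed=1)
        assert p1.n_individuals == np.ceil(panel.n_individuals / 2)
        assert p1.n_individuals + p2.n_individuals == panel.n_individuals

    def test_deterministic_and_conserving(self, cohort):
        panel, traits, _ = cohort
        (p1, _), (p2, _) = split_cohort(panel, traits, seed=2)
        (p1b, _), _ = split_cohort(panel, traits, seed=2)
        np.testing.assert_array_equal(p1.dosages, p1b.dosages)
        total = np.sort(np.concatenate([
            p1.dosages.sum(axis=1), p2.dosages.sum(axis=1)]))
        np.testing.assert_array_equal(
            total, np.sort(panel.dosages.sum(axis=1)))
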