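import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crosslimb.interaction_de import (
    INTERACTION_CONTRAST,
    ModelError,
    bh_adjust,
    ebayes_moderate,
    estimate_weights,
    fit_variance_prior,
    fit_weighted_lm,
    log_cpm,
    make_group_design,
    rank_candidates,
    run_interaction_de,
)
from crosslimb.sim_data import SimConfig, simulate_gene_counts
from tests.conftest import make_joined
from tests.oracles import bh_step_up, classical_contrast_t


def design_8x4():
    samples = pd.DataFrame(
        {
            "sample": ["EF_1", "EF_2", "EH_1", "EH_2", "CF_1", "CF_2", "CH_1", "CH_2"],
            "species": ["emu"] * 4 + ["chicken"] * 4,
            "tissue": ["fore", "fore", "hind", "hind"] * 2,
        }
    )
    return samples, make_group_design(samples)


class TestLogCpm:
    def test_zero_count_closed_form(self):
        # one sample with column total 1e6 - 1, so L + 1 = 1e6
        counts = pd.DataFrame({"s1": [0, 10**6 - 1]}, index=["g1", "g2"])
        y, lib = log_cpm(counts)
        assert y.loc["g1", "s1"] == pytest.approx(np.log2(0.5), abs=1e-12)

    def test_full_library_gene_near_log2_million(self):
        counts = pd.DataFrame({"s1": [10**6]}, index=["g1"])
        y, _ = log_cpm(counts)
        assert y.loc["g1", "s1"] == pytest.approx(np.log2(1e6), abs=0.01)

    def test_proportional_scaling_leaves_cpm_unchanged(self):
        rng = np.random.default_rng(1)
        base = rng.integers(100, 1000, size=20)
        counts = pd.DataFrame({"s1": base, "s2": 2 * base})
        y, _ = log_cpm(counts)
        assert np.abs(y["s1"] - y["s2"]).max() < 0.01

    def test_all_zero_column_rejected(self):
        counts = pd.DataFrame({"s1": [1, 2], "s2": [0, 0]})
        with pytest.raises(ValueError, match="all-zero"):
            log_cpm(counts)

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            log_cpm(pd.DataFrame({"s1": [-1, 2]}))


class TestWeights:
    def test_homoskedastic_data_gets_near_constant_weights(self):
        """Gaussian y with mean-independent variance: the trend is flat and
        the weight spread stays under 2x."""
        rng = np.random.default_rng(2)
        samples, X = design_8x4()
        G = 5000
        y = pd.DataFrame(
            rng.normal(8.0, 1.0, size=(G, 1)) + rng.normal(0, 0.3, size=(G, 8)),
            columns=X.index,
        )
        lib = pd.Series(1e6, index=X.index)
        wx = estimate_weights(y, lib, X)
        w = wx.weights.to_numpy()
        assert w.max() / w.min() < 2.0

    def test_nb_counts_weights_increase_with_expression(self):
        """Counts have a decreasing mean-variance trend on the log scale, so
        weights correlate positively with expression level."""
        cfg = SimConfig(n_genes=3000, seed=3)
        joined, samples, _ = make_joined(cfg)
        y, lib = log_cpm(joined)
        wx = estimate_weights(y, lib, make_group_design(samples))
        rho = stats.spearmanr(joined.mean(axis=1), wx.weights.mean(axis=1)).statistic
        assert rho > 0

    def test_gene_permutation_permutes_weights(self):
        cfg = SimConfig(n_genes=200, seed=4)
        joined, samples, _ = make_joined(cfg)
        X = make_group_design(samples)
        y, lib = log_cpm(joined)
        wx = estimate_weights(y, lib, X)
        perm = y.index[::-1]
        wx_perm = estimate_weights(y.loc[perm], lib, X)
        pd.testing.assert_frame_equal(wx_perm.weights, wx.weights.loc[perm])

    def test_errors_on_no_residual_df_and_tiny_gene_sets(self):
        samples, X = design_8x4()
        y = pd.DataFrame(np.ones((20, 8)), columns=X.index)
        lib = pd.Series(1e6, index=X.index)
        with pytest.raises(ModelError):
            estimate_weights(y.iloc[:5], lib, X)  # < 10 genes
        X4 = X.iloc[[0, 2, 4, 6]]
        with pytest.raises(ModelError):
            estimate_weights(y[X4.index], lib[X4.index], X4)  # n == p


class TestWeightedLm:
    def test_residual_df_is_n_minus_groups(self):
        cfg = SimConfig(n_genes=50, seed=5)
        joined, samples, _ = make_joined(cfg)
        X = make_group_design(samples)
        y, _ = log_cpm(joined)
        fit = fit_weighted_lm(y, pd.DataFrame(1.0, index=y.index, columns=y.columns), X)
        assert fit.df_resid == 4

    def test_unit_weights_give_group_means(self):
        samples, X = design_8x4()
        rng = np.random.default_rng(6)
        y = pd.DataFrame(rng.normal(size=(12, 8)), columns=X.index)
        w = pd.DataFrame(1.0, index=y.index, columns=y.columns)
        fit = fit_weighted_lm(y, w, X)
        for g in ["EF", "EH", "CF", "CH"]:
            cols = [s for s in X.index if X.loc[s, g] == 1]
            assert np.allclose(fit.coefficients[g], y[cols].mean(axis=1))

    def test_constant_gene_has_zero_sigma_and_contrasts(self):
        samples, X = design_8x4()
        y = pd.DataFrame(np.full((12, 8), 3.0), columns=X.index)
        w = pd.DataFrame(1.0, index=y.index, columns=y.columns)
        fit = fit_weighted_lm(y, w, X)
        assert np.allclose(fit.sigma, 0.0)
        assert np.allclose(fit.coefficients.to_numpy() @ INTERACTION_CONTRAST, 0.0)

    def test_rank_deficient_design_rejected(self):
        samples, X = design_8x4()
        X = X.copy()
        X["dup"] = X["EF"]
        y = pd.DataFrame(np.ones((12, 8)), columns=X.index)
        w = pd.DataFrame(1.0, index=y.index, columns=y.columns)
        with pytest.raises(ModelError, match="rank"):
            fit_weighted_lm(y, w, X)


class TestEbayes:
    @staticmethod
    def _fit(seed=7, G=20):
        samples, X = design_8x4()
        rng = np.random.default_rng(seed)
        y = pd.DataFrame(rng.normal(5, 1, size=(G, 8)), columns=X.index)
        w = pd.DataFrame(1.0, index=y.index, columns=y.columns)
        return fit_weighted_lm(y, w, X), y

    def test_d0_zero_equals_classical_t(self):
        """With no shrinkage and unit weights the moderated t is exactly the
        ordinary contrast t from the brute-force dense-algebra oracle."""
        fit, y = self._fit()
        mod = ebayes_moderate(fit, INTERACTION_CONTRAST, d0=0.0)
        expected = classical_contrast_t(
            y.to_numpy(), fit.design.to_numpy(), INTERACTION_CONTRAST
        )
        assert np.max(np.abs(mod["t"].to_numpy() - expected)) < 1e-10

    def test_infinite_d0_pools_variances(self):
        fit, _ = self._fit()
        mod = ebayes_moderate(fit, INTERACTION_CONTRAST, d0=np.inf, s0_2=2.0)
        se = mod["estimate"] / mod["t"]
        unscaled = np.einsum(
            "p,gpq,q->g", INTERACTION_CONTRAST, fit.cov_unscaled, INTERACTION_CONTRAST
        )
        assert np.allclose(se**2, 2.0 * unscaled)

    def test_moderated_variance_between_gene_and_prior(self):
        samples, X = design_8x4()
        rng = np.random.default_rng(7)
        sds = rng.lognormal(0.0, 0.7, size=200)  # gene-specific noise levels
        y = pd.DataFrame(rng.normal(5, 1, size=(200, 8)) * sds[:, None], columns=X.index)
        w = pd.DataFrame(1.0, index=y.index, columns=y.columns)
        fit = fit_weighted_lm(y, w, X)
        mod = ebayes_moderate(fit, INTERACTION_CONTRAST)
        assert np.isfinite(mod.attrs["d0"])
        d0, s0_2 = mod.attrs["d0"], mod.attrs["s0_2"]
        s2 = fit.sigma**2
        s2_post = (d0 * s0_2 + fit.df_resid * s2) / (d0 + fit.df_resid)
        lo = np.minimum(s2, s0_2) - 1e-12
        hi = np.maximum(s2, s0_2) + 1e-12
        assert ((s2_post >= lo) & (s2_post <= hi)).all()

    def test_all_zero_variances_is_degenerate(self):
        samples, X = design_8x4()
        y = pd.DataFrame(np.tile([1.0, 1, 2, 2, 3, 3, 4, 4], (15, 1)), columns=X.index)
        w = pd.DataFrame(1.0, index=y.index, columns=y.columns)
        fit = fit_weighted_lm(y, w, X)
        with pytest.raises(ModelError, match="zero"):
            ebayes_moderate(fit, INTERACTION_CONTRAST)

    def test_contrast_length_checked(self):
        fit, _ = self._fit()
        with pytest.raises(ValueError, match="contrast"):
            ebayes_moderate(fit, np.array([1.0, -1.0]))

    def test_variance_prior_recovers_known_hyperparameters(self):
        """Variances drawn from s0^2 * d0 / chi2(d0) scaled by chi2 sampling
        noise: the moment estimator lands near the truth."""
        rng = np.random.default_rng(8)
        d0_true, s0_true, df = 8.0, 1.5, 4
        g = 20000
        s2_true = s0_true * d0_true / rng.chisquare(d0_true, size=g)
        s2_obs = s2_true * rng.chisquare(df, size=g) / df
        d0, s0_2 = fit_variance_prior(s2_obs, df)
        assert abs(d0 - d0_true) / d0_true < 0.15
        assert abs(s0_2 - s0_true) / s0_true < 0.1


class TestBH:
    def test_hand_evaluated_step_up(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_p_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_matches_textbook_recursion(self, rng):
        p = rng.uniform(size=200)
        assert np.allclose(bh_adjust(p), bh_step_up(list(p)))


class TestRanking:
    @staticmethod
    def results(rows):
        df = pd.DataFrame(rows, columns=["logFC_E", "logFC_C", "fdr"])
        df.index = [f"g{i}" for i in range(len(df))]
        return df

    def test_score_arithmetic_orders_candidates(self):
        res = self.results([[5.0, 0.0, 0.01], [2.0, 1.5, 0.01]])
        ranked = rank_candidates(res)
        assert ranked["gene_id"].tolist() == ["g0", "g1"]
        assert ranked["score"].tolist() == [5.0, 0.5]

    def test_absolute_values_used(self):
        res = self.results([[-6.0, 0.0, 0.01]])
        assert rank_candidates(res)["score"].iloc[0] == 6.0

    def test_only_significant_genes_ranked(self):
        res = self.results([[5.0, 0.0, 0.01], [9.0, 0.0, 0.5]])
        ranked = rank_candidates(res)
        assert ranked["gene_id"].tolist() == ["g0"]

    def test_empty_when_nothing_significant(self):
        res = self.results([[5.0, 0.0, 0.9]])
        assert rank_candidates(res).empty

    def test_ties_break_on_fdr_then_gene_id(self):
        res = self.results([[3.0, 0.0, 0.02], [3.0, 0.0, 0.01], [3.0, 0.0, 0.02]])
        ranked = rank_candidates(res)
        assert ranked["gene_id"].tolist() == ["g1", "g0", "g2"]


class TestPipelineProperties:
    def test_species_offset_invariance(self, small_joined):
        """Adding a gene-wise constant to all emu samples shifts logFC_E and
        logFC_C not at all — the interaction estimate is bias-immune."""
        joined, samples, _ = small_joined
        X = make_group_design(samples)
        y, lib = log_cpm(joined)
        w = pd.DataFrame(1.0, index=y.index, columns=y.columns)
        emu_cols = [s for s in samples["sample"] if s.startswith("E")]

        fit = fit_weighted_lm(y, w, X)
        est = fit.coefficients.to_numpy() @ INTERACTION_CONTRAST

        y_shift = y.copy()
        y_shift[emu_cols] += 3.7
        fit2 = fit_weighted_lm(y_shift, w, X)
        est2 = fit2.coefficients.to_numpy() @ INTERACTION_CONTRAST
        assert np.max(np.abs(est - est2)) < 1e-10

    def test_count_scaling_preserves_interaction_signs(self):
        """Scaling every count by an integer k leaves the sign of each
        interaction estimate unchanged at near-zero dispersion."""
        cfg = SimConfig(
            n_genes=300, seed=9, dispersion=1e-6, baseline_log2_mean=(8.0, 1.0)
        )
        joined, samples, _ = make_joined(cfg)
        joined = joined[joined.min(axis=1) > 20]
        res1, _ = run_interaction_de(joined, samples)
        res2, _ = run_interaction_de(joined * 3, samples)
        big = res1["interaction_logFC"].abs() > 0.2
        assert (
            np.sign(res1.loc[big, "interaction_logFC"])
            == np.sign(res2.loc[big, "interaction_logFC"])
        ).all()

    def test_run_interaction_de_outputs_are_consistent(self, small_joined):
        joined, samples, _ = small_joined
        res, info = run_interaction_de(joined, samples)
        assert np.allclose(
            res["interaction_logFC"], res["logFC_E"] - res["logFC_C"], atol=1e-12
        )
        assert res["p_value"].between(0, 1).all()
        assert res["fdr"].between(0, 1).all()
        assert info["n_genes_tested"] == len(joined)
        ranked = res[res["rank"].notna()].sort_values("rank")
        assert (ranked["fdr"] < 0.05).all()
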