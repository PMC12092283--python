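"""Differential expression: filtering, OLS fits, contrasts, moderation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from graftdd import dge, synthdata as sd
from graftdd.containers import DegenerateInputError, ExpressionMatrix
from graftdd.dge import CELLS, EbayesHyper
from conftest import toy_meta


def make_em(values, meta=None):
    meta = toy_meta(n_per_arm=2) if meta is None else meta
    df = pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))], columns=meta.index)
    return ExpressionMatrix(df, meta)


class TestIqrFilter:
    def test_varying_gene_beats_constant_gene(self):
        em = make_em([np.ones(12), np.arange(12.0)])
        kept = dge.iqr_filter(em, 1)
        assert kept.values.index.tolist() == ["g1"]

    def test_keep_all_is_identity(self, trial):
        assert dge.iqr_filter(trial, trial.values.shape[0]).values.equals(trial.values)

    def test_three_gene_toy_hand_computed_iqrs(self):
        # IQRs across 12 samples: g0 0.55, g1 2.2, g2 1.1 (linear-interp quantiles)
        base = np.arange(12.0) / 10.0
        em = make_em([base * 0.5, base * 2.0, base])
        kept = dge.iqr_filter(em, 2)
        assert kept.values.index.tolist() == ["g1", "g2"]

    def test_fraction_and_bad_keep(self, trial):
        frac = dge.iqr_filter(trial, 0.1)
        assert frac.values.shape[0] == round(0.1 * trial.values.shape[0])
        with pytest.raises(ValueError):
            dge.iqr_filter(trial, 0)
        with pytest.raises(ValueError):
            dge.iqr_filter(trial, 10**6)


class TestBaselineFlags:
    def test_identical_baselines_give_no_flags(self):
        meta = toy_meta(n_per_arm=3)
        rng = np.random.default_rng(0)
        vals = rng.normal(8, 1, size=(5, len(meta)))
        em = make_em(vals, meta)
        base_cols = meta.index[meta["visit"] == "baseline"]
        pl = base_cols[:3]
        fz = base_cols[3:]
        em.values[fz] = em.values[pl].to_numpy()  # identical multisets per arm
        assert not dge.baseline_imbalance_flags(em).any()

    def test_planted_arm_shift_is_flagged(self):
        meta = toy_meta(n_per_arm=5)
        rng = np.random.default_rng(1)
        vals = rng.normal(8, 0.1, size=(3, len(meta)))
        em = make_em(vals, meta)
        fz_base = meta.index[(meta["visit"] == "baseline") & (meta["arm"] == "felzartamab")]
        em.values.loc["g0", fz_base] += 3.0
        flags = dge.baseline_imbalance_flags(em)
        assert flags["g0"] and not flags["g1"]

    def test_null_flag_rate_close_to_alpha(self):
        rates = []
        for seed in range(20):
            truth = sd.make_truth(500, seed=seed, ddfc={}, slopes={})
            trial = sd.generate_trial(sd.TrialDesign(), truth, seed=300 + seed)
            rates.append(dge.baseline_imbalance_flags(trial).mean())
        assert 0.03 < np.mean(rates) < 0.07

    def test_missing_baseline_arm_rejected(self, trial):
        keep = trial.meta.index[~((trial.meta["visit"] == "baseline") & (trial.meta["arm"] == "placebo"))]
        em = ExpressionMatrix(trial.values[keep], trial.meta.loc[keep])
        with pytest.raises(ValueError):
            dge.baseline_imbalance_flags(em)


class TestGeneFits:
    def test_noise_free_coefficients_recovered(self):
        meta = toy_meta(n_per_arm=3)
        rng = np.random.default_rng(5)
        meta["pct_cortex"] = rng.uniform(40, 100, len(meta))
        cell_means = {c: rng.normal(8, 1) for c in CELLS}
        slope = 0.02
        cortex_c = meta["pct_cortex"] - meta["pct_cortex"].mean()
        y = np.array(
            [cell_means[f"{row['arm']}.{row['visit']}"] + slope * cortex_c[sid] for sid, row in meta.iterrows()]
        )
        em = make_em([y], meta)
        fit = dge.fit_gene_models(em)
        for c in CELLS:
            assert fit.cell_coefs.loc["g0", c] == pytest.approx(cell_means[c], abs=1e-10)
        assert fit.cortex_coef["g0"] == pytest.approx(slope, abs=1e-10)

    def test_sample_permutation_invariance(self, trial):
        fit_a = dge.fit_gene_models(trial)
        perm = trial.values.columns[::-1]
        fit_b = dge.fit_gene_models(ExpressionMatrix(trial.values[perm], trial.meta.loc[perm]))
        assert np.allclose(fit_a.cell_coefs.to_numpy(), fit_b.cell_coefs.to_numpy(), atol=1e-9)
        assert np.allclose(fit_a.s2.to_numpy(), fit_b.s2.to_numpy(), atol=1e-9)

    def test_residual_df_is_53_on_full_design(self, trial):
        assert dge.fit_gene_models(trial).df_resid == 60 - 7

    def test_confounded_design_rejected(self, trial):
        meta = trial.meta.copy()
        meta["pct_cortex"] = 70.0  # constant cortex is collinear with the cell means
        with pytest.raises(ValueError, match="rank deficient"):
            dge.fit_gene_models(ExpressionMatrix(trial.values, meta))


class TestContrasts:
    def test_window_arithmetic(self):
        meta = toy_meta(n_per_arm=2)
        vals = np.zeros((1, len(meta)))
        em = make_em(vals, meta)
        fz_w24 = meta.index[(meta["arm"] == "felzartamab") & (meta["visit"] == "week24")]
        fz_w52 = meta.index[(meta["arm"] == "felzartamab") & (meta["visit"] == "week52")]
        em.values.loc["g0", fz_w24] = -1.0
        em.values.loc["g0", fz_w52] = -1.0
        fit = dge.fit_gene_models(em)
        assert dge.delta_delta_contrasts(fit, "b_w24")["g0"] == pytest.approx(-0.5, abs=1e-10)
        assert dge.delta_delta_contrasts(fit, "w24_w52")["g0"] == pytest.approx(0.0, abs=1e-10)
        assert dge.delta_delta_contrasts(fit, "b_w24", scale=1.0)["g0"] == pytest.approx(-1.0, abs=1e-10)

    def test_equal_change_both_arms_gives_zero(self):
        meta = toy_meta(n_per_arm=2)
        em = make_em(np.zeros((1, len(meta))), meta)
        w24 = meta.index[meta["visit"] == "week24"]
        em.values.loc["g0", w24] = 2.0
        fit = dge.fit_gene_models(em)
        assert dge.delta_delta_contrasts(fit, "b_w24")["g0"] == pytest.approx(0.0, abs=1e-12)

    def test_windows_telescope(self, trial):
        fit = dge.fit_gene_models(trial)
        total = dge.delta_delta_contrasts(fit, "b_w52")
        parts = dge.delta_delta_contrasts(fit, "b_w24") + dge.delta_delta_contrasts(fit, "w24_w52")
        assert np.allclose(total.to_numpy(), parts.to_numpy(), atol=1e-12)

    def test_unknown_window_rejected(self, trial):
        fit = dge.fit_gene_models(trial)
        with pytest.raises(ValueError):
            dge.delta_delta_contrasts(fit, "w12")


class TestEbayes:
    def _fit_from_s2(self, s2, d=16):
        genes = [f"g{i}" for i in range(len(s2))]
        return dge.GeneFit(
            cell_coefs=pd.DataFrame(0.0, index=genes, columns=CELLS),
            cortex_coef=pd.Series(0.0, index=genes),
            s2=pd.Series(s2, index=genes),
            df_resid=d,
            xtx_inv=np.eye(7),
        )

    def test_chi_square_variances_give_large_prior_df(self):
        """s² drawn from a pure χ² sampling distribution (d0 = ∞ truth):
        estimated prior df is large in most runs."""
        rng = np.random.default_rng(0)
        d = 16
        big = 0
        for _ in range(20):
            s2 = 0.3 * rng.chisquare(d, size=2000) / d
            hyper = dge.estimate_ebayes_hyper(self._fit_from_s2(s2, d))
            big += hyper.d0 > 50
        assert big / 20 >= 0.9

    def test_scaled_inverse_chi_square_recovery(self):
        """True hyperparameters d0=4, s0²=0.05 recovered within 25% in median
        over repeated simulations."""
        rng = np.random.default_rng(1)
        d = 16
        d0s, s0s = [], []
        for _ in range(100):
            true_var = 4.0 * 0.05 / rng.chisquare(4.0, size=1500)
            s2 = true_var * rng.chisquare(d, size=1500) / d
            hyper = dge.estimate_ebayes_hyper(self._fit_from_s2(s2, d))
            d0s.append(hyper.d0)
            s0s.append(hyper.s0_sq)
        assert abs(np.median(d0s) - 4.0) / 4.0 < 0.25
        assert abs(np.median(s0s) - 0.05) / 0.05 < 0.25

    def test_duplicated_genes_same_hyperparameters(self, trial):
        fit = dge.fit_gene_models(trial)
        dup = self._fit_from_s2(np.tile(fit.s2.to_numpy(), 2), fit.df_resid)
        a = dge.estimate_ebayes_hyper(fit)
        b = dge.estimate_ebayes_hyper(dup)
        assert a.d0 == pytest.approx(b.d0, rel=1e-6) or (np.isinf(a.d0) and np.isinf(b.d0))
        assert a.s0_sq == pytest.approx(b.s0_sq, rel=1e-6)

    def test_all_zero_variances_degenerate(self):
        with pytest.raises(DegenerateInputError):
            dge.estimate_ebayes_hyper(self._fit_from_s2(np.zeros(50)))


class TestModeratedTests:
    def test_zero_prior_df_equals_ordinary_t(self, trial):
        fit = dge.fit_gene_models(trial)
        tab = dge.moderated_tests(fit, EbayesHyper(d0=0.0, s0_sq=1.0), "b_w24")
        c = dge._window_contrast_vector("b_w24", 0.5)
        v = float(c @ fit.xtx_inv @ c)
        ddfc = dge.delta_delta_contrasts(fit, "b_w24")
        t_ord = ddfc / np.sqrt(fit.s2 * v)
        assert np.allclose(tab["t"].to_numpy(), t_ord.to_numpy(), atol=1e-10)

    def test_infinite_prior_df_uses_prior_variance_and_normal(self, trial):
        fit = dge.fit_gene_models(trial)
        tab = dge.moderated_tests(fit, EbayesHyper(d0=np.inf, s0_sq=0.25), "b_w24")
        c = dge._window_contrast_vector("b_w24", 0.5)
        v = float(c @ fit.xtx_inv @ c)
        ddfc = dge.delta_delta_contrasts(fit, "b_w24")
        expect_t = ddfc / np.sqrt(0.25 * v)
        assert np.allclose(tab["t"].to_numpy(), expect_t.to_numpy(), atol=1e-10)
        assert np.allclose(tab["p"], 2 * stats.norm.sf(np.abs(tab["t"])), atol=1e-12)

    def test_three_gene_toy_matches_hand_shrinkage(self):
        """t̃ = ΔΔ/(s̃·√v) with s̃² = (d0·s0² + d·s²)/(d0+d), hand-checked."""
        meta = toy_meta(n_per_arm=2)
        em = make_em(np.zeros((10, len(meta))), meta)
        fz_w24 = meta.index[(meta["arm"] == "felzartamab") & (meta["visit"] == "week24")]
        em.values.loc["g0", fz_w24] = -1.0
        fit = dge.fit_gene_models(em)
        fit.s2.loc[:] = [0.1, 0.4, 0.9, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2, 0.2]
        d0, s0 = 4.0, 0.25
        tab = dge.moderated_tests(fit, EbayesHyper(d0=d0, s0_sq=s0), "b_w24")
        c = dge._window_contrast_vector("b_w24", 0.5)
        v = float(c @ fit.xtx_inv @ c)
        d = fit.df_resid
        for g, s2 in [("g0", 0.1), ("g1", 0.4), ("g2", 0.9)]:
            s2_post = (d0 * s0 + d * s2) / (d0 + d)
            expect = fit.cell_coefs.loc[g] @ c[:6] / np.sqrt(s2_post * v)
            assert tab.loc[g, "t"] == pytest.approx(expect, abs=1e-12)

    def test_shrinkage_monotonicity(self, trial):
        """s̃² lies between s² and s0²; moderation boosts |t| exactly when the
        gene variance exceeds the prior."""
        fit = dge.fit_gene_models(trial)
        hyper = dge.estimate_ebayes_hyper(fit)
        tab = dge.moderated_tests(fit, hyper, "b_w24")
        tab0 = dge.moderated_tests(fit, EbayesHyper(d0=0.0, s0_sq=1.0), "b_w24")
        s2 = fit.s2.to_numpy()
        if np.isfinite(hyper.d0):
            s2_post = (hyper.d0 * hyper.s0_sq + fit.df_resid * s2) / (hyper.d0 + fit.df_resid)
            lo = np.minimum(s2, hyper.s0_sq) - 1e-12
            hi = np.maximum(s2, hyper.s0_sq) + 1e-12
            assert np.all((s2_post >= lo) & (s2_post <= hi))
        gain = np.abs(tab["t"].to_numpy()) >= np.abs(tab0["t"].to_numpy()) - 1e-12
        assert np.array_equal(gain, s2 >= hyper.s0_sq - 1e-12)

    def test_rank_is_a_permutation_and_fdr_dominates_p(self, trial):
        out = dge.run_dge(trial)
        tab = out["tables"]["b_w24"]
        assert sorted(tab["rank"]) == list(range(1, len(tab) + 1))
        assert (tab["FDR"] >= tab["p"] - 1e-12).all()


class TestRankGenes:
    def test_planted_genes_dominate_top_twenty(self, trial, default_truth):
        out = dge.run_dge(trial)
        top = dge.rank_genes(out["tables"]["b_w24"], 20)
        planted = set(default_truth.planted_sets["ifng_activity"]) | set(default_truth.planted_sets["nk_activity"])
        assert len([g for g in top.index if g in planted]) / 20 >= 0.8

    def test_flagged_genes_excluded_and_k_overflow(self, trial):
        out = dge.run_dge(trial)
        tab = out["tables"]["b_w24"].copy()
        tab.iloc[0, tab.columns.get_loc("baseline_imbalance_flag")] = True
        rep = dge.rank_genes(tab, 10**6)
        assert tab.index[0] not in rep.index
        assert len(rep) == (~tab["baseline_imbalance_flag"]).sum()

    def test_direction_filter(self, trial):
        out = dge.run_dge(trial)
        up = dge.rank_genes(out["tables"]["b_w24"], 10, direction="up")
        assert (up["ddfc"] > 0).all()


class TestRecoveryAndCalibration:
    def test_planted_ddfc_recovered_with_small_bias(self):
        """Planted −1.0 log2 week-24 effects: mean estimated half-scaled
        contrast within 5% of −0.5 over seeds, correct sign."""
        ests = []
        for seed in range(10):
            truth = sd.make_truth(400, seed=seed)
            trial = sd.generate_trial(sd.TrialDesign(), truth, seed=700 + seed)
            fit = dge.fit_gene_models(trial)
            dd = dge.delta_delta_contrasts(fit, "b_w24")
            planted = truth.planted_sets["ifng_activity"] + truth.planted_sets["nk_activity"]
            ests.append(dd.loc[planted].mean())
        mean_est = np.mean(ests)
        assert mean_est < 0
        assert abs(mean_est - (-0.5)) < 0.05 * 1.0

    def test_null_moderated_p_approximately_uniform(self):
        ps = []
        for seed in range(3):
            truth = sd.make_truth(800, seed=seed, ddfc={}, slopes={}, patient_sd=0.0)
            trial = sd.generate_trial(sd.TrialDesign(), truth, seed=40 + seed)
            out = dge.run_dge(trial)
            ps.append(out["tables"]["b_w24"]["p"].to_numpy())
        D = stats.kstest(np.concatenate(ps), "uniform").statistic
        assert D < 0.05
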