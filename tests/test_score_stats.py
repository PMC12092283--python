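"""Score-level inference: PERMANOVA, aligned-rank ANOVA, contrasts, slopes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from graftdd import score_stats as ss, synthdata as sd
from graftdd.containers import DegenerateInputError, ScoreTable
from conftest import toy_meta


def brute_force_bh(p):
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    prev = 1.0
    for rank_pos in range(m, 0, -1):
        i = order[rank_pos - 1]
        prev = min(prev, p[i] * m / rank_pos)
        q[i] = prev
    return np.minimum(q, 1.0)


class TestBhFdr:
    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_matches_brute_force_definition(self, p):
        assert np.allclose(ss.bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_worked_example(self):
        assert np.allclose(ss.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_and_all_ones(self):
        assert ss.bh_fdr([0.3])[0] == pytest.approx(0.3)
        assert np.allclose(ss.bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            ss.bh_fdr([0.5, 1.5])


class TestPermanova:
    def test_univariate_pseudo_f_equals_anova_f(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        labels = np.repeat(["a", "b"], 15)
        res = ss.omnibus_permanova(pd.DataFrame({"s": x}), labels, n_perm=99, seed=0)
        f_classic = stats.f_oneway(x[:15], x[15:]).statistic
        assert res.pseudo_f == pytest.approx(f_classic, abs=1e-10)

    def test_identical_group_multisets_give_p_one(self):
        block = np.array([[1.0, 2.0], [3.0, 4.0], [5.0, 0.0]])
        X = np.vstack([block, block])
        labels = np.repeat(["a", "b"], 3)
        res = ss.omnibus_permanova(pd.DataFrame(X), labels, n_perm=99, seed=1)
        assert res.pseudo_f == pytest.approx(0.0, abs=1e-10)
        assert res.p == 1.0

    def test_null_p_values_approximately_uniform(self):
        """Permuted labels give a uniform permutation p over replicates."""
        rng = np.random.default_rng(7)
        ps = []
        for rep in range(200):
            X = rng.normal(size=(20, 2))
            labels = rng.permutation(np.repeat(["a", "b"], 10))
            ps.append(ss.omnibus_permanova(pd.DataFrame(X), labels, n_perm=99, seed=rep).p)
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_constant_matrix_degenerate(self):
        with pytest.raises(DegenerateInputError):
            ss.omnibus_permanova(pd.DataFrame(np.ones((10, 2))), np.repeat(["a", "b"], 5), n_perm=99)

    def test_restricted_permutation_respects_patient_blocks(self, score_table):
        labels = score_table.meta["arm"].to_numpy()
        strata = score_table.meta["patient_id"].to_numpy()
        res = ss.omnibus_permanova(score_table.scores, labels, n_perm=199, seed=5, strata=strata)
        assert 0 < res.p <= 1
        with pytest.raises(ValueError, match="strata"):
            visit_labels = score_table.meta["visit"].to_numpy()
            ss.omnibus_permanova(score_table.scores, visit_labels, n_perm=99, seed=0, strata=strata)

    def test_seeded_determinism_and_p_floor(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(16, 3)))
        labels = np.repeat(["a", "b"], 8)
        a = ss.omnibus_permanova(X, labels, n_perm=199, seed=9)
        b = ss.omnibus_permanova(X, labels, n_perm=199, seed=9)
        assert a.p == b.p
        assert a.p >= 1.0 / 200


class TestArtTransform:
    def test_single_factor_alignment_is_grand_mean_residual(self):
        df = pd.DataFrame({"y": [1.0, 4.0, 2.0, 8.0], "f": ["a", "a", "b", "b"]})
        aligned, ranked = ss.art_transform(df, "y", ["f"], "f")
        assert np.allclose(aligned, df["y"] - df["y"].mean())
        assert np.array_equal(ranked.to_numpy(), stats.rankdata(df["y"]))

    def test_constant_response_all_ranks_tied(self):
        df = pd.DataFrame({"y": 2.0, "f": ["a", "a", "b", "b"]})
        aligned, ranked = ss.art_transform(df, "y", ["f"], "f")
        assert np.allclose(aligned, 0.0)
        assert np.allclose(ranked, (len(df) + 1) / 2)

    def test_two_by_two_matches_brute_force_alignment(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(
            {
                "y": rng.normal(size=12),
                "A": np.repeat(["a1", "a2"], 6),
                "B": np.tile(np.repeat(["b1", "b2"], 3), 2),
            }
        )
        cell = df.groupby(["A", "B"])["y"].transform("mean")
        marg_a = df.groupby("A")["y"].transform("mean")
        marg_b = df.groupby("B")["y"].transform("mean")
        grand = df["y"].mean()
        expect = df["y"] - marg_a - marg_b + grand  # residual + interaction estimate
        aligned, _ = ss.art_transform(df, "y", ["A", "B"], "A:B")
        assert np.allclose(aligned, expect, atol=1e-12)
        expect_a = (df["y"] - cell) + (marg_a - grand)
        aligned_a, _ = ss.art_transform(df, "y", ["A", "B"], "A")
        assert np.allclose(aligned_a, expect_a, atol=1e-12)

    def test_empty_cells_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0], "A": ["a", "a", "b"], "B": ["x", "y", "x"]})
        with pytest.raises(ValueError, match="cells"):
            ss.art_transform(df, "y", ["A", "B"], "A:B")


class TestSplitPlotAnova:
    def test_matches_pingouin_mixed_anova(self):
        pg = pytest.importorskip("pingouin")
        d = sd.simulate_null_scores(n_per_arm=6, seed=42).reset_index()
        mine = ss._split_plot_anova(d, "score", "arm", "visit", "patient_id")
        theirs = pg.mixed_anova(data=d, dv="score", within="visit", between="arm", subject="patient_id")
        lut = {"arm": "arm", "visit": "visit", "Interaction": "arm:visit"}
        for _, row in theirs.iterrows():
            mine_row = mine.loc[lut[row["Source"]]]
            assert mine_row["F"] == pytest.approx(row["F"], rel=1e-8)
            assert mine_row["p"] == pytest.approx(row["p_unc"], rel=1e-6)

    def test_unbalanced_design_rejected(self):
        d = sd.simulate_null_scores(n_per_arm=4, seed=0).reset_index()
        with pytest.raises(ValueError, match="nbalanced|ncomplete"):
            ss._split_plot_anova(d.iloc[:-1], "score", "arm", "visit", "patient_id")


class TestArtAnova:
    def test_invariance_under_affine_transform(self):
        """Alignment uses cell means, so any positive affine rescaling of the
        response leaves every ART statistic unchanged (nonlinear monotone
        maps change the alignment itself and are not expected to)."""
        d = sd.simulate_null_scores(seed=8)
        a = ss.art_anova(d).anova
        d2 = d.copy()
        d2["score"] = 3.5 * d2["score"] + 11.0
        b = ss.art_anova(d2).anova
        assert np.allclose(a["F"], b["F"], atol=1e-10)

    def test_constant_response_degenerate(self):
        d = sd.simulate_null_scores(seed=8)
        d["score"] = 1.0
        with pytest.raises(DegenerateInputError):
            ss.art_anova(d)

    def test_power_against_planted_interaction(self):
        """A −1.0 score-unit week-24 suppression in the treated arm is
        detected in >= 80% of simulations at alpha 0.05."""
        hits = 0
        n = 200
        for seed in range(n):
            d = sd.simulate_null_scores(seed=10_000 + seed, interaction={("felzartamab", "week24"): -1.0})
            r = ss.art_anova(d, effects=("arm:visit",))
            hits += r.anova.loc["arm:visit", "p"] < 0.05
        assert hits / n >= 0.8


class TestInteractionContrasts:
    def test_fifteen_pairs_plus_three_primary_windows(self, score_table):
        res = ss.art_anova(score_table.long("ifng_activity"))
        tab = ss.interaction_contrasts(res)
        assert (tab["kind"] == "cell_pair").sum() == 15
        assert (tab["kind"] == "dd_window").sum() == 3
        assert tab.loc[tab["primary"], "kind"].eq("dd_window").all()

    def test_fdr_at_least_p(self, score_table):
        res = ss.art_anova(score_table.long("nk_activity"))
        tab = ss.interaction_contrasts(res)
        assert (tab["FDR"] >= tab["p"] - 1e-12).all()

    def test_symmetric_opposite_effects_double_the_window_contrast(self):
        d = sd.simulate_null_scores(
            patient_sd=0.2,
            resid_sd=0.05,
            seed=3,
            interaction={("felzartamab", "week24"): -1.0, ("placebo", "week24"): 1.0},
        )
        res = ss.art_anova(d)
        tab = ss.interaction_contrasts(res).set_index("pair")
        dd = abs(tab.loc["dd_b_w24", "estimate"])
        single = abs(tab.loc["felzartamab.baseline - felzartamab.week24", "estimate"])
        assert dd == pytest.approx(2 * single, rel=0.15)


class TestMixedSlopes:
    def _table(self, slopes, noise_sd=0.0, n_per_arm=5, seed=0):
        meta = toy_meta(n_per_arm=n_per_arm)
        rng = np.random.default_rng(seed)
        weeks = {"baseline": 0.0, "week24": 24.0, "week52": 52.0}
        intercepts = {p: 0.1 * i for i, p in enumerate(meta["patient_id"].unique())}
        vals = []
        for sid, row in meta.iterrows():
            y = intercepts[row["patient_id"]] + slopes[row["arm"]] * weeks[row["visit"]]
            vals.append(y + rng.normal(0, noise_sd))
        return ScoreTable(pd.DataFrame({"s": vals}, index=meta.index), meta)

    def test_noise_free_slopes_recovered_exactly(self):
        table = self._table({"placebo": 0.01, "felzartamab": -0.01})
        fit = ss.fit_mixed_slopes(table, "s")
        assert fit.slopes.loc["placebo", "slope"] == pytest.approx(0.01, abs=1e-8)
        assert fit.slopes.loc["felzartamab", "slope"] == pytest.approx(-0.01, abs=1e-8)

    def test_variance_components_nonnegative_and_ci_contains_estimate(self, score_table):
        fit = ss.fit_mixed_slopes(score_table, "injury_up")
        re_cov = np.asarray(fit.var_components["re_cov"])
        assert np.all(np.linalg.eigvalsh(re_cov) >= -1e-8)
        assert fit.var_components["resid_var"] >= 0
        for _, row in fit.slopes.iterrows():
            assert row["ci_lo"] <= row["slope"] <= row["ci_hi"]

    def test_sign_recovery_on_generator_fixtures(self):
        """Estimated injury slopes match the planted signs (negative treated,
        positive placebo) across seeds."""
        ok = 0
        n = 30
        from graftdd import scoring

        for seed in range(n):
            truth = sd.make_truth(300, seed=seed)
            trial = sd.generate_trial(sd.TrialDesign(), truth, seed=900 + seed)
            table = scoring.assemble_score_table(trial, sd.planted_library(truth))
            fit = ss.fit_mixed_slopes(table, "injury_up")
            ok += (fit.slopes.loc["felzartamab", "slope"] < 0) and (fit.slopes.loc["placebo", "slope"] > 0)
        assert ok / n >= 0.95

    def test_prediction_band_contains_fit(self, score_table):
        fit = ss.fit_mixed_slopes(score_table, "injury_down")
        traj = fit.predict()
        assert ((traj["lo"] <= traj["fit"]) & (traj["fit"] <= traj["hi"])).all()

    def test_single_timepoint_rejected(self, score_table):
        sub = score_table.meta[score_table.meta["visit"] == "baseline"]
        table = ScoreTable(score_table.scores.loc[sub.index], sub)
        with pytest.raises(ValueError):
            ss.fit_mixed_slopes(table, "injury_up")
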