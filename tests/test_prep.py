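import numpy as np
import pandas as pd
import pytest

from selfrag.prep import (DegenerateFitWarning, fit_lmm, fit_random_intercept,
                          illusion_scores, ownership_reduction,
                          residualize_ratings)
from selfrag.synthio import SynthConfig, generate_study, ground_truth
from _oracles import reml_dense


def _toy_table(values, traits, pid="p1"):
    return pd.DataFrame({
        "participant_id": pid, "dyad_id": "d1", "target": "self",
        "condition": "syncSelf", "trait_id": traits,
        "rating": pd.array(values, dtype="Int64"),
        "reaction_time_s": 1.0,
    })


class TestRandomIntercept:
    def test_identical_group_means_give_zero_between_variance(self):
        fit = fit_random_intercept([1, 2, 3, 1, 2, 3], list("aaabbb"))
        assert fit.var_between == pytest.approx(0.0, abs=1e-6)
        assert all(abs(u) < 1e-4 for u in fit.group_effects.values())
        assert fit.grand_mean == pytest.approx(2.0)

    def test_reml_matches_dense_grid_oracle_two_groups(self):
        values = [1, 2, 3, 7, 8, 9]
        groups = list("aaabbb")
        fit = fit_random_intercept(values, groups)
        oracle = reml_dense(values, np.ones((6, 1)), groups)
        assert fit.var_between == pytest.approx(oracle["var_between"], abs=1e-4)
        assert fit.var_within == pytest.approx(oracle["var_within"], abs=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_reml_matches_dense_grid_oracle_random(self, seed):
        rng = np.random.default_rng(seed)
        groups = np.repeat(list("abcde"), 5)
        values = rng.normal(0, 1, 25) + np.repeat(rng.normal(0, 1.5, 5), 5)
        fit = fit_random_intercept(values, groups)
        oracle = reml_dense(values, np.ones((25, 1)), groups)
        assert fit.var_between == pytest.approx(oracle["var_between"], abs=1e-4)
        assert fit.var_within == pytest.approx(oracle["var_within"], abs=1e-4)

    def test_matches_statsmodels_mixedlm(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        groups = np.repeat(np.arange(8), 6)
        y = rng.normal(5, 1, 48) + np.repeat(rng.normal(0, 0.8, 8), 6)
        fit = fit_random_intercept(y, groups)
        sm_fit = sm.MixedLM(y, np.ones((48, 1)), groups=groups).fit(reml=True)
        assert fit.grand_mean == pytest.approx(sm_fit.params[0], abs=1e-4)
        # statsmodels' default convergence is looser than the grid-refined
        # profile likelihood; agreement to a few percent is the cross-check
        assert fit.var_between == pytest.approx(
            float(np.asarray(sm_fit.cov_re)[0, 0]), rel=0.05)
        assert fit.var_within == pytest.approx(sm_fit.scale, rel=0.05)

    def test_single_observation_groups_shrink_strictly(self):
        fit = fit_random_intercept([1.0, 2.0, 5.0, 9.0], list("abcd"))
        for g, val in zip("abcd", [1.0, 2.0, 5.0, 9.0]):
            raw = val - fit.grand_mean
            if raw != 0:
                assert abs(fit.group_effects[g]) < abs(raw)

    def test_degenerate_constant_values_signalled(self):
        with pytest.warns(DegenerateFitWarning):
            fit = fit_random_intercept([4.0] * 6, list("aabbcc"))
        assert fit.degenerate

    def test_fixed_covariates_match_dense_oracle(self):
        rng = np.random.default_rng(9)
        groups = np.repeat(np.arange(5), 4)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = X @ [2.0, 0.7] + np.repeat(rng.normal(0, 1.0, 5), 4) \
            + rng.normal(0, 0.5, 20)
        fit = fit_lmm(y, X, groups, coef_names=["int", "slope"])
        oracle = reml_dense(y, X, groups)
        assert fit.beta == pytest.approx(oracle["beta"], abs=1e-5)
        assert fit.var_between == pytest.approx(oracle["var_between"], abs=1e-4)
        assert fit.var_within == pytest.approx(oracle["var_within"], abs=1e-4)


class TestResidualize:
    def test_flat_traits_residuals_are_deviations_from_grand_mean(self):
        t = _toy_table([5, 5, 5, 5, 5, 5], list("abcabc"))
        out = residualize_ratings(t)
        assert np.allclose(out["residual"], 0.0, atol=1e-8)

    def test_shifting_one_trait_moves_its_blup_only(self):
        # with many traits, boosting one barely moves the variance ratio,
        # so other traits' residuals shift (almost) only via the grand mean
        rng = np.random.default_rng(1)
        n_traits, reps = 40, 5
        traits = [f"t{i % n_traits}" for i in range(n_traits * reps)]
        eff = rng.normal(0, 1.2, n_traits)[np.arange(n_traits * reps) % n_traits]
        vals = np.clip(np.round(5 + eff + rng.normal(0, 0.8, n_traits * reps)),
                       1, 9).astype(int)
        base = residualize_ratings(_toy_table(vals, traits))
        shifted_vals = np.clip(vals + 1 * (np.array(traits) == "t0"), 1, 9)
        shifted = residualize_ratings(_toy_table(shifted_vals, traits))
        fit0 = base.attrs["fit"]
        fit1 = shifted.attrs["fit"]
        assert fit1.group_effects["t0"] > fit0.group_effects["t0"]
        other = np.array(traits) != "t0"
        d = (shifted["residual"].to_numpy()[other]
             - base["residual"].to_numpy()[other])
        assert np.ptp(d) < 0.05  # small against the 1-point planted shift

    def test_relabeling_traits_leaves_residuals_unchanged(self, study7):
        rated = study7.ratings[study7.ratings["rating"].notna()].head(2000)
        out1 = residualize_ratings(rated)
        relabeled = rated.copy()
        relabeled["trait_id"] = "x_" + relabeled["trait_id"]
        out2 = residualize_ratings(relabeled)
        assert np.allclose(out1["residual"].to_numpy(),
                           out2["residual"].to_numpy(), atol=1e-10)

    def test_constant_shift_absorbed_by_grand_mean(self):
        rng = np.random.default_rng(4)
        groups = np.repeat(list("abcdef"), 5)
        y = rng.normal(5, 1, 30) + np.repeat(rng.normal(0, 1, 6), 5)
        f0 = fit_random_intercept(y, groups)
        f1 = fit_random_intercept(y + 3.0, groups)
        assert f1.grand_mean == pytest.approx(f0.grand_mean + 3.0, abs=1e-6)
        for g in "abcdef":
            assert f1.group_effects[g] == pytest.approx(f0.group_effects[g],
                                                        abs=1e-6)

    def test_recovers_planted_trait_baselines(self, study7, residuals7):
        cfg = SynthConfig(seed=7)
        gt = ground_truth(cfg)
        fit = residuals7.attrs["fit"]
        blups = np.array([fit.group_effects[t] for t in gt["trait_ids"]])
        assert np.corrcoef(blups, gt["baselines"])[0, 1] > 0.9

    def test_too_few_traits_rejected(self):
        with pytest.raises(ValueError):
            residualize_ratings(_toy_table([5, 6], ["a", "a"]))


class TestQuestionnaires:
    def _qs(self, rows):
        return pd.DataFrame(rows, columns=["participant_id", "condition",
                                           "statement_id", "rating"])

    def test_illusion_score_arithmetic(self):
        rows = ([("p1", "syncSelf", s, 0) for s in
                 ("I1", "I2", "I3", "C1", "C2", "C3", "C4")]
                + [("p2", "syncSelf", s, v) for s, v in
                   zip(("I1", "I2", "I3", "C1", "C2", "C3", "C4"),
                       (3, 3, 3, -3, -3, -3, -3))]
                + [("p3", "syncSelf", s, v) for s, v in
                   zip(("I1", "I2", "I3", "C1", "C2", "C3", "C4"),
                       (3, 2, 1, 0, -1, 1, 0))])
        out = illusion_scores(self._qs(rows)).set_index("participant_id")
        assert out.loc["p1", "illusion_score"] == 0
        assert out.loc["p2", "illusion_score"] == 6
        assert out.loc["p3", "illusion_score"] == pytest.approx(2.0)

    def test_missing_statement_flags_cell(self):
        rows = [("p1", "syncSelf", s, 1) for s in ("I1", "I2", "I3", "C1",
                                                   "C2", "C3")]
        out = illusion_scores(self._qs(rows))
        assert out["illusion_score"].isna().all()

    def test_ownership_reduction_difference(self):
        rows = [("p1", "syncSelf", "I1", 3), ("p1", "asyncSelf", "I1", -2),
                ("p2", "syncSelf", "I1", 1), ("p2", "asyncSelf", "I1", 1)]
        out = ownership_reduction(self._qs(rows))
        assert out["p1"] == 5
        assert out["p2"] == 0

    def test_ownership_reduction_matches_discretized_normal_oracle(self, study7):
        from scipy.stats import norm

        def disc_moments(mu):
            ks = np.arange(-3, 4)
            p = norm.cdf(ks + 0.5 - mu) - norm.cdf(ks - 0.5 - mu)
            p[0] = norm.cdf(-2.5 - mu)
            p[-1] = 1 - norm.cdf(2.5 - mu)
            m = (ks * p).sum()
            return m, (ks ** 2 * p).sum() - m ** 2

        m_s, v_s = disc_moments(2.0)
        m_a, v_a = disc_moments(-0.5)
        own = ownership_reduction(study7.questionnaires)
        se = np.sqrt((v_s + v_a) / len(own))
        assert abs(own.mean() - (m_s - m_a)) < 4 * se
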