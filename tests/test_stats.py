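import numpy as np
import pytest
from scipy import stats as sps

from selfrag.stats import (anova_2x2_within, jzs_bf01_correlation,
                           jzs_bf01_ttest, mediate, mixed_model, paired_t,
                           spearman, wilcoxon_signed_rank)
from _oracles import (corr_bf01_trapezoid, jzs_bf01_trapezoid, reml_dense,
                      rm_anova_ss, spearman_permutation_p, wilcoxon_enumerate)


class TestPairedT:
    def test_equal_samples_zero_variance_signalled(self):
        with pytest.raises(ValueError):
            paired_t([1, 2, 3], [1, 2, 3])

    def test_hand_computed_example(self):
        # diffs (1,2,3): mean 2, sd 1 -> t = 2*sqrt(3)
        r = paired_t([2, 4, 6], [1, 2, 3])
        assert r.t == pytest.approx(2 * np.sqrt(3), abs=1e-10)
        assert r.df == 2
        assert r.p_two_sided == pytest.approx(
            2 * sps.t.sf(2 * np.sqrt(3), 2), abs=1e-12)

    def test_matches_scipy(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=20), rng.normal(size=20)
        r = paired_t(x, y)
        ref = sps.ttest_rel(x, y)
        assert r.t == pytest.approx(ref.statistic, abs=1e-12)
        assert r.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)


class TestAnova2x2:
    def _cells(self, rng, n=20):
        return {c: rng.normal(size=n) for c in
                ("syncSelf", "asyncSelf", "syncFriend", "asyncFriend")}

    def test_identical_cells_give_zero_F(self):
        x = np.arange(10.0)
        res = anova_2x2_within({c: x for c in
                                ("syncSelf", "asyncSelf", "syncFriend",
                                 "asyncFriend")})
        assert res.F_interaction == 0.0
        assert res.F_synchrony == 0.0
        assert res.F_person == 0.0

    def test_interaction_equals_squared_double_difference_t(self):
        rng = np.random.default_rng(1)
        cells = self._cells(rng)
        cells["asyncSelf"] = cells["asyncSelf"] + 0.8
        res = anova_2x2_within(cells)
        dd = ((cells["asyncSelf"] - cells["syncSelf"])
              - (cells["asyncFriend"] - cells["syncFriend"]))
        t = dd.mean() / (dd.std(ddof=1) / np.sqrt(len(dd)))
        assert res.F_interaction == pytest.approx(t ** 2, abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sums_of_squares_oracle(self, seed):
        rng = np.random.default_rng(seed)
        cells = self._cells(rng)
        res = anova_2x2_within(cells)
        oracle = rm_anova_ss(cells)
        assert res.F_interaction == pytest.approx(oracle["F_interaction"],
                                                  abs=1e-10)
        assert res.F_synchrony == pytest.approx(oracle["F_synchrony"],
                                                abs=1e-10)
        assert res.F_person == pytest.approx(oracle["F_person"], abs=1e-10)


class TestWilcoxon:
    def test_all_zero_differences_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1, 2, 3], [1, 2, 3])

    def test_three_positive_diffs_exact(self):
        # all-positive signs: one-sided exact p = 1/8 -> two-sided 1/4
        w, p, n = wilcoxon_signed_rank([2, 4, 6], [1, 2, 3])
        assert w == 6.0
        assert p == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(5, 13)
        x = rng.integers(-5, 6, size=n).astype(float)  # integer diffs -> ties
        y = np.zeros(n)
        if np.all(x == 0):
            x[0] = 1.0
        w, p, _ = wilcoxon_signed_rank(x, y)
        w_o, p_o = wilcoxon_enumerate(x)
        assert w == pytest.approx(w_o)
        assert p == pytest.approx(p_o, abs=1e-12)

    def test_matches_scipy_without_ties(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=15)
        w, p, _ = wilcoxon_signed_rank(x, np.zeros(15))
        ref = sps.wilcoxon(x, mode="exact")
        assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_large_n_normal_approximation(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0.3, 1, size=40)
        w, p, n = wilcoxon_signed_rank(x, np.zeros(40))
        assert 0 <= p <= 1
        ref = sps.wilcoxon(x, correction=False, mode="approx")
        assert p == pytest.approx(ref.pvalue, rel=1e-6)


class TestSpearman:
    def test_monotone_transforms(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        rho, _, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)
        rho, _, _ = spearman(x, -x ** 3)
        assert rho == pytest.approx(-1.0)

    def test_p_close_to_exact_permutation(self):
        rng = np.random.default_rng(2)
        x, y = rng.normal(size=7), rng.normal(size=7)
        rho, p, _ = spearman(x, y)
        p_exact = spearman_permutation_p(x, y)
        assert p == pytest.approx(p_exact, abs=0.02)

    def test_one_sided_halves_in_the_right_direction(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=30)
        y = -x + rng.normal(0, 0.7, size=30)
        rho, p_less, _ = spearman(x, y, "less")
        _, p_two, _ = spearman(x, y)
        assert rho < 0
        assert p_less == pytest.approx(p_two / 2, abs=1e-12)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])


class TestJzsBayesFactor:
    def test_symmetry_in_t(self):
        a = jzs_bf01_ttest(1.3, 40).bf01
        b = jzs_bf01_ttest(-1.3, 40).bf01
        assert a == pytest.approx(b, rel=1e-8)

    def test_decreasing_in_absolute_t(self):
        vals = [jzs_bf01_ttest(t, 65).bf01 for t in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_null_support_grows_with_n_at_t_zero(self):
        assert jzs_bf01_ttest(0.0, 100).bf01 > jzs_bf01_ttest(0.0, 20).bf01

    def test_overwhelming_evidence_limit(self):
        assert jzs_bf01_ttest(10.0, 65).bf01 < 1e-6

    @pytest.mark.parametrize("t,n", [(0.06, 65), (1.19, 65), (-0.98, 65),
                                     (2.46, 65), (0.5, 12)])
    def test_matches_dense_quadrature_oracle(self, t, n):
        mine = jzs_bf01_ttest(t, n).bf01
        oracle = jzs_bf01_trapezoid(t, n)
        assert mine == pytest.approx(oracle, rel=1e-5)


class TestCorrelationBayesFactor:
    def test_null_favored_at_zero_effect(self):
        assert jzs_bf01_correlation(0.0, 65) > 1

    def test_strong_correlation_crushes_null(self):
        assert jzs_bf01_correlation(0.95, 65) < 1e-6

    @pytest.mark.parametrize("rho", [-0.044, -0.22, 0.3])
    def test_consistent_with_trapezoid_quadrature(self, rho):
        assert jzs_bf01_correlation(rho, 65) == pytest.approx(
            corr_bf01_trapezoid(rho, 65), rel=1e-4)


class TestMediation:
    def test_deterministic_chain_exact_paths(self):
        # m a near-exact linear function of x (exact collinearity is
        # rejected), y an exact function of m -> paths recovered exactly
        rng = np.random.default_rng(0)
        x = np.linspace(-2, 2, 20)
        m = 1.5 * x + 1e-3 * rng.normal(size=20)
        y = -0.8 * m
        res = mediate(x, m, y, n_boot=200, seed=1)
        assert res.a == pytest.approx(1.5, abs=1e-3)
        assert res.b == pytest.approx(-0.8, abs=1e-9)
        assert res.indirect_ab == pytest.approx(-1.2, abs=2e-3)
        assert res.c_prime == pytest.approx(0.0, abs=1e-8)

    def test_total_effect_identity(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=40)
        m = 0.5 * x + rng.normal(size=40)
        y = 0.3 * x + 0.7 * m + rng.normal(size=40)
        res = mediate(x, m, y, n_boot=100, seed=2)
        assert res.c_total == pytest.approx(res.c_prime + res.a * res.b,
                                            abs=1e-10)

    def test_bootstrap_reproducible_with_seed(self):
        rng = np.random.default_rng(6)
        x, m, y = rng.normal(size=(3, 30))
        r1 = mediate(x, m, y, n_boot=500, seed=42)
        r2 = mediate(x, m, y, n_boot=500, seed=42)
        assert r1.boot_ci == r2.boot_ci
        assert r1.z == r2.z

    def test_null_mediator_ci_coverage(self):
        # m independent of x and y: the 95% CI should cover 0 ~95% of the time
        rng = np.random.default_rng(7)
        cover = 0
        small_z = 0
        R = 500
        for i in range(R):
            x = rng.normal(size=65)
            m = rng.normal(size=65)
            y = 0.4 * x + rng.normal(size=65)
            res = mediate(x, m, y, n_boot=1000, seed=i)
            cover += res.boot_ci[0] <= 0 <= res.boot_ci[1]
            small_z += abs(res.z) < 1.96
        assert cover / R >= 0.94
        assert small_z / R >= 0.90

    def test_collinearity_rejected(self):
        x = np.arange(10.0)
        with pytest.raises(ValueError):
            mediate(x, 2 * x, x + 1)


class TestMixedModel:
    def test_balanced_two_condition_coefficient_is_mean_difference(self):
        rng = np.random.default_rng(8)
        n = 12
        subj = np.repeat(np.arange(n), 2)
        cond = np.tile([0.0, 1.0], n)
        y = rng.normal(size=2 * n) + 0.6 * cond + np.repeat(
            rng.normal(0, 1, n), 2)
        X = np.column_stack([np.ones(2 * n), cond])
        fit = mixed_model(y, X, subj, coef_names=["intercept", "cond"])
        within = (y[cond == 1] - y[cond == 0]).mean()
        assert fit.beta[1] == pytest.approx(within, abs=1e-8)

    def test_no_group_variance_coincides_with_ols(self):
        # residual group means forced to zero -> between variance hits the
        # boundary and the GLS fit coincides with OLS
        rng = np.random.default_rng(9)
        X = np.column_stack([np.ones(30), np.tile(rng.normal(size=6), 5)])
        groups = np.repeat(np.arange(5), 6)
        resid = rng.normal(0, 1, size=30)
        for g in range(5):
            resid[groups == g] -= resid[groups == g].mean()
        y = X @ [1.0, 0.5] + resid
        fit = mixed_model(y, X, groups)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert fit.var_between == pytest.approx(0.0, abs=1e-6)
        assert fit.beta == pytest.approx(ols, abs=1e-6)

    def test_matches_dense_reml_oracle(self):
        rng = np.random.default_rng(10)
        groups = np.repeat(np.arange(4), 5)
        X = np.column_stack([np.ones(20), rng.normal(size=20)])
        y = X @ [0.5, 1.2] + np.repeat(rng.normal(0, 0.7, 4), 5) \
            + rng.normal(0, 0.5, 20)
        fit = mixed_model(y, X, groups)
        oracle = reml_dense(y, X, groups)
        assert fit.var_between == pytest.approx(oracle["var_between"], abs=1e-4)
        assert fit.var_within == pytest.approx(oracle["var_within"], abs=1e-4)
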