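"""Logistic / linear / modified-Poisson fits, DL meta-analysis, BH FDR,
grade trend, and partial correlation."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lvddlink import (bh_fdr, fit_linear, fit_logistic, grade_trend,
                      modified_poisson, pairwise_linear_assoc,
                      partial_correlation, random_effects_meta)
from lvddlink.models import build_design, standardize


def two_by_two(n_exp, ev_exp, n_unexp, ev_unexp):
    x = np.r_[np.ones(n_exp), np.zeros(n_unexp)]
    y = np.r_[np.ones(ev_exp), np.zeros(n_exp - ev_exp),
              np.ones(ev_unexp), np.zeros(n_unexp - ev_unexp)]
    return x, y


class TestLogistic:
    def test_two_by_two_cross_product_ratio(self):
        # saturated model: OR = (20*90)/(80*10) = 2.25 exactly
        x, y = two_by_two(100, 20, 100, 10)
        res = fit_logistic(y, x)
        assert res.effect == pytest.approx(2.25, rel=1e-6)
        assert res.effect_measure == "OR"
        lo, hi = res.ci95
        assert lo < res.effect < hi

    def test_null_exposure_near_unity(self, rng):
        n = 2000
        y = rng.binomial(1, 0.4, n)
        x = rng.normal(size=n)
        res = fit_logistic(y, x)
        assert 0.9 < res.effect < 1.1

    def test_constant_outcome_errors(self):
        with pytest.raises(ValueError):
            fit_logistic(np.ones(50), np.random.default_rng(0).normal(size=50))

    def test_separation_flagged_not_silent(self):
        x = np.r_[np.zeros(20), np.ones(20)]
        y = x.copy()
        res = fit_logistic(y, x + np.random.default_rng(1).normal(0, 1e-9, 40))
        assert not res.converged

    def test_covariate_adjustment_changes_estimate(self, rng):
        n = 800
        c = rng.normal(size=n)
        x = c + rng.normal(size=n)
        y = rng.binomial(1, 1 / (1 + np.exp(-c)))
        crude = fit_logistic(y, x)
        adj = fit_logistic(y, x, pd.DataFrame({"c": c}))
        assert abs(adj.beta) < abs(crude.beta)


class TestLinear:
    def test_identity_regression(self, rng):
        x = rng.normal(size=100)
        res = fit_linear(x, x)
        assert res.beta == pytest.approx(1.0, abs=1e-10)
        assert res.p < 1e-20

    def test_rank_deficiency_errors(self, rng):
        x = rng.normal(size=50)
        covs = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="rank"):
            fit_linear(rng.normal(size=50), x, covs)

    def test_planted_slope_recovered(self, rng):
        n, slope, n_rep = 800, 0.4, 30
        betas = []
        for _ in range(n_rep):
            x = rng.normal(size=n)
            y = slope * x + rng.normal(size=n)
            betas.append(fit_linear(y, x).beta)
        mc_se = np.std(betas, ddof=1) / np.sqrt(n_rep)
        assert abs(np.mean(betas) - slope) < 3 * mc_se


class TestPairwiseLinear:
    def test_matches_statsmodels_exactly(self, rng):
        import statsmodels.api as sm
        n = 120
        covs = pd.DataFrame({"age": rng.normal(50, 8, n),
                             "sex": rng.binomial(1, 0.5, n)})
        X = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"),
                         index=covs.index)
        Y = pd.DataFrame(rng.normal(size=(n, 4)), columns=list("wxyz"),
                         index=covs.index)
        bulk = pairwise_linear_assoc(X, Y, covs)
        for _, row in bulk.iterrows():
            D = build_design(covs).assign(x=X[row["exposure_id"]])
            fit = sm.OLS(Y[row["feature_id"]], D).fit()
            assert row["beta"] == pytest.approx(fit.params["x"], abs=1e-10)
            assert row["se"] == pytest.approx(fit.bse["x"], abs=1e-10)
            assert row["p"] == pytest.approx(fit.pvalues["x"], abs=1e-10)


class TestModifiedPoisson:
    def test_two_by_two_rr_exact(self):
        # risks 10/50 vs 5/50 -> RR = 2.0
        x, y = two_by_two(50, 10, 50, 5)
        res = modified_poisson(y, x)
        assert res.effect == pytest.approx(2.0, rel=1e-6)
        assert res.effect_measure == "RR"

    def test_robust_se_closed_form(self):
        # var(log RR) = 1/10 - 1/50 + 1/5 - 1/50 for the saturated 2x2
        x, y = two_by_two(50, 10, 50, 5)
        res = modified_poisson(y, x)
        assert res.se == pytest.approx(np.sqrt(1/10 - 1/50 + 1/5 - 1/50),
                                       rel=1e-4)

    def test_all_zero_outcome_errors(self):
        with pytest.raises(ValueError):
            modified_poisson(np.zeros(40), np.random.default_rng(0).normal(size=40))

    def test_log_link_rr_recovery(self, rng):
        # planted RR = 1.5 per SD under a log-link Bernoulli model
        n, log_rr, reps = 600, np.log(1.5), 40
        betas = []
        for _ in range(reps):
            x = rng.normal(size=n)
            p = np.minimum(np.exp(-1.4 + log_rr * x), 0.95)
            y = rng.binomial(1, p)
            betas.append(modified_poisson(y, x).beta)
        mc_se = np.std(betas, ddof=1) / np.sqrt(reps)
        assert abs(np.mean(betas) - log_rr) < 3 * mc_se


class TestMeta:
    def test_homogeneous_limit(self):
        res = random_effects_meta([(0.5, 0.2), (0.5, 0.2)])
        assert res.beta == pytest.approx(0.5)
        assert res.tau2 == 0.0
        assert res.se == pytest.approx(0.2 / np.sqrt(2))

    def test_discordant_never_retained(self):
        res = random_effects_meta([(0.5, 0.01), (-0.5, 0.01)])
        assert not res.concordant and not res.retained

    def test_matches_statsmodels_dl(self):
        from statsmodels.stats.meta_analysis import combine_effects
        betas, ses = [0.8, 0.3, 0.55], [0.2, 0.15, 0.3]
        ours = random_effects_meta(list(zip(betas, ses)))
        ref = combine_effects(np.array(betas), np.array(ses) ** 2,
                              method_re="dl")
        assert ours.tau2 == pytest.approx(float(ref.tau2), rel=1e-8)
        summ = ref.summary_frame()
        assert ours.beta == pytest.approx(
            float(summ.loc["random effect", "eff"]), rel=1e-8)

    def test_se_must_be_positive(self):
        with pytest.raises(ValueError):
            random_effects_meta([(0.5, 0.0), (0.4, 0.1)])

    def test_retention_requires_significance(self):
        res = random_effects_meta([(0.05, 0.2), (0.04, 0.25)])
        assert res.concordant and not res.retained


class TestBH:
    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_fdr([0.01]), [0.01])

    def test_step_up_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        np.testing.assert_allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))

    def test_domain_check(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_null_mwaa_family_rarely_significant(self, rng):
        # permuted exposure: essentially no q < 0.1 discoveries
        n, m = 250, 150
        X = pd.DataFrame(rng.normal(size=(n, 1)), columns=["sp"])
        Y = pd.DataFrame(rng.normal(size=(n, m)),
                         columns=[f"m{j}" for j in range(m)], index=X.index)
        bulk = pairwise_linear_assoc(X, Y, None)
        q = bh_fdr(bulk["p"].to_numpy())
        assert (q < 0.1).mean() < 0.02


class TestGradeTrend:
    def test_flat_abundance(self, rng):
        g = np.tile([0, 1, 2, 3], 50)
        res = grade_trend(np.full(200, 2.0) + rng.normal(0, 1e-12, 200), g)
        assert abs(res.beta) < 1e-6

    def test_identity_slope(self):
        g = np.tile([0, 1, 2, 3], 25)
        res = grade_trend(g.astype(float), g)
        assert res.beta == pytest.approx(1.0, abs=1e-10)

    def test_planted_monotone_decrease(self, rng):
        n = 1000
        g = rng.integers(0, 4, n)
        x = -0.3 * g + rng.normal(size=n)
        res = grade_trend(x, g)
        assert res.beta < 0 and res.p < 0.05

    def test_constant_grade_errors(self):
        with pytest.raises(ValueError):
            grade_trend(np.ones(50), np.ones(50))


class TestPartialCorrelation:
    def test_reduces_to_pearson(self, rng):
        x, y = rng.normal(size=(2, 200))
        r, p = partial_correlation(x, y)
        rr, pp = stats.pearsonr(x, y)
        assert r == pytest.approx(rr, abs=1e-10)
        assert p == pytest.approx(pp, abs=1e-8)

    def test_identity(self, rng):
        x = rng.normal(size=100)
        r, _ = partial_correlation(x, x + 0.0, pd.DataFrame({"c": rng.normal(size=100)}))
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_trivariate_closed_form(self, rng):
        # partial r = (r_xy - r_xz r_zy) / sqrt((1-r_xz^2)(1-r_zy^2))
        n = 60_000
        z = rng.normal(size=n)
        x = 0.6 * z + rng.normal(size=n)
        y = 0.5 * z + 0.3 * x + rng.normal(size=n)
        r_xy = np.corrcoef(x, y)[0, 1]
        r_xz = np.corrcoef(x, z)[0, 1]
        r_zy = np.corrcoef(z, y)[0, 1]
        expected = (r_xy - r_xz * r_zy) / np.sqrt((1 - r_xz**2) * (1 - r_zy**2))
        r, p = partial_correlation(x, y, pd.DataFrame({"z": z}))
        assert r == pytest.approx(expected, abs=0.01)
        assert p < 1e-10

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        n = 150
        df = pd.DataFrame(rng.normal(size=(n, 3)), columns=["x", "y", "z"])
        df["y"] += 0.4 * df["x"]
        ours_r, ours_p = partial_correlation(df["x"], df["y"],
                                             df[["z"]])
        ref = pg.partial_corr(df, x="x", y="y", covar="z")
        assert ours_r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-8)
        assert ours_p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-8)

    def test_zero_residual_variance_errors(self, rng):
        z = rng.normal(size=50)
        with pytest.raises(ValueError):
            partial_correlation(2 * z, rng.normal(size=50),
                                pd.DataFrame({"z": z}))


def test_model_covariate_nesting():
    from lvddlink.tables import (MODEL1_COVARIATES, MODEL2_COVARIATES,
                                 MODEL3_COVARIATES)
    assert MODEL2_COVARIATES[:len(MODEL1_COVARIATES)] == MODEL1_COVARIATES
    assert set(MODEL2_COVARIATES) - set(MODEL1_COVARIATES) == {"bmi", "sbp"}
    assert set(MODEL3_COVARIATES) - set(MODEL2_COVARIATES) == {
        "med_antidiabetic", "med_antihypertensive", "med_lipidlowering"}


def test_standardize_unit_sd(rng):
    x = rng.normal(3, 7, 500)
    assert standardize(x).std(ddof=1) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        standardize(np.ones(10))
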