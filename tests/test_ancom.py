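"""Zero classification and the pairwise log-ratio W statistic."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from lvddlink import AncomII, classify_zeros, bh_fdr
from lvddlink.models import build_design

from conftest import make_table


def _table_with_outcome(rng, n=60, m=8, mu=None):
    mu = np.zeros(m) if mu is None else mu
    latent = np.exp(mu[None, :] + rng.normal(0, 1, (n, m)))
    comp = latent / latent.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(5000, comp[i]) for i in range(n)])
    y = rng.binomial(1, 0.5, n)
    return make_table(counts.astype(float)), y


def naive_w(table, outcome, covariates, alpha=0.05, pseudocount=0.5):
    """Independent double-loop oracle: one statsmodels OLS per taxon pair."""
    X = table.values
    m = X.shape[1]
    L = np.log(np.where(X > 0, X, pseudocount))
    idx = pd.RangeIndex(len(outcome))
    D = build_design(covariates, index=idx).assign(_y=np.asarray(outcome, float))
    P = np.full((m, m), np.nan)
    for i in range(m):
        for j in range(m):
            if i == j:
                continue
            fit = sm.OLS(L[:, i] - L[:, j], D.to_numpy()).fit()
            P[i, j] = fit.pvalues[-1]
    W = np.zeros(m, dtype=int)
    for i in range(m):
        pi = np.delete(P[i], i)
        W[i] = int((bh_fdr(pi) < alpha).sum())
    return W


class TestZeroClassification:
    def test_structural_zero_definitional(self, rng):
        n = 40
        y = np.r_[np.zeros(20), np.ones(20)]
        X = rng.integers(1, 100, (n, 4)).astype(float)
        # taxon 0: absent in group 1, present in 60% of group 0
        X[y == 1, 0] = 0
        X[rng.choice(np.where(y == 0)[0], 8, replace=False), 0] = 0
        zc = classify_zeros(make_table(X), y)
        assert zc.structural.loc["f0", 1.0]
        assert not zc.structural.loc["f0", 0.0]
        assert zc.one_sided_structural()["f0"]

    def test_no_zeros_no_flags(self, rng):
        X = rng.integers(1, 100, (30, 5)).astype(float)
        y = np.r_[np.zeros(15), np.ones(15)]
        zc = classify_zeros(make_table(X), y)
        assert not zc.structural.to_numpy().any()
        assert not zc.outlier.to_numpy().any()
        assert not zc.sampling.to_numpy().any()

    def test_each_zero_gets_exactly_one_class(self, rng):
        X = rng.integers(0, 6, (60, 10)).astype(float)
        X[:, 0] += 1  # avoid all-zero samples
        y = rng.binomial(1, 0.5, 60)
        t = make_table(X)
        zc = classify_zeros(t, y)
        struct_cells = np.zeros(X.shape, dtype=bool)
        for g in (0.0, 1.0):
            struct_cells[y == g] |= zc.structural[g].to_numpy()[None, :]
        n_classes = (zc.outlier.to_numpy().astype(int)
                     + zc.sampling.to_numpy().astype(int)
                     + (struct_cells & (X == 0)).astype(int))
        np.testing.assert_array_equal(n_classes == 1, X == 0)

    def test_outlier_zero_in_abundant_taxon(self, rng):
        n = 60
        y = np.r_[np.zeros(30), np.ones(30)]
        X = rng.integers(1, 5, (n, 6)).astype(float)
        X[:, 0] = rng.integers(4000, 6000, n)  # very abundant, tight spread
        X[3, 0] = 0  # a technical zero
        zc = classify_zeros(make_table(X), y)
        assert zc.outlier.iloc[3, 0]
        assert not zc.sampling.iloc[3, 0]

    def test_small_group_errors(self, rng):
        X = rng.integers(1, 10, (10, 4)).astype(float)
        y = np.r_[np.zeros(8), np.ones(2)]
        with pytest.raises(ValueError, match="fewer than"):
            classify_zeros(make_table(X), y)

    def test_injected_structural_map_recovered(self, small_cohort):
        species, _, _, meta, truth = small_cohort
        y = meta.frame["prevalent_lvdd"].to_numpy()
        zc = classify_zeros(species, y)
        calls = set(zc.one_sided_structural()[lambda s: s].index)
        assert set(truth.structural_zero_species) <= calls


class TestAncomW:
    def test_w_matches_double_loop_oracle(self, rng):
        table, y = _table_with_outcome(rng, n=80, m=10)
        covs = pd.DataFrame({"age": rng.normal(50, 5, 80)})
        res = AncomII(table, y, covs).fit()
        expected = naive_w(table, y, covs)
        np.testing.assert_array_equal(res.frame["W"].to_numpy(), expected)

    def test_w_oracle_no_covariates(self, rng):
        table, y = _table_with_outcome(rng, n=60, m=7)
        res = AncomII(table, y).fit()
        np.testing.assert_array_equal(res.frame["W"].to_numpy(),
                                      naive_w(table, y, None))

    def test_planted_taxon_attains_max_w(self, rng):
        n, m = 200, 10
        latent = np.exp(rng.normal(0, 1, (n, m)))
        y = rng.binomial(1, 0.5, n)
        latent[:, 0] *= np.exp(1.5 * y)  # 1.5-log-unit shift in cases
        comp = latent / latent.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(8000, comp[i]) for i in range(n)])
        res = AncomII(make_table(counts.astype(float)), y).fit()
        W = res.frame["W"]
        assert W["f0"] == W.max()
        assert res.frame.loc["f0", "detected"]

    def test_null_three_taxa_nothing_detected(self, rng):
        table, y = _table_with_outcome(rng, n=400, m=3)
        res = AncomII(table, y).fit()
        assert not res.frame["detected"].any()
        assert (res.frame["W"] <= 1).all()

    def test_w_bounded_by_m_minus_one(self, rng):
        table, y = _table_with_outcome(rng, n=60, m=9)
        res = AncomII(table, y).fit()
        assert (res.frame["W"] <= res.m_tested - 1).all()

    def test_reference_taxon_preserves_ordering(self, rng):
        # graded planted shifts so W varies across taxa
        n, m = 150, 8
        latent = np.exp(rng.normal(0, 1, (n, m)))
        y = rng.binomial(1, 0.5, n)
        for k, shift in enumerate((2.0, 1.2, 0.6)):
            latent[:, k] *= np.exp(shift * y)
        comp = latent / latent.sum(axis=1, keepdims=True)
        counts = np.vstack([rng.multinomial(8000, comp[i]) for i in range(n)])
        table = make_table(counts.astype(float))
        base = AncomII(table, y).fit().frame["W"]
        # add a near-constant-composition reference taxon
        ref = np.round(table.data.sum(axis=1) * 0.05)
        aug = table.data.assign(ref=ref)
        res2 = AncomII(make_table(aug.to_numpy()), y).fit()
        aug_w = res2.frame["W"].iloc[:-1].to_numpy()
        b = base.to_numpy()
        # no strict inversion of the original taxa's W ordering
        for i in range(len(b)):
            for j in range(len(b)):
                if b[i] > b[j]:
                    assert aug_w[i] >= aug_w[j]

    def test_structural_taxon_autodetected_and_excluded(self, rng):
        n = 80
        y = np.r_[np.zeros(40), np.ones(40)]
        X = rng.integers(1, 200, (n, 6)).astype(float)
        X[y == 1, 0] = 0
        res = AncomII(make_table(X), y).fit()
        row = res.frame.loc["f0"]
        assert row["structural_zero_call"] and row["detected"]
        assert np.isnan(row["W"])
        assert res.m_tested == 5

    def test_too_few_taxa_errors(self, rng):
        table, y = _table_with_outcome(rng, n=40, m=2)
        with pytest.raises(ValueError):
            AncomII(table, y).fit()

    def test_rank_deficient_covariates_error(self, rng):
        table, y = _table_with_outcome(rng, n=50, m=5)
        covs = pd.DataFrame({"a": np.ones(50)})  # collinear with intercept
        with pytest.raises(ValueError, match="rank"):
            AncomII(table, y, covs).fit()

    def test_outlier_zero_fallback_matches_complete_case_oracle(self, rng):
        # a taxon with an outlier zero is refit per pair on complete rows
        n, m = 80, 6
        X = rng.integers(50, 150, (n, m)).astype(float)
        X[:, 0] = rng.integers(4000, 6000, n)
        X[5, 0] = 0
        y = rng.binomial(1, 0.5, n)
        table = make_table(X)
        res = AncomII(table, y).fit()
        # oracle for taxon 0 vs taxon 1 on rows without the outlier zero
        keep = np.ones(n, dtype=bool); keep[5] = False
        L = np.log(X)
        D = sm.add_constant(y[keep].astype(float))
        fit = sm.OLS(L[keep, 0] - L[keep, 1], D).fit()
        # recompute taxon 0's W by hand over all pairs
        ps = []
        for j in range(1, m):
            fitj = sm.OLS(L[keep, 0] - L[keep, j], D).fit()
            ps.append(fitj.pvalues[-1])
        expected_w = int((bh_fdr(np.array(ps)) < 0.05).sum())
        assert res.frame.loc["f0", "W"] == expected_w
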