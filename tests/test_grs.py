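import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from sklearn.base import clone

from mrkit.exceptions import ConfigurationError, ValidationError
from mrkit.grs import (CohortTable, CrossValidatedGRS, ScoreResult, assign_folds,
                       build_grs, cv_score, cv_weights, inverse_normal_transform,
                       one_sample_mr, residualize_and_int, variance_explained)


def make_cohort(n=500, J=5, seed=0, h2=0.5, binary_outcome=False, theta=0.0):
    rng = np.random.default_rng(seed)
    maf = rng.uniform(0.1, 0.5, J)
    beta = rng.uniform(0.05, 0.3, J)
    G = rng.binomial(2, maf, size=(n, J)).astype(float)
    g = G @ beta
    noise_sd = math.sqrt(g.var() * (1 - h2) / h2) if h2 < 1 else 0.0
    pheno = g + rng.normal(0, noise_sd, n)
    sex = rng.integers(0, 2, n).astype(float)
    age = rng.normal(57, 8, n)
    cov = pd.DataFrame({"age": age, "age2": age**2})
    outcome = None
    if binary_outcome:
        x_sd = (pheno - pheno.mean()) / pheno.std()
        p = 1 / (1 + np.exp(-(-2.2 + theta * x_sd)))
        outcome = pd.Series((rng.random(n) < p).astype(float))
    return CohortTable(dosages=pd.DataFrame(G, columns=[f"rs{j}" for j in range(J)]),
                       phenotype=pd.Series(pheno), covariates=cov,
                       sex=pd.Series(sex), outcome=outcome), beta


class TestInverseNormal:
    def test_blom_three_values(self):
        out = inverse_normal_transform(np.array([5.0, 2.0, 9.0]))
        expect = stats.norm.ppf((np.array([2, 1, 3]) - 0.375) / 3.25)
        np.testing.assert_allclose(out, expect, atol=1e-12)
        assert out[0] == pytest.approx(0.0, abs=1e-12)
        assert out[2] == pytest.approx(0.8694, abs=1e-4)
        assert out[1] == pytest.approx(-out[2])

    def test_middle_rank_exactly_zero_odd_n(self):
        out = inverse_normal_transform(np.arange(7.0))
        assert out[3] == pytest.approx(0.0, abs=1e-12)

    def test_standardized_for_large_n(self):
        rng = np.random.default_rng(0)
        out = inverse_normal_transform(rng.exponential(1, 500))
        assert abs(out.mean()) < 0.01
        assert out.var() == pytest.approx(1.0, abs=0.05)

    def test_constant_input_raises(self):
        with pytest.raises(ValidationError):
            inverse_normal_transform(np.ones(10))


class TestResidualize:
    def test_removes_covariate_signal(self):
        cohort, _ = make_cohort(n=800, seed=1)
        # contaminate the phenotype with a strong age effect
        cohort = CohortTable(dosages=cohort.dosages,
                             phenotype=cohort.phenotype + 0.1 * cohort.covariates["age"],
                             covariates=cohort.covariates, sex=cohort.sex)
        out = residualize_and_int(cohort)
        r = np.corrcoef(out, cohort.covariates["age"])[0, 1]
        assert abs(r) < 0.05

    def test_sex_strata_pooled_each_standardized(self):
        cohort, _ = make_cohort(n=600, seed=2)
        out = residualize_and_int(cohort, stratify_by_sex=True)
        for s in (0.0, 1.0):
            mask = cohort.sex.to_numpy() == s
            assert abs(out[mask].mean()) < 0.02
            assert out[mask].var() == pytest.approx(1.0, abs=0.1)

    def test_constant_phenotype_raises(self):
        cohort = CohortTable(dosages=pd.DataFrame({"rs0": [0.0, 1.0, 2.0]}),
                             phenotype=pd.Series([1.0, 1.0, 1.0]))
        with pytest.raises(ValidationError, match="constant"):
            residualize_and_int(cohort)


class TestBuildGRS:
    def test_score_arithmetic(self):
        cohort = CohortTable(dosages=pd.DataFrame([[0.0, 1.0, 2.0]],
                                                  columns=["a", "b", "c"]),
                             phenotype=pd.Series([1.0]))
        res = build_grs(cohort, [0.1, 0.2, 0.3])
        assert res.score[0] == pytest.approx(0.8)

    def test_zero_weights_zero_score_zero_r2(self):
        cohort, _ = make_cohort(n=100)
        res = build_grs(cohort, np.zeros(5))
        assert np.all(res.score == 0) and res.r_squared == 0.0

    def test_noiseless_phenotype_r2_near_one(self):
        cohort, beta = make_cohort(n=400, h2=0.9999, seed=3)
        res = build_grs(cohort, beta)
        assert res.r_squared > 0.99

    def test_series_weights_align_by_snp_id(self):
        cohort, beta = make_cohort(n=50, seed=4)
        shuffled = pd.Series(beta, index=[f"rs{j}" for j in range(5)]).sample(
            frac=1, random_state=0)
        res1 = build_grs(cohort, shuffled)
        res2 = build_grs(cohort, beta)
        np.testing.assert_allclose(res1.score, res2.score)

    def test_misaligned_weights_raise(self):
        cohort, _ = make_cohort(n=20)
        with pytest.raises(ConfigurationError, match="length"):
            build_grs(cohort, [0.1, 0.2])


class TestCVWeights:
    def test_folds_partition(self):
        folds = assign_folds(103, 20, seed=5)
        assert sorted(np.unique(folds)) == list(range(1, 21))
        counts = np.bincount(folds)[1:]
        assert counts.sum() == 103 and counts.max() - counts.min() <= 1

    def test_orthogonal_noiseless_recovers_beta(self):
        # phenotype exactly X @ beta with uncorrelated SNPs: both folds'
        # marginal fits recover beta (least-squares oracle)
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        n, J = 6000, 4
        G = rng.binomial(2, 0.5, size=(n, J)).astype(float)
        beta = np.array([0.1, -0.2, 0.3, 0.05])
        y = G @ beta
        cohort = CohortTable(dosages=pd.DataFrame(G, columns=list("abcd")),
                             phenotype=pd.Series(y))
        W, folds = cv_weights(cohort, k=2, seed=7)
        assert W.shape == (2, 4)
        # exact oracle: each cell equals a simple OLS fit on the training fold
        for i, f in enumerate(W.index):
            train = folds != f
            for j in range(J):
                fit = sm.OLS(y[train], sm.add_constant(G[train, j])).fit()
                assert W.iloc[i, j] == pytest.approx(fit.params[1], abs=1e-10)
        # approximate recovery: empirical dosage correlation shrinks with n
        np.testing.assert_allclose(W.to_numpy(), np.tile(beta, (2, 1)), atol=0.05)

    def test_permuted_phenotype_cv_r2_near_zero(self):
        cohort, _ = make_cohort(n=1000, seed=8)
        rng = np.random.default_rng(9)
        perm = CohortTable(dosages=cohort.dosages,
                           phenotype=pd.Series(rng.permutation(cohort.phenotype)))
        res = cv_score(perm, k=5, seed=10)
        assert res.r_squared < 0.02

    def test_cv_r2_not_above_insample(self):
        cohort, _ = make_cohort(n=800, h2=0.3, seed=11)
        W, folds = cv_weights(cohort, k=10, seed=12)
        cv = cv_score(cohort, k=10, seed=12)
        # in-sample: weights fitted on everyone
        full = CohortTable(dosages=cohort.dosages, phenotype=cohort.phenotype)
        gw, _ = cv_weights(full, k=2, seed=0)
        y = cohort.phenotype.to_numpy()
        G = cohort.dosages.to_numpy()
        gm, ym = G.mean(0), y.mean()
        w_all = ((G - gm) * (y - ym)[:, None]).sum(0) / ((G - gm) ** 2).sum(0)
        insample = build_grs(cohort, w_all)
        assert cv.r_squared <= insample.r_squared + 0.01

    def test_monomorphic_snp_gets_zero_weight(self):
        G = pd.DataFrame({"mono": np.ones(40), "poly": np.tile([0.0, 1.0], 20)})
        cohort = CohortTable(dosages=G, phenotype=pd.Series(np.random.default_rng(0).normal(size=40)))
        W, _ = cv_weights(cohort, k=2, seed=1)
        assert (W["mono"] == 0).all()


class TestSklearnShape:
    def test_clone_and_params(self):
        est = CrossValidatedGRS(k=5, random_state=3)
        cl = clone(est)
        assert cl.get_params() == {"k": 5, "random_state": 3}

    def test_fit_transform_matches_cv_score(self):
        cohort, _ = make_cohort(n=300, seed=13)
        est = CrossValidatedGRS(k=4, random_state=14)
        oof = est.fit_transform(cohort.dosages, cohort.phenotype).ravel()
        direct = cv_score(CohortTable(dosages=cohort.dosages,
                                      phenotype=cohort.phenotype),
                          k=4, seed=14)
        np.testing.assert_allclose(oof, direct.score)

    def test_transform_uses_pooled_weights(self):
        cohort, _ = make_cohort(n=300, seed=15)
        est = CrossValidatedGRS(k=4, random_state=16).fit(cohort.dosages,
                                                          cohort.phenotype)
        out = est.transform(cohort.dosages.iloc[:10])
        expect = cohort.dosages.iloc[:10].to_numpy() @ est.weights_
        np.testing.assert_allclose(out.ravel(), expect)


class TestVarianceExplained:
    def test_single_snp_arithmetic(self):
        assert variance_explained([0.1], [0.5]) == pytest.approx(0.005)

    def test_zero_betas(self):
        assert variance_explained(np.zeros(10), np.full(10, 0.3)) == 0.0

    def test_allele_relabeling_invariant(self):
        rng = np.random.default_rng(17)
        beta, eaf = rng.normal(0, 0.1, 20), rng.uniform(0.05, 0.95, 20)
        assert variance_explained(beta, eaf) == pytest.approx(
            variance_explained(-beta, 1 - eaf))

    def test_missing_eaf_skipped(self):
        v = variance_explained([0.1, 0.1], [0.5, np.nan])
        assert v == pytest.approx(0.005)


class TestOneSampleMR:
    def test_exact_linear_outcome(self):
        cohort, beta = make_cohort(n=400, seed=18)
        cohort = CohortTable(dosages=cohort.dosages, phenotype=cohort.phenotype,
                             outcome=2.0 * cohort.phenotype)
        score = build_grs(cohort, beta)
        res = one_sample_mr(cohort, score, outcome_type="quantitative")
        assert res.beta == pytest.approx(2.0, abs=1e-8)

    def test_independent_outcome_ci_covers_zero(self):
        rng = np.random.default_rng(19)
        cohort, beta = make_cohort(n=2000, seed=20)
        cohort = CohortTable(dosages=cohort.dosages, phenotype=cohort.phenotype,
                             outcome=pd.Series(rng.normal(size=2000)))
        score = build_grs(cohort, beta)
        res = one_sample_mr(cohort, score, outcome_type="quantitative")
        assert res.ci_low < 0 < res.ci_high

    def test_equals_two_stage_least_squares_without_covariates(self):
        # oracle: with a single instrument (the score) and no covariates the
        # ratio estimator equals the 2SLS slope cov(y,s)/cov(x,s)
        rng = np.random.default_rng(21)
        cohort, beta = make_cohort(n=600, seed=22)
        y = 0.5 * cohort.phenotype.to_numpy() + rng.normal(0, 0.3, 600)
        cohort = CohortTable(dosages=cohort.dosages, phenotype=cohort.phenotype,
                             outcome=pd.Series(y))
        score = build_grs(cohort, beta)
        res = one_sample_mr(cohort, score, outcome_type="quantitative",
                            adjust_covariates=False)
        s = score.score
        tsls = np.cov(y, s)[0, 1] / np.cov(cohort.phenotype, s)[0, 1]
        assert res.beta == pytest.approx(tsls, abs=1e-8)

    def test_zero_variance_score_raises(self):
        cohort, _ = make_cohort(n=50, seed=23)
        cohort = CohortTable(dosages=cohort.dosages, phenotype=cohort.phenotype,
                             outcome=cohort.phenotype)
        score = ScoreResult(score=np.zeros(50), weight_source="global",
                            r_squared=0.0)
        with pytest.raises(ConfigurationError, match="zero variance"):
            one_sample_mr(cohort, score)
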