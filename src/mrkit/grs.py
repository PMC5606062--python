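"""Genetic risk scores, cross-validated weights, and one-sample MR.

This module covers the individual-level side of the analysis: preparing a
quantitative phenotype for association (covariate residualization followed by
rank-based inverse-normal transformation, per sex stratum), building a
weighted allele score, estimating score weights by k-fold cross-validation so
each individual's score uses weights from models that exclude them (avoiding
the overfitting that inflates in-sample variance explained), and a one-sample
MR that uses the cross-validated score as the instrument.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .estimators import MRResult, Z95
from .exceptions import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class CohortTable:
    """Individual-level data: dosages, phenotype, covariates, optional outcome.

    ``dosages`` is an (n individuals x J SNPs) frame of expected allele counts
    in [0, 2], columns named by snp_id and oriented to the trait-increasing
    allele.  ``sex`` (if given) enables sex-stratified phenotype preparation.
    ``fold`` is assigned once by :func:`assign_folds` and partitions the
    cohort.
    """

    dosages: pd.DataFrame
    phenotype: pd.Series
    covariates: pd.DataFrame | None = None
    sex: pd.Series | None = None
    outcome: pd.Series | None = None
    fold: np.ndarray | None = None

    def __post_init__(self):
        n = len(self.phenotype)
        if len(self.dosages) != n:
            raise ValidationError("dosages and phenotype have different lengths")
        d = self.dosages.to_numpy()
        if d.size and (np.nanmin(d) < 0 or np.nanmax(d) > 2):
            raise ValidationError("dosages must lie in [0, 2]")
        for other in (self.covariates, self.sex, self.outcome):
            if other is not None and len(other) != n:
                raise ValidationError("all cohort columns must share one length")

    @property
    def n(self) -> int:
        return len(self.phenotype)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)


@dataclass
class ScoreResult:
    """Per-individual genetic risk score with its variance explained."""

    score: np.ndarray
    weight_source: str  # "global" | "fold-specific"
    r_squared: float

    def __post_init__(self):
        if not (0 <= self.r_squared <= 1 or math.isnan(self.r_squared)):
            raise ValidationError(f"r_squared out of [0,1]: {self.r_squared}")


# ---------------------------------------------------------------------------
# phenotype preparation


def inverse_normal_transform(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform with the Blom offset.

    Maps rank r (1-based, ties broken by average rank) through
    ``Phi^{-1}((r - offset) / (n + 1 - 2*offset))``; the default
    offset 3/8 gives the Blom formula (r - 3/8)/(n + 1/4).
    """
    v = np.asarray(values, dtype=float)
    if np.ptp(v) == 0:
        raise ValidationError("constant input: rank transform degenerate")
    ranks = stats.rankdata(v, method="average")
    return stats.norm.ppf((ranks - offset) / (v.size + 1.0 - 2.0 * offset))


def residualize_and_int(
    cohort: CohortTable,
    stratify_by_sex: bool = True,
    offset: float = 3.0 / 8.0,
) -> np.ndarray:
    """Covariate-adjusted, inverse-normal-transformed phenotype.

    Within each sex stratum (when ``stratify_by_sex`` and a sex column exist)
    the phenotype is regressed on the covariates by OLS, the residuals are
    rank-inverse-normal transformed, and the per-stratum results are pooled
    back in the original row order.
    """
    y = cohort.phenotype.to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValidationError("constant phenotype: cannot residualize/rank")
    out = np.empty_like(y)
    if stratify_by_sex and cohort.sex is not None:
        strata = [np.flatnonzero(cohort.sex.to_numpy() == s)
                  for s in pd.unique(cohort.sex)]
    else:
        strata = [np.arange(y.size)]
    for idx in strata:
        ys = y[idx]
        if cohort.covariates is not None and len(cohort.covariates.columns):
            Xs = sm.add_constant(cohort.covariates.iloc[idx].to_numpy(dtype=float))
            resid = ys - sm.OLS(ys, Xs).fit().fittedvalues
        else:
            resid = ys - ys.mean()
        out[idx] = inverse_normal_transform(resid, offset=offset)
    return out


# ---------------------------------------------------------------------------
# scores and cross-validated weights


def build_grs(
    cohort: CohortTable,
    weights: pd.Series | Sequence[float],
    phenotype: np.ndarray | None = None,
) -> ScoreResult:
    """Weighted allele score: score_i = sum_j dosage_ij * weight_j.

    ``weights`` must align with the dosage columns (a Series is reindexed by
    snp_id; a plain sequence must match the column count).  ``r_squared`` is
    the squared Pearson correlation between the score and the (transformed)
    phenotype; pass ``phenotype`` to score against a prepared phenotype
    instead of the raw column.
    """
    if isinstance(weights, pd.Series):
        missing = set(cohort.snp_ids) - set(weights.index)
        if missing:
            raise ConfigurationError(f"weights missing for SNPs: {sorted(missing)[:5]}")
        w = weights.reindex(cohort.snp_ids).to_numpy(dtype=float)
    else:
        w = np.asarray(weights, dtype=float)
        if w.size != len(cohort.snp_ids):
            raise ConfigurationError(
                f"weight vector length {w.size} != {len(cohort.snp_ids)} dosage columns")
    score = cohort.dosages.to_numpy(dtype=float) @ w
    y = cohort.phenotype.to_numpy(dtype=float) if phenotype is None else np.asarray(phenotype)
    if score.std() == 0 or y.std() == 0:
        r2 = 0.0
    else:
        r2 = float(np.corrcoef(score, y)[0, 1] ** 2)
    return ScoreResult(score=score, weight_source="global", r_squared=r2)


def assign_folds(n: int, k: int, seed: int | None) -> np.ndarray:
    """Random balanced partition of n individuals into folds 1..k."""
    if k < 2:
        raise ConfigurationError(f"k must be >= 2, got {k}")
    if n < k:
        raise ConfigurationError(f"need n >= k, got n={n}, k={k}")
    rng = np.random.default_rng(seed)
    folds = np.arange(n) % k + 1
    rng.shuffle(folds)
    return folds


def cv_weights(
    cohort: CohortTable,
    k: int = 20,
    seed: int | None = 0,
    phenotype: np.ndarray | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-fold marginal regression weights.

    Individuals are partitioned into ``k`` seeded folds (reusing
    ``cohort.fold`` when already assigned).  For each fold, the weight of SNP
    j is the coefficient of a simple regression of the (transformed)
    phenotype on dosage j fitted on the *other* k-1 folds — marginal rather
    than joint fits, mirroring GWAS-derived weights for LD-independent SNPs.
    A training fold where a SNP is monomorphic gets weight 0 (logged).

    Returns (weights frame indexed by fold 1..k, columns snp_id; fold labels).
    """
    y = cohort.phenotype.to_numpy(dtype=float) if phenotype is None else np.asarray(phenotype)
    G = cohort.dosages.to_numpy(dtype=float)
    n, J = G.shape
    folds = cohort.fold if cohort.fold is not None else assign_folds(n, k, seed)
    fold_ids = np.unique(folds)
    W = np.zeros((fold_ids.size, J))
    n_zero = 0
    for i, f in enumerate(fold_ids):
        train = folds != f
        Gt, yt = G[train], y[train]
        gm = Gt.mean(axis=0)
        gv = ((Gt - gm) ** 2).sum(axis=0)
        zero = gv == 0
        n_zero += int(zero.sum())
        cov = ((Gt - gm) * (yt - yt.mean())[:, None]).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            W[i] = np.where(zero, 0.0, cov / gv)
    if n_zero:
        logger.info("cv_weights: %d fold x SNP cell(s) monomorphic in training; weight 0",
                    n_zero)
    return pd.DataFrame(W, index=fold_ids, columns=cohort.snp_ids), folds


def cv_score(
    cohort: CohortTable,
    k: int = 20,
    seed: int | None = 0,
    phenotype: np.ndarray | None = None,
) -> ScoreResult:
    """Out-of-fold genetic risk score: each individual scored with weights
    estimated on folds excluding them."""
    y = cohort.phenotype.to_numpy(dtype=float) if phenotype is None else np.asarray(phenotype)
    W, folds = cv_weights(cohort, k=k, seed=seed, phenotype=y)
    G = cohort.dosages.to_numpy(dtype=float)
    score = np.empty(len(y))
    for f in W.index:
        mask = folds == f
        score[mask] = G[mask] @ W.loc[f].to_numpy()
    r2 = 0.0 if score.std() == 0 or y.std() == 0 else float(np.corrcoef(score, y)[0, 1] ** 2)
    return ScoreResult(score=score, weight_source="fold-specific", r_squared=r2)


class CrossValidatedGRS(BaseEstimator, TransformerMixin):
    """scikit-learn-shaped wrapper: fit learns per-fold marginal weights,
    ``fit_transform`` returns out-of-fold scores, ``transform`` scores new
    dosage matrices with the pooled (mean-over-folds) weights.
    """

    def __init__(self, k: int = 20, random_state: int | None = 0):
        self.k = k
        self.random_state = random_state

    def fit(self, X, y):
        X = pd.DataFrame(X)
        cohort = CohortTable(dosages=X, phenotype=pd.Series(np.asarray(y, float)))
        self.fold_weights_, self.folds_ = cv_weights(
            cohort, k=self.k, seed=self.random_state)
        self.weights_ = self.fold_weights_.mean(axis=0).to_numpy()
        return self

    def fit_transform(self, X, y):
        self.fit(X, y)
        G = pd.DataFrame(X).to_numpy(dtype=float)
        score = np.empty(len(G))
        for f in self.fold_weights_.index:
            mask = self.folds_ == f
            score[mask] = G[mask] @ self.fold_weights_.loc[f].to_numpy()
        return score.reshape(-1, 1)

    def transform(self, X):
        G = pd.DataFrame(X).to_numpy(dtype=float)
        return (G @ self.weights_).reshape(-1, 1)


# ---------------------------------------------------------------------------
# variance explained from summary statistics


def variance_explained(beta, eaf) -> float:
    """Variance of a unit-variance phenotype explained by independent SNPs:
    ``sum_j 2 * eaf_j * (1 - eaf_j) * beta_j^2``.

    Assumes the phenotype is standardized (post-INT) and the SNPs are
    LD-independent.  SNPs with missing eaf are skipped with a warning.
    """
    beta = np.asarray(beta, dtype=float)
    eaf = np.asarray(eaf, dtype=float)
    ok = np.isfinite(eaf)
    if not ok.all():
        logger.warning("variance_explained: skipping %d SNP(s) with missing eaf",
                       int((~ok).sum()))
    return float(np.sum(2.0 * eaf[ok] * (1.0 - eaf[ok]) * beta[ok] ** 2))


# ---------------------------------------------------------------------------
# one-sample MR


def one_sample_mr(
    cohort: CohortTable,
    score: ScoreResult,
    outcome_type: str = "binary",
    exposure: np.ndarray | None = None,
    adjust_covariates: bool = True,
) -> MRResult:
    """One-sample MR using the genetic score as the instrument.

    The causal estimate is the ratio of the outcome-on-score coefficient to
    the exposure-on-score coefficient.  Binary outcomes use the log-odds from
    a logistic fit of outcome on score (plus covariates when present);
    quantitative outcomes use OLS.  The SE is first-order delta method
    treating the denominator as fixed — standard Wald-ratio practice, valid
    when the score-exposure association is strong.
    """
    if cohort.outcome is None:
        raise ConfigurationError("cohort has no outcome column")
    if outcome_type not in ("binary", "quantitative"):
        raise ConfigurationError(f"outcome_type must be binary|quantitative, got {outcome_type}")
    s = np.asarray(score.score, dtype=float)
    if s.std() == 0:
        raise ConfigurationError("score has zero variance; one-sample MR undefined")
    x = cohort.phenotype.to_numpy(dtype=float) if exposure is None else np.asarray(exposure)
    yout = cohort.outcome.to_numpy(dtype=float)

    cols = [s]
    if adjust_covariates and cohort.covariates is not None and len(cohort.covariates.columns):
        cols.append(cohort.covariates.to_numpy(dtype=float))
    design = sm.add_constant(np.column_stack(cols))

    den_fit = sm.OLS(x, design).fit()
    den = den_fit.params[1]
    if den == 0:
        raise ConfigurationError("exposure-on-score coefficient is zero")
    if outcome_type == "binary":
        num_fit = sm.Logit(yout, design).fit(disp=0)
    else:
        num_fit = sm.OLS(yout, design).fit()
    num, num_se = num_fit.params[1], num_fit.bse[1]

    beta = float(num / den)
    se = float(num_se / abs(den))
    pvalue = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0
    res = MRResult(method="one_sample", n_snp=len(cohort.snp_ids), beta=beta,
                   se=se, pvalue=pvalue)
    if outcome_type == "binary":
        res.with_or()
    return res
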