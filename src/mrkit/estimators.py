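"""Two-sample Mendelian randomization estimators and pleiotropy diagnostics.

All estimators consume per-SNP summary associations: exposure betas ``bx``
with SEs ``sx`` and outcome betas ``by`` with SEs ``sy`` for J harmonized,
approximately independent instruments.  They are written as scikit-learn
style estimators — ``fit(X, y, ...)`` with fitted attributes ending in an
underscore — so they compose with sklearn tooling; the module-level functions
(:func:`ivw`, :func:`egger`, ...) are thin wrappers that accept harmonized
instrument lists and return :class:`MRResult` records.

Methods
-------
IVW
    Inverse-variance-weighted estimate: zero-intercept weighted regression of
    by on bx with weights 1/sy^2; equivalently the precision-weighted mean of
    the per-SNP Wald ratios.  The multiplicative random-effects variant
    inflates the SE by sqrt(Q/(J-1)) when Cochran's Q exceeds its degrees of
    freedom, accommodating heterogeneity without changing the point estimate.
MREgger
    The same weighted regression with a free intercept.  Under the InSiDE
    condition (instrument strength independent of direct effects) the slope
    remains consistent in the presence of directional pleiotropy and the
    intercept estimates the average direct effect; a nonzero intercept is
    evidence of unbalanced horizontal pleiotropy.
WeightedMedian
    The weighted median of the per-SNP Wald ratios: consistent when valid
    instruments contribute more than half the total weight.
WeightedMode
    The mode of the inverse-variance-weighted kernel density of Wald ratios:
    consistent when the largest group of instruments with similar ratios is
    the valid one, even if they are a minority.
MRPresso
    A residual-sum-of-squares global pleiotropy test with per-SNP outlier
    detection by parametric simulation, outlier-corrected re-estimation, and
    a distortion test comparing the corrected and raw estimates.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import ConfigurationError, InsufficientInstrumentsError
from .harmonize import HarmonizedInstrument

Z95 = 1.959963984540054  # normal 97.5% quantile


# ---------------------------------------------------------------------------
# result containers


@dataclass
class MRResult:
    """A causal-effect estimate from one method.

    ``beta`` is the effect on the outcome per 1-SD increase in the exposure
    (log-odds for binary outcomes).  ``or_scale`` carries the exponentiated
    (OR, CI) triple when the outcome is binary.
    """

    method: str
    n_snp: int
    beta: float
    se: float
    pvalue: float
    ci_low: float = field(default=math.nan)
    ci_high: float = field(default=math.nan)
    cochran_q: float | None = None
    q_pvalue: float | None = None
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_pvalue: float | None = None
    or_scale: tuple[float, float, float] | None = None

    def __post_init__(self):
        if math.isnan(self.ci_low):
            self.ci_low = self.beta - Z95 * self.se
        if math.isnan(self.ci_high):
            self.ci_high = self.beta + Z95 * self.se

    def with_or(self) -> "MRResult":
        """Attach the odds-ratio-scale triple (for binary outcomes)."""
        self.or_scale = to_odds_ratio(self.beta, self.se)
        return self


@dataclass
class PressoResult:
    """Global RSS pleiotropy test, per-SNP outlier calls, corrected estimate."""

    rss_obs: float
    global_pvalue: float
    n_sim: int
    per_snp_outlier_p: list[float]
    outlier_ids: list[str]
    corrected: MRResult | None
    distortion_pvalue: float | None


# ---------------------------------------------------------------------------
# shared validation


def _as_arrays(X, y, se_out, se_exp=None, min_snp=2, need_se_exp=False, method=""):
    bx = np.asarray(X, dtype=float).reshape(-1)
    by = np.asarray(y, dtype=float).reshape(-1)
    if se_out is None:
        raise ConfigurationError(f"{method}: se_out (outcome SEs) is required")
    sy = np.asarray(se_out, dtype=float).reshape(-1)
    if not (bx.shape == by.shape == sy.shape):
        raise ConfigurationError(f"{method}: X, y, se_out must have equal length")
    if bx.size < min_snp:
        raise InsufficientInstrumentsError(
            f"{method} requires >= {min_snp} instruments, got {bx.size}")
    if np.any(sy <= 0) or not np.all(np.isfinite(np.c_[bx, by, sy])):
        raise ConfigurationError(f"{method}: betas/SEs must be finite with se_out > 0")
    sx = None
    if se_exp is not None:
        sx = np.asarray(se_exp, dtype=float).reshape(-1)
        if sx.shape != bx.shape or np.any(sx <= 0):
            raise ConfigurationError(f"{method}: se_exp must match X with se_exp > 0")
    elif need_se_exp:
        raise ConfigurationError(f"{method}: se_exp (exposure SEs) is required")
    return bx, by, sy, sx


def _unpack(instruments: Iterable[HarmonizedInstrument]):
    hs = [h for h in instruments if not h.dropped]
    bx = np.array([h.beta_exp for h in hs])
    by = np.array([h.beta_out for h in hs])
    sx = np.array([h.se_exp for h in hs])
    sy = np.array([h.se_out for h in hs])
    ids = [h.snp_id for h in hs]
    return bx, by, sx, sy, ids


# ---------------------------------------------------------------------------
# IVW


def _ivw_core(bx, by, w):
    """Zero-intercept weighted least squares: slope, fixed-effect SE, Cochran Q."""
    den = float(np.sum(w * bx * bx))
    beta = float(np.sum(w * bx * by)) / den
    se_fixed = den ** -0.5
    q = float(np.sum(w * (by - beta * bx) ** 2))
    return beta, se_fixed, q


class IVW(BaseEstimator):
    """Inverse-variance-weighted MR estimator.

    Parameters
    ----------
    model : {"multiplicative_random_effects", "fixed"}
        Fixed effects uses the analytic zero-intercept WLS standard error;
        multiplicative random effects (the default) multiplies it by
        ``max(1, sqrt(Q / (J - 1)))`` so between-SNP heterogeneity widens the
        CI but never narrows it below the fixed-effect SE.

    Attributes
    ----------
    beta_, se_, pvalue_, ci_low_, ci_high_ : float
    cochran_q_, q_pvalue_ : float
        Heterogeneity of the per-SNP Wald ratios (df = J - 1).
    n_snp_ : int
    """

    def __init__(self, model: str = "multiplicative_random_effects"):
        self.model = model

    def fit(self, X, y, se_out=None):
        if self.model not in ("fixed", "multiplicative_random_effects"):
            raise ConfigurationError(f"unknown IVW model {self.model!r}")
        bx, by, sy, _ = _as_arrays(X, y, se_out, min_snp=2, method="IVW")
        w = sy ** -2.0
        beta, se_fixed, q = _ivw_core(bx, by, w)
        df = bx.size - 1
        se = se_fixed
        if self.model == "multiplicative_random_effects":
            se = se_fixed * max(1.0, math.sqrt(q / df))
        self.n_snp_ = int(bx.size)
        self.beta_, self.se_ = beta, float(se)
        self.cochran_q_ = q
        self.q_pvalue_ = float(stats.chi2.sf(q, df))
        self.pvalue_ = float(2.0 * stats.norm.sf(abs(beta) / se)) if se > 0 else 0.0
        self.ci_low_, self.ci_high_ = beta - Z95 * se, beta + Z95 * se
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float).reshape(-1)
        return self.beta_ * X


# ---------------------------------------------------------------------------
# MR-Egger


class MREgger(BaseEstimator):
    """MR-Egger regression: WLS of outcome betas on exposure betas with intercept.

    Requires instruments oriented so every exposure beta is positive (the
    harmonization step's convention); otherwise the intercept has no
    pleiotropy interpretation.  SEs for slope and intercept are inflated by
    ``max(1, sqrt(RSS / (J - 2)))`` (multiplicative random effects); the
    intercept p-value uses a t distribution with J-2 df, the slope a normal.

    Attributes
    ----------
    beta_, se_, pvalue_ : slope (causal estimate)
    intercept_, intercept_se_, intercept_pvalue_ : average directional pleiotropy
    """

    def fit(self, X, y, se_out=None):
        bx, by, sy, _ = _as_arrays(X, y, se_out, min_snp=3, method="MR-Egger")
        if np.ptp(bx) == 0:
            raise ConfigurationError("MR-Egger: zero variance in exposure betas (collinear)")
        w = sy ** -2.0
        # weighted least squares with intercept, solved in closed form
        sw = w.sum()
        xbar = np.sum(w * bx) / sw
        ybar = np.sum(w * by) / sw
        sxx = np.sum(w * (bx - xbar) ** 2)
        sxy = np.sum(w * (bx - xbar) * (by - ybar))
        slope = float(sxy / sxx)
        intercept = float(ybar - slope * xbar)
        resid = by - intercept - slope * bx
        df = bx.size - 2
        rss = float(np.sum(w * resid ** 2))
        scale = max(1.0, math.sqrt(rss / df))
        se_slope = float(math.sqrt(1.0 / sxx)) * scale
        se_icpt = float(math.sqrt(1.0 / sw + xbar ** 2 / sxx)) * scale
        self.n_snp_ = int(bx.size)
        self.beta_, self.se_ = slope, se_slope
        self.pvalue_ = float(2.0 * stats.norm.sf(abs(slope) / se_slope))
        self.ci_low_, self.ci_high_ = slope - Z95 * se_slope, slope + Z95 * se_slope
        self.intercept_, self.intercept_se_ = intercept, se_icpt
        self.intercept_pvalue_ = float(2.0 * stats.t.sf(abs(intercept) / se_icpt, df))
        self.rss_, self.scale_ = rss, scale
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float).reshape(-1)
        return self.intercept_ + self.beta_ * X


# ---------------------------------------------------------------------------
# weighted median


def _weighted_median(theta, w):
    """Weighted median with linear interpolation of the cumulative weight.

    Cumulative standardized weight of the j-th ordered ratio is
    ``(S_j - w_j/2) / S_total``; the estimate interpolates theta at 0.5.
    """
    order = np.argsort(theta)
    th, wo = np.asarray(theta)[order], np.asarray(w)[order]
    p = (np.cumsum(wo) - 0.5 * wo) / wo.sum()
    return float(np.interp(0.5, p, th))


class WeightedMedian(BaseEstimator):
    """Weighted-median MR estimator with parametric-bootstrap SE.

    The per-SNP Wald ratios are weighted by their inverse variance
    (first-order delta method).  The SE is the standard deviation of the
    estimator over ``n_boot`` parametric resamples drawing each (bx, by) from
    its normal sampling distribution, which is why exposure SEs are required.
    """

    def __init__(self, n_boot: int = 1000, random_state: int | None = 0):
        self.n_boot = n_boot
        self.random_state = random_state

    @staticmethod
    def _estimate(bx, by, sy):
        theta = by / bx
        w = (sy / np.abs(bx)) ** -2.0
        return _weighted_median(theta, w)

    def fit(self, X, y, se_out=None, se_exp=None):
        bx, by, sy, sx = _as_arrays(X, y, se_out, se_exp, min_snp=3,
                                    need_se_exp=True, method="weighted median")
        self.beta_ = self._estimate(bx, by, sy)
        rng = np.random.default_rng(self.random_state)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            bxb = rng.normal(bx, sx)
            byb = rng.normal(by, sy)
            bxb[bxb == 0] = np.finfo(float).tiny  # guard: ratio undefined at 0
            boots[b] = self._estimate(bxb, byb, sy)
        self.se_ = float(boots.std(ddof=1))
        self.n_snp_ = int(bx.size)
        self.pvalue_ = float(2.0 * stats.norm.sf(abs(self.beta_) / self.se_))
        self.ci_low_, self.ci_high_ = self.beta_ - Z95 * self.se_, self.beta_ + Z95 * self.se_
        return self


# ---------------------------------------------------------------------------
# weighted mode


class WeightedMode(BaseEstimator):
    """Mode-based MR estimator (inverse-variance-weighted kernel density).

    The causal estimate is the argmax over a dense grid of the weighted
    normal-kernel density of the per-SNP Wald ratios.  Bandwidth is
    ``phi`` times a modified Silverman rule computed on the ratios:
    ``0.9 * min(weighted SD, MAD * 1.4826) * J^(-1/5)``.  Grid: 512 points
    spanning ``[min ratio - 3h, max ratio + 3h]``; an exact tie in density
    returns the lower mode (deterministic).
    """

    GRID_POINTS = 512

    def __init__(self, phi: float = 1.0, n_boot: int = 1000,
                 random_state: int | None = 0):
        self.phi = phi
        self.n_boot = n_boot
        self.random_state = random_state

    @classmethod
    def _estimate(cls, bx, by, sy, phi):
        theta = by / bx
        w = (sy / np.abs(bx)) ** -2.0
        w = w / w.sum()
        mu = float(np.sum(w * theta))
        sd = float(math.sqrt(np.sum(w * (theta - mu) ** 2)))
        mad = float(np.median(np.abs(theta - np.median(theta)))) * 1.4826
        s = 0.9 * min(sd, mad) * theta.size ** (-1.0 / 5.0) if min(sd, mad) > 0 else 0.0
        h = phi * s
        if h <= 0:
            # degenerate spread (e.g. all ratios identical): weighted median of point mass
            return _weighted_median(theta, w)
        grid = np.linspace(theta.min() - 3 * h, theta.max() + 3 * h, cls.GRID_POINTS)
        dens = np.sum(w * np.exp(-0.5 * ((grid[:, None] - theta[None, :]) / h) ** 2), axis=1)
        return float(grid[int(np.argmax(dens))])  # argmax takes first (lower) tie

    def fit(self, X, y, se_out=None, se_exp=None):
        if not self.phi > 0:
            raise ConfigurationError(f"phi must be > 0, got {self.phi}")
        bx, by, sy, sx = _as_arrays(X, y, se_out, se_exp, min_snp=3,
                                    need_se_exp=True, method="weighted mode")
        self.beta_ = self._estimate(bx, by, sy, self.phi)
        rng = np.random.default_rng(self.random_state)
        boots = np.empty(self.n_boot)
        for b in range(self.n_boot):
            bxb = rng.normal(bx, sx)
            byb = rng.normal(by, sy)
            bxb[bxb == 0] = np.finfo(float).tiny
            boots[b] = self._estimate(bxb, byb, sy, self.phi)
        self.se_ = float(boots.std(ddof=1))
        self.n_snp_ = int(bx.size)
        self.pvalue_ = float(2.0 * stats.norm.sf(abs(self.beta_) / self.se_))
        self.ci_low_, self.ci_high_ = self.beta_ - Z95 * self.se_, self.beta_ + Z95 * self.se_
        return self


# ---------------------------------------------------------------------------
# MR-PRESSO


def _loo_ivw(bx, by, w):
    """Leave-one-out IVW estimates, vectorized over SNPs (and sims if 2-D).

    For inputs of shape (..., J) returns theta_{-j} of the same shape.
    """
    num = np.sum(w * bx * by, axis=-1, keepdims=True)
    den = np.sum(w * bx * bx, axis=-1, keepdims=True)
    return (num - w * bx * by) / (den - w * bx * bx)


class MRPresso(BaseEstimator):
    """Pleiotropy residual-sum-of-squares outlier test with corrected estimate.

    The observed statistic is ``RSS = sum_j w_j (by_j - theta_{-j} bx_j)^2``
    with ``theta_{-j}`` the leave-one-out IVW estimate and ``w_j = 1/sy_j^2``.
    Its null distribution is built by parametric simulation: each replicate
    redraws ``bx* ~ N(bx, sx)`` and ``by* ~ N(theta_{-j} bx_j, sy)`` and
    recomputes RSS by the same leave-one-out procedure.  Per-SNP outlier
    p-values compare each observed residual term with its simulated
    distribution, Bonferroni-corrected at ``outlier_alpha``.  The corrected
    estimate refits IVW on non-outliers; the distortion test compares the
    observed shift (corrected vs raw) with shifts from removing equally many
    randomly chosen SNPs.
    """

    def __init__(self, n_sim: int = 1000, outlier_alpha: float = 0.05,
                 ivw_model: str = "multiplicative_random_effects",
                 random_state: int | None = 0):
        self.n_sim = n_sim
        self.outlier_alpha = outlier_alpha
        self.ivw_model = ivw_model
        self.random_state = random_state

    def fit(self, X, y, se_out=None, se_exp=None, snp_ids: Sequence[str] | None = None):
        if self.n_sim < 100:
            raise ConfigurationError("MR-PRESSO needs n_sim >= 100")
        bx, by, sy, sx = _as_arrays(X, y, se_out, se_exp, min_snp=4,
                                    need_se_exp=True, method="MR-PRESSO")
        J = bx.size
        ids = list(snp_ids) if snp_ids is not None else [f"snp{j}" for j in range(J)]
        w = sy ** -2.0

        theta_loo = _loo_ivw(bx, by, w)
        res_obs = w * (by - theta_loo * bx) ** 2
        self.rss_obs_ = float(res_obs.sum())

        rng = np.random.default_rng(self.random_state)
        bx_sim = rng.normal(bx, sx, size=(self.n_sim, J))
        by_sim = rng.normal(theta_loo * bx, sy, size=(self.n_sim, J))
        theta_sim = _loo_ivw(bx_sim, by_sim, w)
        res_sim = w * (by_sim - theta_sim * bx_sim) ** 2  # (n_sim, J)
        rss_sim = res_sim.sum(axis=1)

        self.global_pvalue_ = float(
            (1 + np.sum(rss_sim >= self.rss_obs_)) / (self.n_sim + 1))
        per_snp = (1 + np.sum(res_sim >= res_obs[None, :], axis=0)) / (self.n_sim + 1)
        self.per_snp_outlier_p_ = per_snp.tolist()
        outlier_mask = per_snp < self.outlier_alpha / J  # Bonferroni
        self.outlier_mask_ = outlier_mask
        self.outlier_ids_ = [ids[j] for j in np.flatnonzero(outlier_mask)]
        self.n_snp_ = int(J)

        keep = ~outlier_mask
        if keep.sum() < 2:
            self.corrected_ = None
            self.distortion_pvalue_ = None
            self.all_outliers_ = True
            return self
        self.all_outliers_ = False

        raw = IVW(model=self.ivw_model).fit(bx, by, se_out=sy)
        corr = IVW(model=self.ivw_model).fit(bx[keep], by[keep], se_out=sy[keep])
        self.raw_beta_ = raw.beta_
        self.corrected_ = MRResult(
            method="presso_corrected", n_snp=int(keep.sum()),
            beta=corr.beta_, se=corr.se_, pvalue=corr.pvalue_,
            cochran_q=corr.cochran_q_, q_pvalue=corr.q_pvalue_,
        )

        n_out = int(outlier_mask.sum())
        if n_out == 0:
            self.distortion_pvalue_ = None
        else:
            obs_shift = abs(raw.beta_ - corr.beta_)
            shifts = np.empty(self.n_sim)
            idx = np.arange(J)
            for b in range(self.n_sim):
                drop = rng.choice(idx, size=n_out, replace=False)
                m = np.ones(J, bool)
                m[drop] = False
                beta_b, _, _ = _ivw_core(bx[m], by[m], w[m])
                shifts[b] = abs(raw.beta_ - beta_b)
            self.distortion_pvalue_ = float(
                (1 + np.sum(shifts >= obs_shift)) / (self.n_sim + 1))
        return self

    def result(self) -> PressoResult:
        if getattr(self, "all_outliers_", False):
            raise InsufficientInstrumentsError(
                "MR-PRESSO flagged (almost) all SNPs as outliers; corrected estimate undefined")
        return PressoResult(
            rss_obs=self.rss_obs_, global_pvalue=self.global_pvalue_,
            n_sim=self.n_sim, per_snp_outlier_p=self.per_snp_outlier_p_,
            outlier_ids=self.outlier_ids_, corrected=self.corrected_,
            distortion_pvalue=self.distortion_pvalue_,
        )


# ---------------------------------------------------------------------------
# presentation-scale helpers


def to_odds_ratio(beta: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate to (OR, 95% CI low, 95% CI high)."""
    if not se > 0:
        raise ConfigurationError(f"se must be > 0, got {se}")
    return (math.exp(beta), math.exp(beta - Z95 * se), math.exp(beta + Z95 * se))


def compare_estimates(b1: float, se1: float, b2: float, se2: float) -> tuple[float, float]:
    """Two-sided z test of heterogeneity between two independent estimates."""
    if not (se1 > 0 and se2 > 0):
        raise ConfigurationError("standard errors must be > 0")
    z = (b1 - b2) / math.hypot(se1, se2)
    return z, float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# function wrappers over the estimator classes


def ivw(instruments: Iterable[HarmonizedInstrument],
        model: str = "multiplicative_random_effects") -> MRResult:
    """IVW causal estimate from harmonized instruments."""
    bx, by, sx, sy, _ = _unpack(instruments)
    est = IVW(model=model).fit(bx, by, se_out=sy)
    name = "ivw_fixed" if model == "fixed" else "ivw_mre"
    return MRResult(method=name, n_snp=est.n_snp_, beta=est.beta_, se=est.se_,
                    pvalue=est.pvalue_, cochran_q=est.cochran_q_,
                    q_pvalue=est.q_pvalue_)


def egger(instruments: Iterable[HarmonizedInstrument]) -> MRResult:
    """MR-Egger slope with the intercept pleiotropy test."""
    bx, by, sx, sy, _ = _unpack(instruments)
    est = MREgger().fit(bx, by, se_out=sy)
    return MRResult(method="egger", n_snp=est.n_snp_, beta=est.beta_, se=est.se_,
                    pvalue=est.pvalue_, egger_intercept=est.intercept_,
                    intercept_se=est.intercept_se_,
                    intercept_pvalue=est.intercept_pvalue_)


def weighted_median(instruments: Iterable[HarmonizedInstrument],
                    n_boot: int = 1000, seed: int | None = 0) -> MRResult:
    """Weighted-median causal estimate (bootstrap SE)."""
    bx, by, sx, sy, _ = _unpack(instruments)
    est = WeightedMedian(n_boot=n_boot, random_state=seed).fit(
        bx, by, se_out=sy, se_exp=sx)
    return MRResult(method="weighted_median", n_snp=est.n_snp_, beta=est.beta_,
                    se=est.se_, pvalue=est.pvalue_)


def weighted_mode(instruments: Iterable[HarmonizedInstrument], phi: float = 1.0,
                  n_boot: int = 1000, seed: int | None = 0) -> MRResult:
    """Weighted-mode causal estimate (bootstrap SE)."""
    bx, by, sx, sy, _ = _unpack(instruments)
    est = WeightedMode(phi=phi, n_boot=n_boot, random_state=seed).fit(
        bx, by, se_out=sy, se_exp=sx)
    return MRResult(method="weighted_mode", n_snp=est.n_snp_, beta=est.beta_,
                    se=est.se_, pvalue=est.pvalue_)


def mr_presso(instruments: Iterable[HarmonizedInstrument], n_sim: int = 1000,
              outlier_alpha: float = 0.05, seed: int | None = 0) -> PressoResult:
    """MR-PRESSO global test, outlier detection and corrected estimate."""
    bx, by, sx, sy, ids = _unpack(instruments)
    est = MRPresso(n_sim=n_sim, outlier_alpha=outlier_alpha,
                   random_state=seed).fit(bx, by, se_out=sy, se_exp=sx, snp_ids=ids)
    return est.result()
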