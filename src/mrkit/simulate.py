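"""Synthetic two-sample GWAS and individual-level cohorts with known truth.

The generator emulates the statistical structure the two-sample design
assumes: J independent instruments with per-allele exposure effects drawn
from the 0.02-0.41 SD range of a large heel-bone-density GWAS, exposure and
outcome associations estimated in non-overlapping cohorts (independent
noise), a linear causal effect theta on the outcome mean or log-odds, and
per-SNP horizontal-pleiotropy effects alpha_j under balanced, directional,
or InSiDE-violating regimes.  Every dataset carries its generating truth so
recovery tests never re-derive it.

Emitted standard errors are the analytic sampling SEs for the stated sample
sizes: for a unit-variance quantitative trait ``se = 1/sqrt(2 p (1-p) n)``,
and for a case-control trait the score-test log-OR approximation
``se = sqrt((1/n_cases + 1/n_controls) / (2 p (1-p)))``.

One master seed drives everything; per-stage streams are split with
``numpy.random.SeedSequence.spawn`` in a fixed order (maf/effects, exposure
noise, outcome noise, allele labelling, cohort) so each stage is
independently reproducible.
"""
from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .grs import CohortTable
from .sumstats import COMPLEMENT, SumstatsTable, table_from_arrays, write_sumstats

#: allele pairs that are not strand-ambiguous (exclude A/T and C/G)
_NONPALINDROMIC_PAIRS = [
    ("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
    ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T"),
]

GENOME_WIDE_P = 5e-8


@dataclass(frozen=True)
class Pleiotropy:
    """Horizontal-pleiotropy regime for the direct SNP-outcome effects alpha_j.

    ``frac`` is the fraction of instruments carrying a nonzero alpha (invalid
    instruments); the rest are valid.  ``corr`` correlates alpha with
    instrument strength, violating the InSiDE condition MR-Egger needs.
    """

    kind: str = "none"  # none | balanced | directional | inside_violating
    mu: float = 0.0
    sigma: float = 0.0
    frac: float = 1.0
    corr: float = 0.0

    @classmethod
    def none(cls) -> "Pleiotropy":
        return cls()

    @classmethod
    def balanced(cls, sigma: float = 0.01, frac: float = 1.0) -> "Pleiotropy":
        """Zero-mean direct effects: InSiDE holds, IVW remains consistent on average."""
        return cls(kind="balanced", sigma=sigma, frac=frac)

    @classmethod
    def directional(cls, mu: float = 0.02, sigma: float = 0.005,
                    frac: float = 1.0) -> "Pleiotropy":
        """Common-direction direct effects: biases IVW by the mean-alpha term."""
        return cls(kind="directional", mu=mu, sigma=sigma, frac=frac)

    @classmethod
    def inside_violating(cls, corr: float = 0.5, sigma: float = 0.01,
                         frac: float = 1.0) -> "Pleiotropy":
        """Direct effects correlated with instrument strength (breaks MR-Egger)."""
        return cls(kind="inside_violating", sigma=sigma, corr=corr, frac=frac)

    def draw(self, beta_x: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        J = beta_x.size
        alpha = np.zeros(J)
        if self.kind == "none":
            return alpha
        n_aff = int(round(self.frac * J))
        affected = rng.choice(J, size=n_aff, replace=False)
        if self.kind == "balanced":
            alpha[affected] = rng.normal(0.0, self.sigma, n_aff)
        elif self.kind == "directional":
            alpha[affected] = rng.normal(self.mu, self.sigma, n_aff)
        elif self.kind == "inside_violating":
            bz = (beta_x - beta_x.mean()) / (beta_x.std() or 1.0)
            eps = rng.normal(0.0, 1.0, J)
            full = self.sigma * (self.corr * bz + math.sqrt(1 - self.corr ** 2) * eps)
            alpha[affected] = full[affected]
        else:
            raise ConfigurationError(f"unknown pleiotropy kind {self.kind!r}")
        return alpha


@dataclass(frozen=True)
class SimConfig:
    """Generating parameters for a synthetic two-sample MR study.

    Defaults mirror the discovery-scale design the package targets:
    J=235 independent instruments, per-allele exposure effects 0.02-0.41 SD,
    an exposure GWAS of n=116,501, and a binary outcome with
    26,676 cases / 132,532 controls.  ``theta`` is the causal effect of a
    1-SD exposure increase on the outcome mean (quantitative) or log-odds
    (binary).
    """

    J: int = 235
    maf_range: tuple[float, float] = (0.05, 0.5)
    beta_exp_range: tuple[float, float] = (0.02, 0.41)
    n_exposure: int = 116_501
    n_outcome: int = 133_010
    n_cases: int = 26_676
    n_controls: int = 132_532
    theta: float = 0.0
    pleiotropy: Pleiotropy = field(default_factory=Pleiotropy.none)
    outcome_type: str = "binary"
    prevalence: float = 0.1
    n_cohort: int = 20_000
    seed: int = 0
    ensure_discoverable: bool = True

    def __post_init__(self):
        if self.J < 1:
            raise ConfigurationError("J must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("maf_range must lie within (0, 0.5]")
        if self.outcome_type not in ("quantitative", "binary"):
            raise ConfigurationError("outcome_type must be quantitative|binary")
        if not (0 < self.prevalence < 1):
            raise ConfigurationError("prevalence must be in (0,1)")
        for name in ("n_exposure", "n_outcome", "n_cases", "n_controls", "n_cohort"):
            if getattr(self, name) < 2:
                raise ConfigurationError(f"{name} must be >= 2")


@dataclass
class SimTruth:
    """A simulated dataset paired with its generating parameters."""

    config: SimConfig
    beta_x_true: np.ndarray
    alpha: np.ndarray
    maf: np.ndarray
    exposure: SumstatsTable
    outcome: SumstatsTable
    #: sign of each outcome record's effect allele relative to the
    #: exposure-increasing allele (+1 aligned, -1 relabelled)
    orient_out: np.ndarray | None = None
    cohort: CohortTable | None = None

    @property
    def theta(self) -> float:
        return self.config.theta

    def save(self, outdir) -> None:
        """Write the canonical sumstats tables plus a JSON truth sidecar."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_sumstats(self.exposure, outdir / "exposure.tsv")
        write_sumstats(self.outcome, outdir / "outcome.tsv")
        truth = {
            "config": _config_dict(self.config),
            "beta_x_true": self.beta_x_true.tolist(),
            "alpha": self.alpha.tolist(),
            "maf": self.maf.tolist(),
        }
        (outdir / "truth.json").write_text(json.dumps(truth, indent=1))
        if self.cohort is not None:
            frame = self.cohort.dosages.copy()
            frame["phenotype"] = self.cohort.phenotype.to_numpy()
            if self.cohort.sex is not None:
                frame["sex"] = self.cohort.sex.to_numpy()
            if self.cohort.outcome is not None:
                frame["outcome"] = self.cohort.outcome.to_numpy()
            if self.cohort.covariates is not None:
                for c in self.cohort.covariates.columns:
                    frame[c] = self.cohort.covariates[c].to_numpy()
            frame.to_csv(outdir / "cohort.tsv", sep="\t", index=False)


def _config_dict(config: SimConfig) -> dict:
    d = dataclasses.asdict(config)
    d["pleiotropy"] = dataclasses.asdict(config.pleiotropy)
    return d


def se_quantitative(maf: np.ndarray, n: int) -> np.ndarray:
    """Sampling SE of a per-allele effect on a unit-variance trait."""
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def se_binary(maf: np.ndarray, n_cases: int, n_controls: int) -> np.ndarray:
    """Score-test approximation to the log-OR SE in a case-control GWAS."""
    return np.sqrt((1.0 / n_cases + 1.0 / n_controls) / (2.0 * maf * (1.0 - maf)))


def _two_sided_p(z: np.ndarray) -> np.ndarray:
    from scipy import stats

    # floor at the smallest positive double: p must stay in (0, 1]
    return np.maximum(2.0 * stats.norm.sf(np.abs(z)), np.finfo(float).tiny)


def simulate_two_sample(config: SimConfig) -> SimTruth:
    """Draw a complete synthetic two-sample summary-statistics dataset.

    Exposure records are emitted on the exposure-increasing allele; outcome
    records are randomly relabelled (allele swap and/or strand complement)
    so the harmonization stage is genuinely exercised.  When
    ``ensure_discoverable`` is set (default), (maf, beta) pairs are redrawn
    until the expected association z-score clears the genome-wide threshold
    with margin, mimicking a discovered instrument set whose members rarely
    fall below significance in the emitted data.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_par, rng_exp, rng_out, rng_lab, _rng_cohort = (
        np.random.default_rng(s) for s in ss.spawn(5))

    J = config.J
    maf = rng_par.uniform(*config.maf_range, J)
    beta_x = rng_par.uniform(*config.beta_exp_range, J)
    if config.ensure_discoverable:
        # z for p=5e-8 is ~5.45; require expected z > 7.5 so emitted hits
        # rarely drop below the discovery threshold
        for _ in range(1000):
            z_exp = beta_x / se_quantitative(maf, config.n_exposure)
            weak = z_exp <= 7.5
            if not weak.any():
                break
            maf[weak] = rng_par.uniform(*config.maf_range, int(weak.sum()))
            beta_x[weak] = rng_par.uniform(*config.beta_exp_range, int(weak.sum()))

    alpha = config.pleiotropy.draw(beta_x, rng_par)

    # exposure side
    se_x = se_quantitative(maf, config.n_exposure)
    bhat_x = rng_exp.normal(beta_x, se_x)
    p_x = _two_sided_p(bhat_x / se_x)

    # outcome side (non-overlapping cohort: independent noise stream)
    by_true = config.theta * beta_x + alpha
    if config.outcome_type == "binary":
        se_y = se_binary(maf, config.n_cases, config.n_controls)
        n_out = np.full(J, config.n_cases + config.n_controls, float)
    else:
        se_y = se_quantitative(maf, config.n_outcome)
        n_out = np.full(J, config.n_outcome, float)
    bhat_y = rng_out.normal(by_true, se_y)
    p_y = _two_sided_p(bhat_y / se_y)

    snp_id = np.array([f"rs{j + 1}" for j in range(J)])
    chrom = np.array([str(j % 22 + 1) for j in range(J)])
    pos = np.array([10_000_000 + (j // 22) * 2_000_000 for j in range(J)])
    pair_idx = rng_lab.integers(0, len(_NONPALINDROMIC_PAIRS), J)
    ea = np.array([_NONPALINDROMIC_PAIRS[i][0] for i in pair_idx])
    oa = np.array([_NONPALINDROMIC_PAIRS[i][1] for i in pair_idx])

    exposure = table_from_arrays(
        snp_id, chrom, pos, ea, oa, bhat_x, se_x, p_x, eaf=maf,
        n=np.full(J, config.n_exposure, float),
        trait_label="exposure", trait_type="quantitative", units="SD")

    # random relabelling of the outcome records
    swap = rng_lab.random(J) < 0.5
    strand = rng_lab.random(J) < 0.5
    ea_o, oa_o = ea.copy(), oa.copy()
    b_o, eaf_o = bhat_y.copy(), maf.copy()
    orient = np.ones(J)
    ea_o[swap], oa_o[swap] = oa[swap], ea[swap]
    b_o[swap] *= -1.0
    eaf_o[swap] = 1.0 - eaf_o[swap]
    orient[swap] = -1.0
    for j in np.flatnonzero(strand):
        ea_o[j], oa_o[j] = COMPLEMENT[ea_o[j]], COMPLEMENT[oa_o[j]]
    outcome = table_from_arrays(
        snp_id, chrom, pos, ea_o, oa_o, b_o, se_y, p_y, eaf=eaf_o, n=n_out,
        trait_label="outcome", trait_type=config.outcome_type,
        units="log-odds" if config.outcome_type == "binary" else "SD")

    return SimTruth(config=config, beta_x_true=beta_x, alpha=alpha, maf=maf,
                    exposure=exposure, outcome=outcome, orient_out=orient)


def inject_outliers(truth: SimTruth, ids: Sequence[str],
                    alpha_size: float) -> SimTruth:
    """Add ``alpha_size * se_Yj`` of directional pleiotropy to chosen SNPs.

    The shift is applied on the exposure-increasing-allele orientation (so a
    positive ``alpha_size`` biases the harmonized Wald ratio upward) and the
    recorded truth ``alpha`` is updated.  Exposure records are untouched.
    """
    import dataclasses as _dc

    idx = {r.snp_id: j for j, r in enumerate(truth.outcome.records)}
    unknown = [i for i in ids if i not in idx]
    if unknown:
        raise ConfigurationError(f"unknown snp_id(s): {unknown}")
    records = list(truth.outcome.records)
    alpha = truth.alpha.copy()
    for snp in ids:
        j = idx[snp]
        rec = records[j]
        sign = truth.orient_out[j] if truth.orient_out is not None else 1.0
        shift = alpha_size * rec.se
        records[j] = _dc.replace(rec, beta=rec.beta + sign * shift)
        alpha[j] += shift
    outcome = SumstatsTable(records, trait_label=truth.outcome.trait_label,
                            trait_type=truth.outcome.trait_type,
                            units=truth.outcome.units)
    return SimTruth(config=truth.config, beta_x_true=truth.beta_x_true,
                    alpha=alpha, maf=truth.maf, exposure=truth.exposure,
                    outcome=outcome, orient_out=truth.orient_out,
                    cohort=truth.cohort)


def simulate_cohort(config: SimConfig, h2_score: float = 0.139) -> tuple[CohortTable, SimTruth]:
    """Individual-level cohort for the one-sample MR / GRS stages.

    Dosages are Binomial(2, maf); the quantitative exposure is the true
    allele score plus Gaussian noise scaled so the score explains
    ``h2_score`` of the exposure variance.  The phenotype column adds linear
    covariate effects (age, sex, height, weight) on top of the exposure so
    the residualize-and-transform stage has real work to do.  A binary
    outcome is drawn from a logistic model with per-1-SD-exposure log-odds
    ``config.theta`` at the configured baseline prevalence.
    """
    if not 0 < h2_score < 1:
        raise ConfigurationError("h2_score must be in (0,1)")
    ss = np.random.SeedSequence(config.seed)
    *_, rng = (np.random.default_rng(s) for s in ss.spawn(5))

    J, n = config.J, config.n_cohort
    maf = rng.uniform(*config.maf_range, J)
    beta_x = rng.uniform(*config.beta_exp_range, J)
    G = rng.binomial(2, maf, size=(n, J)).astype(float)

    g_eff = G @ beta_x
    var_g = float(np.sum(2.0 * maf * (1.0 - maf) * beta_x ** 2))
    noise_sd = math.sqrt(var_g * (1.0 - h2_score) / h2_score)
    exposure_raw = g_eff + rng.normal(0.0, noise_sd, n)
    total_sd = math.sqrt(var_g / h2_score)
    exposure_sd = (exposure_raw - exposure_raw.mean()) / total_sd  # SD units

    age = rng.normal(57.0, 8.0, n)
    sex = rng.integers(0, 2, n).astype(float)
    height = rng.normal(169.0, 9.0, n) + 7.0 * sex
    weight = rng.normal(78.0, 14.0, n) + 6.0 * sex
    covariates = pd.DataFrame({
        "age": age, "age2": age ** 2, "height": height, "weight": weight,
    })
    # observed phenotype in natural units: 1 SD of the trait = 0.14
    pheno = (0.54 + 0.14 * exposure_sd + 0.004 * (age - 57.0)
             + 0.0006 * (height - 169.0) + 0.0008 * (weight - 78.0)
             + rng.normal(0.0, 0.002, n))

    logit0 = math.log(config.prevalence / (1.0 - config.prevalence))
    p_case = 1.0 / (1.0 + np.exp(-(logit0 + config.theta * exposure_sd)))
    outcome = (rng.random(n) < p_case).astype(float)

    cohort = CohortTable(
        dosages=pd.DataFrame(G, columns=[f"rs{j + 1}" for j in range(J)]),
        phenotype=pd.Series(pheno, name="phenotype"),
        covariates=covariates,
        sex=pd.Series(sex, name="sex"),
        outcome=pd.Series(outcome, name="outcome"),
    )
    truth = SimTruth(config=config, beta_x_true=beta_x, alpha=np.zeros(J),
                     maf=maf, exposure=table_from_arrays(
                         np.array([f"rs{j + 1}" for j in range(J)]),
                         np.array(["1"] * J),
                         np.arange(1, J + 1) * 1_000_000,
                         np.array(["A"] * J), np.array(["G"] * J),
                         beta_x, se_quantitative(maf, n),
                         np.full(J, 1e-10), eaf=maf,
                         trait_label="exposure", units="SD"),
                     outcome=table_from_arrays(
                         np.array([f"rs{j + 1}" for j in range(J)]),
                         np.array(["1"] * J),
                         np.arange(1, J + 1) * 1_000_000,
                         np.array(["A"] * J), np.array(["G"] * J),
                         np.zeros(J), np.ones(J), np.ones(J),
                         trait_label="outcome", trait_type="binary"),
                     cohort=cohort)
    return cohort, truth
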