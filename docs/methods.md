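# Methods

This note records the statistical model behind each stage, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that make results reproducible.

## The two-sample design

The package assumes the standard two-sample summary-statistics setting:
SNP–exposure associations (β̂ₓⱼ, σₓⱼ) from one GWAS and SNP–outcome
associations (β̂ᵧⱼ, σᵧⱼ) from a non-overlapping GWAS, for J biallelic,
approximately LD-independent instruments. The identifying assumptions are
the usual instrumental-variable ones: relevance (enforced by the
genome-wide p-value filter), independence from confounders (by Mendelian
inheritance), and exclusion (probed, not assumed, by the sensitivity
battery). Exposure effects are treated as measured in SD units so causal
estimates read "per 1-SD exposure"; binary outcomes are on the log-odds
scale and exponentiated only at the presentation layer.

## Instrument selection

Selection keeps records with p strictly below the threshold (default
5×10⁻⁸; the sweep extends to 5×10⁻²⁰ to probe winner's-curse sensitivity),
then greedily clumps: take the most significant remaining SNP, discard
in-window (±500 kb, same chromosome) candidates with r² ≥ 0.05. Ties in p
break by (chromosome, position, snp_id) so results are identical across
platforms. LD comes from a user-supplied r² table or a reference dosage
matrix (r² = squared Pearson correlation of dosages); pairs absent from the
source are treated as independent with a logged warning by default, because
published r² tables are usually sparse, with a `fail` mode for strict runs.
Instruments missing from an outcome dataset are dropped outright — no proxy
search — and counted in the report.

## Harmonization

Outcome records are rewritten onto the exposure's effect allele (allele
swap ⇒ negate beta, complement frequency; strand flip ⇒ complement both
alleles; both as needed). Palindromic SNPs (A/T, C/G) cannot be oriented
from labels alone, so they are kept only when both effect-allele
frequencies are outside [0.42, 0.58] *and* fall on the same side of 0.5;
anything else — including informative frequencies on opposite sides, and
missing frequencies — is dropped as ambiguous. This is deliberately
stricter than tools that frequency-flip opposite-side palindromes: an
opposite-side pattern is equally consistent with a strand flip and a real
frequency difference between cohorts, and with hundreds of instruments the
cost of dropping a handful is smaller than the risk of a sign error. The
0.42 limit is a common community default and is exposed as a flag.
Finally every instrument is oriented so β̂ₓ > 0. This is inert for
ratio-based estimators (verified by a property test) but necessary for the
Egger intercept to mean "average directional pleiotropy on the
exposure-increasing allele".

## Estimators

* **IVW.** Closed-form zero-intercept WLS with weights σᵧⱼ⁻². Both the
  fixed-effect SE and the multiplicative random-effects SE (scaled by
  max(1, √(Q/(J−1)))) are always reported; the random-effects version is
  the headline default because between-SNP heterogeneity is the norm at
  J ≈ 200 and the floor at 1 prevents the CI from shrinking below the
  fixed-effect one under homogeneity.
* **MR-Egger.** WLS with intercept, same weights, both SEs scaled by
  max(1, √(RSS/(J−2))). The intercept test uses a t distribution with J−2
  df; the slope CI uses the normal 1.96 multiplier like every other
  method. Caveat: with a *constant-variance* pleiotropy term added to
  sampling variances that vary several-fold across minor-allele
  frequencies, the single multiplicative scale misstates per-SNP residual
  variances and the intercept test runs slightly hot (measured ≈6–7%
  rejection at nominal 5% in the balanced-pleiotropy stress test). This is
  a property of the standard formulation, kept deliberately; the test
  suite checks the level stays within [3%, 7%].
* **Weighted median.** Ratios ordered ascending; cumulative standardized
  weight pⱼ = (Sⱼ − wⱼ/2)/S with wⱼ the inverse-variance ratio weights;
  the estimate interpolates θ̂ at p = 0.5. SE by parametric bootstrap:
  redraw (β̂ₓⱼ, β̂ᵧⱼ) from their sampling normals, recompute, take the SD
  over n_boot = 1000 seeded resamples.
* **Weighted mode.** Argmax over a 512-point grid spanning
  [min θ̂ − 3h, max θ̂ + 3h] of the weighted normal-kernel density;
  bandwidth h = φ · 0.9·min(weighted SD, 1.4826·MAD)·J^(−1/5) with φ = 1
  by default. Exact density ties return the lower mode; a degenerate
  spread (all ratios equal) falls back to the weighted median of the point
  mass. SE by the same bootstrap.
* **MR-PRESSO.** Observed statistic RSS = Σwⱼ(β̂ᵧⱼ − θ̂₍₋ⱼ₎β̂ₓⱼ)² with
  leave-one-out IVW estimates θ̂₍₋ⱼ₎. The null distribution redraws
  β̂ₓⱼ* ~ N(β̂ₓⱼ, σₓⱼ) and β̂ᵧⱼ* ~ N(θ̂₍₋ⱼ₎β̂ₓⱼ, σᵧⱼ) and recomputes RSS by
  the identical leave-one-out procedure (vectorized across simulations).
  Global p = (1 + #{RSS* ≥ RSS})/(n_sim + 1), so it is bounded below by
  1/(n_sim+1). Per-SNP outlier p-values compare each observed residual
  term with its simulated distribution and are Bonferroni-thresholded at
  α/J (α = 0.05, n_sim = 1000 by default; n_sim must exceed J/α for the
  threshold to be reachable). The corrected estimate is IVW on
  non-outliers; the distortion p compares the observed corrected-vs-raw
  shift against shifts from removing equally many random SNPs. If fewer
  than two SNPs survive, the corrected estimate is an explicit error
  state rather than a number.

Estimator classes follow scikit-learn conventions (`fit(X, y, se_out=...)`,
trailing-underscore attributes, `get_params`); X is the vector of exposure
betas and y the outcome betas, with SEs passed as fit parameters because
they are per-observation data, not hyperparameters.

## Risk-score and one-sample stage

Phenotype preparation regresses the raw phenotype on covariates by OLS
within each sex stratum, maps residual ranks through the normal quantile
function with the Blom offset (r − 3/8)/(n + 1/4), and pools strata. Blom
is the common default for GWAS phenotype preparation; the offset is a flag.

Cross-validated weights partition the cohort into k = 20 seeded folds; the
weight of SNP j for fold f is the *marginal* OLS coefficient of the
transformed phenotype on dosage j fitted on the other folds. Marginal
rather than joint fits mirror how GWAS-derived weights are produced and are
appropriate because instruments are LD-independent by construction; the
residual finite-sample dosage correlation this ignores is part of why
cross-validated R² sits slightly below the generating target. Each
individual's score uses only weights from models that exclude them, so the
reported R² is an honest out-of-sample quantity.

One-sample MR is the ratio of the outcome-on-score coefficient (logistic
for binary outcomes, OLS otherwise, covariates included) to the
exposure-on-score coefficient, with a first-order delta-method SE that
treats the denominator as fixed — standard for strong scores, and a
documented limitation for weak ones. For binary outcomes the estimate
inherits logistic non-collapsibility: marginalizing over the exposure
variance not captured by the score attenuates the log-OR by a few percent,
which is visible as a small conservative bias in recovery experiments.

Summary-level variance explained is Σⱼ2pⱼ(1−pⱼ)βⱼ² on a unit-variance
phenotype, skipping SNPs with missing frequency.

## What the generator emulates — and what it does not

`simulate_two_sample` draws maf ~ U(0.05, 0.5) and per-allele exposure
effects ~ U(0.02, 0.41) SD (the span observed in large heel-BMD GWAS), with
rejection sampling so expected association z-scores clear the discovery
threshold with margin — the emitted pool behaves like a *discovered*
instrument set. Emitted SEs are exactly the analytic sampling SEs:
1/√(2p(1−p)n) for quantitative traits and the score-test log-OR
approximation √((1/n_cases + 1/n_controls)/(2p(1−p))) for case-control
traits. Default sizes mirror the discovery design: J = 235, exposure
n = 116,501, binary outcome 26,676 cases / 132,532 controls. Outcome
records are randomly allele-swapped and strand-complemented so
harmonization is genuinely exercised end to end.

Pleiotropy regimes set the direct effects αⱼ in
β̂ᵧⱼ ~ N(θβ̂ₓⱼ + αⱼ, σᵧⱼ): `balanced` (mean zero, σ_α = 0.01),
`directional` (μ_α = 0.02, σ_α = 0.005), `inside_violating` (αⱼ correlated
with instrument strength), each with a fraction of affected instruments.
The magnitudes were fixed once at values comparable to θ·β̂ₓ for
mid-strength instruments — large enough to visibly distort IVW, small
enough that robust estimators retain signal.

Not emulated: LD between instruments (emitted SNPs are placed >2 Mb apart),
realistic allele-frequency spectra, sample overlap between exposure and
outcome cohorts, winner's-curse inflation of the selected effect sizes, and
population stratification. Passing tests therefore show the estimators are
correct *given* the standard two-sample assumptions; they cannot show
robustness to violations the generator does not produce.

`simulate_cohort` draws Binomial(2, maf) dosages and scales exposure noise
so the true score explains a target fraction (default 13.9%) of exposure
variance, adds linear age/sex/height/weight effects to the observed
phenotype, and draws a binary outcome from a logistic model at a stated
baseline prevalence (default 10%).

## Numerical conventions and problem sizes

One master seed drives every stochastic component; per-stage streams split
via `numpy.random.SeedSequence.spawn` in fixed order, so identical configs
reproduce byte-identical outputs (asserted by tests). CI multipliers are
the exact normal 1.96 quantile. p-values are carried at full precision and
rounded only in reports. Degenerate inputs raise typed errors rather than
returning NaN: too few instruments, zero exposure beta in a Wald ratio,
zero-variance scores, constant phenotypes.

Replication sizes used by the test suite and acceptance script — 200
replicates for recovery/coverage and outlier detection, 500 for bias
comparisons, 1000 for test-level checks, cohorts of n = 20,000 — were
chosen so Monte-Carlo error is a small fraction of each tested margin while
a full run stays in the tens of seconds.

## Known limitations

Variant QC applies per-field thresholds only (no cross-field logic); the
Wald-ratio SE is first order; the weighted-mode bandwidth rule is a
heuristic and φ materially affects small-J results; MR-PRESSO's Bonferroni
outlier rule is conservative when many moderate outliers coexist;
multivariable MR, overlapping-sample corrections, and directionality
(Steiger) filtering are out of scope.
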