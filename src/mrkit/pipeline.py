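"""End-to-end analysis orchestration: forward MR to one or more outcomes
across a sweep of instrument p-value thresholds, the estimator battery with
pleiotropy diagnostics, optional comparison against externally supplied
observational estimates, and reverse (bidirectional) MR.

Each (outcome x threshold) cell runs: select instruments below the threshold
-> greedy LD clump -> intersect with the outcome dataset -> harmonize alleles
-> IVW (fixed and multiplicative random effects), MR-Egger, weighted median,
weighted mode, and MR-PRESSO -> odds-ratio conversion for binary outcomes.
Failures are row-scoped: an outcome with too few harmonized instruments is
marked failed with its reason and the run continues.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import estimators as est
from .exceptions import ConfigurationError, InsufficientInstrumentsError, MRKitError
from .harmonize import harmonize, retained, to_frame
from .instruments import (InstrumentSet, LDSource, clump, intersect_with_outcome,
                          select_by_pvalue)
from .sumstats import SumstatsTable, read_sumstats

logger = logging.getLogger(__name__)

#: threshold sweep default: genome-wide significance down to 5e-20
DEFAULT_THRESHOLDS = (5e-8, 5e-10, 5e-12, 5e-14, 5e-16, 5e-18, 5e-20)

REPORT_COLUMNS = [
    "outcome", "threshold", "method", "status", "reason", "n_snp",
    "beta", "se", "ci_low", "ci_high", "pvalue",
    "or_", "or_ci_low", "or_ci_high",
    "cochran_q", "q_pvalue",
    "egger_intercept", "egger_intercept_se", "egger_intercept_pvalue",
    "presso_global_pvalue", "presso_distortion_pvalue", "presso_n_outliers",
    "n_candidates", "n_clumped", "n_dropped_outcome", "n_dropped_harmonize",
    "obs_beta", "obs_se", "obs_het_z", "obs_het_pvalue",
]


@dataclass
class OutcomeSpec:
    """One outcome dataset plus an optional external observational estimate."""

    table: SumstatsTable
    label: str
    observational_beta: float | None = None
    observational_se: float | None = None

    @property
    def is_binary(self) -> bool:
        return self.table.trait_type == "binary"


@dataclass
class AnalysisConfig:
    """Declarative settings for a full forward-MR run."""

    exposure: SumstatsTable
    outcomes: list[OutcomeSpec]
    p_thresholds: Sequence[float] = DEFAULT_THRESHOLDS
    ld: LDSource = field(default_factory=LDSource)
    clump_r2: float = 0.05
    clump_window_bp: int = 500_000
    palindromic_eaf_limit: float = 0.42
    n_boot: int = 1000
    presso_n_sim: int = 1000
    presso_outlier_alpha: float = 0.05
    mode_phi: float = 1.0
    seed: int = 0
    bonferroni: bool = False

    def __post_init__(self):
        if not self.outcomes:
            raise ConfigurationError("at least one outcome dataset is required")
        for t in self.p_thresholds:
            if not 0 < t < 1:
                raise ConfigurationError(f"p_threshold must be in (0,1), got {t}")
        labels = [o.label for o in self.outcomes]
        if len(set(labels)) != len(labels):
            raise ConfigurationError("outcome labels must be unique")


def _blank_row(outcome: str, threshold: float, method: str) -> dict:
    row = {c: math.nan for c in REPORT_COLUMNS}
    row.update(outcome=outcome, threshold=threshold, method=method,
               status="ok", reason="")
    return row


def _fill(row: dict, r: est.MRResult, binary: bool) -> dict:
    row.update(n_snp=r.n_snp, beta=r.beta, se=r.se, ci_low=r.ci_low,
               ci_high=r.ci_high, pvalue=r.pvalue)
    if r.cochran_q is not None:
        row.update(cochran_q=r.cochran_q, q_pvalue=r.q_pvalue)
    if r.egger_intercept is not None:
        row.update(egger_intercept=r.egger_intercept,
                   egger_intercept_se=r.intercept_se,
                   egger_intercept_pvalue=r.intercept_pvalue)
    if binary:
        or_, lo, hi = est.to_odds_ratio(r.beta, r.se)
        row.update(or_=or_, or_ci_low=lo, or_ci_high=hi)
    return row


def _battery(harmonized, spec: OutcomeSpec, threshold: float, counts: dict,
             cfg: AnalysisConfig, seed: int) -> list[dict]:
    """All estimators on one harmonized instrument set, row-scoped failures."""
    rows = []
    kept = retained(harmonized)
    plan = [
        ("ivw_fixed", lambda: est.ivw(kept, model="fixed")),
        ("ivw_mre", lambda: est.ivw(kept, model="multiplicative_random_effects")),
        ("egger", lambda: est.egger(kept)),
        ("weighted_median", lambda: est.weighted_median(kept, n_boot=cfg.n_boot,
                                                        seed=seed)),
        ("weighted_mode", lambda: est.weighted_mode(kept, phi=cfg.mode_phi,
                                                    n_boot=cfg.n_boot, seed=seed + 1)),
    ]
    for method, run in plan:
        row = _blank_row(spec.label, threshold, method)
        row.update(counts)
        try:
            r = run()
            _fill(row, r, spec.is_binary)
            if method == "ivw_mre" and spec.observational_beta is not None:
                z, p = est.compare_estimates(
                    r.beta, r.se, spec.observational_beta, spec.observational_se)
                row.update(obs_beta=spec.observational_beta,
                           obs_se=spec.observational_se,
                           obs_het_z=z, obs_het_pvalue=p)
        except MRKitError as exc:
            row.update(status="failed", reason=str(exc))
        rows.append(row)

    row = _blank_row(spec.label, threshold, "presso_corrected")
    row.update(counts)
    try:
        pres = est.mr_presso(kept, n_sim=cfg.presso_n_sim,
                             outlier_alpha=cfg.presso_outlier_alpha, seed=seed + 2)
        if pres.corrected is not None:
            _fill(row, pres.corrected, spec.is_binary)
        else:
            row.update(status="failed", reason="all instruments flagged as outliers")
        row.update(presso_global_pvalue=pres.global_pvalue,
                   presso_distortion_pvalue=(pres.distortion_pvalue
                                             if pres.distortion_pvalue is not None
                                             else math.nan),
                   presso_n_outliers=len(pres.outlier_ids))
    except MRKitError as exc:
        row.update(status="failed", reason=str(exc))
    rows.append(row)
    return rows


def run_forward(cfg: AnalysisConfig) -> pd.DataFrame:
    """Forward MR: every configured (outcome x threshold x method) cell.

    Deterministic given the config and master seed; per-cell estimator seeds
    are split from the master seed in a fixed job order.
    """
    jobs = [(spec, thr) for spec in cfg.outcomes for thr in cfg.p_thresholds]
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(cfg.seed).spawn(len(jobs))]
    rows: list[dict] = []
    for (spec, threshold), seed in zip(jobs, seeds):
        candidates = select_by_pvalue(cfg.exposure, threshold)
        instruments = clump(candidates, cfg.ld, r2_max=cfg.clump_r2,
                            window_bp=cfg.clump_window_bp,
                            selection_p=threshold, provenance="forward")
        instruments, dropped = intersect_with_outcome(instruments, spec.table)
        harmonized = harmonize(instruments, spec.table,
                               palindromic_eaf_limit=cfg.palindromic_eaf_limit)
        counts = dict(
            n_candidates=len(candidates), n_clumped=len(instruments) + len(dropped),
            n_dropped_outcome=len(dropped),
            n_dropped_harmonize=sum(h.dropped for h in harmonized),
        )
        n_usable = len(retained(harmonized))
        if n_usable < 3:
            row = _blank_row(spec.label, threshold, "all")
            row.update(counts, status="failed",
                       reason=f"only {n_usable} harmonized instrument(s)")
            rows.append(row)
            logger.warning("run_forward: %s @ %.2g failed (%s)",
                           spec.label, threshold, row["reason"])
            continue
        rows.extend(_battery(harmonized, spec, threshold, counts, cfg, seed))
    df = pd.DataFrame(rows, columns=REPORT_COLUMNS)
    if cfg.bonferroni:
        m = len(cfg.outcomes)
        df["pvalue_bonferroni"] = (df["pvalue"] * m).clip(upper=1.0)
    return df


def run_reverse(
    disease_tables: Sequence[tuple[SumstatsTable, Sequence[str], str]],
    exposure_as_outcome: SumstatsTable,
    cfg: AnalysisConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Bidirectional MR: test each disease's instruments against the former
    exposure.

    ``disease_tables`` is a list of (disease sumstats, instrument snp_id
    list, label); instruments are looked up in the disease table (absent ids
    are dropped and logged), then the identical estimator battery runs with
    roles swapped.  Note this is *not* the algebraic inverse of the forward
    estimate: the instruments, and hence the identified effect, differ.
    """
    rows: list[dict] = []
    n_boot = cfg.n_boot if cfg else 1000
    presso_n_sim = cfg.presso_n_sim if cfg else 1000
    base = AnalysisConfig(
        exposure=exposure_as_outcome,
        outcomes=[OutcomeSpec(exposure_as_outcome, "self")],
        n_boot=n_boot, presso_n_sim=presso_n_sim,
        presso_outlier_alpha=cfg.presso_outlier_alpha if cfg else 0.05,
        mode_phi=cfg.mode_phi if cfg else 1.0,
        palindromic_eaf_limit=cfg.palindromic_eaf_limit if cfg else 0.42,
    )
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(seed).spawn(len(disease_tables))]
    for (table, snp_ids, label), job_seed in zip(disease_tables, seeds):
        present = [table.get(i) for i in snp_ids if i in table]
        missing = [i for i in snp_ids if i not in table]
        if missing:
            logger.info("run_reverse(%s): %d instrument id(s) absent from disease table",
                        label, len(missing))
        instruments = InstrumentSet(present, provenance=f"reverse:{label}")
        instruments, dropped = intersect_with_outcome(instruments, exposure_as_outcome)
        harmonized = harmonize(instruments, exposure_as_outcome,
                               palindromic_eaf_limit=base.palindromic_eaf_limit)
        spec = OutcomeSpec(exposure_as_outcome, label)
        counts = dict(
            n_candidates=len(snp_ids), n_clumped=len(present),
            n_dropped_outcome=len(dropped) + len(missing),
            n_dropped_harmonize=sum(h.dropped for h in harmonized),
        )
        if len(retained(harmonized)) < 3:
            row = _blank_row(label, math.nan, "all")
            row.update(counts, status="failed",
                       reason=f"only {len(retained(harmonized))} harmonized instrument(s)")
            rows.append(row)
            continue
        rows.extend(_battery(harmonized, spec, math.nan, counts, base, job_seed))
    return pd.DataFrame(rows, columns=REPORT_COLUMNS)


# ---------------------------------------------------------------------------
# report serialization and config files


def write_report(df: pd.DataFrame, outdir, stem: str = "mr_report",
                 settings: dict | None = None) -> None:
    """Tidy tab-delimited report plus a JSON mirror (forest-plot-ready)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / f"{stem}.tsv", "w") as fh:
        if settings:
            fh.write("# settings: " + json.dumps(settings, sort_keys=True) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")
    payload = {"settings": settings or {},
               "rows": json.loads(df.to_json(orient="records"))}
    (outdir / f"{stem}.json").write_text(json.dumps(payload, indent=1))


def load_config(path, overrides: dict | None = None) -> AnalysisConfig:
    """Build an :class:`AnalysisConfig` from a YAML file.

    Layout::

        exposure: {path: exposure.tsv, dialect: {...}}
        outcomes:
          - {path: outcome.tsv, label: T2D, trait_type: binary,
             observational_beta: 0.04, observational_se: 0.01}
        p_thresholds: [5e-8]
        ld_table: ld.tsv          # optional
        clump_r2: 0.05
        clump_window_bp: 500000
        seed: 1

    CLI flags override config keys via ``overrides``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    raw.update(overrides or {})
    exp = raw.pop("exposure")
    exposure = read_sumstats(exp["path"], dialect=exp.get("dialect"),
                             trait_label=exp.get("label", "exposure"),
                             trait_type=exp.get("trait_type", "quantitative"))
    outcomes = []
    for o in raw.pop("outcomes"):
        table = read_sumstats(o["path"], dialect=o.get("dialect"),
                              trait_label=o.get("label", "outcome"),
                              trait_type=o.get("trait_type", "quantitative"))
        outcomes.append(OutcomeSpec(
            table=table, label=o.get("label", table.trait_label or "outcome"),
            observational_beta=o.get("observational_beta"),
            observational_se=o.get("observational_se")))
    ld = LDSource.from_file(raw.pop("ld_table")) if raw.get("ld_table") else LDSource()
    raw.pop("ld_table", None)
    allowed = {"p_thresholds", "clump_r2", "clump_window_bp",
               "palindromic_eaf_limit", "n_boot", "presso_n_sim",
               "presso_outlier_alpha", "mode_phi", "seed", "bonferroni"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    return AnalysisConfig(exposure=exposure, outcomes=outcomes, ld=ld, **raw)
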