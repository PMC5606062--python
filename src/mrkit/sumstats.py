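"""GWAS summary-statistics data model, I/O and variant-level quality control.

A summary-statistics table holds one association record per SNP for a single
trait: alleles, effect-allele frequency, per-allele effect (SD units for
quantitative traits, log-odds for case-control traits), its standard error,
p-value, sample size and optional per-variant QC metrics (imputation quality,
missingness, Hardy-Weinberg p).  Only biallelic single-nucleotide variants are
modelled; indels and multi-allelic records are rejected at parse time because
all downstream allele logic (strand complementing, palindrome detection)
assumes single bases.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGT")

#: canonical column order of the on-disk tab-delimited format
CANONICAL_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "eaf", "beta", "se", "pvalue", "n", "info", "missingness", "hwe_p",
]

REQUIRED_COLUMNS = [
    "snp_id", "chrom", "pos", "effect_allele", "other_allele",
    "beta", "se", "pvalue",
]

#: default header mapping: canonical field -> column name in the file.
#: Covers the common SNP/CHR/BP/EA/NEA/EAF/BETA/SE/P/N/INFO layout.
DEFAULT_DIALECT: Mapping[str, str] = {
    "snp_id": "SNP", "chrom": "CHR", "pos": "BP",
    "effect_allele": "EA", "other_allele": "NEA",
    "eaf": "EAF", "beta": "BETA", "se": "SE", "pvalue": "P",
    "n": "N", "info": "INFO", "missingness": "MISSING", "hwe_p": "HWE_P",
}


@dataclass(frozen=True)
class VariantAssoc:
    """One SNP's association record in one GWAS.

    Coordinates are 1-based inclusive.  ``beta`` is the per-effect-allele
    effect: SD units for quantitative traits, log-odds for binary traits.
    ``eaf``/``info``/``missingness``/``hwe_p`` may be NaN when the source file
    does not provide them (typical for downloaded consortium files).
    """

    snp_id: str
    chrom: str
    pos: int
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pvalue: float
    eaf: float = math.nan
    n: float = math.nan
    info: float = math.nan
    missingness: float = math.nan
    hwe_p: float = math.nan

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_BASES or self.other_allele not in VALID_BASES:
            raise ValidationError(
                f"{self.snp_id}: alleles must be single bases in ACGT, "
                f"got {self.effect_allele}/{self.other_allele}"
            )
        if self.effect_allele == self.other_allele:
            raise ValidationError(f"{self.snp_id}: effect and other allele identical")
        if not self.se > 0:
            raise ValidationError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.pvalue <= 1):
            raise ValidationError(f"{self.snp_id}: pvalue must be in (0,1], got {self.pvalue}")
        if self.pos < 1:
            raise ValidationError(f"{self.snp_id}: pos must be >= 1 (1-based), got {self.pos}")
        if not math.isnan(self.eaf) and not (0 < self.eaf < 1):
            raise ValidationError(f"{self.snp_id}: eaf must be strictly inside (0,1)")

    @property
    def maf(self) -> float:
        """Minor-allele frequency, NaN when eaf is missing."""
        return min(self.eaf, 1.0 - self.eaf) if not math.isnan(self.eaf) else math.nan

    @property
    def is_palindromic(self) -> bool:
        """True for strand-ambiguous A/T and C/G variants."""
        return complement(self.effect_allele) == self.other_allele


COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def complement(base: str) -> str:
    return COMPLEMENT[base]


@dataclass
class SumstatsTable:
    """An ordered collection of :class:`VariantAssoc`, unique by ``snp_id``.

    ``trait_type`` is ``"quantitative"`` (betas in SD or natural units) or
    ``"binary"`` (betas are log-odds).
    """

    records: list[VariantAssoc]
    trait_label: str = ""
    trait_type: str = "quantitative"
    units: str = ""
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if self.trait_type not in ("quantitative", "binary"):
            raise ValidationError(f"trait_type must be quantitative|binary, got {self.trait_type}")
        self._index = {}
        for i, rec in enumerate(self.records):
            if rec.snp_id in self._index:
                raise ValidationError(f"duplicate snp_id: {rec.snp_id!r}")
            self._index[rec.snp_id] = i

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[VariantAssoc]:
        return iter(self.records)

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def get(self, snp_id: str) -> VariantAssoc:
        return self.records[self._index[snp_id]]

    def to_frame(self) -> pd.DataFrame:
        """Return the table as a DataFrame in canonical column order."""
        return pd.DataFrame([vars(r) for r in self.records], columns=CANONICAL_COLUMNS)


def _coerce_row(row: pd.Series, has: Mapping[str, str]) -> VariantAssoc:
    def fval(key: str) -> float:
        if key not in has:
            return math.nan
        v = row[has[key]]
        return float(v) if v is not None and str(v).strip() not in ("", "NA", "NaN", ".") else math.nan

    beta, se, pvalue = fval("beta"), fval("se"), fval("pvalue")
    if math.isnan(beta) or math.isnan(se) or math.isnan(pvalue):
        raise ValidationError("missing beta/se/pvalue")
    return VariantAssoc(
        snp_id=str(row[has["snp_id"]]),
        chrom=str(row[has["chrom"]]),
        pos=int(row[has["pos"]]),
        effect_allele=str(row[has["effect_allele"]]).upper(),
        other_allele=str(row[has["other_allele"]]).upper(),
        beta=beta, se=se, pvalue=pvalue,
        eaf=fval("eaf"), n=fval("n"), info=fval("info"),
        missingness=fval("missingness"), hwe_p=fval("hwe_p"),
    )


def read_sumstats(
    path,
    dialect: Mapping[str, str] | None = None,
    trait_label: str = "",
    trait_type: str = "quantitative",
    units: str = "",
) -> SumstatsTable:
    """Read a tab- or comma-delimited GWAS summary file into a :class:`SumstatsTable`.

    ``dialect`` maps canonical field names (see :data:`CANONICAL_COLUMNS`) to
    the column names used in the file; unspecified fields fall back to
    :data:`DEFAULT_DIALECT` when those columns exist.  Rows that fail the
    :class:`VariantAssoc` invariants (non-ACGT alleles, missing beta/se/p,
    out-of-range values) are dropped with a logged count; row order is
    preserved.  gzip-compressed files are accepted (pandas infers from the
    ``.gz`` suffix).

    Raises
    ------
    ConfigurationError
        if a required column named by the dialect is absent.
    ValidationError
        if two rows share a snp_id.
    """
    dialect = dict(DEFAULT_DIALECT, **(dialect or {}))
    df = pd.read_csv(path, sep=None, engine="python", dtype=str, comment="#")
    # canonical field names always work as a fallback, so the package's own
    # output (and any file already using canonical headers) needs no dialect
    has = {}
    for k, v in dialect.items():
        if v in df.columns:
            has[k] = v
        elif k in df.columns:
            has[k] = k
    for key in REQUIRED_COLUMNS:
        if key not in has:
            raise ConfigurationError(
                f"required column {dialect[key]!r} (field {key!r}) not found in {path}"
            )

    records: list[VariantAssoc] = []
    rejected: dict[str, int] = {}
    for _, row in df.iterrows():
        try:
            records.append(_coerce_row(row, has))
        except (ValidationError, ValueError) as exc:
            reason = type(exc).__name__ if isinstance(exc, ValueError) else "invariant"
            rejected[reason] = rejected.get(reason, 0) + 1
    for reason, count in rejected.items():
        logger.info("read_sumstats(%s): rejected %d row(s) [%s]", path, count, reason)

    seen: set[str] = set()
    for rec in records:
        if rec.snp_id in seen:
            raise ValidationError(f"duplicate snp_id in {path}: {rec.snp_id!r}")
        seen.add(rec.snp_id)
    return SumstatsTable(records, trait_label=trait_label, trait_type=trait_type, units=units)


def write_sumstats(table: SumstatsTable, path) -> None:
    """Write the canonical tab-delimited format (fixed column order).

    Missing optional fields are written as ``NA``; a read->write->read
    round trip reproduces all finite fields bit-identically (floats are
    serialized with ``repr`` precision).
    """
    df = table.to_frame()
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.17g")


def apply_variant_qc(
    table: SumstatsTable,
    min_info: float = 0.4,
    min_maf: float = 0.001,
    max_missing: float = 0.1,
    min_hwe_p: float = 1e-6,
    strict: bool = False,
) -> SumstatsTable:
    """Variant-level QC filter.

    Retains records with imputation quality ``info >= min_info``, minor-allele
    frequency ``>= min_maf``, ``missingness < max_missing`` and Hardy-Weinberg
    ``p > min_hwe_p`` (boundary conventions follow common biobank-scale GWAS
    practice: >= for info and MAF, strict < for missingness, strict > for HWE).

    A record missing a QC field passes that single criterion by default —
    downloaded consortium outcome files typically lack info/missingness/HWE
    columns — unless ``strict=True``, in which case a missing field fails.
    The input table is not modified; the operation is idempotent.
    """
    for name, thr in (("min_info", min_info), ("min_maf", min_maf),
                      ("max_missing", max_missing), ("min_hwe_p", min_hwe_p)):
        if not 0 <= thr <= 1:
            raise ConfigurationError(f"{name} must be in [0,1], got {thr}")

    missing_default = not strict

    def _passes(value: float, ok) -> bool:
        if math.isnan(value):
            return missing_default
        return ok(value)

    kept, dropped = [], {"info": 0, "maf": 0, "missingness": 0, "hwe": 0}
    for rec in table.records:
        if not _passes(rec.info, lambda v: v >= min_info):
            dropped["info"] += 1
        elif not _passes(rec.maf, lambda v: v >= min_maf):
            dropped["maf"] += 1
        elif not _passes(rec.missingness, lambda v: v < max_missing):
            dropped["missingness"] += 1
        elif not _passes(rec.hwe_p, lambda v: v > min_hwe_p):
            dropped["hwe"] += 1
        else:
            kept.append(rec)
    for reason, count in dropped.items():
        if count:
            logger.info("apply_variant_qc: dropped %d record(s) [%s]", count, reason)
    return SumstatsTable(list(kept), trait_label=table.trait_label,
                         trait_type=table.trait_type, units=table.units)


def table_from_arrays(
    snp_id, chrom, pos, effect_allele, other_allele, beta, se, pvalue,
    eaf=None, n=None, trait_label: str = "", trait_type: str = "quantitative",
    units: str = "",
) -> SumstatsTable:
    """Assemble a :class:`SumstatsTable` from parallel arrays (simulation helper)."""
    m = len(snp_id)
    eaf = np.full(m, math.nan) if eaf is None else np.asarray(eaf, float)
    n = np.full(m, math.nan) if n is None else np.asarray(n, float)
    recs = [
        VariantAssoc(
            snp_id=str(snp_id[j]), chrom=str(chrom[j]), pos=int(pos[j]),
            effect_allele=str(effect_allele[j]), other_allele=str(other_allele[j]),
            beta=float(beta[j]), se=float(se[j]), pvalue=float(pvalue[j]),
            eaf=float(eaf[j]), n=float(n[j]),
        )
        for j in range(m)
    ]
    return SumstatsTable(recs, trait_label=trait_label, trait_type=trait_type, units=units)


def reorient(rec: VariantAssoc) -> VariantAssoc:
    """Relabel a record to its opposite effect allele (swap alleles, negate beta, 1-eaf)."""
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=1.0 - rec.eaf if not math.isnan(rec.eaf) else math.nan,
    )
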