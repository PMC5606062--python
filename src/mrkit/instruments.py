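"""Instrument selection: genome-wide significance filtering, greedy LD clumping,
and intersection with outcome datasets.

Instruments are SNPs robustly associated with the exposure.  Selection follows
the standard GWAS recipe: keep variants below a p-value threshold (genome-wide
significance, 5e-8, by default), then reduce to approximately LD-independent
lead SNPs by greedy clumping — repeatedly take the most significant remaining
variant and discard everything within a physical window whose squared
correlation with it exceeds the clump threshold (defaults r2 < 0.05 within
+/-500 kb).
"""
from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ValidationError
from .sumstats import SumstatsTable, VariantAssoc

logger = logging.getLogger(__name__)


class LDSource:
    """Pairwise linkage-disequilibrium (r-squared) lookup.

    Backed either by a precomputed symmetric table of (snp_id_1, snp_id_2, r2)
    pairs, or by a reference panel of genotype dosages from which r2 is
    computed as the squared Pearson correlation of dosages.  The diagonal is
    implicitly 1.  Lookups for pairs absent from the source return ``None``;
    :func:`clump` decides how to treat them.
    """

    def __init__(self, pairs: dict[tuple[str, str], float] | None = None):
        self._pairs: dict[tuple[str, str], float] = {}
        if pairs:
            for (a, b), r2 in pairs.items():
                self._set(a, b, r2)

    def _set(self, a: str, b: str, r2: float) -> None:
        if not 0 <= r2 <= 1:
            raise ValidationError(f"r2 must be in [0,1], got {r2} for ({a},{b})")
        self._pairs[(a, b)] = r2
        self._pairs[(b, a)] = r2

    @classmethod
    def from_table(cls, df: pd.DataFrame) -> "LDSource":
        """Build from a 3-column table (snp_id_1, snp_id_2, r2)."""
        required = {"snp_id_1", "snp_id_2", "r2"}
        if not required.issubset(df.columns):
            raise ConfigurationError(f"LD table needs columns {sorted(required)}")
        src = cls()
        for a, b, r2 in df[["snp_id_1", "snp_id_2", "r2"]].itertuples(index=False):
            src._set(str(a), str(b), float(r2))
        return src

    @classmethod
    def from_file(cls, path) -> "LDSource":
        return cls.from_table(pd.read_csv(path, sep="\t"))

    @classmethod
    def from_dosages(cls, dosages: pd.DataFrame) -> "LDSource":
        """Build from a reference dosage matrix (individuals x SNP columns).

        r2 for every pair of columns is the squared Pearson correlation of
        dosages; monomorphic columns yield r2 = 0 with every partner.
        """
        src = cls()
        X = dosages.to_numpy(dtype=float)
        sd = X.std(axis=0)
        ids = list(dosages.columns)
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(X, rowvar=False)
        for i, j in itertools.combinations(range(len(ids)), 2):
            r = 0.0 if sd[i] == 0 or sd[j] == 0 else corr[i, j]
            src._set(ids[i], ids[j], float(r * r))
        return src

    def r2(self, a: str, b: str) -> float | None:
        """r-squared between two SNPs, 1.0 on the diagonal, None if unknown."""
        if a == b:
            return 1.0
        return self._pairs.get((a, b))

    def __len__(self) -> int:
        return len(self._pairs) // 2


@dataclass
class InstrumentSet:
    """An ordered, LD-pruned set of exposure-scale instruments."""

    snps: list[VariantAssoc]
    selection_p: float | None = None
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)

    @property
    def snp_ids(self) -> list[str]:
        return [s.snp_id for s in self.snps]


def _p_order_key(rec: VariantAssoc):
    # ties in p break by (chrom, pos, snp_id) for cross-platform determinism
    return (rec.pvalue, rec.chrom, rec.pos, rec.snp_id)


def select_by_pvalue(table: SumstatsTable, p_threshold: float) -> list[VariantAssoc]:
    """Records with ``pvalue < p_threshold`` (strict), sorted ascending by p.

    The genome-wide significance convention: the study's instrument pool is
    everything strictly below 5e-8; threshold sweeps down to 5e-20 restrict
    to the strongest signals.
    """
    if not 0 < p_threshold <= 1:
        raise ConfigurationError(f"p_threshold must be in (0,1], got {p_threshold}")
    hits = [r for r in table.records if r.pvalue < p_threshold]
    return sorted(hits, key=_p_order_key)


def clump(
    candidates: Sequence[VariantAssoc],
    ld: LDSource,
    r2_max: float = 0.05,
    window_bp: int = 500_000,
    missing_ld: str = "independent",
    selection_p: float | None = None,
    provenance: str = "",
) -> InstrumentSet:
    """Greedy p-value clumping.

    Repeatedly take the lowest-p remaining candidate as an index SNP, then
    discard every remaining candidate on the same chromosome within
    ``+/-window_bp`` whose r2 with the index is ``>= r2_max``.  Candidates
    outside the window are never tested for LD.  Deterministic: ties in p
    break by (chrom, pos, snp_id).

    ``missing_ld`` controls pairs absent from the LD source: ``"independent"``
    (default) keeps the candidate with a logged warning; ``"fail"`` raises.
    """
    if window_bp <= 0:
        raise ConfigurationError(f"window_bp must be > 0, got {window_bp}")
    if not 0 <= r2_max <= 1:
        raise ConfigurationError(f"r2_max must be in [0,1], got {r2_max}")
    if missing_ld not in ("independent", "fail"):
        raise ConfigurationError(f"missing_ld must be independent|fail, got {missing_ld!r}")

    remaining = sorted(candidates, key=_p_order_key)
    kept: list[VariantAssoc] = []
    n_missing = 0
    while remaining:
        index = remaining.pop(0)
        kept.append(index)
        survivors = []
        for cand in remaining:
            if cand.chrom == index.chrom and abs(cand.pos - index.pos) <= window_bp:
                r2 = ld.r2(index.snp_id, cand.snp_id)
                if r2 is None:
                    if missing_ld == "fail":
                        raise ConfigurationError(
                            f"no LD value for in-window pair ({index.snp_id},{cand.snp_id})"
                        )
                    n_missing += 1
                    survivors.append(cand)  # treated as independent
                    continue
                if r2 >= r2_max:
                    continue  # clumped away
            survivors.append(cand)
        remaining = survivors
    if n_missing:
        logger.warning("clump: %d in-window pair(s) had no LD value; treated as independent",
                       n_missing)
    return InstrumentSet(kept, selection_p=selection_p, provenance=provenance)


def intersect_with_outcome(
    instruments: InstrumentSet, outcome: SumstatsTable
) -> tuple[InstrumentSet, list[str]]:
    """Retain instruments whose snp_id appears in the outcome table.

    No proxy substitution is attempted: instruments absent from the outcome
    GWAS are simply dropped (returned and logged), mirroring standard
    two-sample practice when a handful of exposure hits are missing from the
    outcome consortium file.
    """
    kept = [s for s in instruments.snps if s.snp_id in outcome]
    dropped = [s.snp_id for s in instruments.snps if s.snp_id not in outcome]
    if dropped:
        logger.info("intersect_with_outcome: dropped %d instrument(s) absent from %s: %s",
                    len(dropped), outcome.trait_label or "outcome", ", ".join(dropped[:10]))
    return (
        InstrumentSet(kept, selection_p=instruments.selection_p,
                      provenance=instruments.provenance),
        dropped,
    )


def write_instruments(instruments: InstrumentSet, path) -> None:
    """Serialize as the canonical sumstats table plus a provenance header line."""
    from .sumstats import SumstatsTable, write_sumstats

    with open(path, "w") as fh:
        fh.write(f"# provenance: {instruments.provenance}; "
                 f"selection_p: {instruments.selection_p}\n")
        SumstatsTable(list(instruments.snps)).to_frame().to_csv(
            fh, sep="\t", index=False, na_rep="NA", float_format="%.17g")
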