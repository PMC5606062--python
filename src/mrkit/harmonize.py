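"""Allele harmonization across two GWAS datasets and per-SNP Wald ratios.

Two summary files report effects of the *same* variant but possibly for
different effect alleles and on different strands.  Harmonization rewrites the
outcome record onto the exposure's effect allele:

* alleles identical -> no action;
* alleles swapped -> negate the outcome beta and complement its frequency;
* alleles match only after complementing the outcome's strand -> the same two
  cases, recorded as strand flips;
* palindromic variants (A/T or C/G) are strand-ambiguous: allele labels alone
  cannot reveal a strand flip, so they are retained only when both effect-allele
  frequencies fall on the same side of 0.5 and both are far enough from 0.5 to
  be informative (outside ``[limit, 1-limit]``); otherwise they are dropped.

Finally each instrument is oriented so the exposure beta is positive (the
"exposure-increasing allele" convention).  This is mathematically inert for
ratio-based estimators but required for the Egger intercept to be
interpretable as average directional pleiotropy.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .exceptions import UndefinedRatioError
from .instruments import InstrumentSet
from .sumstats import SumstatsTable, VariantAssoc, complement

logger = logging.getLogger(__name__)

#: actions recorded for every input SNP
ACTIONS = (
    "none", "flip_beta", "strand_flip", "strand_flip_and_beta",
    "dropped_palindromic", "mismatch",
)


@dataclass(frozen=True)
class HarmonizedInstrument:
    """A SNP's exposure and outcome effects expressed on the same effect allele.

    ``ratio`` is the per-SNP Wald estimate beta_out/beta_exp and ``ratio_se``
    its first-order delta-method standard error se_out/|beta_exp|.  Dropped
    SNPs (palindromic-ambiguous or irreconcilable alleles) carry NaN effect
    fields and ``dropped`` is True.
    """

    snp_id: str
    effect_allele: str
    other_allele: str
    beta_exp: float
    se_exp: float
    beta_out: float
    se_out: float
    action: str
    eaf_exp: float = math.nan
    eaf_out: float = math.nan

    @property
    def dropped(self) -> bool:
        return self.action in ("dropped_palindromic", "mismatch")

    @property
    def ratio(self) -> float:
        est, _ = wald_ratio(self)
        return est

    @property
    def ratio_se(self) -> float:
        _, se = wald_ratio(self)
        return se


def wald_ratio(h: HarmonizedInstrument) -> tuple[float, float]:
    """Per-SNP causal estimate: (beta_out/beta_exp, se_out/|beta_exp|).

    The SE is the first-order delta-method approximation that treats the
    exposure beta as fixed — standard Wald-ratio practice for strong
    instruments.
    """
    if h.beta_exp == 0:
        raise UndefinedRatioError(f"{h.snp_id}: beta_exp is zero, Wald ratio undefined")
    return h.beta_out / h.beta_exp, h.se_out / abs(h.beta_exp)


def _dropped(exposure: VariantAssoc, outcome: VariantAssoc, action: str) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        snp_id=exposure.snp_id,
        effect_allele=exposure.effect_allele, other_allele=exposure.other_allele,
        beta_exp=math.nan, se_exp=exposure.se, beta_out=math.nan, se_out=outcome.se,
        action=action, eaf_exp=exposure.eaf, eaf_out=outcome.eaf,
    )


def harmonize_pair(
    exposure: VariantAssoc,
    outcome: VariantAssoc,
    palindromic_eaf_limit: float = 0.42,
) -> HarmonizedInstrument:
    """Harmonize one exposure/outcome record pair onto a shared effect allele.

    Returns a :class:`HarmonizedInstrument` whose ``action`` field records the
    transformation applied (or why the SNP was dropped).  ``palindromic_eaf_limit``
    is the ambiguity band for strand-ambiguous SNPs: frequencies inside
    ``[limit, 1-limit]`` are too close to 0.5 to disambiguate.
    """
    if exposure.snp_id != outcome.snp_id:
        raise ValueError(f"snp_id mismatch: {exposure.snp_id} vs {outcome.snp_id}")

    e_ea, e_oa = exposure.effect_allele, exposure.other_allele
    o_ea, o_oa = outcome.effect_allele, outcome.other_allele
    beta_out, eaf_out = outcome.beta, outcome.eaf

    if exposure.is_palindromic:
        # A/T or C/G: direct and strand-complemented allele sets coincide, so
        # orientation must come from allele frequencies.
        if {o_ea, o_oa} != {e_ea, e_oa}:
            return _dropped(exposure, outcome, "mismatch")
        if math.isnan(exposure.eaf) or math.isnan(eaf_out):
            return _dropped(exposure, outcome, "dropped_palindromic")
        eaf_out_on_e_ea = eaf_out if o_ea == e_ea else 1.0 - eaf_out
        lim_lo, lim_hi = palindromic_eaf_limit, 1.0 - palindromic_eaf_limit
        informative = (
            not (lim_lo <= exposure.eaf <= lim_hi)
            and not (lim_lo <= eaf_out_on_e_ea <= lim_hi)
        )
        same_side = (exposure.eaf - 0.5) * (eaf_out_on_e_ea - 0.5) > 0
        if not (informative and same_side):
            return _dropped(exposure, outcome, "dropped_palindromic")
        action = "none" if o_ea == e_ea else "flip_beta"
        if o_ea != e_ea:
            beta_out, eaf_out = -beta_out, 1.0 - eaf_out
    elif (o_ea, o_oa) == (e_ea, e_oa):
        action = "none"
    elif (o_ea, o_oa) == (e_oa, e_ea):
        action = "flip_beta"
        beta_out = -beta_out
        eaf_out = 1.0 - eaf_out if not math.isnan(eaf_out) else math.nan
    else:
        c_ea, c_oa = complement(o_ea), complement(o_oa)
        if (c_ea, c_oa) == (e_ea, e_oa):
            action = "strand_flip"
        elif (c_ea, c_oa) == (e_oa, e_ea):
            action = "strand_flip_and_beta"
            beta_out = -beta_out
            eaf_out = 1.0 - eaf_out if not math.isnan(eaf_out) else math.nan
        else:
            return _dropped(exposure, outcome, "mismatch")

    beta_exp, eaf_exp = exposure.beta, exposure.eaf
    ea, oa = e_ea, e_oa
    if beta_exp < 0:
        # orient to the exposure-increasing allele
        beta_exp, beta_out = -beta_exp, -beta_out
        ea, oa = oa, ea
        eaf_exp = 1.0 - eaf_exp if not math.isnan(eaf_exp) else math.nan
        eaf_out = 1.0 - eaf_out if not math.isnan(eaf_out) else math.nan

    return HarmonizedInstrument(
        snp_id=exposure.snp_id, effect_allele=ea, other_allele=oa,
        beta_exp=beta_exp, se_exp=exposure.se,
        beta_out=beta_out, se_out=outcome.se,
        action=action, eaf_exp=eaf_exp, eaf_out=eaf_out,
    )


def harmonize(
    instruments: InstrumentSet | Sequence[VariantAssoc],
    outcome: SumstatsTable,
    palindromic_eaf_limit: float = 0.42,
) -> list[HarmonizedInstrument]:
    """Harmonize every instrument present in ``outcome``; audit every SNP.

    Instruments absent from the outcome table are skipped (use
    :func:`mrkit.instruments.intersect_with_outcome` first to account for
    them).  The returned list includes dropped SNPs so the harmonization
    audit is complete; filter with :func:`retained` before estimation.
    """
    out = []
    for rec in instruments:
        if rec.snp_id not in outcome:
            continue
        out.append(harmonize_pair(rec, outcome.get(rec.snp_id), palindromic_eaf_limit))
    n_drop = sum(h.dropped for h in out)
    if n_drop:
        logger.info("harmonize: dropped %d of %d SNP(s) (palindromic/mismatch)",
                    n_drop, len(out))
    return out


def retained(harmonized: Iterable[HarmonizedInstrument]) -> list[HarmonizedInstrument]:
    """The harmonized instruments that survived (non-dropped)."""
    return [h for h in harmonized if not h.dropped]


def to_frame(harmonized: Iterable[HarmonizedInstrument]) -> pd.DataFrame:
    """Tab-separated-ready audit table including the action column."""
    rows = []
    for h in harmonized:
        row = {
            "snp_id": h.snp_id, "effect_allele": h.effect_allele,
            "other_allele": h.other_allele,
            "beta_exp": h.beta_exp, "se_exp": h.se_exp,
            "beta_out": h.beta_out, "se_out": h.se_out,
            "eaf_exp": h.eaf_exp, "eaf_out": h.eaf_out,
            "action": h.action,
        }
        if not h.dropped and h.beta_exp != 0:
            row["ratio"], row["ratio_se"] = wald_ratio(h)
        else:
            row["ratio"] = row["ratio_se"] = math.nan
        rows.append(row)
    return pd.DataFrame(rows)
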