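import math

import numpy as np
import pytest
from hypothesis import settings

from mrkit.harmonize import HarmonizedInstrument
from mrkit.sumstats import SumstatsTable, VariantAssoc

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def variant(snp_id="rs1", chrom="1", pos=1000, ea="A", oa="G", beta=0.1,
            se=0.01, pvalue=1e-10, eaf=0.3, **kw) -> VariantAssoc:
    """Shorthand VariantAssoc constructor with sensible defaults."""
    return VariantAssoc(snp_id=snp_id, chrom=chrom, pos=pos, effect_allele=ea,
                        other_allele=oa, beta=beta, se=se, pvalue=pvalue,
                        eaf=eaf, **kw)


def hset(bx, by, sy, sx=None) -> list[HarmonizedInstrument]:
    """Build a harmonized instrument list from parallel effect arrays."""
    bx = np.asarray(bx, float)
    by = np.asarray(by, float)
    sy = np.asarray(sy, float)
    sx = np.full_like(bx, 1e-6) if sx is None else np.asarray(sx, float)
    return [
        HarmonizedInstrument(snp_id=f"rs{j + 1}", effect_allele="A",
                             other_allele="G", beta_exp=float(bx[j]),
                             se_exp=float(sx[j]), beta_out=float(by[j]),
                             se_out=float(sy[j]), action="none", eaf_exp=0.3,
                             eaf_out=0.3)
        for j in range(len(bx))
    ]


@pytest.fixture
def small_table() -> SumstatsTable:
    recs = [
        variant("rs1", "1", 1000, "A", "G", beta=0.10, se=0.01, pvalue=1e-10,
                eaf=0.30, info=0.95, missingness=0.01, hwe_p=0.5),
        variant("rs2", "1", 200_000, "T", "C", beta=-0.05, se=0.02, pvalue=1e-9,
                eaf=0.45, info=0.80, missingness=0.02, hwe_p=0.9),
        variant("rs3", "2", 5_000, "G", "C", beta=0.20, se=0.03, pvalue=4e-8,
                eaf=0.10, info=0.99, missingness=0.0, hwe_p=1.0),
    ]
    return SumstatsTable(recs, trait_label="toy", trait_type="quantitative")
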