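"""Shared fixtures: tiny hand-built tables and instrument sets."""

from __future__ import annotations

import numpy as np
import pytest

from mrmediate.harmonize import HarmonizedInstrument
from mrmediate.sumstats import SumstatsTable, VariantAssociation


def make_variant(
    variant_id: str,
    chrom: str = "1",
    pos: int = 1_000_000,
    ea: str = "A",
    oa: str = "G",
    eaf: float | None = 0.3,
    beta: float = 0.1,
    se: float = 0.01,
    pvalue: float = 1e-10,
    n: int = 10000,
) -> VariantAssociation:
    return VariantAssociation(
        variant_id=variant_id,
        chrom=chrom,
        pos=pos,
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        pvalue=pvalue,
        n=n,
    )


def make_table(records, trait_id="trait", trait_type="continuous") -> SumstatsTable:
    return SumstatsTable(trait_id=trait_id, trait_type=trait_type, records=tuple(records))


def make_instrument(
    variant_id: str = "rs1",
    beta_exp: float = 0.1,
    se_exp: float = 0.01,
    beta_out: float = 0.05,
    se_out: float = 0.01,
    **kwargs,
) -> HarmonizedInstrument:
    return HarmonizedInstrument(
        variant_id=variant_id,
        effect_allele="A",
        beta_exp=beta_exp,
        se_exp=se_exp,
        beta_out=beta_out,
        se_out=se_out,
        **kwargs,
    )


def instruments_from_ratios(ratios, ratio_ses, beta_exp=1.0, se_exp=0.01):
    """Instrument set whose Wald ratios and ratio SEs are exactly as given."""
    return [
        make_instrument(
            variant_id=f"rs{i}",
            beta_exp=beta_exp,
            se_exp=se_exp,
            beta_out=r * beta_exp,
            se_out=s * abs(beta_exp),
        )
        for i, (r, s) in enumerate(zip(ratios, ratio_ses))
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240522)


@pytest.fixture
def hand_ivw_instruments():
    """Ratios {0.5, 0.6, 0.7} with ratio SEs {0.1, 0.2, 0.1}."""
    return instruments_from_ratios([0.5, 0.6, 0.7], [0.1, 0.2, 0.1])
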