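import numpy as np
import pandas as pd
import pytest

from mrkit.harmonise import HarmonisedSet
from mrkit.sumstats import SumStatTable


def hset(gamma, se_gamma, Gamma, se_Gamma, snp_ids=None) -> HarmonisedSet:
    """Harmonised set straight from aligned effect arrays."""
    return HarmonisedSet.from_arrays(gamma, se_gamma, Gamma, se_Gamma, snp_ids)


def sim_hset(exposure: SumStatTable, outcome: SumStatTable) -> HarmonisedSet:
    """Fast path for simulated tables that share allele conventions by
    construction (skips the allele bookkeeping of full harmonisation)."""
    return HarmonisedSet.from_arrays(
        exposure.df["beta"].to_numpy(),
        exposure.df["se"].to_numpy(),
        outcome.df["beta"].to_numpy(),
        outcome.df["se"].to_numpy(),
        list(exposure.df["snp_id"]),
    )


def make_table(
    label="trait",
    trait_type="quantitative",
    snp_ids=("rs1", "rs2", "rs3"),
    chrom=None,
    pos=None,
    ea=None,
    oa=None,
    eaf=None,
    beta=None,
    se=None,
    pval=None,
    n=10_000,
    case_fraction=None,
) -> SumStatTable:
    k = len(snp_ids)
    return SumStatTable.from_arrays(
        label, trait_type,
        snp_id=list(snp_ids),
        chrom=chrom or ["1"] * k,
        pos=pos or list(range(100, 100 + k)),
        effect_allele=ea or ["A"] * k,
        other_allele=oa or ["G"] * k,
        eaf=eaf if eaf is not None else [0.3] * k,
        beta=beta if beta is not None else [0.1] * k,
        se=se if se is not None else [0.01] * k,
        pval=pval if pval is not None else [1e-9] * k,
        n=[n] * k,
        case_fraction=case_fraction,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def three_snp_table():
    return make_table()
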