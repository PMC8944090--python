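import numpy as np
import pandas as pd
import pytest

from repromr.mr import HARMONISED_COLUMNS, HarmonisedSet
from repromr.simulate import Block, CausalConfig, simulate_genotypes, simulate_traits
from repromr.sumstats import SummaryStats, build_table


@pytest.fixture(scope="session")
def small_panel():
    """10 independent blocks of 5 SNPs, 2000 individuals."""
    return simulate_genotypes(2000, [Block(5, 0.3) for _ in range(10)], seed=7)


@pytest.fixture(scope="session")
def cohort():
    """Mid-sized cohort with the default causal architecture."""
    panel = simulate_genotypes(8000, [Block(30, 0.4) for _ in range(15)], seed=11)
    config = CausalConfig(seed=11)
    return panel, simulate_traits(panel, config), config


def make_sumstats(snp, beta, se, eaf=None, ea="A", oa="G", chrom=1, pos=None,
                  n=10_000, trait_id="trait", **kwargs):
    k = len(snp)
    if eaf is None:
        eaf = np.full(k, 0.3)
    if pos is None:
        pos = np.arange(1, k + 1) * 100_000
    ea = [ea] * k if isinstance(ea, str) else ea
    oa = [oa] * k if isinstance(oa, str) else oa
    table = build_table(snp, chrom, pos, ea, oa, eaf, beta, se, n)
    return SummaryStats(table, trait_id=trait_id, **kwargs)


def make_harmonised(beta_exp, se_exp, beta_out, se_out, exposure="exp",
                    outcome="out"):
    k = len(beta_exp)
    table = pd.DataFrame({
        "snp": [f"rs{i + 1}" for i in range(k)],
        "beta_exp": beta_exp, "se_exp": se_exp,
        "beta_out": beta_out, "se_out": se_out,
        "eaf_exp": 0.3, "eaf_out": 0.3, "action": "kept",
    }, columns=HARMONISED_COLUMNS)
    return HarmonisedSet(table, exposure, outcome)


@pytest.fixture
def fixed_harmonised():
    """A fixed 5-SNP harmonised table used by the oracle tests."""
    return make_harmonised(
        beta_exp=[0.10, 0.08, -0.12, 0.05, 0.15],
        se_exp=[0.010, 0.012, 0.011, 0.009, 0.014],
        beta_out=[0.021, 0.018, -0.031, 0.008, 0.030],
        se_out=[0.008, 0.010, 0.009, 0.007, 0.012],
    )
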