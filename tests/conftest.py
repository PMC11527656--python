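import numpy as np
import pandas as pd
import pytest

from mrsuite.gwas_io import GwasTable, CANONICAL_COLUMNS
from mrsuite.harmonize import HarmonizedSet


def make_gwas(
    snp, beta, se, pval=None, chrom=None, pos=None, ea=None, oa=None,
    eaf=None, n=1000.0, name="trait", trait_type="continuous",
):
    """Build a GwasTable from parallel lists with sensible defaults."""
    k = len(snp)
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if pval is None:
        from scipy import stats

        pval = 2 * stats.norm.sf(np.abs(beta / se))
    df = pd.DataFrame(
        {
            "snp": snp,
            "chr": chrom if chrom is not None else ["1"] * k,
            "pos": pos if pos is not None else (np.arange(k) * 1_000_000 + 1),
            "effect_allele": ea if ea is not None else ["A"] * k,
            "other_allele": oa if oa is not None else ["G"] * k,
            "eaf": eaf if eaf is not None else [0.3] * k,
            "beta": beta,
            "se": se,
            "pval": pval,
            "n": n,
        }
    )[CANONICAL_COLUMNS]
    return GwasTable(trait_name=name, df=df, trait_type=trait_type)


def make_harmonized(beta_exp, se_exp, beta_out, se_out, **kw):
    n = len(beta_exp)
    return HarmonizedSet(
        snp_ids=[f"rs{i+1}" for i in range(n)],
        beta_exp=np.asarray(beta_exp, dtype=float),
        se_exp=np.asarray(se_exp, dtype=float),
        beta_out=np.asarray(beta_out, dtype=float),
        se_out=np.asarray(se_out, dtype=float),
        **kw,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_harmonized(rng):
    """A generic 25-variant harmonized set with mild heterogeneity."""
    n = 25
    gamma = rng.uniform(0.05, 0.3, n) * rng.choice([-1, 1], n)
    se_exp = rng.uniform(0.01, 0.02, n)
    se_out = rng.uniform(0.01, 0.02, n)
    big = 0.25 * gamma
    return make_harmonized(
        rng.normal(gamma, se_exp),
        se_exp,
        rng.normal(big, se_out),
        se_out,
    )
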