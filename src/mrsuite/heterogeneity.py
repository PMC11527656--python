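"""Heterogeneity diagnostics: Cochran's Q and leave-one-out analysis."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from mrsuite.estimators import MrEstimate, ivw, _ivw_core
from mrsuite.harmonize import HarmonizedSet


@dataclass
class HeterogeneityResult:
    """Cochran's Q against chi-square with (n_snp - 1) df."""

    q: float
    df: int
    pvalue: float


@dataclass
class LooTable:
    """Per-left-out-variant IVW estimates plus the all-variant row.

    ``df`` has one row per left-out snp (column ``left_out``) and a final
    row with ``left_out = "none"``; ``flagged`` lists left-out snps whose
    reduced-set CI excludes the full-set estimate.
    """

    df: pd.DataFrame
    flagged: list[str]

    def to_tsv(self, path: str | Path) -> Path:
        self.df.to_csv(path, sep="\t", index=False)
        return Path(path)


def cochran_q(h: HarmonizedSet, second_order: bool = False) -> HeterogeneityResult:
    """Q = sum (theta_i - theta_hat)^2 / v_i on the Wald-ratio scale.

    theta_hat is the fixed-effects IVW estimate; v_i = se_Gamma_i^2 /
    gamma_i^2 first-order ratio variances (``second_order`` adds the
    theta^2 se_gamma^2 / gamma^2 term).  Upper-tail chi-square p with
    n - 1 degrees of freedom.
    """
    n = len(h)
    if n < 2:
        raise ValueError("cochran_q needs >= 2 variants")
    if (h.beta_exp == 0).any():
        raise ValueError("gamma = 0 variants must be excluded upstream")
    theta_hat, _, _ = _ivw_core(h)
    ratio = h.beta_out / h.beta_exp
    v = h.se_out**2 / h.beta_exp**2
    if second_order:
        v = v + theta_hat**2 * h.se_exp**2 / h.beta_exp**2
    q = float(np.sum((ratio - theta_hat) ** 2 / v))
    df = n - 1
    return HeterogeneityResult(q=q, df=df, pvalue=float(stats.chi2.sf(q, df)))


def leave_one_out(h: HarmonizedSet, mode: str = "multiplicative_random_effects") -> LooTable:
    """IVW re-estimated with each variant left out in turn."""
    n = len(h)
    if n < 3:
        raise ValueError("leave_one_out needs >= 3 variants")
    full = ivw(h, mode=mode)
    rows = []
    flagged = []
    for i in range(n):
        sub = h.subset(np.arange(n) != i)
        e = ivw(sub, mode=mode)
        rows.append(
            dict(left_out=h.snp_ids[i], theta=e.theta, se=e.se,
                 ci_low=e.ci_low, ci_high=e.ci_high, pvalue=e.pvalue, n_snp=e.n_snp)
        )
        if not (e.ci_low <= full.theta <= e.ci_high):
            flagged.append(h.snp_ids[i])
    rows.append(
        dict(left_out="none", theta=full.theta, se=full.se,
             ci_low=full.ci_low, ci_high=full.ci_high, pvalue=full.pvalue,
             n_snp=full.n_snp)
    )
    return LooTable(df=pd.DataFrame(rows), flagged=flagged)
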