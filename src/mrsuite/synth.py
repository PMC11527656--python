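"""Synthetic GWAS summary statistics and expression matrices with known truth.

Summary statistics are generated directly at the summary level — no
individual genotypes — under the linear causal model

    Gamma_i = theta * gamma_i + alpha_i,

where gamma_i are true per-variant exposure effects, alpha_i direct
(pleiotropic) effects on the outcome, and the observed betas add
independent Gaussian measurement noise at the configured SE magnitudes.
Pleiotropy modes: ``none``; ``balanced`` (zero-mean alpha); ``directional``
(shifted-mean alpha, InSIDE holding); ``inside_violating`` (alpha
correlated with gamma through a Gaussian copula — the regime that breaks
MR-Egger's consistency, for negative-control tests).

``binary_outcome_scale`` shrinks the outcome side to the near-null
magnitude of linear-model betas on binary biobank traits (odds ratios
within ~0.5% of 1), the regime of plasma-protein exposures against
coronary-disease outcomes in large cohort GWAS.

Expression matrices are log2-scale Gaussian baselines with designated
gene sets shifted in cases by signed effects — a ground-truth-known
stand-in for a small case/control microarray comparison.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from mrsuite.gwas_io import GwasTable, CANONICAL_COLUMNS
from mrsuite.gsea import ExpressionMatrix
from mrsuite.instruments import LdMatrix


@dataclass
class MrSimConfig:
    """Study conditions for one simulated exposure/outcome GWAS pair.

    Defaults mirror a strong plasma-protein exposure instrumented by ~20
    variants (per-variant F well above 10) against a binary disease
    outcome when ``binary_outcome_scale`` is set.
    """

    n_snp: int = 20
    theta: float = 0.0
    gamma_low: float = 0.05  # |gamma| ~ Uniform(low, high), random sign
    gamma_high: float = 0.3
    se_exp_low: float = 0.01
    se_exp_high: float = 0.02
    se_out_low: float = 0.01
    se_out_high: float = 0.02
    pleiotropy_mode: str = "none"  # none|balanced|directional|inside_violating
    pleiotropy_scale: float = 0.0  # sd of alpha (and mean, when directional)
    inside_rho: float = 0.7  # corr(alpha, |gamma|) under inside_violating
    binary_outcome_scale: bool = False
    # effect allele oriented to increase the exposure (gamma > 0), the
    # reporting convention of large biobank protein GWAS
    orient_exposure_increasing: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snp < 1:
            raise ValueError("n_snp must be >= 1")
        if self.pleiotropy_mode not in (
            "none", "balanced", "directional", "inside_violating"
        ):
            raise ValueError(f"unknown pleiotropy_mode {self.pleiotropy_mode!r}")
        if self.pleiotropy_scale < 0:
            raise ValueError("pleiotropy_scale must be >= 0")


# shrink factor taking protein-scale effects to linear-probability scale
_BINARY_SHRINK = 1e-2


def simulate_mr_summary(
    cfg: MrSimConfig,
) -> tuple[GwasTable, GwasTable, dict]:
    """Draw one exposure/outcome summary-statistic pair plus the truth record.

    The truth record carries theta, the true gamma_i and alpha_i, so tests
    can score any estimator's recovery exactly.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snp
    if cfg.orient_exposure_increasing:
        sign = np.ones(n)
    else:
        sign = rng.choice([-1.0, 1.0], size=n)
    gamma = sign * rng.uniform(cfg.gamma_low, cfg.gamma_high, size=n)
    se_exp = rng.uniform(cfg.se_exp_low, cfg.se_exp_high, size=n)
    se_out = rng.uniform(cfg.se_out_low, cfg.se_out_high, size=n)

    scale = cfg.pleiotropy_scale
    if cfg.pleiotropy_mode == "none" or scale == 0:
        alpha = np.zeros(n)
    elif cfg.pleiotropy_mode == "balanced":
        alpha = rng.normal(0.0, scale, size=n)
    elif cfg.pleiotropy_mode == "directional":
        alpha = rng.normal(scale, scale / 4, size=n)
    else:  # inside_violating: Gaussian copula between alpha and |gamma|
        z = stats.norm.ppf(
            stats.uniform.cdf(np.abs(gamma), cfg.gamma_low,
                              cfg.gamma_high - cfg.gamma_low)
        )
        e = rng.standard_normal(n)
        alpha = scale * (cfg.inside_rho * z + np.sqrt(1 - cfg.inside_rho**2) * e)

    theta = cfg.theta
    if cfg.binary_outcome_scale:
        se_out = se_out * _BINARY_SHRINK
        alpha = alpha * _BINARY_SHRINK

    big_gamma = theta * gamma + alpha
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(big_gamma, se_out)

    snp = [f"rs{i+1:05d}" for i in range(n)]
    pos = np.arange(n) * 2_000_000 + 1_000_000  # well-spaced by default
    eaf = rng.uniform(0.05, 0.95, size=n)

    def table(name, beta, se, n_samp, trait_type):
        p = 2 * stats.norm.sf(np.abs(beta / se))
        p = np.maximum(p, np.nextafter(0, 1))
        return GwasTable(
            trait_name=name,
            trait_type=trait_type,
            df=pd.DataFrame(
                {
                    "snp": snp, "chr": ["1"] * n, "pos": pos,
                    "effect_allele": ["A"] * n, "other_allele": ["G"] * n,
                    "eaf": eaf, "beta": beta, "se": se, "pval": p,
                    "n": float(n_samp),
                }
            )[CANONICAL_COLUMNS],
        )

    exposure = table("sim_exposure", beta_exp, se_exp, 3000, "continuous")
    outcome = table(
        "sim_outcome", beta_out, se_out, 330_000,
        "binary" if cfg.binary_outcome_scale else "continuous",
    )
    truth = {
        "theta": theta,
        "gamma": gamma, "alpha": alpha, "big_gamma": big_gamma,
        "config": cfg,
    }
    return exposure, outcome, truth


def simulate_mvmr_summary(
    thetas: list[float],
    cfg: MrSimConfig,
    exposure_corr: float = 0.0,
) -> tuple[dict[str, GwasTable], GwasTable, dict]:
    """Joint panel for multivariable MR: k exposures, one outcome.

    Every variant carries a true effect on each exposure (pairwise
    correlation ``exposure_corr`` across exposures) and the outcome is
    Gamma_i = sum_j theta_j * gamma_ij (plus pleiotropy as configured).
    Returns ({label: exposure GwasTable}, outcome GwasTable, truth).
    """
    k = len(thetas)
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_snp
    # gamma magnitudes with optional cross-exposure correlation
    cov = np.full((k, k), exposure_corr)
    np.fill_diagonal(cov, 1.0)
    z = rng.multivariate_normal(np.zeros(k), cov, size=n)
    u = stats.norm.cdf(z)
    gamma = np.sign(rng.standard_normal((n, k))) * (
        cfg.gamma_low + u * (cfg.gamma_high - cfg.gamma_low)
    )
    se_exp = rng.uniform(cfg.se_exp_low, cfg.se_exp_high, size=(n, k))
    se_out = rng.uniform(cfg.se_out_low, cfg.se_out_high, size=n)
    alpha = (rng.normal(cfg.pleiotropy_scale, cfg.pleiotropy_scale / 4, size=n)
             if cfg.pleiotropy_mode == "directional" and cfg.pleiotropy_scale > 0
             else np.zeros(n))
    if cfg.binary_outcome_scale:
        se_out = se_out * _BINARY_SHRINK
        alpha = alpha * _BINARY_SHRINK
    big_gamma = gamma @ np.asarray(thetas) + alpha
    beta_exp = rng.normal(gamma, se_exp)
    beta_out = rng.normal(big_gamma, se_out)

    snp = [f"rs{i+1:05d}" for i in range(n)]
    pos = np.arange(n) * 2_000_000 + 1_000_000
    eaf = rng.uniform(0.05, 0.95, size=n)

    def table(name, beta, se, trait_type):
        p = np.maximum(2 * stats.norm.sf(np.abs(beta / se)), np.nextafter(0, 1))
        return GwasTable(
            trait_name=name, trait_type=trait_type,
            df=pd.DataFrame({
                "snp": snp, "chr": ["1"] * n, "pos": pos,
                "effect_allele": ["A"] * n, "other_allele": ["G"] * n,
                "eaf": eaf, "beta": beta, "se": se, "pval": p, "n": 3000.0,
            })[CANONICAL_COLUMNS],
        )

    exposures = {
        f"exposure_{j+1}": table(f"exposure_{j+1}", beta_exp[:, j], se_exp[:, j],
                                 "continuous")
        for j in range(k)
    }
    outcome = table(
        "sim_outcome", beta_out, se_out,
        "binary" if cfg.binary_outcome_scale else "continuous",
    )
    truth = {"thetas": list(thetas), "gamma": gamma, "alpha": alpha}
    return exposures, outcome, truth


def simulate_ld(
    n_snp: int, block_sizes: list[int], within_block_r2: float, seed: int = 0
) -> LdMatrix:
    """Block-diagonal r^2: ``within_block_r2`` inside blocks, 0 between."""
    if sum(block_sizes) != n_snp:
        raise ValueError("block sizes must partition n_snp")
    if not (0 <= within_block_r2 <= 1):
        raise ValueError("within_block_r2 must lie in [0, 1]")
    r2 = np.zeros((n_snp, n_snp))
    start = 0
    for b in block_sizes:
        r2[start : start + b, start : start + b] = within_block_r2
        start += b
    np.fill_diagonal(r2, 1.0)
    return LdMatrix(snp_ids=[f"rs{i+1:05d}" for i in range(n_snp)], r2=r2)


@dataclass
class ExprSimConfig:
    """Conditions for a synthetic log2 expression matrix.

    Defaults mirror a 3-vs-3 case/control microarray comparison: ~1,000
    genes, baseline N(7, 1) per gene with residual noise sd 0.5, and
    planted sets shifted in cases by their signed log2 effect.
    """

    n_genes: int = 1000
    n_per_group: int = 3
    planted_sets: dict[str, tuple[list[str], float]] = field(default_factory=dict)
    baseline_mean: float = 7.0
    baseline_sd: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0
    allow_overlap: bool = False

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if not self.allow_overlap:
            seen: set[str] = set()
            for name, (genes, _) in self.planted_sets.items():
                inter = seen & set(genes)
                if inter:
                    raise ValueError(f"planted sets overlap at {sorted(inter)[:3]}")
                seen |= set(genes)


def simulate_expression(cfg: ExprSimConfig) -> tuple[ExpressionMatrix, dict]:
    """Generate the matrix plus a truth record of planted sets/directions."""
    rng = np.random.default_rng(cfg.seed)
    genes = [f"G{i+1:05d}" for i in range(cfg.n_genes)]
    ns = 2 * cfg.n_per_group
    base = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=(cfg.n_genes, 1))
    vals = base + rng.normal(0.0, cfg.noise_sd, size=(cfg.n_genes, ns))
    groups = ["case"] * cfg.n_per_group + ["control"] * cfg.n_per_group
    gene_index = {g: i for i, g in enumerate(genes)}
    case_cols = np.array([g == "case" for g in groups])
    for name, (members, effect) in cfg.planted_sets.items():
        idx = [gene_index[g] for g in members if g in gene_index]
        vals[np.ix_(idx, np.flatnonzero(case_cols))] += effect
    mat = ExpressionMatrix(
        gene_ids=genes,
        sample_ids=[f"S{i+1}" for i in range(ns)],
        values=vals,
        groups=groups,
    )
    truth = {
        "planted_sets": {
            name: {"genes": members, "effect": effect}
            for name, (members, effect) in cfg.planted_sets.items()
        },
        "config": cfg,
    }
    return mat, truth
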