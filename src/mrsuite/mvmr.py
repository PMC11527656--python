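"""Multivariable MR: joint direct effects of several exposures.

The outcome effects Gamma are regressed on the n_snp x k matrix of
exposure effects with weights 1/se_out^2 — without intercept (MVMR-IVW)
or with one (MVMR-Egger, after orienting rows so the first exposure's
effect is non-negative).  Weights use the outcome SE only; exposure
measurement error is a documented limitation, not corrected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from mrsuite.estimators import MrEstimate, EggerIntercept, _wald_ci_p


@dataclass
class MvmrInput:
    """Per-variant effects on k >= 2 exposures and one outcome."""

    snp_ids: list[str]
    beta_exp: np.ndarray  # (n_snp, k)
    se_exp: np.ndarray  # (n_snp, k)
    beta_out: np.ndarray
    se_out: np.ndarray
    exposure_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.beta_exp = np.atleast_2d(np.asarray(self.beta_exp, dtype=float))
        self.se_exp = np.atleast_2d(np.asarray(self.se_exp, dtype=float))
        self.beta_out = np.asarray(self.beta_out, dtype=float)
        self.se_out = np.asarray(self.se_out, dtype=float)
        n, k = self.beta_exp.shape
        if self.exposure_names is None:
            self.exposure_names = [f"exposure_{j+1}" for j in range(k)]
        if self.se_exp.shape != (n, k) or self.beta_out.shape != (n,):
            raise ValueError("shape mismatch in MvmrInput")
        if (self.se_exp <= 0).any() or (self.se_out <= 0).any():
            raise ValueError("all SEs must be positive")
        if (self.beta_exp == 0).all(axis=0).any():
            raise ValueError("an exposure column is all zero")
        if np.linalg.matrix_rank(self.beta_exp) < k:
            raise ValueError("exposure effect matrix is rank deficient")

    @property
    def n_snp(self) -> int:
        return self.beta_exp.shape[0]

    @property
    def k(self) -> int:
        return self.beta_exp.shape[1]


def _wls(X: np.ndarray, y: np.ndarray, w: np.ndarray, df_resid: int,
         floor_dispersion: bool):
    """Weighted normal equations with multiplicative residual dispersion.

    ``floor_dispersion`` keeps the dispersion at >= 1 (the random-effects
    convention for IVW-type fits, never reporting less than the
    fixed-effects SE); the Egger-type fits leave it free so the intercept
    test is exactly t-distributed under the null.
    """
    xtwx = X.T @ (w[:, None] * X)
    try:
        xtwx_inv = np.linalg.inv(xtwx)
    except np.linalg.LinAlgError as exc:
        raise ValueError("design matrix is rank deficient") from exc
    coef = xtwx_inv @ (X.T @ (w * y))
    resid = y - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / max(df_resid, 1)
    if floor_dispersion:
        sigma2 = max(1.0, sigma2)
    cov = sigma2 * xtwx_inv
    return coef, np.sqrt(np.diag(cov))


def mvmr_ivw(m: MvmrInput) -> list[MrEstimate]:
    """Weighted multiple regression of Gamma on exposure betas, no intercept."""
    if m.n_snp < m.k + 1:
        raise ValueError(f"need >= k+1 = {m.k + 1} variants, got {m.n_snp}")
    w = 1.0 / m.se_out**2
    coef, ses = _wls(m.beta_exp, m.beta_out, w, m.n_snp - m.k,
                     floor_dispersion=True)
    out = []
    for name, b, s in zip(m.exposure_names, coef, ses):
        (lo, hi), p = _wald_ci_p(float(b), float(s))
        out.append(
            MrEstimate("mvmr_ivw", float(b), float(s), lo, hi, p,
                       n_snp=m.n_snp, extra={"exposure": name})
        )
    return out


def mvmr_egger(m: MvmrInput) -> tuple[list[MrEstimate], EggerIntercept]:
    """As mvmr_ivw but with an intercept, rows oriented on the first exposure."""
    if m.n_snp < m.k + 2:
        raise ValueError(f"need >= k+2 = {m.k + 2} variants, got {m.n_snp}")
    sign = np.where(m.beta_exp[:, 0] < 0, -1.0, 1.0)
    X = np.column_stack([np.ones(m.n_snp), sign[:, None] * m.beta_exp])
    y = sign * m.beta_out
    w = 1.0 / m.se_out**2
    df = m.n_snp - m.k - 1
    coef, ses = _wls(X, y, w, df, floor_dispersion=False)
    out = []
    for name, b, s in zip(m.exposure_names, coef[1:], ses[1:]):
        (lo, hi), p = _wald_ci_p(float(b), float(s), dist="t", df=df)
        out.append(
            MrEstimate("mvmr_egger", float(b), float(s), lo, hi, p,
                       n_snp=m.n_snp, extra={"exposure": name})
        )
    p_int = 2 * stats.t.sf(abs(coef[0] / ses[0]), df)
    return out, EggerIntercept(float(coef[0]), float(ses[0]), float(p_int))
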