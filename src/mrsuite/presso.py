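"""MR-PRESSO: pleiotropy residual sum and outlier test.

Three stages, all simulation-based:

1. **Global test** — for each variant i, predict its outcome effect from
   the leave-one-out IVW slope, accumulate the standardized residual sum
   of squares, and compare against the RSS distribution of parametric
   replicates drawn under the no-pleiotropy model.
2. **Outlier test** — each variant's observed residual contribution is
   referred to its own simulated distribution; Bonferroni across variants.
3. **Distortion test** — the shift between the all-variant and
   outlier-removed estimates is compared with the shifts produced by
   removing random subsets of the same size.

The corrected estimate is IVW on the non-outlier variants.  With fewer
than four variants the result is marked inapplicable (reported as NA,
matching how published MR tables print PRESSO for tiny instrument sets).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mrsuite.estimators import MrEstimate, ivw
from mrsuite.harmonize import HarmonizedSet


@dataclass
class PressoResult:
    rss_obs: float | None
    global_p: float | None
    outlier_p: dict[str, float] = field(default_factory=dict)
    outliers: list[str] = field(default_factory=list)
    distortion_p: float | None = None
    corrected: MrEstimate | None = None
    na_reason: str | None = None

    @property
    def applicable(self) -> bool:
        return self.na_reason is None


def _loo_residuals(bx: np.ndarray, by: np.ndarray, sx: np.ndarray, sy: np.ndarray):
    """Per-variant standardized LOO residuals, vectorized.

    Works on 1-D observed data or a (n_sim, n) batch of simulated data.
    Returns (rss_contributions, total_rss) with the same leading shape.
    """
    w = 1.0 / sy**2  # weights from the observed outcome SEs
    sxx = np.sum(w * bx**2, axis=-1, keepdims=True)
    sxy = np.sum(w * bx * by, axis=-1, keepdims=True)
    theta_loo = (sxy - w * bx * by) / (sxx - w * bx**2)
    resid = by - theta_loo * bx
    var = sy**2 + theta_loo**2 * sx**2  # expected variance of the residual
    contrib = resid**2 / var
    return contrib, np.sum(contrib, axis=-1)


def presso(
    h: HarmonizedSet,
    n_sim: int = 1000,
    sig: float = 0.05,
    seed: int | None = None,
    n_distortion: int = 1000,
) -> PressoResult:
    """Run the global, outlier and distortion tests on a harmonized set."""
    n = len(h)
    if n < 4:
        return PressoResult(rss_obs=None, global_p=None,
                            na_reason=f"needs >= 4 variants, got {n}")
    if n_sim < 100:
        raise ValueError("n_sim must be >= 100 for usable p resolution")
    if seed is None:
        raise ValueError("seed is mandatory")
    rng = np.random.default_rng(seed)
    bx, by, sx, sy = h.beta_exp, h.beta_out, h.se_exp, h.se_out

    contrib_obs, rss_obs = _loo_residuals(bx, by, sx, sy)

    # parametric replicates under the no-pleiotropy LOO model
    w = 1.0 / sy**2
    sxx = np.sum(w * bx**2)
    sxy = np.sum(w * bx * by)
    theta_loo = (sxy - w * bx * by) / (sxx - w * bx**2)
    by_hat = theta_loo * bx
    by_sim = rng.normal(by_hat, sy, size=(n_sim, n))
    bx_sim = rng.normal(bx, sx, size=(n_sim, n))
    contrib_sim, rss_sim = _loo_residuals(bx_sim, by_sim, sx, sy)

    global_p = float((1 + np.sum(rss_sim >= rss_obs)) / (n_sim + 1))

    # per-variant outlier p, Bonferroni across variants
    outlier_p = {}
    outliers = []
    for i, snp in enumerate(h.snp_ids):
        p_i = float((1 + np.sum(contrib_sim[:, i] >= contrib_obs[i])) / (n_sim + 1))
        outlier_p[snp] = p_i
        if p_i * n < sig:
            outliers.append(snp)

    result = PressoResult(
        rss_obs=float(rss_obs), global_p=global_p,
        outlier_p=outlier_p, outliers=outliers,
    )
    if not outliers or n - len(outliers) < 2:
        return result

    mask = np.array([s not in outliers for s in h.snp_ids])
    corrected = ivw(h.subset(mask))
    raw = ivw(h)
    result.corrected = corrected

    # distortion: observed shift vs shifts from random same-size removals
    k = len(outliers)
    denom = abs(corrected.theta) if corrected.theta != 0 else np.finfo(float).tiny
    d_obs = (raw.theta - corrected.theta) / denom
    d_null = np.empty(n_distortion)
    idx = np.arange(n)
    for b in range(n_distortion):
        drop = rng.choice(idx, size=k, replace=False)
        keep = np.setdiff1d(idx, drop)
        e = ivw(h.subset(keep))
        dnm = abs(e.theta) if e.theta != 0 else np.finfo(float).tiny
        d_null[b] = (raw.theta - e.theta) / dnm
    result.distortion_p = float(
        (1 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_distortion + 1)
    )
    return result
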