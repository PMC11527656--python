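"""Univariable two-sample MR estimators.

All methods operate on a :class:`~mrsuite.harmonize.HarmonizedSet` of
per-variant effect pairs (gamma_i, Gamma_i) with standard errors, and
return a :class:`MrEstimate` on the beta scale; :func:`to_or_scale`
exponentiates for odds-ratio reporting.

* Wald ratio      theta_i = Gamma_i / gamma_i,  se = se_Gamma / |gamma_i|
* IVW             origin-constrained weighted regression of Gamma on gamma,
                  weights 1/se_Gamma^2; multiplicative-random-effects SE
                  inflation max(1, sqrt(Q/(n-1))) is the default
* MR-Egger        the same regression with a free intercept (average
                  directional pleiotropy), after orienting gamma_i >= 0;
                  t(n-2) reference
* Weighted median consistent when valid instruments carry > 50% of weight;
                  parametric-bootstrap SE
* RAPS            profile-likelihood estimate under
                  Gamma_i ~ N(theta*gamma_i, se_Gamma^2 + theta^2 se_gamma^2
                  + tau^2), optionally with a Huber-robustified loss

These are written from the estimating equations directly (no MR package);
tests cross-check the linear ones against a generic WLS solver.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, optimize, stats

from mrsuite.harmonize import HarmonizedSet

Z975 = stats.norm.ppf(0.975)


@dataclass
class MrEstimate:
    """A causal-effect estimate from one method (beta scale).

    ``or_scale``, when present, holds (OR, OR CI low, OR CI high) =
    exp of the beta-scale point estimate and Wald interval.
    """

    method: str
    theta: float
    se: float
    ci_low: float
    ci_high: float
    pvalue: float
    n_snp: int
    or_scale: tuple[float, float, float] | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError("se must be positive")
        if not (self.ci_low <= self.theta <= self.ci_high):
            raise ValueError("CI must bracket the point estimate")


@dataclass
class EggerIntercept:
    """MR-Egger intercept: average directional pleiotropy per variant."""

    intercept: float
    se: float
    pvalue: float


def _wald_ci_p(theta: float, se: float, dist: str = "normal", df: int = 0):
    ci = (theta - Z975 * se, theta + Z975 * se)
    if dist == "t":
        p = 2 * stats.t.sf(abs(theta / se), df)
        ci = (theta - stats.t.ppf(0.975, df) * se, theta + stats.t.ppf(0.975, df) * se)
    else:
        p = 2 * stats.norm.sf(abs(theta / se))
    return ci, float(max(p, np.nextafter(0, 1)))


def wald_ratio(
    beta_exp: float, se_exp: float, beta_out: float, se_out: float
) -> MrEstimate:
    """Single-variant ratio estimate with the first-order delta-method SE."""
    if beta_exp == 0:
        raise ValueError("wald_ratio undefined for gamma = 0")
    theta = beta_out / beta_exp
    se = se_out / abs(beta_exp)
    (lo, hi), p = _wald_ci_p(theta, se)
    return MrEstimate("wald_ratio", theta, se, lo, hi, p, n_snp=1)


def _ivw_core(h: HarmonizedSet) -> tuple[float, float, float]:
    """Return (theta, fixed-effects se, Q) for the origin-constrained WLS."""
    w = 1.0 / h.se_out**2
    sxx = float(np.sum(w * h.beta_exp**2))
    sxy = float(np.sum(w * h.beta_exp * h.beta_out))
    theta = sxy / sxx
    se_fe = 1.0 / np.sqrt(sxx)
    q = float(np.sum(w * (h.beta_out - theta * h.beta_exp) ** 2))
    return theta, se_fe, q


def ivw(h: HarmonizedSet, mode: str = "multiplicative_random_effects") -> MrEstimate:
    """Inverse-variance-weighted estimate.

    Fixed effects: se = 1/sqrt(sum w_i gamma_i^2).  Multiplicative random
    effects (default) inflates the SE by max(1, sqrt(Q/(n-1))), never
    deflating below the fixed-effects value.
    """
    n = len(h)
    if n < 2:
        raise ValueError("ivw needs >= 2 variants; use wald_ratio for one")
    if mode not in ("fixed", "multiplicative_random_effects"):
        raise ValueError(f"unknown mode {mode!r}")
    theta, se, q = _ivw_core(h)
    if mode == "multiplicative_random_effects":
        se = se * max(1.0, np.sqrt(q / (n - 1)))
    (lo, hi), p = _wald_ci_p(theta, se)
    return MrEstimate("ivw_" + ("fe" if mode == "fixed" else "mre"),
                      theta, se, lo, hi, p, n_snp=n, extra={"Q": q})


def _oriented(h: HarmonizedSet) -> tuple[np.ndarray, np.ndarray]:
    """Orient each pair so gamma_i >= 0 (negating both members)."""
    sign = np.where(h.beta_exp < 0, -1.0, 1.0)
    return sign * h.beta_exp, sign * h.beta_out


def egger(h: HarmonizedSet) -> tuple[MrEstimate, EggerIntercept]:
    """MR-Egger regression: WLS of Gamma on gamma with a free intercept.

    Solved from the weighted normal equations; coefficient SEs scale with
    the multiplicative residual dispersion RSS/(n-2) (unfloored, so the
    intercept test is exactly t(n-2) under the no-pleiotropy null).
    """
    n = len(h)
    if n < 3:
        raise ValueError("egger needs >= 3 variants")
    x, y = _oriented(h)
    w = 1.0 / h.se_out**2
    X = np.column_stack([np.ones(n), x])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * y)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = y - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / (n - 2)
    cov = sigma2 * np.linalg.inv(xtwx)
    se_b0, se_b1 = np.sqrt(np.diag(cov))
    (lo, hi), p_slope = _wald_ci_p(coef[1], se_b1, dist="t", df=n - 2)
    _, p_int = _wald_ci_p(coef[0], se_b0, dist="t", df=n - 2)
    est = MrEstimate("egger", float(coef[1]), float(se_b1), lo, hi, p_slope, n_snp=n)
    return est, EggerIntercept(float(coef[0]), float(se_b0), p_int)


def weighted_median(
    h: HarmonizedSet, n_boot: int = 1000, seed: int | None = None
) -> MrEstimate:
    """Weighted median of the per-variant ratio estimates.

    Weights w_i = gamma_i^2 / se_Gamma_i^2 (inverse first-order ratio
    variance), normalized; the estimate interpolates the weighted CDF of
    sorted ratios at 0.5 using cumulative-weight midpoints.  The SE comes
    from a parametric bootstrap resampling (gamma_i, Gamma_i) from normals.
    """
    n = len(h)
    if n < 3:
        raise ValueError("weighted_median needs >= 3 variants")
    if seed is None:
        raise ValueError("seed is mandatory for the bootstrap")

    def wm(bexp: np.ndarray, bout: np.ndarray) -> float:
        ratio = bout / bexp
        w = bexp**2 / h.se_out**2
        order = np.argsort(ratio, kind="stable")
        ratio, w = ratio[order], w[order]
        w = w / w.sum()
        mid = np.cumsum(w) - 0.5 * w
        return float(np.interp(0.5, mid, ratio))

    theta = wm(h.beta_exp, h.beta_out)
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for b in range(n_boot):
        bexp = rng.normal(h.beta_exp, h.se_exp)
        bout = rng.normal(h.beta_out, h.se_out)
        boots[b] = wm(bexp, bout)
    se = float(np.std(boots, ddof=1))
    (lo, hi), p = _wald_ci_p(theta, se)
    return MrEstimate("weighted_median", theta, se, lo, hi, p, n_snp=n)


_HUBER_C = 1.345


def _huber_delta(c: float = _HUBER_C) -> float:
    """E[rho'(Z) Z]/... consistency constant: E[psi(Z) Z] under Z~N(0,1)."""
    val, _ = integrate.quad(
        lambda z: np.clip(z, -c, c) * z * stats.norm.pdf(z), -np.inf, np.inf
    )
    return val


def raps(
    h: HarmonizedSet,
    overdispersion: bool = True,
    loss: str = "squared",
) -> MrEstimate:
    """Robust adjusted profile score estimate.

    Solves the adjusted profile-score estimating equations of the
    measurement-error model

        Gamma_i ~ N(theta*gamma_i, v_i),
        v_i = se_Gamma_i^2 + theta^2 se_gamma_i^2 + tau^2,

    with standardized residuals t_i = (Gamma_i - theta*gamma_i)/sqrt(v_i):

        theta:  sum_i psi(t_i) [gamma_i/sqrt(v_i) + t_i theta se_gamma_i^2/v_i] = 0
        tau^2:  sum_i (psi(t_i) t_i - delta)/v_i = 0      (overdispersion only)

    where psi is the identity (squared loss) or the Huber psi with tuning
    constant 1.345 (``loss="huber"``) and delta = E[psi(Z)Z] under
    Z ~ N(0,1) makes the tau^2 equation unbiased.  Both equations have
    mean zero at the truth, which removes the Neyman-Scott bias a naive
    profile likelihood would incur from the n nuisance gamma_i.  The SE
    is the sandwich estimate from the per-variant score contributions.
    """
    n = len(h)
    if n < 3:
        raise ValueError("raps needs >= 3 variants")
    if loss not in ("squared", "huber"):
        raise ValueError(f"unknown loss {loss!r}")
    bx, sx, by, sy = h.beta_exp, h.se_exp, h.beta_out, h.se_out
    delta = 1.0 if loss == "squared" else _huber_delta()

    def psi(t: np.ndarray) -> np.ndarray:
        if loss == "squared":
            return t
        return np.clip(t, -_HUBER_C, _HUBER_C)

    def contribs(params: np.ndarray) -> np.ndarray:
        """(n, k) per-variant estimating-equation contributions."""
        theta = params[0]
        tau2 = params[1] if overdispersion else 0.0
        var = sy**2 + theta**2 * sx**2 + tau2
        r = by - theta * bx
        t = r / np.sqrt(var)
        p = psi(t)
        g_theta = p * (bx / np.sqrt(var) + t * theta * sx**2 / var)
        if not overdispersion:
            return g_theta[:, None]
        g_tau = (p * t - delta) / var
        return np.column_stack([g_theta, g_tau])

    def equations(params: np.ndarray) -> np.ndarray:
        return contribs(params).sum(axis=0)

    def g_theta_at(theta: float, tau2: float) -> float:
        var = sy**2 + theta**2 * sx**2 + tau2
        t = (by - theta * bx) / np.sqrt(var)
        p = psi(t)
        return float(np.sum(p * (bx / np.sqrt(var) + t * theta * sx**2 / var)))

    def g_tau_at(theta: float, tau2: float) -> float:
        var = sy**2 + theta**2 * sx**2 + tau2
        t = (by - theta * bx) / np.sqrt(var)
        return float(np.sum((psi(t) * t - delta) / var))

    def solve_tau2(theta: float) -> float:
        """g_tau is decreasing in tau^2; bracket by doubling, then brentq."""
        if not overdispersion or g_tau_at(theta, 0.0) <= 0:
            return 0.0
        hi = float(np.mean(sy**2))
        for _ in range(200):
            if g_tau_at(theta, hi) < 0:
                break
            hi *= 2
        else:
            raise RuntimeError("raps failed to converge: tau^2 unbounded")
        return float(optimize.brentq(lambda s: g_tau_at(theta, s), 0.0, hi,
                                     xtol=1e-14, rtol=1e-12))

    def profile_score(theta: float) -> float:
        return g_theta_at(theta, solve_tau2(theta))

    theta0, se0, _ = _ivw_core(h)
    # expanding bracket around the IVW start; the score crosses zero there
    span = max(10 * se0, 1e-3 * max(1.0, abs(theta0)))
    lo_b, hi_b = theta0 - span, theta0 + span
    f_lo, f_hi = profile_score(lo_b), profile_score(hi_b)
    for _ in range(60):
        if f_lo * f_hi <= 0:
            break
        span *= 2
        lo_b, hi_b = theta0 - span, theta0 + span
        f_lo, f_hi = profile_score(lo_b), profile_score(hi_b)
    else:
        raise RuntimeError("raps failed to converge: no sign change in score")
    theta = float(optimize.brentq(profile_score, lo_b, hi_b,
                                  xtol=1e-12, rtol=1e-12))
    tau2 = solve_tau2(theta)
    if overdispersion and tau2 == 0.0:
        overdispersion = False  # boundary solution: report tau^2 = 0
    params = np.array([theta, tau2]) if overdispersion else np.array([theta])

    # sandwich variance A^-1 B A^-T with numerical Jacobian A
    k = len(params)
    g = contribs(params)
    B = g.T @ g
    eps = 1e-6 * np.maximum(np.abs(params), 1e-3)
    A = np.empty((k, k))
    for j in range(k):
        pp, pm = params.copy(), params.copy()
        pp[j] += eps[j]
        pm[j] -= eps[j]
        A[:, j] = (equations(pp) - equations(pm)) / (2 * eps[j])
    try:
        Ainv = np.linalg.inv(A)
        cov = Ainv @ B @ Ainv.T
        se = float(np.sqrt(max(cov[0, 0], 0.0)))
    except np.linalg.LinAlgError:
        se = float("nan")
    if not np.isfinite(se) or se <= 0:
        # Fisher-information fallback at the solution
        var = sy**2 + theta**2 * sx**2 + tau2
        se = float(1.0 / np.sqrt(np.sum(bx**2 / var)))
    (lo, hi), p = _wald_ci_p(theta, se)
    return MrEstimate(
        "raps", theta, se, lo, hi, p, n_snp=n,
        extra={"tau2": max(tau2, 0.0), "loss": loss,
               "overdispersion": overdispersion},
    )


def to_or_scale(e: MrEstimate) -> MrEstimate:
    """Attach the exponentiated (OR, CI) triple; beta-scale fields unchanged."""
    e.or_scale = (float(np.exp(e.theta)), float(np.exp(e.ci_low)), float(np.exp(e.ci_high)))
    return e
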