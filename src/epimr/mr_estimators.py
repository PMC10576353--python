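"""Two-sample Mendelian randomization estimators from summary statistics.

Given allele-aligned per-variant effects on an exposure (beta_X, SD units)
and a binary outcome (beta_Y, log-odds), these estimators combine the
per-variant ratio information into a causal log-odds-ratio per exposure SD:

- Wald ratio: single instrument, beta_Y / beta_X with first-order delta SE.
- Fixed-effects IVW: precision-weighted regression of beta_Y on beta_X
  through the origin, weights 1/SE_Y^2.
- Correlated-instrument IVW: the same regression by generalized least
  squares with outcome covariance Omega = D rho D (D = diag(SE_Y)), for
  instruments in linkage disequilibrium.
- MR-Egger: weighted regression with a free intercept; a nonzero
  intercept indicates directional horizontal pleiotropy.

All confidence intervals use the normal quantile z = 1.959964.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .summary_associations import HarmonizedInstrument, InstrumentSet

Z95 = 1.959964


@dataclass(frozen=True)
class MRResult:
    """Causal-effect estimate on the log-OR-per-exposure-SD scale."""

    method: str
    beta_causal: float
    se: float
    or_point: float
    ci_low: float
    ci_high: float
    p_value: float
    n_instruments: int
    egger_intercept: float | None = None
    egger_intercept_se: float | None = None
    pleiotropy_p: float | None = None


@dataclass(frozen=True)
class HeterogeneityTest:
    """Cochran Q between independent stratum estimates (fixed-effect pooling)."""

    q_statistic: float
    df: int
    p_value: float


def _result(method: str, beta: float, se: float, k: int, **extra) -> MRResult:
    z = beta / se
    return MRResult(
        method=method,
        beta_causal=beta,
        se=se,
        or_point=float(np.exp(beta)),
        ci_low=float(np.exp(beta - Z95 * se)),
        ci_high=float(np.exp(beta + Z95 * se)),
        p_value=float(2 * stats.norm.sf(abs(z))),
        n_instruments=k,
        **extra,
    )


def wald_ratio(instrument: HarmonizedInstrument, second_order: bool = False) -> MRResult:
    """Single-instrument ratio estimate beta_Y / beta_X.

    The default SE is the first-order delta approximation SE_Y/|beta_X|;
    ``second_order`` adds the exposure-uncertainty term
    beta_Y^2 SE_X^2 / beta_X^4 under the square root.
    """
    bx, by = instrument.beta_exposure, instrument.beta_outcome
    if bx == 0:
        raise ValueError(f"{instrument.variant_id}: beta_exposure is zero; Wald ratio undefined")
    beta = by / bx
    var = (instrument.se_outcome / bx) ** 2
    if second_order:
        var += by**2 * instrument.se_exposure**2 / bx**4
    return _result("wald", beta, float(np.sqrt(var)), 1)


def ivw_fixed(instrument_set: InstrumentSet, random_effects: bool = False) -> MRResult:
    """Fixed-effects inverse-variance-weighted estimate.

    beta = sum(bx*by/sy^2) / sum(bx^2/sy^2); se = sum(bx^2/sy^2)^(-1/2).
    With ``random_effects`` the SE is inflated by the multiplicative
    overdispersion factor max(1, sigma_hat) estimated from the weighted
    residuals (needs >= 2 instruments to be meaningful).
    """
    if len(instrument_set) == 0:
        raise ValueError("empty instrument set")
    bx = instrument_set.beta_exposure
    by = instrument_set.beta_outcome
    sy = instrument_set.se_outcome
    w = 1.0 / sy**2
    denom = float(np.sum(bx**2 * w))
    beta = float(np.sum(bx * by * w)) / denom
    se = denom**-0.5
    k = len(instrument_set)
    if random_effects and k >= 2:
        rss = float(np.sum(w * (by - beta * bx) ** 2))
        sigma = np.sqrt(rss / (k - 1))
        se *= max(1.0, sigma)
    return _result("ivw", beta, se, k)


def ivw_correlated(instrument_set: InstrumentSet) -> MRResult:
    """IVW accounting for instrument correlation via generalized least squares.

    Regression of beta_Y on beta_X through the origin with outcome
    covariance Omega = D rho D, D = diag(SE_Y). Requires a positive
    definite correlation matrix on the instrument set.
    """
    rho = instrument_set.correlation
    if rho is None:
        raise ValueError("instrument set carries no correlation matrix")
    bx = instrument_set.beta_exposure
    by = instrument_set.beta_outcome
    sy = instrument_set.se_outcome
    omega = np.outer(sy, sy) * rho
    try:
        chol = np.linalg.cholesky(omega)
    except np.linalg.LinAlgError as exc:
        raise ValueError("correlation matrix yields non-positive-definite Omega") from exc
    # solve via Cholesky for numerical stability
    xw = np.linalg.solve(chol, bx)
    yw = np.linalg.solve(chol, by)
    denom = float(xw @ xw)
    beta = float(xw @ yw) / denom
    se = denom**-0.5
    return _result("ivw_correlated", beta, se, len(instrument_set))


def mr_egger(
    instrument_set: InstrumentSet,
    fix_intercept: bool = False,
    t_dist: bool = False,
) -> MRResult:
    """MR-Egger regression: weighted regression of beta_Y on beta_X with intercept.

    Instruments are oriented so every beta_X >= 0 (both betas flipped
    where needed; the slope is invariant, the intercept is only
    identified under this orientation). Weights 1/SE_Y^2. Both SEs are
    multiplied by the residual scale max(1, sigma_hat) with
    sigma_hat^2 = weighted RSS/(k-2). P-values use the normal reference
    by default, or Student t with k-2 df when ``t_dist`` is set.

    ``fix_intercept`` constrains the intercept to zero (an internal mode
    that reproduces fixed-effects IVW).
    """
    k = len(instrument_set)
    if fix_intercept:
        return ivw_fixed(instrument_set)
    if k < 3:
        raise ValueError(f"MR-Egger requires >= 3 instruments, got {k}")
    bx = instrument_set.beta_exposure.copy()
    by = instrument_set.beta_outcome.copy()
    sy = instrument_set.se_outcome
    neg = bx < 0
    bx[neg] *= -1
    by[neg] *= -1
    w = 1.0 / sy**2
    X = np.column_stack([np.ones(k), bx])
    xtwx = X.T @ (w[:, None] * X)
    xtwy = X.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    cov = np.linalg.inv(xtwx)
    resid = by - X @ coef
    sigma2 = float(np.sum(w * resid**2)) / (k - 2)
    scale = max(1.0, np.sqrt(sigma2))
    intercept, slope = coef
    se_int = float(np.sqrt(cov[0, 0])) * scale
    se_slope = float(np.sqrt(cov[1, 1])) * scale

    if t_dist:
        p_slope = float(2 * stats.t.sf(abs(slope / se_slope), df=k - 2))
        p_int = float(2 * stats.t.sf(abs(intercept / se_int), df=k - 2))
    else:
        p_slope = float(2 * stats.norm.sf(abs(slope / se_slope)))
        p_int = float(2 * stats.norm.sf(abs(intercept / se_int)))
    return MRResult(
        method="egger",
        beta_causal=float(slope),
        se=se_slope,
        or_point=float(np.exp(slope)),
        ci_low=float(np.exp(slope - Z95 * se_slope)),
        ci_high=float(np.exp(slope + Z95 * se_slope)),
        p_value=p_slope,
        n_instruments=k,
        egger_intercept=float(intercept),
        egger_intercept_se=se_int,
        pleiotropy_p=p_int,
    )


def heterogeneity_q(estimates) -> HeterogeneityTest:
    """Cochran Q across stratum estimates (e.g. men vs women per-SD effects).

    ``estimates`` is an iterable of (beta, se) pairs. Q = sum w_i
    (beta_i - pooled)^2 with w_i = 1/se_i^2 and the inverse-variance
    pooled mean; the p-value is the chi-square upper tail at
    (count - 1) degrees of freedom.
    """
    pairs = list(estimates)
    if len(pairs) < 2:
        raise ValueError("heterogeneity test needs >= 2 estimates")
    beta = np.array([b for b, _ in pairs], dtype=float)
    se = np.array([s for _, s in pairs], dtype=float)
    if np.any(se <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / se**2
    pooled = float(np.sum(w * beta) / np.sum(w))
    q = float(np.sum(w * (beta - pooled) ** 2))
    df = len(pairs) - 1
    return HeterogeneityTest(q_statistic=q, df=df, p_value=float(stats.chi2.sf(q, df)))


def estimate_from_ci(or_point: float, ci_low: float, ci_high: float) -> tuple[float, float]:
    """Recover (log-OR, SE) from a printed OR and 95% CI (width / 2*1.96)."""
    return float(np.log(or_point)), float((np.log(ci_high) - np.log(ci_low)) / (2 * Z95))
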