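"""Conditional-logistic inference for 1:1 incidence-density matched sets.

A nested case-control study with incidence-density sampling conditions on
matched sets (one case, its matched control(s)); the conditional-logistic
odds ratios then estimate incidence rate ratios and are interpreted as
relative risks. This module provides the covariate-construction steps
(sex-specific quintile coding with control-based cut-offs, per-control-SD
standardization, BMI/height-adjusted waist residuals, the a-body-shape
index) and the inference engine (Newton-Raphson conditional logistic fit,
likelihood-ratio tests, fractional-polynomial non-linearity scan,
Spearman partial correlations).

Cohort data are carried as a pandas DataFrame with one row per subject,
a matched-set label column, a case indicator, a sex column, and covariate
columns; missing values are NaN ("NA" on disk).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

FP1_POWERS = (-2.0, -1.0, -0.5, 0.0, 0.5, 1.0, 2.0, 3.0)


@dataclass
class Subject:
    """One study participant within a matched set."""

    subject_id: str
    set_id: str
    is_case: bool
    sex: str
    age: float | None = None
    biomarker: float | None = None
    weight: float | None = None
    height: float | None = None
    bmi: float | None = None
    waist: float | None = None
    categories: dict = field(default_factory=dict)
    continuous: dict = field(default_factory=dict)


@dataclass
class MatchedSet:
    """Exactly one case plus its matched control(s)."""

    set_id: str
    members: list[Subject]

    def __post_init__(self) -> None:
        n_cases = sum(m.is_case for m in self.members)
        if n_cases != 1:
            raise ValueError(f"set {self.set_id}: expected exactly one case, found {n_cases}")


def sets_to_frame(sets: Iterable[MatchedSet]) -> pd.DataFrame:
    """Flatten matched sets into the one-row-per-subject DataFrame layout."""
    rows = []
    for s in sets:
        for m in s.members:
            row = {
                "subject_id": m.subject_id,
                "set_id": s.set_id,
                "is_case": int(m.is_case),
                "sex": m.sex,
                "age": m.age,
                "biomarker": m.biomarker,
                "weight": m.weight,
                "height": m.height,
                "bmi": m.bmi,
                "waist": m.waist,
            }
            row.update(m.categories)
            row.update(m.continuous)
            rows.append(row)
    return pd.DataFrame(rows)


def _as_frame(data) -> pd.DataFrame:
    if isinstance(data, pd.DataFrame):
        return data
    return sets_to_frame(data)


# ---------------------------------------------------------------------------
# covariate construction


def absi(waist_cm, weight_kg, height_cm):
    """A-body-shape index: waist (mm) x weight(kg)^(-2/3) x height(m)^(5/6).

    Inputs are in clinical units (waist and height in cm, weight in kg);
    the mm and m conversions are internal. Vectorized.
    """
    waist_cm = np.asarray(waist_cm, dtype=float)
    weight_kg = np.asarray(weight_kg, dtype=float)
    height_cm = np.asarray(height_cm, dtype=float)
    if np.any(waist_cm <= 0) or np.any(weight_kg <= 0) or np.any(height_cm <= 0):
        raise ValueError("waist, weight, and height must all be positive")
    out = (waist_cm * 10.0) * weight_kg ** (-2.0 / 3.0) * (height_cm / 100.0) ** (5.0 / 6.0)
    return float(out) if out.ndim == 0 else out


def covariate_residuals(
    data,
    response: str = "waist",
    predictors: Sequence[str] = ("bmi", "height"),
    sex_col: str = "sex",
) -> pd.DataFrame:
    """OLS residuals of ``response`` on ``predictors`` with simple imputation.

    The regression (with intercept) is fitted over complete cases.
    Subjects missing the response receive the sex-specific median residual
    and an ``imputed`` flag — the single-imputation rule used for missing
    waist circumference. Returns a DataFrame with columns ``residual``
    and ``imputed`` indexed like ``data``.
    """
    df = _as_frame(data)
    y = df[response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(df))] + [df[p].to_numpy(dtype=float) for p in predictors]
    )
    complete = ~np.isnan(y) & ~np.isnan(X).any(axis=1)
    if complete.sum() < len(predictors) + 1:
        raise ValueError("need at least len(predictors)+1 complete cases")
    Xc = X[complete]
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise ValueError("degenerate design: predictors are collinear or constant")
    coef, *_ = np.linalg.lstsq(Xc, y[complete], rcond=None)
    resid = np.full(len(df), np.nan)
    resid[complete] = y[complete] - X[complete] @ coef
    imputed = ~complete
    if imputed.any():
        for sex, grp in df.groupby(sex_col):
            med = np.nanmedian(resid[(df[sex_col] == sex).to_numpy() & complete])
            fill = imputed & (df[sex_col] == sex).to_numpy()
            resid[fill] = med
    return pd.DataFrame({"residual": resid, "imputed": imputed}, index=df.index)


@dataclass
class QuintileScheme:
    """Sex-specific quintile cut-offs and trend scores from control data."""

    cutoffs: dict  # sex -> 4 thresholds (20/40/60/80th control percentiles)
    medians: dict  # sex -> 5 control medians (trend scores)
    control_sd: float

    def category(self, sex: str, value: float) -> int:
        """1-based quintile. Intervals are half-open [low, high); when a
        value ties with more than one cut-off the tie resolves downward."""
        cuts = np.asarray(self.cutoffs[sex])
        lo = int(np.searchsorted(cuts, value, side="left"))
        hi = int(np.searchsorted(cuts, value, side="right"))
        idx = lo if hi - lo >= 2 else hi
        return idx + 1

    def trend_score(self, sex: str, value: float) -> float:
        return self.medians[sex][self.category(sex, value) - 1]


def assign_quintiles(
    data,
    value_col: str = "biomarker",
    sex_col: str = "sex",
    case_col: str = "is_case",
    quantile_method: str = "linear",
) -> tuple[QuintileScheme, pd.DataFrame]:
    """Sex-specific quintile coding with cut-offs from the control distribution.

    Cut-offs are the 20/40/60/80th percentiles of control values within
    each sex (``quantile_method`` names the numpy interpolation rule,
    default linear). Each subject receives a 1-based category and the
    control-median trend score of that category; the overall control SD
    is recorded for per-SD scaling.
    """
    df = _as_frame(data)
    controls = df[df[case_col] == 0]
    cutoffs: dict = {}
    medians: dict = {}
    scheme_sexes = df[sex_col].unique()
    for sex in scheme_sexes:
        vals = controls.loc[controls[sex_col] == sex, value_col].dropna().to_numpy(dtype=float)
        if len(np.unique(vals)) < 5:
            raise ValueError(f"fewer than 5 distinct control values for sex {sex!r}")
        cuts = np.quantile(vals, [0.2, 0.4, 0.6, 0.8], method=quantile_method)
        cutoffs[sex] = cuts
        scheme = QuintileScheme({sex: cuts}, {}, 1.0)
        cats = np.array([scheme.category(sex, v) for v in vals])
        meds = []
        for q in range(1, 6):
            sub = vals[cats == q]
            meds.append(float(np.median(sub)) if len(sub) else float("nan"))
        medians[sex] = meds
    control_sd = float(controls[value_col].std(ddof=1))
    result = QuintileScheme(cutoffs=cutoffs, medians=medians, control_sd=control_sd)
    assigned = df.copy()
    assigned["quintile"] = [
        result.category(s, v) for s, v in zip(df[sex_col], df[value_col])
    ]
    assigned["trend_score"] = [
        result.trend_score(s, v) for s, v in zip(df[sex_col], df[value_col])
    ]
    return result, assigned


def standardize_by_control_sd(values, scheme: QuintileScheme):
    """Express biomarker values in units of the control standard deviation."""
    if not scheme.control_sd > 0:
        raise ValueError("control SD must be positive")
    out = np.asarray(values, dtype=float) / scheme.control_sd
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# conditional logistic regression


@dataclass
class CLogitFit:
    """Fitted conditional-logistic model.

    ``coefficients`` are log rate ratios (per the incidence-density
    interpretation); ``covariance`` is the inverse observed information.
    """

    coefficients: dict
    covariance: np.ndarray
    log_likelihood: float
    converged: bool
    n_sets_informative: int
    separation: bool = False
    aliased: list = field(default_factory=list)

    @property
    def beta(self) -> np.ndarray:
        return np.array(list(self.coefficients.values()))

    @property
    def names(self) -> list[str]:
        return list(self.coefficients)

    @property
    def se(self) -> dict:
        s = np.sqrt(np.diag(self.covariance))
        return dict(zip(self.coefficients, s))

    def rate_ratio(self, name: str, z: float = 1.959964) -> tuple[float, float, float]:
        """(RR, CI low, CI high) for one coefficient."""
        b = self.coefficients[name]
        s = self.se[name]
        return float(np.exp(b)), float(np.exp(b - z * s)), float(np.exp(b + z * s))

    def wald_p(self, name: str) -> float:
        return float(2 * stats.norm.sf(abs(self.coefficients[name] / self.se[name])))


def _conditional_ll_parts(beta, X, case_idx, starts, ends):
    """Log-likelihood, gradient, and Hessian of the conditional likelihood."""
    eta = X @ beta
    ll = 0.0
    grad = np.zeros_like(beta)
    hess = np.zeros((len(beta), len(beta)))
    for c, s, e in zip(case_idx, starts, ends):
        eta_s = eta[s:e]
        m = eta_s.max()
        w = np.exp(eta_s - m)
        denom = w.sum()
        p = w / denom
        ll += eta[c] - (m + np.log(denom))
        xbar = p @ X[s:e]
        grad += X[c] - xbar
        hess -= (X[s:e].T * p) @ X[s:e] - np.outer(xbar, xbar)
    return ll, grad, hess


def clogit_fit(
    data,
    covariates: Sequence[str],
    set_col: str = "set_id",
    case_col: str = "is_case",
    tol: float = 1e-8,
    max_iter: int = 25,
) -> CLogitFit:
    """Maximize the matched-set conditional likelihood by Newton-Raphson.

    The likelihood is prod_sets exp(x_case' beta) / sum_members
    exp(x_m' beta); for 1:1 sets this coincides with no-intercept
    logistic regression on case-minus-control covariate differences.
    Newton steps are halved whenever the likelihood would decrease;
    convergence is declared at gradient infinity-norm below ``tol``.
    Sets in which case and controls share identical covariate values are
    uninformative and do not contribute.
    """
    df = _as_frame(data)
    covariates = list(covariates)
    cols = df[list(covariates)].to_numpy(dtype=float)
    if np.isnan(cols).any():
        raise ValueError("covariates contain missing values; impute or drop first")
    order = np.argsort(df[set_col].to_numpy(), kind="stable")
    X = cols[order]
    is_case = df[case_col].to_numpy()[order].astype(bool)
    set_ids = df[set_col].to_numpy()[order]
    boundaries = np.flatnonzero(np.r_[True, set_ids[1:] != set_ids[:-1]])
    starts = boundaries
    ends = np.r_[boundaries[1:], len(set_ids)]

    case_idx, keep_s, keep_e = [], [], []
    n_informative = 0
    for s, e in zip(starts, ends):
        cases = np.flatnonzero(is_case[s:e])
        if len(cases) != 1:
            raise ValueError(f"set {set_ids[s]!r} has {len(cases)} cases; expected 1")
        if e - s < 2:
            continue
        if np.all(X[s:e] == X[s]):
            continue  # uninformative: identical covariates across members
        n_informative += 1
        case_idx.append(s + cases[0])
        keep_s.append(s)
        keep_e.append(e)
    if n_informative == 0:
        raise ValueError("no informative matched sets (no within-set covariate variation)")

    # covariates constant within every set are absorbed by the conditioning
    # (matching factors); their likelihood direction is flat, so they are
    # pinned at zero and excluded from the Newton iteration
    varies = np.zeros(X.shape[1], dtype=bool)
    for s, e in zip(keep_s, keep_e):
        varies |= np.ptp(X[s:e], axis=0) > 0
    aliased = np.flatnonzero(~varies)
    active = np.flatnonzero(varies)
    X_full = X
    X = X[:, active]

    beta = np.zeros(len(active))
    ll, grad, hess = _conditional_ll_parts(beta, X, case_idx, keep_s, keep_e)
    converged = False
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-hess, grad, rcond=None)[0]
        scale = 1.0
        for _half in range(30):
            new_beta = beta + scale * step
            new_ll, new_grad, new_hess = _conditional_ll_parts(new_beta, X, case_idx, keep_s, keep_e)
            if new_ll >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll, grad, hess = new_beta, new_ll, new_grad, new_hess
    else:
        if np.max(np.abs(grad)) < tol:
            converged = True
    separation = bool(np.max(np.abs(beta), initial=0.0) > 20.0)
    try:
        cov_active = np.linalg.inv(-hess)
    except np.linalg.LinAlgError:
        cov_active = np.linalg.pinv(-hess)
    cov_active = (cov_active + cov_active.T) / 2.0
    p = X_full.shape[1]
    beta_full = np.zeros(p)
    beta_full[active] = beta
    cov = np.full((p, p), np.nan)
    cov[np.ix_(active, active)] = cov_active
    for i in aliased:
        cov[i, i] = np.inf
    return CLogitFit(
        coefficients=dict(zip(covariates, beta_full)),
        covariance=cov,
        log_likelihood=float(ll),
        converged=converged and not separation,
        n_sets_informative=n_informative,
        separation=separation,
        aliased=[covariates[i] for i in aliased],
    )


def lrt(full: CLogitFit, reduced: CLogitFit, tol: float = 1e-6) -> float:
    """Likelihood-ratio p-value for nested conditional-logistic models."""
    df = len(full.coefficients) - len(reduced.coefficients)
    if df < 1:
        raise ValueError("full model must have more coefficients than the reduced model")
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if stat < -tol:
        raise ValueError(
            f"full model log-likelihood below reduced ({stat/2:.4g}); "
            "models non-nested or not converged"
        )
    return float(stats.chi2.sf(max(stat, 0.0), df))


def lrt_from_deviances(deviance_reduced: float, deviance_full: float, df: int) -> float:
    """Chi-square upper tail of a deviance difference (reduced minus full)."""
    return float(stats.chi2.sf(max(deviance_reduced - deviance_full, 0.0), df))


# ---------------------------------------------------------------------------
# fractional polynomials


def _fp_terms(x: np.ndarray, powers: tuple[float, ...]) -> np.ndarray:
    """Fractional-polynomial basis; power 0 is log, repeated powers add a
    log-multiplied copy (the standard FP convention)."""
    cols = []
    seen: dict[float, int] = {}
    for p in powers:
        base = np.log(x) if p == 0 else x**p
        reps = seen.get(p, 0)
        cols.append(base * np.log(x) ** reps)
        seen[p] = reps + 1
    return np.column_stack(cols)


@dataclass(frozen=True)
class FractionalPolynomialResult:
    fp1_power: float
    fp2_powers: tuple[float, float]
    p_nonlinearity: float
    ll_linear: float
    ll_fp1: float
    ll_fp2: float


def fractional_polynomial_test(
    data,
    exposure: str,
    adjustment: Sequence[str] = (),
    set_col: str = "set_id",
    case_col: str = "is_case",
) -> FractionalPolynomialResult:
    """Fractional-polynomial non-linearity scan inside the conditional model.

    Searches FP1 powers (-2, -1, -0.5, 0, 0.5, 1, 2, 3) and all FP2
    pairs; the non-linearity p-value compares the best FP2 to the linear
    model by a 3-df likelihood-ratio test. The exposure must be positive
    (a shift is applied when it is not).
    """
    df = _as_frame(data).copy()
    x = df[exposure].to_numpy(dtype=float)
    if np.isnan(x).any():
        raise ValueError("exposure contains missing values")
    if x.min() <= 0:
        shift = -x.min() + np.diff(np.unique(x)).min() if len(np.unique(x)) > 1 else 1.0
        x = x + shift
        if x.min() <= 0:
            raise ValueError("exposure not positive after shift")

    def fit_with(terms: np.ndarray) -> float:
        work = df.copy()
        names = []
        for j in range(terms.shape[1]):
            col = terms[:, j]
            sd = col.std()
            work[f"_fp{j}"] = (col - col.mean()) / (sd if sd > 0 else 1.0)
            names.append(f"_fp{j}")
        fit = clogit_fit(work, names + list(adjustment), set_col=set_col, case_col=case_col)
        return fit.log_likelihood

    ll_linear = fit_with(x[:, None])
    best_fp1, ll_fp1 = 1.0, -np.inf
    for p in FP1_POWERS:
        ll = fit_with(_fp_terms(x, (p,)))
        if ll > ll_fp1 + 1e-9:
            best_fp1, ll_fp1 = p, ll
    best_fp2, ll_fp2 = (1.0, 1.0), -np.inf
    for i, p1 in enumerate(FP1_POWERS):
        for p2 in FP1_POWERS[i:]:
            ll = fit_with(_fp_terms(x, (p1, p2)))
            if ll > ll_fp2 + 1e-9:
                best_fp2, ll_fp2 = (p1, p2), ll
    p_nonlin = float(stats.chi2.sf(max(2.0 * (ll_fp2 - ll_linear), 0.0), 3))
    return FractionalPolynomialResult(
        fp1_power=best_fp1,
        fp2_powers=best_fp2,
        p_nonlinearity=p_nonlin,
        ll_linear=ll_linear,
        ll_fp1=ll_fp1,
        ll_fp2=ll_fp2,
    )


# ---------------------------------------------------------------------------
# correlations, multiplicity, exclusions


def spearman_partial(x, y, covariates=None) -> tuple[float, float]:
    """Spearman partial correlation of x and y given covariate columns.

    All variables — x, y, and the covariates — are rank-transformed
    (average ranks for ties, the standard convention); the ranked x and y
    are residualized on the ranked covariates (with intercept) by least
    squares, and the Pearson correlation of the rank residuals is
    returned with its t-based p-value at n - n_covariates - 2 degrees of
    freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if covariates is None:
        C = np.empty((n, 0))
    else:
        C = np.column_stack([np.asarray(c, dtype=float) for c in covariates])
    if n <= C.shape[1] + 2:
        raise ValueError("need n > n_covariates + 2")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant input vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    Z = np.column_stack([np.ones(n)] + [stats.rankdata(C[:, j]) for j in range(C.shape[1])])
    rx_res = rx - Z @ np.linalg.lstsq(Z, rx, rcond=None)[0]
    ry_res = ry - Z @ np.linalg.lstsq(Z, ry, rcond=None)[0]
    r = float(rx_res @ ry_res / np.sqrt((rx_res @ rx_res) * (ry_res @ ry_res)))
    df_t = n - C.shape[1] - 2
    r_clip = min(max(r, -1 + 1e-15), 1 - 1e-15)
    t = r_clip * np.sqrt(df_t / (1.0 - r_clip**2))
    p = float(2 * stats.t.sf(abs(t), df_t))
    return r, p


def bonferroni(p_value: float, n_tests: int) -> float:
    """Bonferroni-adjusted p-value, capped at 1 (test count passed explicitly)."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    return min(1.0, p_value * n_tests)


def exclude_sets(data, subject_mask, set_col: str = "set_id", case_col: str = "is_case",
                 drop_if: str = "case") -> pd.DataFrame:
    """Set-level exclusion: removing a flagged subject removes its whole set.

    ``drop_if='case'`` drops sets whose case is flagged (e.g. cases
    diagnosed within two years of recruitment, together with their
    matched controls); ``drop_if='any'`` drops sets with any flagged
    member (e.g. prevalent diabetes in either case or control).
    """
    df = _as_frame(data)
    mask = np.asarray(subject_mask, dtype=bool)
    if drop_if == "case":
        flagged = mask & df[case_col].astype(bool).to_numpy()
    elif drop_if == "any":
        flagged = mask
    else:
        raise ValueError("drop_if must be 'case' or 'any'")
    bad_sets = set(df.loc[flagged, set_col])
    return df[~df[set_col].isin(bad_sets)].copy()
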