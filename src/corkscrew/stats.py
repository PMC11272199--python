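"""Cohort-level statistical battery for tortuosity studies.

Implements the analysis set used in age-cohort small-vessel studies:
Bonferroni-corrected two-group comparisons with a normality screen and
nonparametric fallback, one-way ANOVA with Tukey HSD, quadratic
regression of tortuous-vessel counts on age, partial correlation with
covariate adjustment, multiple linear regression with standardized
coefficients, and two-way random-effects single-measure intraclass
correlation (ICC(2,1), absolute agreement) for inter-rater reliability.

Ordinary fits delegate to statsmodels / scipy; partial correlation and
the ICC are computed from first principles (residual correlation and
two-way ANOVA mean squares respectively) so they can be validated
against independent implementations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multicomp import pairwise_tukeyhsd

__all__ = [
    "RegressionResult", "PartialCorrResult", "ICCResult",
    "group_compare", "anova_tukey", "quadratic_fit", "partial_corr",
    "multiple_regression", "icc_interrater",
]


@dataclass
class RegressionResult:
    """Linear-model fit summary (raw and standardized coefficients)."""

    coefficients: dict                 # name -> raw coefficient
    std_coefficients: dict             # name -> standardized coefficient
    pvalues: dict
    r2: float
    adjusted_r2: float
    n: int
    resid_normality_p: float = float("nan")


@dataclass
class PartialCorrResult:
    r: float
    p: float
    covariates: tuple
    n: int
    collinear: bool = False


@dataclass
class ICCResult:
    icc: float
    ci95_low: float
    ci95_high: float
    model: str = "ICC(2,1) two-way random, absolute agreement, single measure"


# ---------------------------------------------------------------------------
# group comparisons
# ---------------------------------------------------------------------------

def group_compare(table, group_col, value_cols, categorical_cols=(),
                  alpha=0.05, n_tests=None, normality_alpha=0.05):
    """Two-group comparison battery with Bonferroni-adjusted threshold.

    Continuous variables are screened for normality (Shapiro-Wilk per
    group); normal variables use an independent two-sided t-test,
    non-normal ones fall back to Kruskal-Wallis (with two groups this is
    the rank test; Dunn post-hocs are moot).  Categorical (boolean)
    columns use Fisher's exact test on the 2x2 table.  The significance
    threshold is ``alpha / n_tests`` with ``n_tests`` defaulting to the
    number of continuous variables compared.

    Returns a tidy DataFrame with one row per variable.
    """
    groups = sorted(pd.unique(table[group_col]))
    if len(groups) != 2:
        raise ValueError("group_compare expects exactly two groups")
    g1 = table[table[group_col] == groups[0]]
    g2 = table[table[group_col] == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs at least two observations")
    n_tests = n_tests or max(1, len(value_cols))
    threshold = alpha / n_tests

    rows = []
    for col in value_cols:
        x, y = g1[col].to_numpy(float), g2[col].to_numpy(float)
        normal = True
        for arr in (x, y):
            if len(arr) >= 3 and np.ptp(arr) > 0:
                if sps.shapiro(arr).pvalue < normality_alpha:
                    normal = False
        if normal:
            test = "t-test"
            with np.errstate(divide="ignore", invalid="ignore"):
                stat, p = sps.ttest_ind(x, y)
        else:
            test = "kruskal-wallis"
            stat, p = sps.kruskal(x, y)
        if np.isnan(p) and np.allclose(np.concatenate([x, y]),
                                       np.concatenate([x, y])[0]):
            p = 1.0  # degenerate zero-variance case: indistinguishable
        rows.append({
            "variable": col, "test": test, "statistic": float(stat),
            "p": float(p), "threshold": threshold,
            "significant": bool(p < threshold),
            "mean_1": float(np.mean(x)), "mean_2": float(np.mean(y)),
        })
    for col in categorical_cols:
        tab = pd.crosstab(table[group_col], table[col])
        if tab.shape == (2, 2):
            _, p = sps.fisher_exact(tab.to_numpy())
        else:
            p = 1.0
        rows.append({
            "variable": col, "test": "fisher-exact", "statistic": float("nan"),
            "p": float(p), "threshold": alpha, "significant": bool(p < alpha),
            "mean_1": float("nan"), "mean_2": float("nan"),
        })
    return pd.DataFrame(rows)


def anova_tukey(table, group_col, value_col, alpha=0.05):
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    Returns a dict with keys ``F``, ``p`` and ``pairwise`` (DataFrame of
    group pairs, mean differences and Tukey-adjusted p-values using the
    studentized range).  A fully degenerate input (all values identical)
    returns F = nan, p = 1.
    """
    groups = sorted(pd.unique(table[group_col]))
    if len(groups) < 2:
        raise ValueError("ANOVA needs at least two groups")
    samples = [table.loc[table[group_col] == g, value_col].to_numpy(float)
               for g in groups]
    if any(len(s) < 2 for s in samples):
        raise ValueError("each group needs at least two observations")
    values = np.concatenate(samples)
    if np.ptp(values) == 0:
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1:]]
        pairwise = pd.DataFrame({
            "group1": [p[0] for p in pairs], "group2": [p[1] for p in pairs],
            "meandiff": 0.0, "p_adj": 1.0, "reject": False,
        })
        return {"F": float("nan"), "p": 1.0, "pairwise": pairwise}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_stat, p = sps.f_oneway(*samples)
    res = pairwise_tukeyhsd(
        endog=table[value_col].to_numpy(float),
        groups=table[group_col].to_numpy(), alpha=alpha)
    pairwise = pd.DataFrame(
        res.summary().data[1:],
        columns=[str(c) for c in res.summary().data[0]],
    ).rename(columns={"p-adj": "p_adj"})
    return {"F": float(f_stat), "p": float(p), "pairwise": pairwise}


# ---------------------------------------------------------------------------
# regressions
# ---------------------------------------------------------------------------

def quadratic_fit(ages, counts):
    """OLS fit of ``count = a*age^2 + b*age + c``.

    Coefficients are reported under keys ``a``, ``b``, ``c``; the fit is
    exact (machine precision) on noise-free polynomial data.
    """
    ages = np.asarray(ages, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if len(ages) < 4:
        raise ValueError("quadratic fit needs n >= 4")
    if np.ptp(ages) == 0:
        raise ValueError("all ages identical: design matrix is rank deficient")
    X = np.column_stack([ages**2, ages, np.ones_like(ages)])
    model = sm.OLS(counts, X).fit()
    a, b, c = model.params
    names = ("a", "b", "c")
    std = _standardize_params(X[:, :2], counts, model.params[:2])
    return RegressionResult(
        coefficients=dict(zip(names, map(float, model.params))),
        std_coefficients={"a": std[0], "b": std[1]},
        pvalues=dict(zip(names, map(float, model.pvalues))),
        r2=float(model.rsquared), adjusted_r2=float(model.rsquared_adj),
        n=int(len(ages)),
    )


def _standardize_params(X, y, params):
    sy = np.std(y, ddof=1)
    if sy == 0:
        return [0.0 for _ in params]
    return [float(p * np.std(X[:, j], ddof=1) / sy)
            for j, p in enumerate(params)]


def partial_corr(table, x, y, covariates=()):
    """Partial correlation of ``x`` and ``y`` given ``covariates``.

    Both variables are residualized on the covariates (plus intercept)
    by least squares; the Pearson correlation of the residuals is the
    partial correlation, with a t-test on n - k - 2 degrees of freedom.
    With no covariates this reduces exactly to the Pearson correlation.
    """
    covariates = tuple(covariates)
    data = table[[x, y, *covariates]].dropna()
    n = len(data)
    k = len(covariates)
    if n <= k + 2:
        raise ValueError("need n > number of covariates + 2")
    xv = data[x].to_numpy(float)
    yv = data[y].to_numpy(float)
    Z = np.column_stack([np.ones(n)] +
                        [data[c].to_numpy(float) for c in covariates])
    collinear = np.linalg.matrix_rank(Z) < Z.shape[1]
    if collinear:
        warnings.warn("covariates are collinear; partial r uses a "
                      "minimum-norm projection", stacklevel=2)
    beta_x, *_ = np.linalg.lstsq(Z, xv, rcond=None)
    beta_y, *_ = np.linalg.lstsq(Z, yv, rcond=None)
    rx = xv - Z @ beta_x
    ry = yv - Z @ beta_y
    # a variable fully explained by the covariates has no residual
    # variance left to correlate; report exactly zero rather than the
    # correlation of numerical noise
    tol_x = 1e-10 * max(np.linalg.norm(xv - xv.mean()), 1.0)
    tol_y = 1e-10 * max(np.linalg.norm(yv - yv.mean()), 1.0)
    degenerate = (np.linalg.norm(rx) < tol_x) or (np.linalg.norm(ry) < tol_y)
    denom = np.linalg.norm(rx) * np.linalg.norm(ry)
    r = float(rx @ ry / denom) if denom > 0 and not degenerate else 0.0
    r = float(np.clip(r, -1.0, 1.0))
    df = n - k - 2
    if abs(r) >= 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2 * sps.t.sf(abs(t), df))
    return PartialCorrResult(r=r, p=p, covariates=covariates, n=n,
                             collinear=bool(collinear))


def multiple_regression(table, response, predictors):
    """Multiple linear regression with standardized coefficients.

    Predictors and response are z-scored, so the reported standardized
    coefficients are comparable across predictors (single-predictor
    case: the coefficient equals the Pearson correlation).  Raw
    coefficients from the unstandardized fit are reported alongside,
    with the adjusted R^2 and a Kolmogorov-Smirnov normality screen of
    the standardized residuals.
    """
    data = table[[response, *predictors]].dropna().astype(float)
    n = len(data)
    if n <= len(predictors) + 1:
        raise ValueError("need n > number of predictors + 1")
    y = data[response].to_numpy()
    X = data[list(predictors)].to_numpy()
    raw = sm.OLS(y, sm.add_constant(X)).fit()

    def z(v):
        s = np.std(v, axis=0, ddof=1)
        return (v - np.mean(v, axis=0)) / np.where(s == 0, 1.0, s)

    stdfit = sm.OLS(z(y), sm.add_constant(z(X))).fit()
    resid = raw.resid
    resid_std = (resid - resid.mean()) / (resid.std(ddof=1) or 1.0)
    ks_p = float(sps.kstest(resid_std, "norm").pvalue)
    names = list(predictors)
    return RegressionResult(
        coefficients=dict(zip(["const"] + names, map(float, raw.params))),
        std_coefficients=dict(zip(names, map(float, stdfit.params[1:]))),
        pvalues=dict(zip(["const"] + names, map(float, raw.pvalues))),
        r2=float(raw.rsquared), adjusted_r2=float(raw.rsquared_adj),
        n=int(n), resid_normality_p=ks_p,
    )


# ---------------------------------------------------------------------------
# inter-rater reliability
# ---------------------------------------------------------------------------

def icc_interrater(ratings, alpha=0.05):
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is a subjects x raters array (or DataFrame).  The ICC and
    its 95% CI follow the standard mean-squares formulation of the
    two-way random-effects model (F-distribution bounds for the CI).
    Zero between-subject variance yields ICC = 0.
    """
    R = np.asarray(ratings, dtype=float)
    if R.ndim != 2:
        raise ValueError("ratings must be a 2D subjects x raters array")
    n, k = R.shape
    if k < 2 or n < 5:
        raise ValueError("need >= 2 raters and >= 5 subjects")
    grand = R.mean()
    row_means = R.mean(axis=1)
    col_means = R.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((R - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = max(ss_err / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom <= 0:
        return ICCResult(icc=0.0, ci95_low=0.0, ci95_high=0.0)
    icc = (msr - mse) / denom
    if msr <= mse:  # no between-subject variance signal
        icc = max(icc, 0.0) if np.isclose(msr, mse) else icc

    # McGraw & Wong F-based confidence bounds
    if mse == 0 and msc == 0:
        return ICCResult(icc=float(icc), ci95_low=float(icc),
                         ci95_high=float(icc))
    fj = msc / mse if mse > 0 else np.inf
    vn = (k - 1) * (n - 1) * (
        (k * icc * fj + n * (1 + (k - 1) * icc) - k * icc) ** 2)
    vd = ((n - 1) * k**2 * icc**2 * fj**2
          + (n * (1 + (k - 1) * icc) - k * icc) ** 2)
    v = vn / vd if vd > 0 else 1.0
    f_low = sps.f.ppf(1 - alpha / 2, n - 1, v)
    f_high = sps.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_low * mse) / (
        f_low * (k * msc + (k * n - k - n) * mse) + n * msr)
    upper = n * (f_high * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_high * msr)
    lower, upper = float(min(lower, icc)), float(max(upper, icc))
    return ICCResult(icc=float(icc), ci95_low=lower, ci95_high=upper)
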