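"""Association statistics: correlations and their comparisons, marginal-means
contrasts, standardized regression, and agreement indices.

This module covers the inferential toolkit of the analysis: Pearson and
partial Pearson correlations with Fisher-z confidence intervals and optional
Bonferroni adjustment; Fisher Z tests and Zou modified-asymptotic CIs for
differences of *independent* correlations (male vs female groups); the
Meng-Rosenthal-Rubin Z test for differences of *dependent* correlations that
share one variable; estimated-marginal-means contrasts from a linear model of
biomarker ~ stage * sex + age + edu; standardized multiple linear regression;
two-way absolute-agreement ICC with a subject-level bootstrap; the paired t
test; and Bland-Altman limits of agreement.

All tests are two-sided with normal-theory intervals; Bonferroni adjustment
multiplies p by the number of tests m (capped at 1) and widens intervals to
the simultaneous 1 - alpha/m level.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sstats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from patsy import build_design_matrices


# ---------------------------------------------------------------------------
# result containers


@dataclass
class CorrelationResult:
    estimate: float
    n: int
    ci_low: float
    ci_high: float
    p: float
    adjusted: bool = False
    df: Optional[int] = None


@dataclass
class CorrelationComparison:
    """Difference of two correlation coefficients.

    ``delta`` is on the correlation scale. For ``method='meng_dependent'``
    the confidence interval is on the Fisher-z difference scale, as in the
    original Meng-Rosenthal-Rubin formulation; for the independent-group
    methods it is Zou's interval on the correlation-difference scale.
    """

    delta: float
    method: str
    z: float
    p: float
    ci_low: float
    ci_high: float


@dataclass
class ContrastResult:
    marginal_means: pd.DataFrame
    contrasts: pd.DataFrame
    anova: pd.DataFrame
    df_resid: int


@dataclass
class RegressionResult:
    beta: float
    ci_low: float
    ci_high: float
    p: float
    beta_std: float
    ci_std_low: float
    ci_std_high: float
    adj_r2: float
    df_resid: int
    terms: list = field(default_factory=list)


@dataclass
class AgreementResult:
    icc: Optional[float] = None
    icc_ci: Optional[tuple] = None
    mean_diff: Optional[float] = None
    sd_diff: Optional[float] = None
    mean_diff_ci: Optional[tuple] = None
    loa_low: Optional[float] = None
    loa_high: Optional[float] = None
    loa_low_ci: Optional[tuple] = None
    loa_high_ci: Optional[tuple] = None
    means: Optional[np.ndarray] = None
    diffs: Optional[np.ndarray] = None


# ---------------------------------------------------------------------------
# correlations


def _as_finite(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite values")
    return x


def pearson_ci(
    x: Sequence[float],
    y: Sequence[float],
    alpha: float = 0.05,
    bonferroni_m: int = 1,
) -> CorrelationResult:
    """Pearson correlation with Fisher-z CI and two-sided p.

    With ``bonferroni_m > 1`` the p-value is multiplied by m (capped at 1)
    and the interval widened to the simultaneous 1 - alpha/m level.
    """
    x, y = _as_finite(x), _as_finite(y)
    n = len(x)
    if n < 4 or len(y) != n:
        raise ValueError("need equal-length vectors with n >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance")
    r, p = sstats.pearsonr(x, y)
    lo, hi = _fisher_ci(r, n, alpha / bonferroni_m)
    p_adj = min(1.0, p * bonferroni_m)
    return CorrelationResult(
        estimate=float(r), n=n, ci_low=lo, ci_high=hi, p=float(p_adj),
        adjusted=bonferroni_m > 1, df=n - 2,
    )


def _fisher_ci(r: float, n: int, alpha: float) -> tuple[float, float]:
    zcrit = sstats.norm.ppf(1 - alpha / 2)
    zr = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(n - 3)
    return float(np.tanh(zr - zcrit * se)), float(np.tanh(zr + zcrit * se))


def partial_pearson(
    x: Sequence[float],
    y: Sequence[float],
    covariates: Optional[np.ndarray] = None,
    alpha: float = 0.05,
    bonferroni_m: int = 1,
) -> CorrelationResult:
    """Partial Pearson correlation controlling for ``covariates``.

    Computed as the correlation of the residuals of x and y after linear
    regression on the covariates (with intercept); the p-value uses
    df = n - 2 - k and the Fisher-z interval uses the effective sample size
    n - k, where k is the number of covariates.
    """
    x, y = _as_finite(x), _as_finite(y)
    n = len(x)
    if covariates is None or np.size(covariates) == 0:
        return pearson_ci(x, y, alpha=alpha, bonferroni_m=bonferroni_m)
    Z = np.atleast_2d(np.asarray(covariates, dtype=float))
    if Z.shape[0] != n:
        Z = Z.T
    k = Z.shape[1]
    if n <= k + 3:
        raise ValueError("too few observations for the covariate count")
    design = np.column_stack([np.ones(n), Z])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("collinear covariates")
    hat, *_ = np.linalg.lstsq(design, np.column_stack([x, y]), rcond=None)
    resid = np.column_stack([x, y]) - design @ hat
    rx, ry = resid[:, 0], resid[:, 1]
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("zero residual variance")
    r = float(np.corrcoef(rx, ry)[0, 1])
    df = n - 2 - k
    t = r * np.sqrt(df / (1 - r**2))
    p = 2 * sstats.t.sf(abs(t), df)
    lo, hi = _fisher_ci(r, n - k, alpha / bonferroni_m)
    return CorrelationResult(
        estimate=r, n=n, ci_low=lo, ci_high=hi,
        p=float(min(1.0, p * bonferroni_m)), adjusted=bonferroni_m > 1, df=df,
    )


def fisher_z_independent(
    r1: float, n1: int, r2: float, n2: int, alpha: float = 0.05
) -> CorrelationComparison:
    """Fisher Z test for r1 - r2 from two independent groups.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided p; the
    attached interval for r1 - r2 is Zou's (the two are companions).
    """
    _check_r(r1), _check_r(r2)
    if min(n1, n2) < 4:
        raise ValueError("need n >= 4 in both groups")
    se = np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    z = (np.arctanh(r1) - np.arctanh(r2)) / se
    p = 2 * sstats.norm.sf(abs(z))
    lo, hi = _zou_interval(r1, n1, r2, n2, alpha)
    return CorrelationComparison(
        delta=float(r1 - r2), method="fisher_independent",
        z=float(z), p=float(p), ci_low=lo, ci_high=hi,
    )


def _check_r(r: float):
    if not -1 < r < 1:
        raise ValueError("correlations must lie strictly inside (-1, 1)")


def _zou_interval(r1, n1, r2, n2, alpha) -> tuple[float, float]:
    l1, u1 = _fisher_ci(r1, n1, alpha)
    l2, u2 = _fisher_ci(r2, n2, alpha)
    d = r1 - r2
    lo = d - np.sqrt((r1 - l1) ** 2 + (u2 - r2) ** 2)
    hi = d + np.sqrt((u1 - r1) ** 2 + (r2 - l2) ** 2)
    return float(lo), float(hi)


def zou_ci_difference(
    r1: float, n1: int, r2: float, n2: int, alpha: float = 0.05
) -> CorrelationComparison:
    """Zou's modified-asymptotic CI for the difference of two independent
    correlations, combining the individual Fisher-z intervals."""
    comp = fisher_z_independent(r1, n1, r2, n2, alpha=alpha)
    comp.method = "zou_independent"
    return comp


def meng_z_dependent(
    r_xy: float, r_zy: float, r_xz: float, n: int, alpha: float = 0.05
) -> CorrelationComparison:
    """Meng-Rosenthal-Rubin Z test for two dependent correlations sharing y.

    Tests r_xy - r_zy where both correlations involve the common variable y
    and x, z are correlated r_xz. The confidence interval is on the
    Fisher-z difference scale (the scale on which the statistic is normal).
    """
    for r in (r_xy, r_zy, r_xz):
        _check_r(r)
    if n < 4:
        raise ValueError("need n >= 4")
    R = np.array([[1, r_xz, r_xy], [r_xz, 1, r_zy], [r_xy, r_zy, 1]])
    if np.linalg.eigvalsh(R).min() < -1e-10:
        raise ValueError("infeasible correlation triple (not positive semi-definite)")
    rbar2 = (r_xy**2 + r_zy**2) / 2.0
    f = min((1 - r_xz) / (2 * (1 - rbar2)), 1.0)
    h = (1 - f * rbar2) / (1 - rbar2)
    dz = np.arctanh(r_xy) - np.arctanh(r_zy)
    se = np.sqrt(2 * (1 - r_xz) * h / (n - 3))
    z = dz / se
    p = 2 * sstats.norm.sf(abs(z))
    zcrit = sstats.norm.ppf(1 - alpha / 2)
    return CorrelationComparison(
        delta=float(r_xy - r_zy), method="meng_dependent",
        z=float(z), p=float(p),
        ci_low=float(dz - zcrit * se), ci_high=float(dz + zcrit * se),
    )


# ---------------------------------------------------------------------------
# linear models


def marginal_means_contrasts(
    cohort: pd.DataFrame, response: str, alpha: float = 0.05
) -> ContrastResult:
    """Estimated marginal means of a biomarker by sex and cognitive stage,
    with consecutive-stage contrasts.

    Fits ``response ~ stage * sex + age + edu`` by ordinary least squares
    (a Gaussian GLM with identity link); marginal means are model
    predictions per sex-by-stage cell with age and education fixed at their
    whole-sample means. The consecutive contrasts T2 - T3 and T1 - T2 are
    reported per sex with t statistics on the residual df (n - 8 for the
    full factorial), Bonferroni-adjusted p over the 4 contrasts and
    simultaneous 1 - alpha/4 intervals.
    """
    needed = {response, "stage", "sex", "age", "edu"}
    if not needed <= set(cohort.columns):
        raise ValueError(f"cohort missing columns: {needed - set(cohort.columns)}")
    stages = ("T1", "T2", "T3")
    for st in stages:
        for sx in (0, 1):
            if ((cohort["stage"] == st) & (cohort["sex"] == sx)).sum() == 0:
                raise ValueError(f"empty cell: stage={st}, sex={sx}")
    formula = f"{response} ~ C(stage) * C(sex) + age + edu"
    fit = smf.ols(formula, data=cohort).fit()
    df_resid = int(fit.df_resid)
    design_info = fit.model.data.design_info
    age_m, edu_m = cohort["age"].mean(), cohort["edu"].mean()

    def row(stage, sex):
        new = pd.DataFrame({"stage": [stage], "sex": [sex], "age": [age_m], "edu": [edu_m]})
        return np.asarray(build_design_matrices([design_info], new)[0])[0]

    cov = fit.cov_params().values
    beta = fit.params.values
    mm_rows = []
    for sx in (0, 1):
        for st in stages:
            X = row(st, sx)
            est = float(X @ beta)
            se = float(np.sqrt(X @ cov @ X))
            mm_rows.append({"sex": sx, "stage": st, "mean": est, "se": se})
    marginal = pd.DataFrame(mm_rows)

    m = 4  # Bonferroni over the four consecutive contrasts
    tcrit = sstats.t.ppf(1 - alpha / (2 * m), df_resid)
    con_rows = []
    for sx in (0, 1):
        for hi, lo_ in (("T2", "T3"), ("T1", "T2")):
            L = row(hi, sx) - row(lo_, sx)
            est = float(L @ beta)
            se = float(np.sqrt(L @ cov @ L))
            t = est / se
            p = 2 * sstats.t.sf(abs(t), df_resid)
            con_rows.append(
                {
                    "sex": sx,
                    "contrast": f"{hi}-{lo_}",
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "df": df_resid,
                    "p_adj": min(1.0, m * p),
                    "ci_low": est - tcrit * se,
                    "ci_high": est + tcrit * se,
                }
            )
    anova = sm.stats.anova_lm(fit, typ=2)
    return ContrastResult(marginal, pd.DataFrame(con_rows), anova, df_resid)


def mlr_standardized(
    cohort: pd.DataFrame, response: str, eeg_var: str, alpha: float = 0.05
) -> RegressionResult:
    """MLR of an MMSE score on one biomarker plus sex, age, education.

    Reports the biomarker slope with CI and two-sided p on n - 5 residual
    df, the standardized coefficient beta* = beta * SD(x)/SD(y) with the
    correspondingly scaled CI, and the adjusted R^2 of the model.
    """
    cols = [response, eeg_var, "sex", "age", "edu"]
    if not set(cols) <= set(cohort.columns):
        raise ValueError("cohort missing required columns")
    fit = smf.ols(f"{response} ~ {eeg_var} + sex + age + edu", data=cohort).fit()
    if np.linalg.matrix_rank(fit.model.exog) < fit.model.exog.shape[1]:
        raise ValueError("collinear design")
    beta = float(fit.params[eeg_var])
    ci = fit.conf_int(alpha=alpha).loc[eeg_var]
    p = float(fit.pvalues[eeg_var])
    scale = cohort[eeg_var].std(ddof=1) / cohort[response].std(ddof=1)
    return RegressionResult(
        beta=beta, ci_low=float(ci[0]), ci_high=float(ci[1]), p=p,
        beta_std=beta * scale, ci_std_low=float(ci[0]) * scale,
        ci_std_high=float(ci[1]) * scale,
        adj_r2=float(fit.rsquared_adj), df_resid=int(fit.df_resid),
        terms=list(fit.params.index),
    )


# ---------------------------------------------------------------------------
# agreement


def icc_value(a: np.ndarray, b: np.ndarray) -> float:
    """Two-way absolute-agreement single-measure ICC(A,1) for two raters.

    Variance-component form from the two-way ANOVA without replication:
    (MSR - MSE) / (MSR + MSE + (2/n)(MSC - MSE)) for k = 2 raters.
    """
    a, b = _as_finite(a), _as_finite(b)
    n = len(a)
    if n < 3 or len(b) != n:
        raise ValueError("need equal-length vectors with n >= 3")
    Y = np.column_stack([a, b])
    k = 2
    grand = Y.mean()
    if np.allclose(Y, grand):
        raise ValueError("zero total variance")
    row_means = Y.mean(axis=1)
    col_means = Y.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    sse = np.sum((Y - row_means[:, None] - col_means[None, :] + grand) ** 2)
    mse = sse / ((n - 1) * (k - 1))
    return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))


def icc(
    values_a: Sequence[float],
    values_b: Sequence[float],
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> AgreementResult:
    """ICC(A,1) with a percentile bootstrap CI over subjects."""
    a, b = _as_finite(values_a), _as_finite(values_b)
    point = icc_value(a, b)
    rng = np.random.default_rng(seed)
    n = len(a)
    boot = np.empty(n_boot)
    for i in range(n_boot):
        idx = rng.integers(0, n, n)
        try:
            boot[i] = icc_value(a[idx], b[idx])
        except ValueError:
            boot[i] = np.nan
    lo, hi = np.nanpercentile(boot, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    d = a - b
    return AgreementResult(
        icc=point, icc_ci=(float(lo), float(hi)),
        mean_diff=float(d.mean()), sd_diff=float(d.std(ddof=1)) if n > 1 else 0.0,
    )


def paired_t(values_a: Sequence[float], values_b: Sequence[float]):
    """Paired t test; returns (mean_diff, sd_diff, t, p).

    Zero-variance differences return NaN t and p (degenerate flag)."""
    a, b = _as_finite(values_a), _as_finite(values_b)
    if len(a) != len(b) or len(a) < 2:
        raise ValueError("need equal-length vectors with n >= 2")
    d = a - b
    sd = float(d.std(ddof=1))
    if sd == 0:
        # degenerate: constant differences carry no paired-t information
        return float(d.mean()), 0.0, float("nan"), float("nan")
    t, p = sstats.ttest_rel(a, b)
    return float(d.mean()), sd, float(t), float(p)


def bland_altman(
    true_vals: Sequence[float], pred_vals: Sequence[float], alpha: float = 0.05
) -> AgreementResult:
    """Bland-Altman agreement: mean difference, limits of agreement, CIs.

    Differences are true - predicted; LOA = mean +/- 1.96 SD with the
    standard approximate interval SE(LOA) = SD * sqrt(1/n + z^2/(2(n-1))).
    The per-subject means and differences are returned as plot data.
    """
    a, b = _as_finite(true_vals), _as_finite(pred_vals)
    n = len(a)
    if len(b) != n or n < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    d = a - b
    mean, sd = float(d.mean()), float(d.std(ddof=1))
    zcrit = 1.96
    loa_lo, loa_hi = mean - zcrit * sd, mean + zcrit * sd
    tcrit = sstats.t.ppf(1 - alpha / 2, n - 1)
    se_mean = sd / np.sqrt(n)
    se_loa = sd * np.sqrt(1.0 / n + zcrit**2 / (2 * (n - 1)))
    return AgreementResult(
        mean_diff=mean, sd_diff=sd,
        mean_diff_ci=(mean - tcrit * se_mean, mean + tcrit * se_mean),
        loa_low=loa_lo, loa_high=loa_hi,
        loa_low_ci=(loa_lo - tcrit * se_loa, loa_lo + tcrit * se_loa),
        loa_high_ci=(loa_hi - tcrit * se_loa, loa_hi + tcrit * se_loa),
        means=(a + b) / 2.0, diffs=d,
    )
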