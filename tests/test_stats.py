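"""Correlation machinery, marginal-means contrasts, regression, agreement."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sstats

from eegslow import (
    bland_altman,
    fisher_z_independent,
    icc,
    marginal_means_contrasts,
    meng_z_dependent,
    mlr_standardized,
    paired_t,
    partial_pearson,
    pearson_ci,
    zou_ci_difference,
)
from eegslow.stats import icc_value


# ---------------------------------------------------------------------------
# Pearson and partial Pearson


def test_pearson_basic_values():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert pearson_ci(x, x).estimate == pytest.approx(1.0)
    res = pearson_ci(x, [1.0, 3.0, 2.0, 4.0])
    assert res.estimate == pytest.approx(0.8)  # hand product-moment value
    neg = pearson_ci(x, -x)
    assert neg.estimate == pytest.approx(-1.0)
    assert neg.p < 1e-10
    with pytest.raises(ValueError, match="variance"):
        pearson_ci(x, np.ones(4))


def test_pearson_bonferroni_adjustment():
    rng = np.random.default_rng(0)
    x, y = rng.normal(size=50), rng.normal(size=50)
    plain = pearson_ci(x, y)
    adj = pearson_ci(x, y, bonferroni_m=5)
    assert adj.p == pytest.approx(min(1.0, plain.p * 5))
    assert adj.ci_low < plain.ci_low and adj.ci_high > plain.ci_high
    assert adj.adjusted and not plain.adjusted


def test_partial_pearson_reduces_and_matches_closed_form():
    rng = np.random.default_rng(1)
    x, y = rng.normal(size=200), rng.normal(size=200)
    full = pearson_ci(x, y)
    none = partial_pearson(x, y, covariates=None)
    assert none.estimate == pytest.approx(full.estimate)

    z = rng.normal(size=200)
    xz = x + 0.5 * z
    yz = y + 0.8 * z
    res = partial_pearson(xz, yz, covariates=z[:, None])
    r_xy = np.corrcoef(xz, yz)[0, 1]
    r_xz = np.corrcoef(xz, z)[0, 1]
    r_yz = np.corrcoef(yz, z)[0, 1]
    closed = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    assert res.estimate == pytest.approx(closed, abs=1e-10)
    assert res.df == 200 - 2 - 1


def test_partial_pearson_agrees_with_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(2)
    n = 150
    z1, z2 = rng.normal(size=n), rng.normal(size=n)
    x = 0.4 * z1 - 0.2 * z2 + rng.normal(size=n)
    y = -0.3 * z1 + 0.5 * z2 + rng.normal(size=n)
    df = pd.DataFrame({"x": x, "y": y, "z1": z1, "z2": z2})
    ref = pingouin.partial_corr(df, x="x", y="y", covar=["z1", "z2"])
    res = partial_pearson(x, y, covariates=np.column_stack([z1, z2]))
    assert res.estimate == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
    assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), rel=1e-6)


def test_partial_pearson_affine_covariate_invariance():
    rng = np.random.default_rng(3)
    n = 120
    cov = rng.normal(size=(n, 3))
    x, y = rng.normal(size=n), rng.normal(size=n)
    a = partial_pearson(x, y, covariates=cov)
    b = partial_pearson(x, y, covariates=cov * [2.0, -3.0, 0.5] + [10, -7, 100])
    assert a.estimate == pytest.approx(b.estimate, abs=1e-12)


def test_partial_pearson_null_with_informative_covariate():
    rng = np.random.default_rng(4)
    n = 1000
    z = rng.normal(size=n)
    y = z + rng.normal(size=n)
    x = rng.normal(size=n)
    res = partial_pearson(x, y, covariates=z[:, None])
    assert abs(res.estimate) < 0.08


def test_partial_pearson_collinear_covariates_rejected():
    rng = np.random.default_rng(5)
    z = rng.normal(size=50)
    with pytest.raises(ValueError, match="collinear"):
        partial_pearson(rng.normal(size=50), rng.normal(size=50),
                        covariates=np.column_stack([z, 2 * z]))


# ---------------------------------------------------------------------------
# correlation comparisons


def test_fisher_z_closed_form_and_antisymmetry():
    res = fisher_z_independent(0.5, 100, 0.2, 100)
    se = np.sqrt(2.0 / 97.0)
    expected = (np.arctanh(0.5) - np.arctanh(0.2)) / se
    assert res.z == pytest.approx(expected, abs=1e-12)
    assert res.z == pytest.approx(2.414, abs=5e-3)

    same = fisher_z_independent(0.3, 50, 0.3, 80)
    assert same.z == 0.0 and same.p == pytest.approx(1.0)

    flipped = fisher_z_independent(0.2, 100, 0.5, 100)
    assert flipped.z == pytest.approx(-res.z)
    with pytest.raises(ValueError):
        fisher_z_independent(1.0, 100, 0.2, 100)


def test_zou_ci_symmetry_and_monotonicity():
    res = zou_ci_difference(0.4, 80, 0.4, 80)
    assert res.ci_low == pytest.approx(-res.ci_high, abs=1e-12)
    wide = zou_ci_difference(0.5, 40, 0.2, 40)
    narrow = zou_ci_difference(0.5, 80, 0.2, 80)
    assert wide.ci_high - wide.ci_low > narrow.ci_high - narrow.ci_low
    assert narrow.ci_low <= narrow.delta <= narrow.ci_high


def test_meng_z_null_sign_and_validity():
    same = meng_z_dependent(0.4, 0.4, 0.3, 100)
    assert same.z == 0.0
    a = meng_z_dependent(0.5, 0.2, 0.3, 100)
    b = meng_z_dependent(0.2, 0.5, 0.3, 100)
    assert a.z == pytest.approx(-b.z)
    assert a.ci_low <= np.arctanh(0.5) - np.arctanh(0.2) <= a.ci_high
    with pytest.raises(ValueError, match="infeasible"):
        meng_z_dependent(0.9, -0.9, 0.9, 100)


# ---------------------------------------------------------------------------
# marginal means and contrasts


def make_staged_cohort(n_per_cell=40, effects=None, noise=0.5, seed=0):
    """Balanced sex-by-stage factorial with controllable cell means."""
    rng = np.random.default_rng(seed)
    rows = []
    effects = effects or {}
    for sex in (0, 1):
        for stage in ("T1", "T2", "T3"):
            mu = 8.5 + effects.get((sex, stage), 0.0)
            for _ in range(n_per_cell):
                rows.append({
                    "sex": sex, "stage": stage,
                    "age": rng.uniform(50, 90), "edu": rng.uniform(0, 18),
                    "mdf": mu + noise * rng.standard_normal(),
                })
    return pd.DataFrame(rows)


def test_contrast_degrees_of_freedom():
    df = make_staged_cohort(n_per_cell=20)  # n = 120, 8 parameters
    res = marginal_means_contrasts(df, "mdf")
    assert res.df_resid == 120 - 8


def test_marginal_means_equal_cell_means_when_covariates_null():
    df = make_staged_cohort(n_per_cell=60, effects={(0, "T1"): -1.0}, seed=1)
    res = marginal_means_contrasts(df, "mdf")
    for _, row in res.marginal_means.iterrows():
        cell = df[(df.sex == row["sex"]) & (df.stage == row["stage"])]["mdf"].mean()
        assert row["mean"] == pytest.approx(cell, abs=0.15)


def test_contrasts_match_normal_equation_oracle():
    """Estimates and SEs agree with a hand-built least-squares oracle."""
    df = make_staged_cohort(n_per_cell=25, effects={(1, "T1"): -0.8}, seed=2)
    res = marginal_means_contrasts(df, "mdf")

    # oracle: explicit dummy design, normal equations, contrast covariance
    d_t2 = (df.stage == "T2").astype(float).to_numpy()
    d_t3 = (df.stage == "T3").astype(float).to_numpy()
    sex = df.sex.to_numpy(dtype=float)
    X = np.column_stack([
        np.ones(len(df)), d_t2, d_t3, sex, sex * d_t2, sex * d_t3,
        df.age.to_numpy(), df.edu.to_numpy(),
    ])
    y = df.mdf.to_numpy()
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = XtX_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = resid @ resid / (len(df) - X.shape[1])
    cov = sigma2 * XtX_inv

    def cell_row(stage, sx):
        r = np.zeros(8)
        r[0] = 1.0
        r[1] = 1.0 if stage == "T2" else 0.0
        r[2] = 1.0 if stage == "T3" else 0.0
        r[3] = sx
        r[4] = sx * r[1]
        r[5] = sx * r[2]
        r[6] = df.age.mean()
        r[7] = df.edu.mean()
        return r

    for _, row in res.contrasts.iterrows():
        hi, lo = row["contrast"].split("-")
        L = cell_row(hi, row["sex"]) - cell_row(lo, row["sex"])
        assert row["estimate"] == pytest.approx(L @ beta, abs=1e-8)
        assert row["se"] == pytest.approx(np.sqrt(L @ cov @ L), abs=1e-8)


def test_contrast_recovers_injected_stage_drop():
    """An injected T1 - T2 drop of 0.5 Hz is covered by the 95% CI."""
    hits = 0
    reps = 60
    for rep in range(reps):
        df = make_staged_cohort(
            n_per_cell=40,
            effects={(0, "T1"): -0.5, (1, "T1"): -0.5},
            noise=0.6, seed=100 + rep,
        )
        res = marginal_means_contrasts(df, "mdf")
        row = res.contrasts[(res.contrasts.contrast == "T1-T2")
                            & (res.contrasts.sex == 0)].iloc[0]
        if row["ci_low"] <= -0.5 <= row["ci_high"]:
            hits += 1
    assert hits / reps >= 0.90


def test_contrast_requires_full_cells():
    df = make_staged_cohort(n_per_cell=10)
    df = df[~((df.sex == 0) & (df.stage == "T3"))]
    with pytest.raises(ValueError, match="empty cell"):
        marginal_means_contrasts(df, "mdf")


# ---------------------------------------------------------------------------
# standardized MLR


def test_mlr_exact_fit_and_standardization():
    rng = np.random.default_rng(6)
    n = 100
    df = pd.DataFrame({
        "sex": rng.integers(0, 2, n), "age": rng.uniform(50, 90, n),
        "edu": rng.uniform(0, 18, n), "mdf": rng.normal(8.5, 1.0, n),
    })
    df["mmse_total"] = 2.0 * df["mdf"]
    res = mlr_standardized(df, "mmse_total", "mdf")
    assert res.beta == pytest.approx(2.0, abs=1e-8)
    assert res.adj_r2 == pytest.approx(1.0, abs=1e-8)
    assert res.beta_std == pytest.approx(1.0, abs=1e-8)
    assert res.df_resid == n - 5


def test_mlr_standardized_beta_scale_invariant():
    rng = np.random.default_rng(7)
    n = 200
    df = pd.DataFrame({
        "sex": rng.integers(0, 2, n), "age": rng.uniform(50, 90, n),
        "edu": rng.uniform(0, 18, n), "mdf": rng.normal(8.5, 1.0, n),
    })
    df["mmse_total"] = 25 + 1.2 * df["mdf"] - 0.1 * df["age"] + rng.normal(0, 2, n)
    a = mlr_standardized(df, "mmse_total", "mdf")
    df10 = df.assign(mdf=df["mdf"] * 10)
    b = mlr_standardized(df10, "mmse_total", "mdf")
    assert a.beta_std == pytest.approx(b.beta_std, abs=1e-10)
    assert np.sign(a.beta) == np.sign(a.beta_std)


# ---------------------------------------------------------------------------
# agreement


def test_icc_identity_and_offset():
    rng = np.random.default_rng(8)
    a = rng.normal(10, 2, 100)
    res = icc(a, a.copy(), n_boot=50, seed=1)
    assert res.icc == pytest.approx(1.0)
    # a large constant offset destroys absolute agreement
    off = icc_value(a, a + 10.0)
    assert off < 0.3


def test_icc_matches_variance_components():
    rng = np.random.default_rng(9)
    n = 500
    subject = rng.normal(0, 2.0, n)  # between-subject variance 4
    a = subject + rng.normal(0, 1.0, n)  # error variance 1
    b = subject + rng.normal(0, 1.0, n)
    res = icc(a, b, n_boot=200, seed=2)
    assert res.icc == pytest.approx(0.8, abs=0.05)
    assert res.icc_ci[0] < res.icc < res.icc_ci[1]


def test_icc_agrees_with_pingouin():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(10)
    n = 60
    subject = rng.normal(0, 1.5, n)
    a = subject + rng.normal(0, 1.0, n) + 0.5
    b = subject + rng.normal(0, 1.0, n)
    long = pd.DataFrame({
        "subject": np.tile(np.arange(n), 2),
        "rater": np.repeat(["a", "b"], n),
        "score": np.concatenate([a, b]),
    })
    ref = pingouin.intraclass_corr(long, targets="subject", raters="rater",
                                   ratings="score")
    icc2 = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
    assert icc_value(a, b) == pytest.approx(icc2, abs=1e-6)


def test_paired_t_hand_value_and_sign():
    a = np.array([2.0, 4.0, 6.0])
    b = np.array([1.0, 2.0, 3.0])
    mean, sd, t, p = paired_t(a, b)
    assert (mean, sd) == (2.0, 1.0)
    assert t == pytest.approx(2 * np.sqrt(3.0))
    _, _, t2, _ = paired_t(b, a)
    assert t2 == pytest.approx(-t)
    same = np.array([1.0, 2.0, 3.0])
    mean0, sd0, t0, _ = paired_t(same, same)
    assert mean0 == 0.0 and sd0 == 0.0 and np.isnan(t0)  # degenerate flag


def test_bland_altman_definitions_and_coverage():
    a = np.array([1.0, 2.0, 3.0, 4.0])
    res = bland_altman(a, a)
    assert res.mean_diff == 0.0 and res.loa_low == 0.0 and res.loa_high == 0.0

    rng = np.random.default_rng(11)
    truth = rng.normal(25, 3, 10_000)
    pred = truth - rng.normal(0, 1.0, 10_000)
    res = bland_altman(truth, pred)
    inside = np.mean((res.diffs > res.loa_low) & (res.diffs < res.loa_high))
    assert inside == pytest.approx(0.95, abs=0.006)
    assert res.loa_high - res.loa_low == pytest.approx(2 * 1.96 * res.sd_diff)
    assert res.mean_diff_ci[0] < res.mean_diff < res.mean_diff_ci[1]
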