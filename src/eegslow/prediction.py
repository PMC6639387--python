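"""Predictive modelling of the MMSE total from EEG slowing biomarkers.

The modelling protocol: subjects are staged by fixed MMSE cut points
(T3: 28-30, T2: 25-27, T1: <= 24); continuous predictors (MDF, PF, ATR, age,
education) are standardized on the training data; the design contains, for
each continuous predictor X, the terms X and X^2 plus their interactions
with sex, and a sex main effect (21 columns + intercept). Candidate models
are ordinary (unit-weight) least squares with optional stepwise-AIC
reduction, and the elastic-net family minimizing

    (1/2n) * RSS + lambda * (alpha * ||b||_1 + (1 - alpha) * ||b||_2^2 / 2)

over a grid of 300 log-spaced lambda values from 10 down to 1e-4 crossed
with 11 mixing values alpha in {0.0, 0.1, ..., 1.0} (ridge at 0, LASSO at
1; 3,300 candidates). Hyperparameters are chosen by stage-stratified 10-fold
cross-validated RMSE on an 80% training split; the 20% test split is used
once, for agreement statistics (RMSE, Pearson r, mean difference, bootstrap
ICC, Bland-Altman).

The reference final prediction equations (one per sex, from a LASSO
at lambda = 0.007) are available through :func:`predict_final_equation`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, enet_path
from sklearn.metrics import roc_auc_score, roc_curve

from . import stats as egstats

CONTINUOUS_PREDICTORS = ("mdf", "pf", "atr", "age", "edu")

#: lambda grid: 300 log-spaced values from 10 down to 1e-4 (descending)
LAMBDA_GRID = np.exp(np.linspace(np.log(10.0), np.log(1e-4), 300))
#: mixing-parameter grid: ridge (0.0) to LASSO (1.0) in 0.1 steps
ALPHA_GRID = np.round(np.arange(0.0, 1.01, 0.1), 1)

STAGE_ORDER = ("T1", "T2", "T3")


def assign_stage(mmse_total) -> str:
    """Cognitive stage from fixed MMSE cut points (not data-driven tertiles).

    T3: 28 <= MMSE <= 30; T2: 25 <= MMSE <= 27; T1: MMSE <= 24.
    """
    m = int(mmse_total)
    if not 0 <= m <= 30:
        raise ValueError(f"MMSE total {m} out of [0, 30]")
    if m >= 28:
        return "T3"
    if m >= 25:
        return "T2"
    return "T1"


@dataclass
class Standardizer:
    """Training-set z-scoring applied unchanged to new data."""

    mean: float
    sd: float

    @classmethod
    def fit(cls, values: Sequence[float]) -> "Standardizer":
        v = np.asarray(values, dtype=float)
        sd = float(v.std(ddof=1))
        if sd == 0:
            raise ValueError("constant column cannot be standardized")
        return cls(mean=float(v.mean()), sd=sd)

    def transform(self, values) -> np.ndarray:
        return (np.asarray(values, dtype=float) - self.mean) / self.sd

    def inverse(self, z) -> np.ndarray:
        return np.asarray(z, dtype=float) * self.sd + self.mean


def standardize(train_values, apply_values) -> tuple[np.ndarray, Standardizer]:
    """z-score ``apply_values`` with the mean/SD of ``train_values``."""
    sz = Standardizer.fit(train_values)
    return sz.transform(apply_values), sz


@dataclass
class DesignMatrixSpec:
    """Design construction for the predictive models.

    Columns, in order: sex; then for each continuous predictor X (MDF, PF,
    ATR, age, edu, standardized with the stored training parameters): X,
    X^2, sex:X, sex:X^2 — 21 columns, intercept handled by the fitters.
    """

    standardizers: dict = field(default_factory=dict)

    @classmethod
    def from_train(cls, train: pd.DataFrame) -> "DesignMatrixSpec":
        return cls({v: Standardizer.fit(train[v]) for v in CONTINUOUS_PREDICTORS})

    @property
    def column_names(self) -> list[str]:
        cols = ["sex"]
        for v in CONTINUOUS_PREDICTORS:
            cols += [v, f"{v}2", f"sex:{v}", f"sex:{v}2"]
        return cols

    def build(self, cohort: pd.DataFrame) -> pd.DataFrame:
        sex = cohort["sex"].to_numpy(dtype=float)
        out = {"sex": sex}
        for v in CONTINUOUS_PREDICTORS:
            z = self.standardizers[v].transform(cohort[v])
            out[v] = z
            out[f"{v}2"] = z**2
            out[f"sex:{v}"] = sex * z
            out[f"sex:{v}2"] = sex * z**2
        return pd.DataFrame(out, index=cohort.index)


def stratified_split(
    cohort: pd.DataFrame, test_fraction: float = 0.2, seed: int = 0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Random train/test split stratified by cognitive stage.

    Per-stage test counts use floor(fraction * n_stage) with the remaining
    test slots given to the largest stages, so overall proportions are kept
    within rounding of the requested fraction. Reproducible under ``seed``.
    """
    if "stage" not in cohort.columns:
        cohort = cohort.assign(stage=cohort["mmse_total"].map(assign_stage))
    sizes = cohort["stage"].value_counts()
    if (sizes < 5).any() or len(sizes) == 0:
        raise ValueError("every stage needs at least 5 members")
    rng = np.random.default_rng(seed)
    n_test_total = int(round(test_fraction * len(cohort)))
    base = {st: int(np.floor(test_fraction * sizes[st])) for st in sizes.index}
    remainder = n_test_total - sum(base.values())
    for st in sizes.sort_values(ascending=False).index:
        if remainder <= 0:
            break
        base[st] += 1
        remainder -= 1
    test_idx = []
    for st, n_test in base.items():
        members = cohort.index[cohort["stage"] == st].to_numpy()
        picked = rng.choice(members, size=n_test, replace=False)
        test_idx.extend(picked.tolist())
    test_mask = cohort.index.isin(test_idx)
    return cohort.loc[~test_mask].copy(), cohort.loc[test_mask].copy()


# ---------------------------------------------------------------------------
# fitting


@dataclass
class PenalizedFit:
    """Fit of the elastic-net objective (or its unpenalized limit).

    ``coef`` is on the internally-standardized predictor scale;
    ``column_mean``/``column_scale`` restore raw-scale prediction.
    """

    alpha: float
    lam: float
    coef: np.ndarray
    intercept: float
    column_mean: np.ndarray
    column_scale: np.ndarray
    column_names: list
    objective: float = np.nan
    weights: Optional[np.ndarray] = None
    aic: Optional[float] = None

    def predict(self, X) -> np.ndarray:
        X = _design_values(X)
        Z = (X - self.column_mean) / self.column_scale
        return Z @ self.coef + self.intercept


def _design_values(X) -> np.ndarray:
    return X.to_numpy(dtype=float) if isinstance(X, pd.DataFrame) else np.asarray(X, float)


def _column_standardize(X: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mean = X.mean(axis=0)
    scale = X.std(axis=0, ddof=0)
    scale[scale == 0] = 1.0
    return (X - mean) / scale, mean, scale


def _objective(Z, yc, coef, alpha, lam) -> float:
    n = len(yc)
    rss = float(np.sum((yc - Z @ coef) ** 2))
    pen = lam * (alpha * np.abs(coef).sum() + (1 - alpha) * 0.5 * float(coef @ coef))
    return rss / (2 * n) + pen


def fit_elastic_net(X, y, alpha: float, lam: float, column_names=None) -> PenalizedFit:
    """Solve the elastic-net objective at one (alpha, lambda).

    Columns are standardized internally and the intercept is never
    penalized; at lambda = 0 the solution is the unpenalized least-squares
    fit, at alpha = 0 the ridge closed form (G + n*lambda*I)^-1 X'y.
    """
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must be in [0, 1]")
    if lam < 0:
        raise ValueError("lambda must be non-negative")
    Xv = _design_values(X)
    names = column_names or (list(X.columns) if isinstance(X, pd.DataFrame) else
                             [f"x{i}" for i in range(Xv.shape[1])])
    y = np.asarray(y, dtype=float)
    n = len(y)
    Z, mean, scale = _column_standardize(Xv)
    ybar = float(y.mean())
    yc = y - ybar
    if lam == 0:
        coef, *_ = np.linalg.lstsq(Z, yc, rcond=None)
    elif alpha == 0:
        G = Z.T @ Z
        coef = np.linalg.solve(G + n * lam * np.eye(Z.shape[1]), Z.T @ yc)
    else:
        model = ElasticNet(
            alpha=lam, l1_ratio=alpha, fit_intercept=False,
            max_iter=100_000, tol=1e-10,
        )
        model.fit(Z, yc)
        if model.n_iter_ >= 100_000:
            raise RuntimeError(
                f"coordinate descent did not converge (alpha={alpha}, lambda={lam})"
            )
        coef = model.coef_.copy()
    return PenalizedFit(
        alpha=float(alpha), lam=float(lam), coef=coef, intercept=ybar,
        column_mean=mean, column_scale=scale, column_names=names,
        objective=_objective(Z, yc, coef, alpha, lam),
    )


def lasso_lambda_max(X, y) -> float:
    """Smallest lambda at which the LASSO (alpha=1) slope vector is all
    zero: max|Z'y_c|/n on the standardized design."""
    Xv = _design_values(X)
    y = np.asarray(y, dtype=float)
    Z, _, _ = _column_standardize(Xv)
    return float(np.max(np.abs(Z.T @ (y - y.mean()))) / len(y))


def fit_wls(
    X, y, weights: Optional[np.ndarray] = None, stepwise: bool = False
) -> PenalizedFit:
    """(Weighted) least squares on the full design; optional stepwise-AIC.

    Weights default to unity — the protocol names no weighting scheme, so
    ordinary least squares is the default behaviour. With
    ``stepwise=True`` a both-directions AIC search from the full model
    returns the fit on the reduced term set (dropped columns keep
    zero coefficients so the fit stays design-compatible).
    """
    Xv = _design_values(X)
    names = list(X.columns) if isinstance(X, pd.DataFrame) else [
        f"x{i}" for i in range(Xv.shape[1])
    ]
    y = np.asarray(y, dtype=float)
    n, p = Xv.shape
    if n <= p + 1:
        raise ValueError("need more observations than design columns")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    sw = np.sqrt(w)
    Z, mean, scale = _column_standardize(Xv)

    def ols_fit(cols: list[int]) -> tuple[np.ndarray, float, float]:
        D = np.column_stack([np.ones(n)] + [Z[:, j] for j in cols]) * sw[:, None]
        yv = y * sw
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise ValueError("rank-deficient design")
        beta, *_ = np.linalg.lstsq(D, yv, rcond=None)
        rss = float(np.sum((yv - D @ beta) ** 2))
        k = D.shape[1] + 1  # + error variance
        aic = n * np.log(rss / n) + 2 * k
        return beta, rss, aic

    cols = list(range(p))
    beta, rss, aic = ols_fit(cols)
    if stepwise:
        improved = True
        while improved:
            improved = False
            best = (aic, None, None)
            for j in cols:  # backward
                trial = [c for c in cols if c != j]
                try:
                    b, r, a = ols_fit(trial)
                except ValueError:
                    continue
                if a < best[0] - 1e-10:
                    best = (a, trial, (b, r))
            for j in range(p):  # forward
                if j in cols:
                    continue
                trial = sorted(cols + [j])
                try:
                    b, r, a = ols_fit(trial)
                except ValueError:
                    continue
                if a < best[0] - 1e-10:
                    best = (a, trial, (b, r))
            if best[1] is not None:
                aic, cols, (beta, rss) = best
                improved = True
    coef = np.zeros(p)
    coef[cols] = beta[1:]
    return PenalizedFit(
        alpha=np.nan, lam=0.0, coef=coef, intercept=float(beta[0]),
        column_mean=mean, column_scale=scale, column_names=names,
        objective=rss / (2 * n), weights=w, aic=float(aic),
    )


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class CVResult:
    """Grid of validation RMSEs and the selected candidates.

    ``table`` has one row per candidate (model family, alpha, lambda, mean
    10-fold validation RMSE); ``selected`` maps family name (wls, ridge,
    enet, lasso) to its minimizing row; ``best`` names the overall winner.
    """

    table: pd.DataFrame
    selected: dict
    best: str
    fold_seed: int


def _stratified_folds(stages: np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold assignment (0..k-1) per row, stratified by stage label."""
    rng = np.random.default_rng(seed)
    assignment = np.empty(len(stages), dtype=int)
    for st in np.unique(stages):
        idx = np.flatnonzero(stages == st)
        rng.shuffle(idx)
        assignment[idx] = np.arange(len(idx)) % k
    return assignment


def cross_validate_grid(
    train: pd.DataFrame,
    k: int = 10,
    seed: int = 0,
    response: str = "mmse_total",
    spec: Optional[DesignMatrixSpec] = None,
) -> CVResult:
    """Stage-stratified k-fold CV over the full candidate grid.

    Candidates: the 3,300 (lambda, alpha) elastic-net combinations plus the
    unit-weight least-squares model on the full design. The design is built
    from ``spec`` (default: standardization fitted on ``train``); within
    each fold, fits standardize on the fold-training rows only. Returns the
    mean validation RMSE per candidate and the per-family minimizers.
    """
    if len(train) < k * 5:
        raise ValueError("training set too small for the fold count")
    if spec is None:
        spec = DesignMatrixSpec.from_train(train)
    stages = train["stage"].to_numpy() if "stage" in train.columns else (
        train["mmse_total"].map(assign_stage).to_numpy()
    )
    X = spec.build(train).to_numpy()
    y = train[response].to_numpy(dtype=float)
    folds = _stratified_folds(stages, k, seed)

    n_lam = len(LAMBDA_GRID)
    sq_err = {a: np.zeros(n_lam) for a in ALPHA_GRID}
    counts = {a: np.zeros(n_lam) for a in ALPHA_GRID}
    wls_rmses = []
    for f in range(k):
        tr, va = folds != f, folds == f
        if len(np.unique(stages[va])) < len(np.unique(stages)):
            pass  # a fold may miss a stage at small n; proceed
        Ztr, mean, scale = _column_standardize(X[tr])
        ytr = y[tr]
        ybar = ytr.mean()
        ytr_c = ytr - ybar
        Zva = (X[va] - mean) / scale
        G = Ztr.T @ Ztr
        Xy = Ztr.T @ ytr_c
        n_tr = tr.sum()
        # ridge path by eigendecomposition, all lambdas at once
        evals, evecs = np.linalg.eigh(G)
        proj = evecs.T @ Xy
        ridge_coefs = evecs @ (proj[:, None] / (evals[:, None] + n_tr * LAMBDA_GRID[None, :]))
        for a in ALPHA_GRID:
            if a == 0.0:
                coefs = ridge_coefs
            else:
                with warnings.catch_warnings():
                    # path solutions at the smallest lambdas stop at the
                    # default duality gap; fine for RMSE ranking
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    _, coefs, _ = enet_path(
                        Ztr, ytr_c, l1_ratio=float(a), alphas=LAMBDA_GRID,
                        precompute=G, Xy=Xy,
                    )
            pred = Zva @ coefs + ybar  # (n_va, n_lam)
            rmse_fold = np.sqrt(np.mean((y[va][:, None] - pred) ** 2, axis=0))
            sq_err[a] += rmse_fold
            counts[a] += 1
        # unit-weight least squares on the full design
        D = np.column_stack([np.ones(n_tr), Ztr])
        beta, *_ = np.linalg.lstsq(D, ytr, rcond=None)
        pred = np.column_stack([np.ones(va.sum()), Zva]) @ beta
        wls_rmses.append(float(np.sqrt(np.mean((y[va] - pred) ** 2))))

    rows = [
        {"model": "wls", "alpha": np.nan, "lambda": np.nan,
         "rmse_cv": float(np.mean(wls_rmses))}
    ]
    for a in ALPHA_GRID:
        mean_rmse = sq_err[a] / counts[a]
        family = "ridge" if a == 0.0 else ("lasso" if a == 1.0 else "enet")
        for lam, r in zip(LAMBDA_GRID, mean_rmse):
            rows.append({"model": family, "alpha": float(a), "lambda": float(lam),
                         "rmse_cv": float(r)})
    table = pd.DataFrame(rows)
    selected = {}
    for family in ("wls", "ridge", "enet", "lasso"):
        sub = table[table["model"] == family]
        selected[family] = sub.loc[sub["rmse_cv"].idxmin()].to_dict()
    best = min(selected, key=lambda fam: selected[fam]["rmse_cv"])
    return CVResult(table=table, selected=selected, best=best, fold_seed=seed)


def fit_selected(
    train: pd.DataFrame,
    cv: CVResult,
    family: Optional[str] = None,
    response: str = "mmse_total",
    spec: Optional[DesignMatrixSpec] = None,
) -> PenalizedFit:
    """Refit the CV-selected candidate of a family on the full training set."""
    family = family or cv.best
    if spec is None:
        spec = DesignMatrixSpec.from_train(train)
    X = spec.build(train)
    y = train[response].to_numpy(dtype=float)
    if family == "wls":
        return fit_wls(X, y)
    sel = cv.selected[family]
    return fit_elastic_net(X, y, alpha=sel["alpha"], lam=sel["lambda"])


@dataclass
class PredictionEvaluation:
    rmse: float
    pearson: egstats.CorrelationResult
    mean_diff: float
    sd_diff: float
    icc: egstats.AgreementResult
    bland_altman: egstats.AgreementResult
    n: int


def evaluate_on_test(
    fit: PenalizedFit,
    test: pd.DataFrame,
    spec: DesignMatrixSpec,
    response: str = "mmse_total",
    n_boot: int = 1000,
    seed: int = 0,
) -> PredictionEvaluation:
    """Held-out agreement statistics between true and predicted MMSE.

    RMSE, Pearson r with CI, mean difference (true - predicted) with SD,
    bootstrap ICC(A,1) and Bland-Altman limits of agreement. The test set
    must not have participated in fitting or hyperparameter selection.
    """
    y = test[response].to_numpy(dtype=float)
    yhat = fit.predict(spec.build(test))
    d = y - yhat
    return PredictionEvaluation(
        rmse=float(np.sqrt(np.mean(d**2))),
        pearson=egstats.pearson_ci(y, yhat),
        mean_diff=float(d.mean()),
        sd_diff=float(d.std(ddof=1)),
        icc=egstats.icc(y, yhat, n_boot=n_boot, seed=seed),
        bland_altman=egstats.bland_altman(y, yhat),
        n=len(y),
    )


# ---------------------------------------------------------------------------
# reference final model


#: Final LASSO (lambda = 0.007, alpha = 1) equation coefficients per sex,
#: on the standardized predictor scale. Keys: intercept, then X / X^2 terms.
FINAL_EQUATION_MALE = {
    "intercept": 24.597,
    "mdf": 7.216, "mdf2": -6.318,
    "pf": -0.013, "pf2": 0.0,
    "atr": 0.913, "atr2": -0.93,
    "age": 4.192, "age2": -5.06,
    "edu": 4.725, "edu2": -2.523,
}
FINAL_EQUATION_FEMALE = {
    "intercept": 24.597,
    "mdf": 7.216, "mdf2": -6.343,
    "pf": 0.008, "pf2": 0.4,
    "atr": 1.525, "atr2": -0.939,
    "age": 4.192, "age2": -5.502,
    "edu": 3.277, "edu2": -1.476,
}


def predict_final_equation(mdf_std, pf_std, atr_std, age_std, edu_std, sex):
    """Predicted MMSE from the reference final per-sex polynomial equations.

    Inputs are on the standardized scale; ``sex`` is 1 for female, 0 for
    male. Both equations derive from one model with sex interactions, so
    some coefficients (intercept, MDF, age main terms) are shared. Output
    is not clipped to [0, 30].
    """
    sex = np.asarray(sex)
    vals = {"mdf": np.asarray(mdf_std, float), "pf": np.asarray(pf_std, float),
            "atr": np.asarray(atr_std, float), "age": np.asarray(age_std, float),
            "edu": np.asarray(edu_std, float)}
    out = np.zeros(np.broadcast(sex, vals["mdf"]).shape, dtype=float)
    for s, eq in ((0, FINAL_EQUATION_MALE), (1, FINAL_EQUATION_FEMALE)):
        pred = eq["intercept"] + sum(
            eq[v] * vals[v] + eq[f"{v}2"] * vals[v] ** 2 for v in vals
        )
        out = np.where(sex == s, pred, out)
    return float(out) if out.ndim == 0 else out


def roc_auc(scores, binary_labels) -> tuple[float, float]:
    """AUC (rank statistic) and accuracy at the Youden-optimal threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(binary_labels, dtype=int)
    if len(np.unique(labels)) < 2:
        raise ValueError("need both classes present")
    auc = float(roc_auc_score(labels, scores))
    fpr, tpr, thresholds = roc_curve(labels, scores)
    best = np.argmax(tpr - fpr)
    pred = (scores >= thresholds[best]).astype(int)
    return auc, float(np.mean(pred == labels))
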