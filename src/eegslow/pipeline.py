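"""End-to-end pipeline: simulate/load -> extract -> associate -> predict.

A :class:`PipelineConfig` (loadable from YAML) drives four stages and a run
manifest listing every output file with a checksum, so any run can be
reproduced from its manifest alone. All randomness comes from explicit seeds
in the config; there is no global random state.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import io as egio
from . import prediction as pred
from . import spectral
from . import stats as egstats
from .synth import CohortSimParams, EEGSimParams, simulate_cohort

log = logging.getLogger("eegslow")


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Seeds are separate per stage (simulation, train/test split, CV folds,
    bootstrap) so stages can be varied independently. Band edges, screening
    thresholds and stage cut points document the spectral/staging protocol
    and feed the manifest.
    """

    n_subjects: int = 150
    sim_seed: int = 0
    noise_sd: float = 2.7
    coeffs: dict = field(default_factory=lambda: {"mdf": 1.5, "age": -1.6, "edu": 1.6,
                                                  "sex": -0.2})
    eeg_duration_s: float = 300.0
    eeg_fs: float = 250.0
    blink_rate: float = 0.0
    emg_burst_rate: float = 0.0
    filter_enabled: bool = True
    zero_phase: bool = False
    theta_band: tuple = spectral.THETA_BAND
    alpha_band: tuple = spectral.ALPHA_BAND
    dominant_band: tuple = spectral.DOMINANT_BAND
    screen_thresholds_uV: tuple = spectral.SCREEN_THRESHOLDS_UV
    stage_cutpoints: str = "T3: 28-30; T2: 25-27; T1: <=24"
    test_fraction: float = 0.2
    cv_folds: int = 10
    split_seed: int = 1
    fold_seed: int = 2
    boot_seed: int = 3
    out_dir: str = "eegslow-out"
    log_level: str = "INFO"

    def __post_init__(self):
        for lo, hi in (self.theta_band, self.alpha_band, self.dominant_band):
            if not hi > lo >= 0:
                raise ValueError("band edges must be ordered and non-negative")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("theta_band", "alpha_band", "dominant_band", "screen_thresholds_uV"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d


@dataclass
class RunManifest:
    """Record of one pipeline run: config, seeds, counts, file checksums."""

    config: dict
    version: str
    started: str
    finished: str
    stage_counts: dict
    outputs: dict  # path -> sha256

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def extract_cohort_biomarkers(recordings, config: PipelineConfig) -> pd.DataFrame:
    """Filter (optionally), screen and extract biomarkers per recording."""
    rows = []
    for rec in recordings:
        if config.filter_enabled:
            rec = spectral.apply_device_filters(rec, zero_phase=config.zero_phase)
        bm = spectral.extract_biomarkers(rec)
        row = {"id": rec.subject_id, "mdf": bm.mdf, "pf": bm.pf, "atr": bm.atr}
        for ch, vals in bm.per_channel.items():
            for k, v in vals.items():
                row[f"{k}_{ch.lower()}"] = v
        for th, res in bm.screens.items():
            row[f"screen{th}"] = int(res.passed)
        rows.append(row)
    return pd.DataFrame(rows)


def associate(cohort: pd.DataFrame, alpha: float = 0.05) -> dict[str, pd.DataFrame]:
    """Association tables: correlations by group with sex comparisons,
    marginal-means contrasts per biomarker, and standardized MLR for the
    MMSE total and every domain score."""
    from .synth import DOMAIN_COLUMNS

    groups = {"total": cohort, "male": cohort[cohort.sex == 0],
              "female": cohort[cohort.sex == 1]}
    eeg_vars = ["mdf", "pf", "atr"]
    corr_rows = []
    pairs = [(v, t) for v in ["mmse_total"] + eeg_vars for t in ("age", "edu")]
    pairs += [(v, "mmse_total") for v in eeg_vars]
    m = len(pairs)
    for x, yv in pairs:
        per_group = {}
        for gname, g in groups.items():
            res = egstats.pearson_ci(g[x], g[yv], alpha=alpha, bonferroni_m=m)
            per_group[gname] = res
            corr_rows.append({"var": x, "with": yv, "group": gname, "r": res.estimate,
                              "ci_low": res.ci_low, "ci_high": res.ci_high,
                              "p_adj": res.p, "n": res.n})
        comp = egstats.fisher_z_independent(
            per_group["female"].estimate, per_group["female"].n,
            per_group["male"].estimate, per_group["male"].n, alpha=alpha,
        )
        corr_rows.append({"var": x, "with": yv, "group": "female-male",
                          "r": comp.delta, "ci_low": comp.ci_low,
                          "ci_high": comp.ci_high, "p_adj": min(1.0, comp.p * m),
                          "n": per_group["total"].n})
    correlations = pd.DataFrame(corr_rows)

    contrast_frames = []
    for v in eeg_vars:
        res = egstats.marginal_means_contrasts(cohort, v, alpha=alpha)
        con = res.contrasts.assign(biomarker=v)
        mm = res.marginal_means.assign(biomarker=v)
        contrast_frames.append((mm, con))
    marginal_means = pd.concat([mm for mm, _ in contrast_frames], ignore_index=True)
    contrasts = pd.concat([con for _, con in contrast_frames], ignore_index=True)

    mlr_rows = []
    for v in eeg_vars:
        for resp in ["mmse_total", *DOMAIN_COLUMNS]:
            r = egstats.mlr_standardized(cohort, resp, v, alpha=alpha)
            mlr_rows.append({"eeg_var": v, "response": resp, "beta": r.beta,
                             "ci_low": r.ci_low, "ci_high": r.ci_high, "p": r.p,
                             "beta_std": r.beta_std, "adj_r2": r.adj_r2,
                             "df": r.df_resid})
    mlr = pd.DataFrame(mlr_rows)
    return {"correlations": correlations, "marginal_means": marginal_means,
            "contrasts": contrasts, "mlr": mlr}


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute simulate -> extract -> associate -> predict -> report."""
    logging.basicConfig(level=config.log_level)
    started = time.strftime("%Y-%m-%dT%H:%M:%S")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage_counts = {}

    # simulate
    sim = CohortSimParams(
        n_subjects=config.n_subjects, seed=config.sim_seed, noise_sd=config.noise_sd,
        coeffs=dict(config.coeffs),
        eeg_params=EEGSimParams(
            duration_s=config.eeg_duration_s, fs=config.eeg_fs,
            blink_rate=config.blink_rate, emg_burst_rate=config.emg_burst_rate,
        ),
    )
    cohort, recordings = simulate_cohort(sim)
    stage_counts["simulated_subjects"] = len(cohort)
    log.info("simulated %d subjects with %d recordings", len(cohort), len(recordings))

    # extract
    biomarkers = extract_cohort_biomarkers(recordings, config)
    n_screen_fail = int((biomarkers["screen200"] == 0).sum())
    stage_counts["screen200_failures"] = n_screen_fail
    log.info("extracted biomarkers for %d subjects (%d screen failures at 200 uV)",
             len(biomarkers), n_screen_fail)
    cohort = cohort.drop(columns=["mdf", "pf", "atr"]).merge(biomarkers, on="id")
    cohort["stage"] = cohort["mmse_total"].map(pred.assign_stage)
    biomarkers.to_csv(out / "biomarkers.csv", index=False)
    egio.write_cohort(cohort, out / "cohort.csv")

    # associate
    tables = associate(cohort)
    for name, df in tables.items():
        df.to_csv(out / f"{name}.csv", index=False)
    stage_counts["association_rows"] = {k: len(v) for k, v in tables.items()}

    # predict
    train, test = pred.stratified_split(cohort, config.test_fraction, seed=config.split_seed)
    stage_counts["train"], stage_counts["test"] = len(train), len(test)
    spec = pred.DesignMatrixSpec.from_train(train)
    cv = pred.cross_validate_grid(train, k=config.cv_folds, seed=config.fold_seed, spec=spec)
    cv.table.to_csv(out / "cv_table.csv", index=False)
    eval_rows = {}
    ba = None
    for family in ("wls", "ridge", "enet", "lasso"):
        fit = pred.fit_selected(train, cv, family=family, spec=spec)
        ev = pred.evaluate_on_test(fit, test, spec, seed=config.boot_seed)
        eval_rows[family] = {
            "alpha": cv.selected[family]["alpha"], "lambda": cv.selected[family]["lambda"],
            "rmse_cv": cv.selected[family]["rmse_cv"], "rmse_test": ev.rmse,
            "r": ev.pearson.estimate, "r_ci": [ev.pearson.ci_low, ev.pearson.ci_high],
            "mean_diff": ev.mean_diff, "sd_diff": ev.sd_diff,
            "icc": ev.icc.icc, "icc_ci": list(ev.icc.icc_ci),
        }
        if family == cv.best:
            ba = ev.bland_altman
            coeffs = {"intercept": fit.intercept,
                      **dict(zip(fit.column_names, fit.coef.tolist()))}
            (out / "final_model.json").write_text(json.dumps(
                {"family": family, "alpha": fit.alpha, "lambda": fit.lam,
                 "coefficients_standardized_scale": coeffs}, indent=2))
    (out / "test_evaluation.json").write_text(json.dumps(
        {"best": cv.best, "models": eval_rows}, indent=2))
    pd.DataFrame({"mean": ba.means, "diff": ba.diffs}).to_csv(
        out / "bland_altman.csv", index=False)
    log.info("prediction stage done; best family = %s", cv.best)

    manifest = RunManifest(
        config=config.to_dict(), version=__version__, started=started,
        finished=time.strftime("%Y-%m-%dT%H:%M:%S"), stage_counts=stage_counts,
        outputs={p.name: _sha256(p) for p in sorted(out.iterdir())
                 if p.name != "manifest.json"},
    )
    manifest.write(out / "manifest.json")
    return manifest
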