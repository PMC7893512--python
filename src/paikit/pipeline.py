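"""End-to-end composition of the PAI analysis.

Chains the stages on an imputed trial dataset: outcome construction
(spline AUC, baseline residualization), covariate transforms (optional
collinearity pruning first), stage-1 MOB-forest screening, stage-2
bootstrap backward elimination, cross-validated PAI computation,
Johnson–Neyman probing of the selected moderators, and the evaluation
battery.  ``run_primary`` performs selection on the full sample (the
primary mode); the nested no-double-dipping variant lives in
:mod:`paikit.robustness`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import boot_select, evaluation, mob_forest, outcomes, pai_engine, screening
from .synthetic_trial import TrialDataset

__all__ = ["PipelineConfig", "PrimaryResult", "run_primary", "inverse_transform_value"]


@dataclass
class PipelineConfig:
    forest: mob_forest.MobConfig = field(
        default_factory=lambda: mob_forest.MobConfig(n_trees=10000)
    )
    n_boot: int = 1000
    boot_alpha: float = 0.05
    freq_threshold: float = 0.60
    cv_folds: int = 5
    cv_seed: int = 0
    boot_seed: int = 1
    prune: bool = False
    prune_threshold: float = 0.70
    reliabilities: dict | None = None
    skew_threshold: float = 1.0
    jn_alpha: float = 0.05


@dataclass
class PrimaryResult:
    outcome_records: pd.DataFrame
    screening_report: screening.ScreeningReport | None
    transforms: screening.TransformRecord
    importance_report: mob_forest.ImportanceReport
    bootstrap_report: boot_select.BootstrapSelectionReport | None
    predictors: list
    moderators: list
    final_model: pai_engine.FinalModel | None
    pai_table: pai_engine.PaiTable
    jn_regions: dict
    evaluation_report: evaluation.EvaluationReport


def _roles_from_report(report) -> tuple[list, list]:
    predictors = [v for v, r in report.roles.items() if r == "predictor"]
    moderators = [v for v, r in report.roles.items() if r == "moderator"]
    return predictors, moderators


def run_primary(data: TrialDataset, config: PipelineConfig | None = None) -> PrimaryResult:
    """Full-sample selection followed by cross-validated PAI and evaluation.

    ``data`` must be complete (impute first, e.g. with
    :func:`paikit.rf_impute.impute_dataset`).
    """
    config = config or PipelineConfig()
    rec = outcomes.build_outcome_records(
        data.outcomes, data.schedule, data.baseline_bdi
    )
    y = rec["auc_residual"].to_numpy()

    cov = data.covariates
    screen_report = None
    if config.prune:
        corrected, warns = screening.attenuation_corrected_corr(
            cov, config.reliabilities
        )
        out_corr = cov.corrwith(rec["auc_residual"]).abs()
        screen_report = screening.prune_collinear(
            corrected, threshold=config.prune_threshold, outcome_corr=out_corr
        )
        screen_report.warnings = warns
        cov = cov[screen_report.retained]

    transforms = screening.fit_transforms(
        cov, data.covariate_kinds, skew_threshold=config.skew_threshold
    )
    X = screening.apply_transforms(cov, transforms)
    arm = data.arm_numeric.to_numpy()

    forest = mob_forest.fit_forest(
        X, y, arm, config.forest, kind_map=data.covariate_kinds
    )
    imp = mob_forest.importance(forest, X, y, arm)

    boot_report = None
    predictors, moderators = [], []
    if imp.selected:
        boot_report = boot_select.bootstrap_selection(
            X,
            y,
            arm,
            imp.selected,
            n_boot=config.n_boot,
            alpha=config.boot_alpha,
            freq_threshold=config.freq_threshold,
            seed=config.boot_seed,
        )
        predictors, moderators = _roles_from_report(boot_report)

    pai_table = pai_engine.crossval_predict(
        X,
        y,
        arm,
        predictors=predictors,
        moderators=moderators,
        k=config.cv_folds,
        seed=config.cv_seed,
    )

    final_model = pai_engine.fit_final_model(
        X, y, arm, predictors=predictors, moderators=moderators
    )
    jn = {}
    means = {m: float(X[m].mean()) for m in moderators}
    for m in moderators:
        jn[m] = pai_engine.johnson_neyman(
            final_model,
            m,
            X[m],
            alpha=config.jn_alpha,
            other_moderator_means={k: v for k, v in means.items() if k != m},
        )

    eval_report = evaluation.evaluate_pai(pai_table, rec["avg_bdi"])
    return PrimaryResult(
        outcome_records=rec,
        screening_report=screen_report,
        transforms=transforms,
        importance_report=imp,
        bootstrap_report=boot_report,
        predictors=predictors,
        moderators=moderators,
        final_model=final_model,
        pai_table=pai_table,
        jn_regions=jn,
        evaluation_report=eval_report,
    )


def inverse_transform_value(record: screening.TransformRecord, name: str, value: float):
    """Map a transformed-scale value (e.g. a Johnson–Neyman boundary) back
    to the variable's raw scale."""
    step = record.steps[name]
    v = value
    if step["scale"] is not None:
        v = v * step["scale"]
    v = v + step["center"]
    if step["skew_fix"] == "log1p":
        v = np.expm1(v)
    elif step["skew_fix"] == "sqrt_shift":
        v = v**2 - step["shift"]
    return float(v)
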