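"""Nested fivefold validation: selection without double-dipping.

The primary analysis selects variables on the full sample and only the
final-model weights are cross-validated, so held-out predictions are not
fully independent of the data that chose the variables.  This module
repeats the whole chain — outcome residualization, covariate transforms,
MOB-forest screening, bootstrap backward elimination, final-model fitting —
inside each training fold, predicts only that fold's held-out participants,
pools the five held-out PAI tables, and evaluates them.  A leakage audit
verifies that no participant's data entered the selection or fitting stage
of the model that predicted them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import boot_select, evaluation, mob_forest, outcomes, pai_engine, screening
from .pipeline import PipelineConfig, _roles_from_report
from .synthetic_trial import TrialDataset

__all__ = ["NestedRunReport", "nested_validate", "audit_leakage"]


@dataclass
class NestedRunReport:
    fold_selections: list  # per fold: {"predictors": [...], "moderators": [...]}
    fold_ids: dict  # fold -> {"train": [...], "test": [...]}
    pai_table: pai_engine.PaiTable
    evaluation_report: evaluation.EvaluationReport
    comparison: "evaluation.PaiAgreement | None" = None
    fold_models: list = field(default_factory=list)


def audit_leakage(report: NestedRunReport) -> bool:
    """True when every fold's train and test id sets are disjoint and the
    test sets partition the sample."""
    all_test = []
    for fold, ids in report.fold_ids.items():
        if set(ids["train"]) & set(ids["test"]):
            return False
        all_test.extend(ids["test"])
    return len(all_test) == len(set(all_test)) == len(report.pai_table)


def nested_validate(
    data: TrialDataset,
    config: PipelineConfig | None = None,
    k: int = 5,
    seed: int = 12345,
    n_trees: int = 2000,
    primary_pai: pd.DataFrame | None = None,
    force_selection: tuple | None = None,
) -> NestedRunReport:
    """Run the selection-to-prediction chain inside k training folds.

    ``n_trees`` caps the per-fold forest size (selection inside folds is run
    five times, so the forest is scaled down from the primary run by
    default).  ``primary_pai`` (optional) is compared with the pooled nested
    table via signed-PAI correlation and recommendation agreement.  The fold
    partition uses its own seed stream, independent of the engine's CV
    partition.  ``force_selection=(predictors, moderators)`` bypasses the
    per-fold selection stages and fits the given variable sets in every
    fold (used to isolate weight-setting variability from selection
    variability).
    """
    config = config or PipelineConfig()
    rng = np.random.default_rng(seed)
    arm = data.arm_numeric.to_numpy()
    ids = np.asarray(data.ids)
    fold = np.empty(len(arm), dtype=int)
    for a in np.unique(arm):
        idx = np.flatnonzero(arm == a)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % k

    months = np.asarray(data.schedule, dtype=float)
    auc = np.array(
        [
            outcomes.spline_auc(months, row)
            for row in data.outcomes.to_numpy(dtype=float)
        ]
    )
    baseline = data.baseline_bdi.to_numpy(dtype=float)
    avg_bdi = pd.Series(
        outcomes.to_average_bdi(auc, months[-1] - months[0]), index=data.ids
    )

    pred_ct = np.empty(len(arm))
    pred_ipt = np.empty(len(arm))
    fold_selections, fold_ids, fold_models = [], {}, []
    for f in range(k):
        train = fold != f
        test = ~train
        fold_ids[f] = {"train": ids[train].tolist(), "test": ids[test].tolist()}

        # baseline residualization refit on the training fold only
        design = np.column_stack([np.ones(train.sum()), baseline[train]])
        coef, *_ = np.linalg.lstsq(design, auc[train], rcond=None)
        y_train = auc[train] - design @ coef
        span = months[-1] - months[0]
        y_train = y_train / span  # average-BDI scale keeps folds comparable

        cov_train = data.covariates.loc[train]
        transforms = screening.fit_transforms(
            cov_train, data.covariate_kinds, skew_threshold=config.skew_threshold
        )
        X_train = screening.apply_transforms(cov_train, transforms)
        X_test = screening.apply_transforms(data.covariates.loc[test], transforms)

        if force_selection is not None:
            predictors, moderators = (
                list(force_selection[0]),
                list(force_selection[1]),
            )
            fold_selections.append(
                {"predictors": predictors, "moderators": moderators}
            )
            model = pai_engine.fit_final_model(
                X_train,
                y_train,
                arm[train],
                predictors=predictors,
                moderators=moderators,
            )
            fold_models.append(model)
            pred_ct[test] = pai_engine.predict_under_arm(model, X_test, 0)
            pred_ipt[test] = pai_engine.predict_under_arm(model, X_test, 1)
            continue

        fcfg = mob_forest.MobConfig(
            n_trees=min(n_trees, config.forest.n_trees),
            alpha_split=config.forest.alpha_split,
            min_node=config.forest.min_node,
            mtry=config.forest.mtry,
            bootstrap=config.forest.bootstrap,
            bonferroni=config.forest.bonferroni,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        forest = mob_forest.fit_forest(
            X_train, y_train, arm[train], fcfg, kind_map=data.covariate_kinds
        )
        imp = mob_forest.importance(forest, X_train, y_train, arm[train])
        predictors, moderators = [], []
        if imp.selected:
            boot_report = boot_select.bootstrap_selection(
                X_train,
                y_train,
                arm[train],
                imp.selected,
                n_boot=config.n_boot,
                alpha=config.boot_alpha,
                freq_threshold=config.freq_threshold,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            predictors, moderators = _roles_from_report(boot_report)
        fold_selections.append({"predictors": predictors, "moderators": moderators})

        model = pai_engine.fit_final_model(
            X_train,
            y_train,
            arm[train],
            predictors=predictors,
            moderators=moderators,
        )
        fold_models.append(model)
        pred_ct[test] = pai_engine.predict_under_arm(model, X_test, 0)
        pred_ipt[test] = pai_engine.predict_under_arm(model, X_test, 1)

    pai_table = pai_engine._assemble_pai(data.arm, pred_ct, pred_ipt, fold)
    eval_report = evaluation.evaluate_pai(pai_table, avg_bdi)
    comparison = None
    if primary_pai is not None:
        try:
            comparison = evaluation.compare_pai_sets(pai_table, primary_pai)
        except ValueError:
            comparison = None
    return NestedRunReport(
        fold_selections=fold_selections,
        fold_ids=fold_ids,
        pai_table=pai_table,
        evaluation_report=eval_report,
        comparison=comparison,
        fold_models=fold_models,
    )
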