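"""Iterative random-forest imputation (missForest algorithm).

Missing covariates and outcome scores are imputed jointly: each incomplete
column is regressed on all other columns with a random forest fitted on its
observed rows, missing rows are predicted, and sweeps repeat until the
stratified difference statistic first increases (the previous sweep's matrix
is returned) or an iteration cap is reached.  Continuous columns start at
the column mean, categorical ones at the mode; counts are imputed as
continuous and rounded to the nearest admissible value at the end.

Accuracy is validated by masking cells of a complete matrix, re-imputing,
and scoring NRMSE over masked continuous cells and PFC over masked
categorical cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier, RandomForestRegressor

from .synthetic_trial import TrialDataset

__all__ = [
    "assemble_imputation_features",
    "missforest_impute",
    "validate_imputation",
    "impute_dataset",
    "ImputationResult",
    "ImputationAccuracy",
]


@dataclass
class ImputationResult:
    completed: pd.DataFrame
    n_iterations: int
    diff_history: list  # per sweep: {"continuous": float, "categorical": float}
    converged: bool
    manifest: dict = field(default_factory=dict)


@dataclass
class ImputationAccuracy:
    nrmse: float  # NaN when no continuous cells were masked
    pfc: float  # NaN when no categorical cells were masked
    mask_description: dict


def assemble_imputation_features(data: TrialDataset) -> tuple[pd.DataFrame, dict]:
    """Build the imputation feature matrix.

    Columns: change-from-baseline of every follow-up BDI-II score (month 3
    included when carried), all baseline covariates, and the received-arm
    indicator.  The manifest records each column's provenance and type so
    imputed change scores can be mapped back to raw scores.
    """
    base = data.baseline_bdi.to_numpy(dtype=float)
    if not np.all(np.isfinite(base)):
        raise ValueError("baseline BDI-II must be observed for every participant")

    cols, manifest = {}, {"columns": {}}
    out_frames = []
    if data.month3 is not None:
        out_frames.append(("bdi_m3", data.month3))
    for c in data.outcomes.columns:
        out_frames.append((c, data.outcomes[c]))
    for name, series in out_frames:
        cols[f"chg_{name}"] = series.to_numpy(dtype=float) - base
        manifest["columns"][f"chg_{name}"] = {
            "source": name,
            "role": "outcome_change",
            "type": "continuous",
        }
    for c in data.covariates.columns:
        cols[c] = data.covariates[c].to_numpy(dtype=float)
        kind = data.covariate_kinds.get(c, "continuous")
        manifest["columns"][c] = {
            "source": c,
            "role": "covariate",
            "type": "categorical" if kind == "binary" else "continuous",
            "kind": kind,
        }
    cols["arm_ipt"] = data.arm_numeric.to_numpy(dtype=float)
    manifest["columns"]["arm_ipt"] = {
        "source": "arm",
        "role": "treatment",
        "type": "categorical",
    }
    frame = pd.DataFrame(cols, index=data.ids)
    return frame, manifest


def _column_types(frame: pd.DataFrame, categorical=None) -> dict:
    categorical = set(categorical or [])
    return {
        c: ("categorical" if c in categorical else "continuous")
        for c in frame.columns
    }


def missforest_impute(
    frame: pd.DataFrame,
    categorical=None,
    n_trees: int = 100,
    max_iter: int = 10,
    seed: int = 0,
) -> ImputationResult:
    """Impute a mixed-type matrix with iterated random forests.

    Parameters
    ----------
    frame : DataFrame with NaN marking missing cells.
    categorical : iterable of column names imputed by classification forest.
    n_trees, max_iter : forest size per column and sweep cap.
    seed : drives every forest; the full run is deterministic.
    """
    types = _column_types(frame, categorical)
    x = frame.to_numpy(dtype=float).copy()
    miss = ~np.isfinite(x)
    if miss.all(axis=0).any():
        raise ValueError("a column is entirely missing")
    if miss.all(axis=1).any():
        raise ValueError("a row is entirely missing")
    obs_vals = frame.to_numpy(dtype=float)
    if not np.all(np.isfinite(obs_vals[~miss])):
        raise ValueError("observed values must be finite")

    cols = list(frame.columns)
    if not miss.any():
        return ImputationResult(frame.copy(), 1, [], True)

    # initialization
    for j, c in enumerate(cols):
        col = x[:, j]
        if not miss[:, j].any():
            continue
        obs = col[~miss[:, j]]
        if types[c] == "categorical":
            vals, counts = np.unique(obs, return_counts=True)
            fill = vals[np.argmax(counts)]
        else:
            fill = obs.mean()
        col[miss[:, j]] = fill

    order = np.argsort(miss.sum(axis=0), kind="stable")
    order = [j for j in order if miss[:, j].any()]
    rng = np.random.default_rng(seed)
    cont_cols = [j for j in order if types[cols[j]] == "continuous"]
    cat_cols = [j for j in order if types[cols[j]] == "categorical"]

    prev = x.copy()
    history = []
    best = x.copy()
    n_iter = 0
    converged = False
    for sweep in range(max_iter):
        n_iter += 1
        for j in order:
            rows_obs = ~miss[:, j]
            others = [k for k in range(x.shape[1]) if k != j]
            X_obs = x[np.ix_(rows_obs, others)]
            y_obs = x[rows_obs, j]
            X_mis = x[np.ix_(~rows_obs, others)]
            fs = int(rng.integers(0, 2**31 - 1))
            if types[cols[j]] == "categorical":
                if np.unique(y_obs).size == 1:
                    x[~rows_obs, j] = y_obs[0]
                    continue
                forest = RandomForestClassifier(
                    n_estimators=n_trees, max_features="sqrt", random_state=fs
                )
            else:
                forest = RandomForestRegressor(
                    n_estimators=n_trees, max_features="sqrt", random_state=fs
                )
            forest.fit(X_obs, y_obs)
            x[~rows_obs, j] = forest.predict(X_mis)

        d_cont = 0.0
        if cont_cols:
            new = x[:, cont_cols]
            old = prev[:, cont_cols]
            denom = np.sum(new**2)
            d_cont = float(np.sum((new - old) ** 2) / denom) if denom > 0 else 0.0
        d_cat = 0.0
        if cat_cols:
            m = miss[:, cat_cols]
            if m.sum():
                d_cat = float(
                    np.sum(x[:, cat_cols][m] != prev[:, cat_cols][m]) / m.sum()
                )
        history.append({"continuous": d_cont, "categorical": d_cat})
        if sweep > 0:
            prev_stat = history[-2]
            if (
                d_cont > prev_stat["continuous"]
                or d_cat > prev_stat["categorical"]
            ):
                converged = True
                break  # return previous sweep's matrix
        best = x.copy()
        prev = x.copy()

    completed = pd.DataFrame(best, index=frame.index, columns=frame.columns)
    completed[~pd.DataFrame(miss, index=frame.index, columns=frame.columns)] = frame
    return ImputationResult(completed, n_iter, history, converged)


def validate_imputation(
    complete: pd.DataFrame,
    rate: float,
    seed: int = 0,
    categorical=None,
    imputer=None,
    n_trees: int = 100,
) -> ImputationAccuracy:
    """Mask cells of a fully observed matrix, impute, and score accuracy.

    NRMSE = sqrt(mean((true − imputed)²) / var(true)) over masked continuous
    cells; PFC = misclassified fraction over masked categorical cells.  An
    alternative ``imputer(frame_with_nan) -> DataFrame`` can be scored in
    place of the forest imputer.
    """
    if not np.all(np.isfinite(complete.to_numpy(dtype=float))):
        raise ValueError("validation input must be fully observed")
    rng = np.random.default_rng(seed)
    mask = rng.random(complete.shape) < rate
    # keep every row/column partially observed
    for axis in (0, 1):
        full = mask.all(axis=axis)
        if full.any():
            idx = np.flatnonzero(full)
            other = rng.integers(0, mask.shape[axis], idx.size)
            if axis == 0:
                mask[other, idx] = False
            else:
                mask[idx, other] = False
    masked = complete.copy()
    masked_vals = masked.to_numpy(dtype=float)
    masked_vals[mask] = np.nan
    masked = pd.DataFrame(masked_vals, index=complete.index, columns=complete.columns)

    if imputer is None:
        imputed = missforest_impute(
            masked, categorical=categorical, n_trees=n_trees, seed=seed
        ).completed
    else:
        imputed = imputer(masked)

    types = _column_types(complete, categorical)
    cont = np.array([types[c] == "continuous" for c in complete.columns])
    truth = complete.to_numpy(dtype=float)
    imp = imputed.to_numpy(dtype=float)

    cont_mask = mask & cont[None, :]
    if cont_mask.sum() and np.var(truth[cont_mask]) > 0:
        nrmse = float(
            np.sqrt(
                np.mean((truth[cont_mask] - imp[cont_mask]) ** 2)
                / np.var(truth[cont_mask])
            )
        )
    else:
        nrmse = float("nan")
    cat_mask = mask & ~cont[None, :]
    pfc = (
        float(np.mean(truth[cat_mask] != imp[cat_mask]))
        if cat_mask.sum()
        else float("nan")
    )
    return ImputationAccuracy(
        nrmse=nrmse,
        pfc=pfc,
        mask_description={"rate": rate, "mechanism": "MCAR", "seed": seed},
    )


def impute_dataset(
    data: TrialDataset, n_trees: int = 100, max_iter: int = 10, seed: int = 0
) -> tuple[TrialDataset, ImputationResult]:
    """Impute a trial dataset in place of its missing cells.

    Assembles the feature matrix (outcome change scores, covariates, arm),
    runs the forest imputer, converts change scores back to BDI-II values
    (clipped to [0, 63]), and rounds imputed counts/binaries to admissible
    values.  Observed cells are untouched.
    """
    frame, manifest = assemble_imputation_features(data)
    categorical = [
        c for c, m in manifest["columns"].items() if m["type"] == "categorical"
    ]
    result = missforest_impute(
        frame, categorical=categorical, n_trees=n_trees, max_iter=max_iter, seed=seed
    )
    result.manifest = manifest
    comp = result.completed

    out = data.copy()
    base = data.baseline_bdi.to_numpy(dtype=float)
    new_out = {}
    for c in data.outcomes.columns:
        raw = comp[f"chg_{c}"].to_numpy(dtype=float) + base
        obs = data.outcomes[c].to_numpy(dtype=float)
        new_out[c] = np.where(np.isfinite(obs), obs, np.clip(raw, 0.0, 63.0))
    out.outcomes = pd.DataFrame(new_out, index=data.ids)
    new_cov = {}
    for c in data.covariates.columns:
        kind = data.covariate_kinds.get(c, "continuous")
        imp = comp[c].to_numpy(dtype=float)
        if kind == "count":
            imp = np.clip(np.rint(imp), 0, None)
        elif kind == "binary":
            imp = np.rint(imp).clip(0, 1)
        obs = data.covariates[c].to_numpy(dtype=float)
        new_cov[c] = np.where(np.isfinite(obs), obs, imp)
    out.covariates = pd.DataFrame(new_cov, index=data.ids)
    if out.month3 is not None:
        m3 = comp["chg_bdi_m3"].to_numpy(dtype=float) + base
        obs = data.month3.to_numpy(dtype=float)
        out.month3 = pd.Series(
            np.where(np.isfinite(obs), obs, np.clip(m3, 0.0, 63.0)),
            index=data.ids,
            name="bdi_m3",
        )
    return out, result
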