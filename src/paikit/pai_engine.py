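"""Final moderated regression and the Personalized Advantage Index.

The selected predictors and moderators are combined into one OLS model

    outcome = b0 + Σ b_pred·x_pred + Σ b_mod·x_mod + b_arm·arm
              + Σ b_int·(x_mod × arm)

with arm coded CT=0 / IPT=1 and the arm main effect always included
(marginality).  Fivefold cross-validation, stratified by arm, yields for
every participant a prediction under each arm from a model whose training
data excluded that participant.  The signed PAI is prediction(CT) −
prediction(IPT): negative means CT is the indicated (lower-outcome) arm.

The Johnson–Neyman operation inverts the pointwise t-test on the between-arm
difference delta(m) = b_arm + b_int·m (other moderators folded in at their
sample means) to the moderator values where |delta| is significant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

__all__ = [
    "FinalModel",
    "PaiTable",
    "JNRegion",
    "fit_final_model",
    "predict_under_arm",
    "crossval_predict",
    "johnson_neyman",
]

ARM_CT = "CT"
ARM_IPT = "IPT"


@dataclass
class FinalModel:
    """Fitted moderated regression with coefficient covariance.

    ``params``/``cov`` are indexed by term name: ``const``, each predictor,
    each moderator main effect, ``arm``, and ``<moderator>:arm``
    interactions.  Arm coding: CT=0, IPT=1.
    """

    params: pd.Series
    cov: pd.DataFrame
    df_resid: int
    predictors: list
    moderators: list
    include_arm_main: bool
    arm_coding: dict = field(default_factory=lambda: {ARM_CT: 0, ARM_IPT: 1})

    def term_names(self) -> list:
        return list(self.params.index)


def _design(covariates: pd.DataFrame, arm, predictors, moderators, include_arm_main):
    arm = np.asarray(arm, dtype=float)
    cols = {"const": np.ones(len(arm))}
    for v in predictors:
        cols[v] = covariates[v].to_numpy(dtype=float)
    for v in moderators:
        cols[v] = covariates[v].to_numpy(dtype=float)
    if include_arm_main:
        cols["arm"] = arm
    for v in moderators:
        cols[f"{v}:arm"] = covariates[v].to_numpy(dtype=float) * arm
    return pd.DataFrame(cols, index=covariates.index)


def fit_final_model(
    covariates: pd.DataFrame,
    y,
    arm,
    predictors=(),
    moderators=(),
    include_arm_main: bool = True,
) -> FinalModel:
    """OLS fit of the moderated outcome regression.

    ``arm`` is numeric CT=0 / IPT=1 (or a label series which is mapped).
    Raises on rank deficiency or when n does not exceed the parameter count.
    """
    arm = _to_numeric_arm(arm)
    if not include_arm_main:
        warnings.warn(
            "arm main effect excluded; interaction coefficients are not "
            "marginality-protected",
            stacklevel=2,
        )
    X = _design(covariates, arm, list(predictors), list(moderators), include_arm_main)
    if len(X) <= X.shape[1]:
        raise ValueError("n must exceed the number of model terms")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if len(np.unique(arm)) < 2:
        raise ValueError("both arms must be present")
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    return FinalModel(
        params=fit.params,
        cov=pd.DataFrame(
            fit.cov_params(), index=X.columns, columns=X.columns
        ),
        df_resid=int(fit.df_resid),
        predictors=list(predictors),
        moderators=list(moderators),
        include_arm_main=include_arm_main,
    )


def _to_numeric_arm(arm) -> np.ndarray:
    a = pd.Series(arm)
    if a.dtype == object or str(a.dtype).startswith("category"):
        a = a.map({ARM_CT: 0, ARM_IPT: 1})
        if a.isna().any():
            raise ValueError("arm labels must be CT/IPT")
    return a.to_numpy(dtype=float)


def predict_under_arm(
    model: FinalModel, covariates: pd.DataFrame, arm_value: int
) -> np.ndarray:
    """Predicted outcome with every participant's arm set to ``arm_value``."""
    arm = np.full(len(covariates), float(arm_value))
    X = _design(
        covariates, arm, model.predictors, model.moderators, model.include_arm_main
    )
    return X[model.params.index].to_numpy() @ model.params.to_numpy()


class PaiTable(pd.DataFrame):
    """Per-participant PAI table (a plain DataFrame subclass).

    Columns: arm, pred_ct, pred_ipt, factual, counterfactual, pai_signed,
    pai_abs, pai_percentile, indicated, fold.
    """

    @property
    def _constructor(self):
        return PaiTable


def _assemble_pai(arm_labels: pd.Series, pred_ct, pred_ipt, fold_id) -> PaiTable:
    pai = np.asarray(pred_ct) - np.asarray(pred_ipt)
    is_ct = arm_labels.to_numpy() == ARM_CT
    factual = np.where(is_ct, pred_ct, pred_ipt)
    counterfactual = np.where(is_ct, pred_ipt, pred_ct)
    indicated = np.where(pai < 0, ARM_CT, np.where(pai > 0, ARM_IPT, "none"))
    tab = PaiTable(
        {
            "arm": arm_labels.to_numpy(),
            "pred_ct": pred_ct,
            "pred_ipt": pred_ipt,
            "factual": factual,
            "counterfactual": counterfactual,
            "pai_signed": pai,
            "pai_abs": np.abs(pai),
            "indicated": indicated,
            "fold": fold_id,
        },
        index=arm_labels.index,
    )
    tab["pai_percentile"] = tab["pai_abs"].rank(pct=True, method="average") * 100
    return tab


def _stratified_folds(arm: np.ndarray, k: int, rng) -> np.ndarray:
    """Near-equal random folds, stratified by arm."""
    fold = np.empty(len(arm), dtype=int)
    for a in np.unique(arm):
        idx = np.flatnonzero(arm == a)
        idx = rng.permutation(idx)
        fold[idx] = np.arange(len(idx)) % k
    return fold


def crossval_predict(
    covariates: pd.DataFrame,
    y,
    arm,
    predictors=(),
    moderators=(),
    k: int = 5,
    seed: int = 0,
    include_arm_main: bool = True,
    fold_assignment=None,
) -> PaiTable:
    """K-fold cross-validated factual/counterfactual predictions.

    Folds are random but stratified by arm so every training split keeps
    both arms; for each held-out participant the fold model predicts the
    outcome twice, with arm forced to CT and to IPT.  ``fold_assignment``
    (an integer vector in ``0..k-1``) overrides the random partition.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    arm_labels = pd.Series(arm).map(
        lambda v: v if v in (ARM_CT, ARM_IPT) else (ARM_CT if v == 0 else ARM_IPT)
    )
    arm_labels.index = covariates.index
    arm_num = _to_numeric_arm(arm_labels)
    y = np.asarray(y, dtype=float)
    if fold_assignment is not None:
        fold = np.asarray(fold_assignment, dtype=int)
        if fold.shape != (len(y),) or fold.min() < 0 or fold.max() >= k:
            raise ValueError("fold_assignment must map every row to 0..k-1")
        for f in range(k):
            if len(np.unique(arm_num[fold != f])) < 2:
                raise ValueError(f"training split for fold {f} lacks an arm")
    else:
        if min((arm_num == 0).sum(), (arm_num == 1).sum()) < k:
            raise ValueError(
                "each arm needs at least k members for stratified folds"
            )
        rng = np.random.default_rng(seed)
        for _ in range(100):
            fold = _stratified_folds(arm_num, k, rng)
            ok = all(
                len(np.unique(arm_num[fold != f])) == 2 for f in range(k)
            )
            if ok:
                break
        else:  # pragma: no cover - unreachable with stratification
            raise RuntimeError("could not build folds with both arms in training")

    pred_ct = np.empty(len(y))
    pred_ipt = np.empty(len(y))
    for f in range(k):
        train = fold != f
        test = ~train
        model = fit_final_model(
            covariates.loc[train],
            y[train],
            arm_num[train],
            predictors=predictors,
            moderators=moderators,
            include_arm_main=include_arm_main,
        )
        pred_ct[test] = predict_under_arm(model, covariates.loc[test], 0)
        pred_ipt[test] = predict_under_arm(model, covariates.loc[test], 1)
    return _assemble_pai(arm_labels, pred_ct, pred_ipt, fold)


@dataclass
class JNRegion:
    """Johnson–Neyman output for one moderator.

    ``intervals`` lists (lo, hi, favored_arm) segments of the observed
    moderator range where the between-arm difference is significant at
    ``alpha``; ``favored_arm`` is the arm with the lower predicted outcome.
    """

    moderator: str
    intervals: list
    alpha: float
    t_crit: float
    observed_range: tuple
    delta_coefs: tuple  # (d0, b): delta(m) = d0 + b*m

    def significant_at(self, m: float) -> bool:
        return any(lo <= m <= hi for lo, hi, _ in self.intervals)


def johnson_neyman(
    model: FinalModel,
    moderator: str,
    moderator_values,
    alpha: float = 0.05,
    other_moderator_means: dict | None = None,
) -> JNRegion:
    """Significance region of the between-arm difference along a moderator.

    delta(m) = b_arm + Σ_{other mods} b_int_j·mean_j + b_int·m with variance
    from the coefficient covariance; boundaries are the real roots of
    delta(m)² = t²·SE²(m), clipped to the observed moderator range.
    """
    term = f"{moderator}:arm"
    if term not in model.params.index:
        raise ValueError(f"model has no interaction term for {moderator!r}")
    if "arm" not in model.params.index:
        raise ValueError("model must include the arm main effect")
    mv = np.asarray(moderator_values, dtype=float)
    lo, hi = float(np.nanmin(mv)), float(np.nanmax(mv))

    names = list(model.params.index)
    c_fixed = np.zeros(len(names))
    c_fixed[names.index("arm")] = 1.0
    for other in model.moderators:
        if other == moderator:
            continue
        mean = (
            (other_moderator_means or {}).get(other, 0.0)
        )
        c_fixed[names.index(f"{other}:arm")] = mean
    e_int = np.zeros(len(names))
    e_int[names.index(term)] = 1.0

    beta = model.params.to_numpy()
    sigma = model.cov.to_numpy()
    d0 = float(c_fixed @ beta)
    b = float(e_int @ beta)
    var_a = float(c_fixed @ sigma @ c_fixed)
    cov_ab = float(c_fixed @ sigma @ e_int)
    var_b = float(e_int @ sigma @ e_int)
    t_crit = float(sps.t.ppf(1 - alpha / 2, model.df_resid))
    t2 = t_crit**2

    # f(m) = delta(m)^2 - t^2 SE^2(m) > 0  <=>  significant
    A = b * b - t2 * var_b
    B = 2 * (b * d0 - t2 * cov_ab)
    C = d0 * d0 - t2 * var_a

    roots = []
    if abs(A) > 1e-300:
        disc = B * B - 4 * A * C
        if disc >= 0:
            r = np.sqrt(disc)
            roots = sorted([(-B - r) / (2 * A), (-B + r) / (2 * A)])
    elif abs(B) > 1e-300:
        roots = [-C / B]

    edges = [lo] + [r for r in roots if lo < r < hi] + [hi]
    intervals = []
    for a_edge, b_edge in zip(edges[:-1], edges[1:]):
        mid = 0.5 * (a_edge + b_edge)
        f_mid = (A * mid + B) * mid + C
        if f_mid > 0:
            delta_mid = d0 + b * mid
            favored = ARM_IPT if delta_mid < 0 else ARM_CT
            if intervals and intervals[-1][1] == a_edge and intervals[-1][2] == favored:
                intervals[-1] = (intervals[-1][0], b_edge, favored)
            else:
                intervals.append((a_edge, b_edge, favored))
    return JNRegion(
        moderator=moderator,
        intervals=intervals,
        alpha=alpha,
        t_crit=t_crit,
        observed_range=(lo, hi),
        delta_coefs=(d0, b),
    )
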