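"""Stage-2 variable selection: bootstrap backward elimination.

The stage-1 survivors enter a linear model as main effects plus arm
interactions.  On each of ``n_boot`` bootstrap resamples, backward
elimination drops the least significant droppable term (largest p-value
above alpha, honouring marginality: a main effect stays while its
interaction remains, and the arm main effect and intercept are never
dropped) until every remaining term is significant.  Terms surviving in at
least ``freq_threshold`` of resamples are "robust"; a variable whose
interaction term is robust is classified as a moderator, one whose main
effect alone is robust as a predictor.  Coefficient signs among selections
are tallied to gauge stability of the direction of each effect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "backward_eliminate",
    "bootstrap_selection",
    "BootstrapSelectionReport",
]

_FORCED = ("const", "arm")


def _ols_stats(X: np.ndarray, y: np.ndarray):
    """Coefficients, p-values and kept-column mask; aliased columns are
    dropped (pivoted-QR detection) before fitting."""
    n, p = X.shape
    _, rdiag, piv = _qr_pivot(X)
    tol = max(n, p) * np.finfo(float).eps * (abs(rdiag[0]) if len(rdiag) else 1.0)
    rank = int(np.sum(np.abs(rdiag) > tol))
    keep = np.zeros(p, dtype=bool)
    keep[piv[:rank]] = True
    Xk = X[:, keep]
    coef, *_ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ coef
    dof = n - Xk.shape[1]
    if dof <= 0:
        raise ValueError("model not estimable: n <= number of terms")
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(Xk.T @ Xk)
    se = np.sqrt(np.clip(np.diag(xtx_inv) * sigma2, 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        tval = np.where(se > 0, coef / se, 0.0)
    pval = 2 * special.stdtr(dof, -np.abs(tval))
    return coef, pval, keep


def _qr_pivot(X):
    from scipy.linalg import qr

    _, r, piv = qr(X, mode="economic", pivoting=True)
    return None, np.diag(r), piv


def build_term_design(
    covariates: pd.DataFrame, arm: np.ndarray, variables
) -> pd.DataFrame:
    """Design with columns const, arm, <v> (main), <v>:arm (interaction)."""
    arm = np.asarray(arm, dtype=float)
    cols = {"const": np.ones(len(arm)), "arm": arm}
    for v in variables:
        x = covariates[v].to_numpy(dtype=float)
        cols[v] = x
        cols[f"{v}:arm"] = x * arm
    return pd.DataFrame(cols, index=covariates.index)


def backward_eliminate(
    design: pd.DataFrame,
    y,
    alpha: float = 0.05,
    forced=_FORCED,
):
    """Backward elimination at significance level ``alpha``.

    Returns ``(surviving term list, coefficient Series)``.  At each step the
    droppable term (not forced, main effect with no surviving interaction)
    with the largest p-value above alpha is removed and the model refitted.
    Aliased columns encountered on a resample are dropped first and treated
    as non-selected.
    """
    return _backward_core(
        design.to_numpy(dtype=float),
        list(design.columns),
        np.asarray(y, dtype=float),
        alpha,
        forced,
    )


def _backward_core(X_all: np.ndarray, names: list, y: np.ndarray, alpha, forced):
    forced = set(forced) & set(names)
    col = {t: j for j, t in enumerate(names)}
    terms = list(names)
    while True:
        X = X_all[:, [col[t] for t in terms]]
        coef, pval, keep = _ols_stats(X, y)
        if not keep.all():  # aliased terms: drop non-forced ones first
            aliased = [t for t, k in zip(terms, keep) if not k and t not in forced]
            if aliased:
                terms = [t for t in terms if t not in aliased]
                continue
        kept_terms = [t for t, k in zip(terms, keep) if k]
        pmap = dict(zip(kept_terms, pval))
        cmap = dict(zip(kept_terms, coef))
        interactions_alive = {
            t.split(":")[0] for t in kept_terms if t.endswith(":arm")
        }
        droppable = [
            t
            for t in kept_terms
            if t not in forced
            and not (not t.endswith(":arm") and t in interactions_alive)
        ]
        worst = None
        for t in droppable:
            if pmap[t] > alpha and (worst is None or pmap[t] > pmap[worst]):
                worst = t
        if worst is None:
            return kept_terms, pd.Series(cmap)
        terms = [t for t in kept_terms if t != worst]


@dataclass
class BootstrapSelectionReport:
    table: pd.DataFrame  # per term: frequency, n_selected, pos_fraction, neg_fraction
    robust_terms: list
    roles: dict  # variable -> 'predictor' | 'moderator'
    n_boot: int
    n_redrawn: int
    freq_threshold: float


def bootstrap_selection(
    covariates: pd.DataFrame,
    y,
    arm,
    variables,
    n_boot: int = 1000,
    alpha: float = 0.05,
    freq_threshold: float = 0.60,
    seed: int = 0,
) -> BootstrapSelectionReport:
    """Bootstrap the backward-elimination survivor set.

    ``variables`` is the stage-1 selected set; each resample (with
    replacement, original size) must contain both arms or is redrawn.
    """
    variables = list(variables)
    if not variables:
        raise ValueError("stage-1 variable set is empty")
    y = np.asarray(y, dtype=float)
    arm = np.asarray(arm, dtype=float)
    n = len(y)
    rng = np.random.default_rng(seed)
    design = build_term_design(covariates, arm, variables)
    design_np = design.to_numpy(dtype=float)
    names = list(design.columns)
    term_names = [t for t in names if t not in _FORCED]

    n_sel = {t: 0 for t in term_names}
    n_pos = {t: 0 for t in term_names}
    n_redrawn = 0
    for _ in range(n_boot):
        while True:
            idx = rng.integers(0, n, n)
            if 0 < arm[idx].sum() < n:
                break
            n_redrawn += 1
        survivors, coefs = _backward_core(
            design_np[idx], names, y[idx], alpha, _FORCED
        )
        for t in survivors:
            if t in n_sel:
                n_sel[t] += 1
                if coefs[t] > 0:
                    n_pos[t] += 1

    rows = []
    for t in term_names:
        sel = n_sel[t]
        rows.append(
            {
                "term": t,
                "frequency": sel / n_boot,
                "n_selected": sel,
                "pos_fraction": n_pos[t] / sel if sel else np.nan,
                "neg_fraction": (sel - n_pos[t]) / sel if sel else np.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("term")
    robust = [t for t in term_names if table.loc[t, "frequency"] >= freq_threshold]
    roles = {}
    for v in variables:
        if f"{v}:arm" in robust:
            roles[v] = "moderator"
        elif v in robust:
            roles[v] = "predictor"
    return BootstrapSelectionReport(
        table=table,
        robust_terms=robust,
        roles=roles,
        n_boot=n_boot,
        n_redrawn=n_redrawn,
        freq_threshold=freq_threshold,
    )
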