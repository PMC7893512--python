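"""Candidate-covariate pre-selection and variable transformation.

Covariate batteries assembled from overlapping questionnaires carry strongly
collinear members (subscales vs total scales, alternative indicators of the
same construct).  Screening computes a Pearson correlation matrix corrected
for attenuation, r*_ij = r_ij / sqrt(rel_i · rel_j), and greedily removes one
member of every pair whose corrected |r| exceeds a threshold (default 0.70).

Transforms standardize continuous variables, center discrete/binary ones,
and tame right skew in count variables with log1p (or a shifted square root
when negatives occur) before centering.  Fitted locations/scales are stored
so the identical transform can be replayed on held-out data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "attenuation_corrected_corr",
    "prune_collinear",
    "fit_transforms",
    "apply_transforms",
    "ScreeningReport",
    "TransformRecord",
]


def attenuation_corrected_corr(
    x: pd.DataFrame, reliabilities=None
) -> tuple[pd.DataFrame, list]:
    """Pairwise-complete Pearson correlations corrected for attenuation.

    Parameters
    ----------
    x : DataFrame (participants × variables), NaN allowed.
    reliabilities : mapping or array of per-variable reliabilities in (0, 1];
        default 1.0 for every variable (no correction).

    Returns
    -------
    (corrected matrix, warnings) — corrected entries can exceed |1|; they are
    capped at ±1 and each cap is recorded as a warning tuple.
    """
    cols = list(x.columns)
    if reliabilities is None:
        rel = np.ones(len(cols))
    elif isinstance(reliabilities, dict):
        rel = np.array([reliabilities.get(c, 1.0) for c in cols])
    else:
        rel = np.asarray(reliabilities, dtype=float)
    if np.any(rel <= 0) or np.any(rel > 1):
        raise ValueError("reliabilities must lie in (0, 1]")

    r = x.corr(method="pearson", min_periods=3)
    denom = np.sqrt(np.outer(rel, rel))
    corrected = r.to_numpy() / denom
    np.fill_diagonal(corrected, 1.0)
    warnings = []
    over = np.abs(corrected) > 1
    np.fill_diagonal(over, False)
    for i, j in zip(*np.nonzero(np.triu(over))):
        warnings.append((cols[i], cols[j], float(corrected[i, j])))
    corrected = np.clip(corrected, -1.0, 1.0)
    zero_var = x.std(ddof=1) == 0
    for c in x.columns[zero_var]:
        warnings.append((c, c, np.nan))
    return pd.DataFrame(corrected, index=cols, columns=cols), warnings


@dataclass
class ScreeningReport:
    corrected_corr: pd.DataFrame
    removed: list  # (removed variable, partner kept, corrected r)
    retained: list
    threshold: float
    warnings: list = field(default_factory=list)
    transforms: "TransformRecord | None" = None


def prune_collinear(
    corrected: pd.DataFrame,
    threshold: float = 0.70,
    outcome_corr: pd.Series | None = None,
    priority: list | None = None,
) -> ScreeningReport:
    """Greedy removal of collinear variables.

    Repeatedly finds the pair with the largest corrected |r| above
    ``threshold`` and drops its lower-priority member.  Priority: an explicit
    ordered list if given (earlier = keep); else larger mean |correlation|
    with the outcome; else the earlier-listed variable is kept (the "total
    scale first" convention).
    """
    cols = list(corrected.columns)
    mat = corrected.to_numpy(dtype=float).copy()
    np.fill_diagonal(mat, 0.0)
    mat = np.nan_to_num(mat, nan=0.0)
    alive = {c: True for c in cols}
    idx = {c: i for i, c in enumerate(cols)}
    if priority is not None:
        rank = {c: priority.index(c) if c in priority else len(priority) for c in cols}
    removed = []

    def keep_score(c):
        if priority is not None:
            return (-rank[c], -idx[c])
        if outcome_corr is not None:
            return (abs(float(outcome_corr.get(c, 0.0))), -idx[c])
        return (0.0, -idx[c])

    while True:
        live = [c for c in cols if alive[c]]
        sub = np.abs(mat)
        best, best_val = None, threshold
        for a in live:
            for b in live:
                if idx[a] < idx[b] and sub[idx[a], idx[b]] > best_val:
                    best, best_val = (a, b), sub[idx[a], idx[b]]
        if best is None:
            break
        a, b = best
        drop, keep = (a, b) if keep_score(a) < keep_score(b) else (b, a)
        alive[drop] = False
        removed.append((drop, keep, float(corrected.loc[drop, keep])))
    retained = [c for c in cols if alive[c]]
    return ScreeningReport(
        corrected_corr=corrected,
        removed=removed,
        retained=retained,
        threshold=threshold,
    )


@dataclass
class TransformRecord:
    """Per-variable fitted transform: skew fix + location/scale."""

    steps: dict  # name -> {"skew_fix": none|log1p|sqrt_shift, "shift": float,
    #              "center": float, "scale": float|None, "kind": str}
    skew_threshold: float

    def to_dict(self):
        return {"skew_threshold": self.skew_threshold, "steps": self.steps}

    @classmethod
    def from_dict(cls, d):
        return cls(steps=d["steps"], skew_threshold=d["skew_threshold"])


def fit_transforms(
    x: pd.DataFrame, kinds: dict, skew_threshold: float = 1.0
) -> TransformRecord:
    """Fit per-variable transforms on (training) data.

    continuous → standardize; count/discrete/binary/categorical → center;
    any non-binary variable with |sample skewness| above ``skew_threshold``
    first gets log1p (minimum ≥ 0) or a shifted square root.
    """
    steps = {}
    for c in x.columns:
        kind = kinds.get(c, "continuous")
        v = x[c].to_numpy(dtype=float)
        obs = v[np.isfinite(v)]
        if obs.size < 2:
            raise ValueError(f"variable {c!r} has <2 observed values")
        fix, shift = "none", 0.0
        if (
            kind != "binary"
            and np.ptp(obs) > 0
            and abs(stats.skew(obs, bias=False)) > skew_threshold
        ):
            if obs.min() >= 0:
                fix = "log1p"
                obs = np.log1p(obs)
            else:
                fix = "sqrt_shift"
                shift = -float(obs.min())
                obs = np.sqrt(obs + shift)
        center = float(obs.mean())
        scale = None
        if kind == "continuous":
            sd = float(obs.std(ddof=1))
            if sd == 0:
                raise ValueError(f"variable {c!r} has zero variance")
            scale = sd
        steps[c] = {
            "kind": kind,
            "skew_fix": fix,
            "shift": shift,
            "center": center,
            "scale": scale,
        }
    return TransformRecord(steps=steps, skew_threshold=skew_threshold)


def apply_transforms(x: pd.DataFrame, record: TransformRecord) -> pd.DataFrame:
    """Replay fitted transforms on (possibly new) data; exact on train."""
    out = {}
    for c in x.columns:
        step = record.steps.get(c)
        if step is None:
            out[c] = x[c]
            continue
        v = x[c].to_numpy(dtype=float)
        if step["skew_fix"] == "log1p":
            v = np.log1p(v)
        elif step["skew_fix"] == "sqrt_shift":
            v = np.sqrt(np.clip(v + step["shift"], 0.0, None))
        v = v - step["center"]
        if step["scale"] is not None:
            v = v / step["scale"]
        out[c] = v
    return pd.DataFrame(out, index=x.index)
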