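"""Null distribution of the trimmed sup-LM fluctuation statistic.

Quantiles of sup ||B_2(t)||^2/(t(1-t)) over [trim, 1-trim] were simulated
once (see scripts/make_suplm_table.py) and shipped as JSON; p-values are
interpolated bilinearly in (trim, statistic) with an exponential tail
extension beyond the highest tabulated quantile.
"""

from __future__ import annotations

import json
from functools import lru_cache
from importlib import resources

import numpy as np

__all__ = ["suplm_pvalue"]


@lru_cache(maxsize=1)
def _table():
    text = resources.files("paikit").joinpath("data/suplm_k2.json").read_text()
    tab = json.loads(text)
    trims = np.asarray(tab["trims"], dtype=float)
    probs = np.asarray(tab["probs"], dtype=float)
    quants = np.vstack([tab["quantiles"][str(t)] for t in tab["trims"]])
    return trims, probs, quants


def suplm_pvalue(stat: float, trim: float, k: int = 2) -> float:
    """Asymptotic p-value of the trimmed sup-LM statistic (k = 2 scores)."""
    if k != 2:
        raise NotImplementedError("quantile table is tabulated for k=2 only")
    if not np.isfinite(stat) or stat <= 0:
        return 1.0
    trims, probs, quants = _table()
    t = float(np.clip(trim, trims[0], trims[-1]))
    hi = int(np.searchsorted(trims, t))
    if hi == 0:
        q = quants[0]
    else:
        lo = hi - 1
        hi = min(hi, len(trims) - 1)
        w = 0.0 if trims[hi] == trims[lo] else (t - trims[lo]) / (trims[hi] - trims[lo])
        q = (1 - w) * quants[lo] + w * quants[hi]
    if stat <= q[0]:
        return 1.0
    if stat >= q[-1]:
        # exponential tail: fit log survival on the last tabulated segment
        s1, s2 = 1.0 - probs[-4], 1.0 - probs[-1]
        slope = (np.log(s2) - np.log(s1)) / (q[-1] - q[-4])
        return float(min(1.0, s2 * np.exp(slope * (stat - q[-1]))))
    cdf = float(np.interp(stat, q, probs))
    return float(1.0 - cdf)
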