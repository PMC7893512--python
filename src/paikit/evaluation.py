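"""Evaluating PAI recommendations against observed outcomes.

Because arms were randomized, participants land in their PAI-indicated or
non-indicated treatment by chance; comparing observed follow-up severity
(average-BDI scale) between those two groups estimates the value of the
recommendation.  Contrasts use Student's pooled-variance t (df = n1+n2−2)
and Cohen's d with the pooled SD, reported for the full sample, for the
top-60% |PAI| subset (those with the strongest predicted advantage), and
separately by indicated arm.  Two PAI score sets can be compared via the
correlation of signed scores and a chi-square on the 2×2 recommendation
cross-tabulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "contrast",
    "top_magnitude_subset",
    "evaluate_pai",
    "compare_pai_sets",
    "ContrastRecord",
    "EvaluationReport",
]

ARM_CT = "CT"
ARM_IPT = "IPT"


@dataclass
class ContrastRecord:
    name: str
    n1: int
    n2: int
    mean1: float
    mean2: float
    t: float
    df: int
    p: float
    d: float

    def as_dict(self) -> dict:
        return {
            "name": self.name,
            "n1": self.n1,
            "n2": self.n2,
            "mean1": self.mean1,
            "mean2": self.mean2,
            "t": self.t,
            "df": self.df,
            "p": self.p,
            "d": self.d,
        }


def contrast(values1, values2, name: str = "") -> ContrastRecord:
    """Pooled-variance two-sample t with Cohen's d.

    ``t`` is signed as group2 mean minus group1 mean over the pooled SE, so
    a positive t means group 1 (conventionally the indicated group) has the
    lower outcome.
    """
    x1 = np.asarray(values1, dtype=float)
    x2 = np.asarray(values2, dtype=float)
    n1, n2 = len(x1), len(x2)
    if min(n1, n2) < 2:
        raise ValueError("both groups need >= 2 observations")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / df
    se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    diff = x2.mean() - x1.mean()
    t = diff / se if se > 0 else 0.0
    p = float(2 * sps.t.sf(abs(t), df)) if se > 0 else 1.0
    d = diff / np.sqrt(sp2) if sp2 > 0 else 0.0
    return ContrastRecord(
        name=name,
        n1=n1,
        n2=n2,
        mean1=float(x1.mean()),
        mean2=float(x2.mean()),
        t=float(t),
        df=df,
        p=p,
        d=float(d),
    )


def top_magnitude_subset(pai_table: pd.DataFrame, fraction: float = 0.60) -> pd.Index:
    """Participants with the highest ``fraction`` of |PAI| scores.

    Keeps the ceil(fraction·n) largest |PAI|; boundary ties are broken by
    participant id (earlier id kept).
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must lie in (0, 1]")
    n_keep = ceil(fraction * len(pai_table))
    order = pai_table["pai_abs"].sort_values(
        ascending=False, kind="stable"
    )  # stable sort: ties keep id order
    return order.index[:n_keep]


@dataclass
class EvaluationReport:
    contrasts: dict = field(default_factory=dict)  # name -> ContrastRecord
    skipped: dict = field(default_factory=dict)  # name -> reason
    subset_definition: dict = field(default_factory=dict)
    n_ties_excluded: int = 0

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.as_dict() for c in self.contrasts.values()]).set_index(
            "name"
        )

    def text_table(self) -> str:
        lines = [
            f"{'contrast':<28}{'n1':>5}{'n2':>5}{'mean1':>8}{'mean2':>8}"
            f"{'t':>7}{'df':>5}{'p':>8}{'d':>7}"
        ]
        for c in self.contrasts.values():
            lines.append(
                f"{c.name:<28}{c.n1:>5}{c.n2:>5}{c.mean1:>8.1f}{c.mean2:>8.1f}"
                f"{c.t:>7.2f}{c.df:>5}{c.p:>8.3f}{c.d:>7.2f}"
            )
        for name, reason in self.skipped.items():
            lines.append(f"{name:<28}skipped: {reason}")
        return "\n".join(lines)


def _add_contrast(report, name, g1, g2):
    if min(len(g1), len(g2)) < 2:
        report.skipped[name] = f"group sizes {len(g1)}/{len(g2)} too small"
        return
    report.contrasts[name] = contrast(g1, g2, name=name)


def evaluate_pai(
    pai_table: pd.DataFrame,
    observed_avg_bdi: pd.Series,
    top_fraction: float = 0.60,
) -> EvaluationReport:
    """Full battery of indicated-vs-non-indicated contrasts.

    Contrasts: (a) indicated vs non-indicated, full sample; (b) within the
    top-|PAI| subset; (c)/(d) received-indicated vs received-other among
    CT-indicated and IPT-indicated participants; (e) c and d within the top
    subset.  Participants with signed PAI exactly 0 are excluded (logged).
    """
    tab = pai_table.join(observed_avg_bdi.rename("observed"))
    ties = tab["indicated"] == "none"
    report = EvaluationReport(
        n_ties_excluded=int(ties.sum()),
        subset_definition={"top_fraction": top_fraction},
    )
    tab = tab[~ties]
    got_indicated = tab["arm"] == tab["indicated"]

    _add_contrast(
        report,
        "indicated_vs_non",
        tab.loc[got_indicated, "observed"],
        tab.loc[~got_indicated, "observed"],
    )
    top_ids = top_magnitude_subset(tab, top_fraction)
    top = tab.loc[top_ids]
    top_got = top["arm"] == top["indicated"]
    _add_contrast(
        report,
        "indicated_vs_non_top",
        top.loc[top_got, "observed"],
        top.loc[~top_got, "observed"],
    )
    for arm_label, key in ((ARM_CT, "ct_indicated"), (ARM_IPT, "ipt_indicated")):
        for frame, suffix in ((tab, ""), (top, "_top")):
            sub = frame[frame["indicated"] == arm_label]
            _add_contrast(
                report,
                f"{key}{suffix}",
                sub.loc[sub["arm"] == arm_label, "observed"],
                sub.loc[sub["arm"] != arm_label, "observed"],
            )
    return report


@dataclass
class PaiAgreement:
    correlation: float
    crosstab: pd.DataFrame
    chi2: float
    chi2_p: float
    agreement_overall: float
    agreement_by_arm: dict


def compare_pai_sets(pai_a: pd.DataFrame, pai_b: pd.DataFrame) -> PaiAgreement:
    """Agreement between two PAI score sets on their shared participants.

    Pearson correlation of signed PAIs plus a chi-square test on the 2×2
    indicated-arm cross-tabulation (no continuity correction).
    """
    common = pai_a.index.intersection(pai_b.index)
    if len(common) < 3:
        raise ValueError("need >= 3 overlapping participants")
    a = pai_a.loc[common]
    b = pai_b.loc[common]
    if a["pai_signed"].std(ddof=1) == 0 or b["pai_signed"].std(ddof=1) == 0:
        raise ValueError("a PAI score set has zero variance")
    corr = float(np.corrcoef(a["pai_signed"], b["pai_signed"])[0, 1])
    crosstab = pd.crosstab(a["indicated"], b["indicated"]).reindex(
        index=[ARM_CT, ARM_IPT], columns=[ARM_CT, ARM_IPT], fill_value=0
    )
    chi2, p, _, _ = sps.chi2_contingency(crosstab.to_numpy(), correction=False)
    agree = a["indicated"].to_numpy() == b["indicated"].to_numpy()
    by_arm = {}
    for arm_label in (ARM_CT, ARM_IPT):
        m = a["indicated"] == arm_label
        by_arm[arm_label] = float(agree[m.to_numpy()].mean()) if m.any() else np.nan
    return PaiAgreement(
        correlation=corr,
        crosstab=crosstab,
        chi2=float(chi2),
        chi2_p=float(p),
        agreement_overall=float(agree.mean()),
        agreement_by_arm=by_arm,
    )
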