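"""Stage-1 variable selection: model-based recursive-partitioning forest.

Every tree fits the treatment regression ``outcome ~ intercept + arm`` in
each node and asks, for a random subset of candidate covariates, whether the
node model's per-observation score contributions fluctuate systematically
along a covariate (parameter instability).  Numeric covariates use the
trimmed sup-LM statistic over the covariate's sort order; categorical ones a
chi-square on per-level score sums.  When the Bonferroni-adjusted minimum
p-value beats the split alpha, the node splits on the winning covariate at
the point minimising the summed residual sum of squares of the two child
models, subject to a minimum child size.

A forest of such trees on bootstrap resamples yields permutation variable
importances (out-of-bag MSE with a covariate permuted minus with real
values).  Variables are ranked by importance; the selection threshold is the
absolute importance of the lowest-ranking variable, and variables strictly
above it go forward to stage 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special

from ._suplm import suplm_pvalue

__all__ = [
    "MobConfig",
    "MobNode",
    "MobTree",
    "MobForest",
    "ImportanceReport",
    "fit_node_model",
    "instability_test",
    "grow_tree",
    "fit_forest",
    "importance",
]


@dataclass
class MobConfig:
    n_trees: int = 10000
    alpha_split: float = 0.10
    min_node: int = 15
    mtry: int | None = None  # default floor(sqrt(p))
    bootstrap: bool = True
    bonferroni: bool = True
    seed: int = 0

    def validate(self, p: int) -> None:
        if not 0 < self.alpha_split < 1:
            raise ValueError("alpha_split must lie in (0,1)")
        if self.min_node < 2:
            raise ValueError("min_node must be >= 2")
        m = self.mtry if self.mtry is not None else max(1, int(np.sqrt(p)))
        if not 1 <= m <= p:
            raise ValueError("mtry out of range")


class SingleArmNode(ValueError):
    """Raised when a node holds observations from one arm only."""


def fit_node_model(y: np.ndarray, arm: np.ndarray):
    """Least-squares fit of ``y ~ 1 + arm`` with per-observation scores.

    Returns ``(intercept, arm_coef, scores)`` where ``scores`` is the n×2
    matrix of estimating-function contributions (each column sums to zero at
    the fit).  Raises :class:`SingleArmNode` when only one arm is present.
    """
    y = np.asarray(y, dtype=float)
    a = np.asarray(arm, dtype=float)
    n1 = int(a.sum())
    n0 = len(a) - n1
    if n0 < 2 or n1 < 2:
        raise SingleArmNode("both arms need >=2 observations")
    m0 = y[a == 0].mean()
    m1 = y[a == 1].mean()
    intercept, arm_coef = m0, m1 - m0
    resid = y - (intercept + arm_coef * a)
    scores = np.column_stack([resid, resid * a])
    return intercept, arm_coef, scores


def instability_test(
    scores: np.ndarray,
    variable: np.ndarray,
    kind: str = "numeric",
    min_node: int = 15,
) -> float:
    """Parameter-instability p-value for one candidate partitioning variable.

    Numeric/ordinal variables: trimmed sup-LM over the cumulative score
    process on the variable's sort order, evaluated only at boundaries
    between distinct values that leave ``min_node`` observations on each
    side.  Categorical variables: chi-square on per-level score sums with
    k·(levels−1) degrees of freedom.  Constant variables return p = 1.
    """
    s = np.asarray(scores, dtype=float)
    v = np.asarray(variable, dtype=float)
    if np.ptp(v[np.isfinite(v)]) == 0:
        return 1.0
    info = s.T @ s / len(s)
    try:
        info_inv = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return 1.0
    return _instability_core(s, info_inv, v, kind, min_node)


def _instability_core(s, info_inv, v, kind, min_node) -> float:
    n, k = s.shape

    if kind == "categorical":
        levels = np.unique(v)
        stat = 0.0
        for lev in levels:
            m = v == lev
            sc = s[m].sum(axis=0) / np.sqrt(n)
            stat += float(sc @ info_inv @ sc) * n / m.sum()
        df = k * (len(levels) - 1)
        return float(special.chdtrc(df, stat))

    order = np.argsort(v, kind="stable")
    vs = v[order]
    cum = np.cumsum(s[order], axis=0) / np.sqrt(n)
    i = np.arange(1, n)  # process index: first i observations on the left
    boundary = vs[1:] != vs[:-1]
    admissible = boundary & (i >= min_node) & (n - i >= min_node)
    if not admissible.any():
        return 1.0
    t = i[admissible] / n
    c = cum[:-1][admissible]
    quad = np.einsum("ij,jk,ik->i", c, info_inv, c)
    stat = float(np.max(quad / (t * (1 - t))))
    trim = min_node / n
    return suplm_pvalue(stat, trim, k=k)


@dataclass
class MobNode:
    sample_idx: np.ndarray
    intercept: float
    arm_coef: float
    p_values: dict = field(default_factory=dict)
    split_var: int | None = None  # column index into the full covariate matrix
    split_point: float | None = None
    left: "MobNode | None" = None
    right: "MobNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None


@dataclass
class MobTree:
    root: MobNode
    candidate_vars: np.ndarray  # column indices available to this tree

    def predict(self, X: np.ndarray, arm: np.ndarray) -> np.ndarray:
        out = np.empty(len(X))
        stack = [(self.root, np.arange(len(X)))]
        while stack:
            node, rows = stack.pop()
            if rows.size == 0:
                continue
            if node.is_leaf:
                out[rows] = node.intercept + node.arm_coef * arm[rows]
            else:
                go_left = X[rows, node.split_var] <= node.split_point
                stack.append((node.left, rows[go_left]))
                stack.append((node.right, rows[~go_left]))
        return out

    def depth(self) -> int:
        def d(node):
            return 0 if node.is_leaf else 1 + max(d(node.left), d(node.right))

        return d(self.root)

    def n_splits(self) -> int:
        def c(node):
            return 0 if node.is_leaf else 1 + c(node.left) + c(node.right)

        return c(self.root)

    def dump(self, feature_names=None) -> str:
        """Indented text rendering of the tree's splits and leaf models."""
        lines = []

        def name(j):
            return feature_names[j] if feature_names is not None else f"x[{j}]"

        def walk(node, depth):
            pad = "  " * depth
            model = (
                f"n={len(node.sample_idx)} "
                f"intercept={node.intercept:.3f} arm={node.arm_coef:+.3f}"
            )
            if node.is_leaf:
                lines.append(f"{pad}* leaf {model}")
            else:
                lines.append(
                    f"{pad}+ split {name(node.split_var)}"
                    f" <= {node.split_point:.4g} ({model})"
                )
                walk(node.left, depth + 1)
                walk(node.right, depth + 1)

        walk(self.root, 0)
        return "\n".join(lines)

    def split_vars(self) -> set:
        out = set()

        def walk(node):
            if not node.is_leaf:
                out.add(node.split_var)
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return out


def _node_fit(y, arm):
    """Node model with a mean-only fallback for single-arm nodes."""
    try:
        return (*fit_node_model(y, arm)[:2], True)
    except SingleArmNode:
        return float(np.mean(y)), 0.0, False


def _best_split(v, y, arm, min_node):
    """Scan admissible split points of one variable; returns
    (split_point, total child RSS) or None.  RSS comes from refitting
    ``y ~ 1 + arm`` (per-arm means) in each child."""
    order = np.argsort(v, kind="stable")
    vs, ys, as_ = v[order], y[order], arm[order]
    n = len(vs)
    i = np.arange(1, n)
    boundary = vs[1:] != vs[:-1]
    admissible = boundary & (i >= min_node) & (n - i >= min_node)
    if not admissible.any():
        return None
    y2 = np.cumsum(ys**2)
    s1 = np.cumsum(ys * as_)
    n1 = np.cumsum(as_)
    s0 = np.cumsum(ys) - s1
    n0 = np.arange(1, n + 1) - n1

    def group_fit(sa, na, sb, nb, yy):
        fit = np.zeros_like(yy)
        va = na > 0
        fit[va] += sa[va] ** 2 / na[va]
        vb = nb > 0
        fit[vb] += sb[vb] ** 2 / nb[vb]
        return yy - fit

    left_rss = group_fit(s0[:-1], n0[:-1], s1[:-1], n1[:-1], y2[:-1])
    right_rss = group_fit(
        s0[-1] - s0[:-1],
        n0[-1] - n0[:-1],
        s1[-1] - s1[:-1],
        n1[-1] - n1[:-1],
        y2[-1] - y2[:-1],
    )
    total = left_rss + right_rss
    total[~admissible] = np.inf
    best = int(np.argmin(total))  # argmin takes the first = smaller split point
    point = 0.5 * (vs[best] + vs[best + 1])
    return point, float(total[best])


def grow_tree(
    X: np.ndarray,
    y: np.ndarray,
    arm: np.ndarray,
    candidates: np.ndarray,
    kinds: list,
    config: MobConfig,
    sample_idx: np.ndarray | None = None,
) -> MobTree:
    """Grow one model-based recursive-partitioning tree.

    ``X``/``y``/``arm`` are the tree's (already resampled) data; ``kinds``
    maps every column of ``X`` to 'numeric' or 'categorical'.
    """
    if sample_idx is None:
        sample_idx = np.arange(len(y))

    def build(rows: np.ndarray) -> MobNode:
        yy, aa = y[rows], arm[rows]
        intercept, coef, ok = _node_fit(yy, aa)
        node = MobNode(sample_idx=sample_idx[rows], intercept=intercept, arm_coef=coef)
        if not ok or len(rows) < 2 * config.min_node:
            return node
        _, _, scores = fit_node_model(yy, aa)
        info = scores.T @ scores / len(scores)
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            return node
        pvals = {}
        for j in candidates:
            v = X[rows, j]
            if v[0] == v[-1] and np.ptp(v) == 0:
                continue
            pvals[int(j)] = _instability_core(
                scores, info_inv, v, kinds[j], config.min_node
            )
        node.p_values = pvals
        if not pvals:
            return node
        n_tested = len(pvals)
        winner = min(pvals, key=lambda j: (pvals[j], j))
        p_adj = pvals[winner] * n_tested if config.bonferroni else pvals[winner]
        if p_adj >= config.alpha_split:
            return node
        found = _best_split(X[rows, winner], yy, aa, config.min_node)
        if found is None:
            return node
        point, _ = found
        go_left = X[rows, winner] <= point
        node.split_var = int(winner)
        node.split_point = float(point)
        node.left = build(rows[go_left])
        node.right = build(rows[~go_left])
        return node

    return MobTree(root=build(np.arange(len(y))), candidate_vars=np.asarray(candidates))


@dataclass
class MobForest:
    trees: list
    oob_sets: list  # row indices (into the training data) out of bag per tree
    feature_names: list
    kinds: list
    config: MobConfig


@dataclass
class ImportanceReport:
    table: pd.DataFrame  # index: variable, columns: importance, rank
    threshold: float
    selected: list
    undefined: list


def _resolve_kinds(feature_names, kind_map):
    kinds = []
    for name in feature_names:
        k = (kind_map or {}).get(name, "continuous")
        kinds.append("categorical" if k in ("binary", "categorical") else "numeric")
    return kinds


def fit_forest(
    X: pd.DataFrame,
    y,
    arm,
    config: MobConfig | None = None,
    kind_map: dict | None = None,
) -> MobForest:
    """Fit a forest of MOB trees on bootstrap resamples.

    Each tree draws a bootstrap sample (when ``config.bootstrap``) and a
    random subset of ``mtry`` covariates available for all its splits.
    """
    config = config or MobConfig()
    names = list(X.columns)
    p = len(names)
    config.validate(p)
    kinds = _resolve_kinds(names, kind_map)
    arr = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    av = np.asarray(arm, dtype=float)
    n = len(yv)
    mtry = config.mtry if config.mtry is not None else max(1, int(np.sqrt(p)))
    rng = np.random.default_rng(config.seed)

    trees, oob_sets = [], []
    for _ in range(config.n_trees):
        cand = np.sort(rng.choice(p, size=mtry, replace=False))
        if config.bootstrap:
            idx = rng.integers(0, n, n)
            oob = np.setdiff1d(np.arange(n), idx)
        else:
            idx = np.arange(n)
            oob = np.arange(n)
        tree = grow_tree(
            arr[idx], yv[idx], av[idx], cand, kinds, config, sample_idx=idx
        )
        trees.append(tree)
        oob_sets.append(oob)
    return MobForest(trees, oob_sets, names, kinds, config)


def importance(
    forest: MobForest, X: pd.DataFrame, y, arm, seed: int | None = None
) -> ImportanceReport:
    """Permutation variable importance with the lowest-rank threshold rule.

    For every tree and every covariate available to it, the out-of-bag MSE
    with that covariate's values permuted minus the MSE with real values is
    averaged over trees.  The selection threshold is the absolute importance
    of the lowest-ranking variable; selected = strictly above threshold.
    """
    arr = X.to_numpy(dtype=float)
    yv = np.asarray(y, dtype=float)
    av = np.asarray(arm, dtype=float)
    p = arr.shape[1]
    rng = np.random.default_rng(forest.config.seed + 1 if seed is None else seed)

    sums = np.zeros(p)
    counts = np.zeros(p, dtype=int)
    for tree, oob in zip(forest.trees, forest.oob_sets):
        if oob.size < 2:
            continue
        Xo, yo, ao = arr[oob], yv[oob], av[oob]
        base_err = float(np.mean((tree.predict(Xo, ao) - yo) ** 2))
        used = tree.split_vars()
        for j in tree.candidate_vars:
            if j not in used:
                counts[j] += 1  # permuting an unused variable changes nothing
                continue
            Xp = Xo.copy()
            Xp[:, j] = rng.permutation(Xp[:, j])
            perm_err = float(np.mean((tree.predict(Xp, ao) - yo) ** 2))
            sums[j] += perm_err - base_err
            counts[j] += 1

    imp = np.full(p, np.nan)
    nonzero = counts > 0
    imp[nonzero] = sums[nonzero] / counts[nonzero]
    names = forest.feature_names
    undefined = [names[j] for j in range(p) if not nonzero[j]]
    defined = [(names[j], imp[j]) for j in range(p) if nonzero[j]]
    table = pd.DataFrame(defined, columns=["variable", "importance"]).set_index(
        "variable"
    )
    table["rank"] = table["importance"].rank(ascending=False, method="first").astype(int)
    table = table.sort_values("rank")
    threshold = float(abs(table["importance"].iloc[-1])) if len(table) else float("nan")
    selected = [v for v in table.index if table.loc[v, "importance"] > threshold]
    return ImportanceReport(
        table=table, threshold=threshold, selected=selected, undefined=undefined
    )
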